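"""The two statistical tests: a permutation test for local hyper- or
hypomutation of regions versus their flanks, and a chi-squared comparison
of two conditions (region sets or tumor types).

The permutation test re-positions every mapped mutation uniformly at
random within its own window and asks how often the permuted number of
mutations inside the target intervals reaches the observed number. Because
each mutation lands in its window's target independently with probability
q_w = target_length / window_length, a permutation's target count is the
sum of independent Binomial(n_w, q_w) draws over windows; the test samples
that distribution directly, which is exactly the distribution of the
re-positioning procedure and is seeded for bit-reproducibility.

The p-value is the plain fraction of permutations meeting the criterion
(>= observed for hypermutation, <= for hypomutation). When no permutation
reaches it, the result is flagged as a lower bound ("p < 1/n_permutations").
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import DataError, UndefinedTestError
from .region_windows import (
    MappedMutations,
    Window,
    map_mutations,
    mutation_matches_class,
    parse_class_filter,
)


@dataclass
class PermutationResult:
    """Outcome of the local-enrichment permutation test."""

    mode: str                     # "hyper" or "hypo"
    observed_in_target: int
    n_mapped: int
    n_permutations: int
    p: float                      # plain fraction k / n_permutations
    p_lower_bound_flag: bool      # True when k == 0: report p < 1/n_permutations
    seed: int | None
    class_filter: str

    @property
    def p_display(self) -> str:
        if self.p_lower_bound_flag:
            return f"< {1.0 / self.n_permutations:g}"
        return f"{self.p:g}"

    def to_dict(self) -> dict:
        return {
            "schema": {"name": "PermutationResult", "version": 1},
            "mode": self.mode,
            "observed_in_target": self.observed_in_target,
            "n_mapped": self.n_mapped,
            "n_permutations": self.n_permutations,
            "p": self.p,
            "p_display": self.p_display,
            "p_lower_bound_flag": self.p_lower_bound_flag,
            "seed": self.seed,
            "class_filter": self.class_filter,
        }


def permutation_test(
    windows: Sequence[Window] | MappedMutations,
    mutations=None,
    mode: str = "hyper",
    n_permutations: int = 10_000,
    class_filter: str | None = None,
    seed: int | None = None,
    collapse_complement: bool = True,
) -> PermutationResult:
    """Permutation test for local enrichment of mutations in target regions.

    ``windows`` may be a list of windows (then ``mutations`` is mapped onto
    them) or an already-mapped :class:`MappedMutations`. ``mode`` selects
    hypermutation (permuted count >= observed) or hypomutation (<=).
    """
    if mode not in ("hyper", "hypo"):
        raise DataError(f"mode must be 'hyper' or 'hypo', got {mode!r}")
    if n_permutations < 1:
        raise DataError("n_permutations must be >= 1")
    if isinstance(windows, MappedMutations):
        mapped = windows
    else:
        if mutations is None:
            raise DataError("mutations are required when windows are not pre-mapped")
        mapped = map_mutations(mutations, windows)

    flt = parse_class_filter(class_filter)
    per_window_n: dict[Window, int] = {}
    observed = 0
    n_pass = 0
    for m, w, off in mapped:
        if not mutation_matches_class(m, flt, collapse_complement):
            continue
        n_pass += 1
        per_window_n[w] = per_window_n.get(w, 0) + 1
        if w.contains_offset_in_target(off):
            observed += 1
    if n_pass == 0:
        raise UndefinedTestError("no mapped mutations pass the class filter")

    ns = np.array(list(per_window_n.values()), dtype=np.int64)
    qs = np.array(
        [w.target_length / w.length for w in per_window_n], dtype=float
    )
    rng = np.random.default_rng(seed)
    permuted = rng.binomial(ns, qs, size=(n_permutations, len(ns))).sum(axis=1)
    if mode == "hyper":
        k = int((permuted >= observed).sum())
    else:
        k = int((permuted <= observed).sum())
    return PermutationResult(
        mode=mode,
        observed_in_target=observed,
        n_mapped=n_pass,
        n_permutations=n_permutations,
        p=k / n_permutations,
        p_lower_bound_flag=(k == 0),
        seed=seed,
        class_filter=class_filter or "all",
    )


@dataclass(frozen=True)
class ContingencyInput:
    """Per-base mutation rates for two conditions: flanks (f) and targets (r)."""

    f1: float
    r1: float
    f2: float
    r2: float

    def __post_init__(self) -> None:
        vals = (self.f1, self.r1, self.f2, self.r2)
        if any(v < 0 for v in vals):
            raise DataError("per-base rates must be non-negative")
        if not any(v > 0 for v in vals):
            raise DataError("at least one per-base rate must be positive")

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.f1, self.r1], [self.f2, self.r2]], dtype=float)


@dataclass
class ComparisonResult:
    """Pearson chi-squared test of independence on the 2x2 rate table."""

    chi2: float
    dof: int
    p: float
    table: np.ndarray

    def to_dict(self) -> dict:
        return {
            "schema": {"name": "ComparisonResult", "version": 1},
            "chi2": self.chi2,
            "dof": self.dof,
            "p": self.p,
            "table": self.table,
        }


def chi2_comparison(input: ContingencyInput) -> ComparisonResult:
    """Chi-squared test of independence on C = [[f1, r1], [f2, r2]].

    No continuity correction; df = 1. Rates are used exactly as given
    (per-base averages, not rescaled counts).
    """
    table = input.table
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise UndefinedTestError(
            "chi-squared test undefined: a row or column of the table sums to zero"
        )
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return ComparisonResult(chi2=float(chi2), dof=int(dof), p=float(p), table=table)


def rate_inputs(mapped_1: MappedMutations,
                mapped_2: MappedMutations,
                class_filter: str | None = None,
                collapse_complement: bool = True) -> ContingencyInput:
    """Per-base mutation rates in targets (r_n) and flanks (f_n) of two conditions."""
    flt = parse_class_filter(class_filter)

    def rates(mapped: MappedMutations) -> tuple[float, float]:
        target_bp = sum(w.target_length for w in mapped.windows)
        flank_bp = sum(w.length - w.target_length for w in mapped.windows)
        if target_bp == 0:
            raise DataError("total target length is zero")
        if flank_bp == 0:
            raise DataError(
                "total flank length is zero (half_width equals the target half-size)"
            )
        in_target = 0
        n = 0
        for m, w, off in mapped:
            if not mutation_matches_class(m, flt, collapse_complement):
                continue
            n += 1
            if w.contains_offset_in_target(off):
                in_target += 1
        return (n - in_target) / flank_bp, in_target / target_bp

    f1, r1 = rates(mapped_1)
    f2, r2 = rates(mapped_2)
    return ContingencyInput(f1=f1, r1=r1, f2=f2, r2=r2)
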