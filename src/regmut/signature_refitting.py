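"""Constrained signature refitting on region-restricted spectra.

Exposures e solve the quadratic program

    minimize  || m - S e ||^2    subject to  e >= 0,  sum(e) = 1,

where m is the observed 96-channel fraction vector and S the (optionally
region-adjusted) signature matrix. The problem is convex; it is solved by
an exact active-set method on the KKT system (drop negative exposures,
re-admit signatures with a negative reduced gradient), with a scipy SLSQP
fallback should the active set fail to settle. The unweighted squared
error on the 96 fractions is used throughout.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DataError
from .io_formats import (
    MutationDataset,
    ReferenceGenome,
    RegionSet,
    SignatureCatalog,
)
from .region_windows import intersect_mutations
from .trinuc_context import (
    TrinucSpectrum,
    adjust_catalog,
    correction_factors,
    genome_frequencies,
    spectrum,
    trinuc_frequencies,
)

_ZERO_TOL = 1e-11


def solve_simplex_lsq(S: np.ndarray, m: np.ndarray,
                      max_iter: int | None = None) -> np.ndarray:
    """Minimise ||m - S e||^2 over the probability simplex.

    Deterministic active-set solver on the KKT system of the equality-
    constrained subproblems. Exact (to linear-algebra precision) for
    non-degenerate problems.
    """
    n_channels, K = S.shape
    if m.shape != (n_channels,):
        raise DataError("spectrum / signature-matrix shape mismatch")
    if K == 1:
        return np.array([1.0])
    G = S.T @ S
    b = S.T @ m
    if max_iter is None:
        max_iter = 50 * K + 100

    def solve_support(support: np.ndarray) -> tuple[np.ndarray, float]:
        k = support.size
        A = np.zeros((k + 1, k + 1))
        A[:k, :k] = G[np.ix_(support, support)]
        A[:k, k] = 1.0
        A[k, :k] = 1.0
        rhs = np.concatenate([b[support], [1.0]])
        sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        return sol[:k], float(sol[k])

    support = np.arange(K)
    e = np.zeros(K)
    for _ in range(max_iter):
        e_s, lam = solve_support(support)
        if e_s.min() < -_ZERO_TOL:
            # drop the most negative exposure from the support
            drop = int(np.argmin(e_s))
            support = np.delete(support, drop)
            if support.size == 0:  # numerically degenerate; bail to fallback
                return _slsqp_fallback(S, m)
            continue
        e = np.zeros(K)
        e[support] = np.clip(e_s, 0.0, None)
        # KKT: for zero exposures the reduced gradient must be non-negative
        grad = G @ e - b
        excluded = np.setdiff1d(np.arange(K), support, assume_unique=True)
        if excluded.size:
            reduced = grad[excluded] + lam
            worst = int(np.argmin(reduced))
            if reduced[worst] < -1e-9:
                support = np.sort(np.append(support, excluded[worst]))
                continue
        total = e.sum()
        if not np.isfinite(total) or total <= 0:
            return _slsqp_fallback(S, m)
        return e / total
    return _slsqp_fallback(S, m)


def _slsqp_fallback(S: np.ndarray, m: np.ndarray) -> np.ndarray:
    from scipy.optimize import minimize

    K = S.shape[1]

    def fun(e):
        r = S @ e - m
        return float(r @ r)

    def jac(e):
        return 2.0 * S.T @ (S @ e - m)

    res = minimize(
        fun,
        np.full(K, 1.0 / K),
        jac=jac,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * K,
        constraints=[{"type": "eq", "fun": lambda e: e.sum() - 1.0,
                      "jac": lambda e: np.ones(K)}],
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    e = np.clip(res.x, 0.0, None)
    total = e.sum()
    if total <= 0:
        raise DataError("signature refitting failed to produce a feasible solution")
    return e / total


@dataclass
class ExposureVector:
    """Refitting output: simplex-constrained exposures plus the fit residual."""

    signature_ids: tuple[str, ...]
    exposures: np.ndarray
    residual: float          # squared distance between m and the fitted mixture
    n_mutations: int

    def __post_init__(self) -> None:
        e = np.asarray(self.exposures, dtype=float)
        if e.shape != (len(self.signature_ids),):
            raise DataError("exposures / signature ids length mismatch")
        if (e < 0).any() or abs(e.sum() - 1.0) > 1e-6:
            raise DataError("exposures must be non-negative and sum to one")
        self.exposures = e

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.signature_ids, self.exposures.tolist()))

    def as_percentages(self) -> dict[str, float]:
        return {k: 100.0 * v for k, v in self.as_dict().items()}

    def to_dict(self) -> dict:
        return {
            "schema": {"name": "ExposureVector", "version": 1},
            "signature_ids": list(self.signature_ids),
            "exposures": self.as_dict(),
            "exposures_percent": self.as_percentages(),
            "residual": self.residual,
            "n_mutations": self.n_mutations,
        }


@dataclass
class CohortExposures:
    """Per-donor exposures plus the cohort mean and distribution summaries."""

    signature_ids: tuple[str, ...]
    donor_ids: tuple[str, ...]
    per_donor: tuple[ExposureVector, ...]
    mean_exposures: np.ndarray
    summaries: dict[str, dict[str, float]]   # id -> min/q1/median/q3/max
    excluded_donors: dict[str, int]          # donor -> in-region count below cutoff
    min_mutations: int

    def mean_as_dict(self) -> dict[str, float]:
        return dict(zip(self.signature_ids, self.mean_exposures.tolist()))

    def to_dict(self) -> dict:
        return {
            "schema": {"name": "CohortExposures", "version": 1},
            "signature_ids": list(self.signature_ids),
            "donor_ids": list(self.donor_ids),
            "per_donor": [v.to_dict() for v in self.per_donor],
            "mean_exposures": self.mean_as_dict(),
            "mean_exposures_percent": {
                k: 100.0 * v for k, v in self.mean_as_dict().items()
            },
            "summaries": self.summaries,
            "excluded_donors": self.excluded_donors,
            "min_mutations": self.min_mutations,
        }


def refit(spectrum: TrinucSpectrum, catalog: SignatureCatalog) -> ExposureVector:
    """Fit exposures for one spectrum against a signature catalog."""
    m = spectrum.fractions
    if m is None:
        raise DataError("cannot refit an empty spectrum")
    if tuple(catalog.channel_order) != tuple(spectrum.channel_order):
        raise DataError("catalog and spectrum channel orders do not match")
    S = catalog.matrix
    e = solve_simplex_lsq(S, m)
    residual = float(np.sum((m - S @ e) ** 2))
    return ExposureVector(
        signature_ids=catalog.ids,
        exposures=e,
        residual=residual,
        n_mutations=spectrum.total,
    )


def _summaries(ids: tuple[str, ...], mat: np.ndarray) -> dict[str, dict[str, float]]:
    out = {}
    for k, sig_id in enumerate(ids):
        col = mat[:, k]
        q1, med, q3 = np.percentile(col, [25, 50, 75])
        out[sig_id] = {
            "min": float(col.min()),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "max": float(col.max()),
        }
    return out


def refit_regions(
    dataset: MutationDataset,
    region_set: RegionSet,
    reference: ReferenceGenome,
    catalog: SignatureCatalog,
    adjust: bool = True,
    per_donor: bool = False,
    min_mutations: int = 1,
) -> ExposureVector | CohortExposures:
    """Region-restricted refitting pipeline.

    Intersect the catalog of mutations with the region set, build the
    spectrum, optionally region-adjust every signature, and refit — either
    pooled over all donors or per donor (donors with fewer in-region
    mutations than ``min_mutations`` are excluded from fitting but
    reported). The cohort average is the arithmetic mean of per-donor
    exposure vectors.
    """
    region_set.validate_against(reference)
    muts = intersect_mutations(dataset, region_set)
    if not muts:
        raise DataError("no mutations fall inside the region set")
    if adjust:
        region_freqs = trinuc_frequencies(region_set, reference)
        genome_freqs = genome_frequencies(reference)
        factors = correction_factors(region_freqs, genome_freqs)
        catalog = adjust_catalog(catalog, factors)
    if not per_donor:
        return refit(spectrum(muts, reference), catalog)

    by_donor: dict[str, list] = {d: [] for d in dataset.donors}
    for m in muts:
        by_donor[m.donor_id].append(m)
    fitted: list[ExposureVector] = []
    fitted_ids: list[str] = []
    excluded: dict[str, int] = {}
    for donor_id in sorted(by_donor):
        donor_muts = by_donor[donor_id]
        if len(donor_muts) < min_mutations:
            excluded[donor_id] = len(donor_muts)
            continue
        sp = spectrum(donor_muts, reference)
        if sp.total == 0:
            excluded[donor_id] = 0
            continue
        fitted.append(refit(sp, catalog))
        fitted_ids.append(donor_id)
    if not fitted:
        raise DataError(
            f"no donor has at least {min_mutations} classifiable in-region mutation(s)"
        )
    mat = np.array([v.exposures for v in fitted])
    return CohortExposures(
        signature_ids=catalog.ids,
        donor_ids=tuple(fitted_ids),
        per_donor=tuple(fitted),
        mean_exposures=mat.mean(axis=0),
        summaries=_summaries(catalog.ids, mat),
        excluded_donors=excluded,
        min_mutations=min_mutations,
    )
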