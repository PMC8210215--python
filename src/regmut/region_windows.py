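"""Center alignment, windows, mutation mapping and per-donor summaries.

Distance-based views align regions on their central points, defined as
floor((start + stop) / 2), and measure mutation offsets from those centers.
Each analysis window spans center ± half_width inclusive (odd length), so
offsets are symmetric around zero. Default half-width follows the rule:
half the total window equals the largest region size, floored at 1 kbp and
capped at 5 kbp.
"""
from __future__ import annotations

import math
import re
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from intervaltree import IntervalTree

from .channels import (
    CHANNELS,
    SUBSTITUTION_LABELS,
    collapse_substitution,
    complement,
)
from .exceptions import DataError, PredicateSyntaxError
from .io_formats import (
    GenomicRegion,
    Mutation,
    MutationDataset,
    RegionSet,
)

MIN_HALF_WIDTH = 1000
MAX_HALF_WIDTH = 5000

#: Transition classes after pyrimidine collapse; everything else is a transversion.
TRANSITION_CLASSES = frozenset({"C>T", "T>C"})


# --------------------------------------------------------------------------
# Windows
# --------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class Window:
    """An analysis window: a region of interest plus its flanking sequence.

    The window covers positions [center - half_width, center + half_width]
    inclusive; the target sub-interval (the region of interest, clipped to
    the window) is 0-based half-open.
    """

    chrom: str
    center: int
    half_width: int
    target_start: int
    target_end: int

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise DataError("window half_width must be positive")
        if self.target_end <= self.target_start:
            raise DataError("window target interval is empty")
        if self.target_start < self.start or self.target_end > self.end:
            raise DataError("window target interval exceeds the window")

    @property
    def start(self) -> int:
        return self.center - self.half_width

    @property
    def end(self) -> int:  # half-open
        return self.center + self.half_width + 1

    @property
    def length(self) -> int:
        return 2 * self.half_width + 1

    @property
    def target_length(self) -> int:
        return self.target_end - self.target_start

    def contains_offset_in_target(self, offset: int) -> bool:
        pos = self.center + offset
        return self.target_start <= pos < self.target_end


def region_center(region: GenomicRegion) -> int:
    """Central point of a region: floor((start + stop) / 2)."""
    return (region.start + region.end) // 2


def default_half_width(region_set: RegionSet) -> int:
    """Half-width rule: largest region size, floored at 1 kbp, capped at 5 kbp."""
    largest = max(r.length for r in region_set)
    return min(max(largest, MIN_HALF_WIDTH), MAX_HALF_WIDTH)


def build_windows(region_set: RegionSet,
                  half_width: int | None = None) -> list[Window]:
    """One window per region, centered on the region's central point."""
    if half_width is None:
        half_width = default_half_width(region_set)
    elif half_width <= 0:
        raise DataError(f"half_width must be positive, got {half_width}")
    windows = []
    for r in region_set:
        c = region_center(r)
        windows.append(
            Window(
                chrom=r.chrom,
                center=c,
                half_width=half_width,
                target_start=max(r.start, c - half_width),
                target_end=min(r.end, c + half_width + 1),
            )
        )
    return windows


# --------------------------------------------------------------------------
# Mapping mutations into windows
# --------------------------------------------------------------------------

class MappedMutation(NamedTuple):
    mutation: Mutation
    window: Window
    offset: int  # pos - center, in [-half_width, half_width]


class MappedMutations:
    """Mutation-window pairs together with the windows they were mapped onto.

    A mutation falling under two overlapping windows appears once per window
    (distance-based views count per alignment).
    """

    def __init__(self, windows: Sequence[Window], pairs: list[MappedMutation]):
        self.windows = list(windows)
        self.pairs = pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __getitem__(self, i):
        return self.pairs[i]


def _as_mutations(dataset) -> list[Mutation]:
    if isinstance(dataset, MutationDataset):
        return dataset.mutations
    return list(dataset)


def map_mutations(dataset, windows: Sequence[Window]) -> MappedMutations:
    """Emit every (mutation, window, offset) pair with |offset| <= half_width."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for w in windows:
        trees[w.chrom].addi(w.start, w.end, w)
    pairs: list[MappedMutation] = []
    for m in _as_mutations(dataset):
        tree = trees.get(m.chrom)
        if tree is None:
            continue
        hits = sorted(tree.at(m.pos), key=lambda iv: (iv.begin, iv.data.target_start))
        for iv in hits:
            w: Window = iv.data
            pairs.append(MappedMutation(m, w, m.pos - w.center))
    return MappedMutations(windows, pairs)


# --------------------------------------------------------------------------
# Base-change class filters
# --------------------------------------------------------------------------

_CLASS_RE = re.compile(r"^([ACGT])\s*(?:>|->|→)\s*([ACGT*])$")


def parse_class_filter(token: str | None) -> tuple[str, str] | None:
    """Parse a base-change filter like "C>T", "C→*" or "all" (None)."""
    if token is None:
        return None
    tok = token.strip().upper()
    if tok in ("", "ALL", "*"):
        return None
    m = _CLASS_RE.match(tok)
    if m is None:
        raise DataError(f"unknown base-change class filter {token!r}")
    ref, alt = m.groups()
    if ref == alt:
        raise DataError(f"degenerate class filter {token!r}")
    return ref, alt


def mutation_matches_class(mutation: Mutation,
                           class_filter: tuple[str, str] | None,
                           collapse_complement: bool = True) -> bool:
    """Does a mutation match a base-change filter?

    With ``collapse_complement`` (the default) a filter matches the stated
    change or its reverse complement, so C>T also selects G>A events.
    """
    if class_filter is None:
        return True
    ref, alt = class_filter
    candidates = [(mutation.ref, mutation.alt)]
    if collapse_complement:
        candidates.append((complement(mutation.ref), complement(mutation.alt)))
    if alt == "*":
        return any(r == ref for r, _ in candidates)
    return (ref, alt) in candidates


# --------------------------------------------------------------------------
# Histograms and fold-enrichment profiles
# --------------------------------------------------------------------------

@dataclass
class OffsetHistogram:
    """Counts of mapped mutations by offset bin (bin start = floor division)."""

    bin_size: int
    counts: dict[int, int]
    class_filter: str
    collapse_complement: bool
    n_mapped: int          # pairs passing the class filter (== sum of counts)
    n_pairs_total: int     # all mapped pairs before filtering
    n_windows: int
    half_width: int | None

    def to_dict(self) -> dict:
        starts = sorted(self.counts)
        return {
            "schema": {"name": "OffsetHistogram", "version": 1},
            "bin_size": self.bin_size,
            "bin_starts": starts,
            "counts": [self.counts[b] for b in starts],
            "class_filter": self.class_filter,
            "collapse_complement": self.collapse_complement,
            "n_mapped": self.n_mapped,
            "n_pairs_total": self.n_pairs_total,
            "n_windows": self.n_windows,
            "half_width": self.half_width,
        }


def _common_half_width(windows: Sequence[Window]) -> int | None:
    widths = {w.half_width for w in windows}
    return widths.pop() if len(widths) == 1 else None


def histogram(mapped: MappedMutations, bin_size: int = 1,
              class_filter: str | None = None,
              collapse_complement: bool = True) -> OffsetHistogram:
    """Histogram of mutation offsets from region centers."""
    if bin_size < 1:
        raise DataError(f"bin_size must be >= 1, got {bin_size}")
    flt = parse_class_filter(class_filter)
    counts: Counter[int] = Counter()
    n_pass = 0
    for m, _w, off in mapped:
        if mutation_matches_class(m, flt, collapse_complement):
            counts[math.floor(off / bin_size) * bin_size] += 1
            n_pass += 1
    return OffsetHistogram(
        bin_size=bin_size,
        counts=dict(counts),
        class_filter=class_filter or "all",
        collapse_complement=collapse_complement,
        n_mapped=n_pass,
        n_pairs_total=len(mapped),
        n_windows=len(mapped.windows),
        half_width=_common_half_width(mapped.windows),
    )


@dataclass
class EnrichmentProfile:
    """Per-bin fold enrichment: observed / expected under the window-average rate.

    Expected counts distribute the total mapped count proportionally to the
    number of window positions each bin covers, so the position-weighted
    mean of the profile is one.
    """

    bin_size: int
    bin_starts: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    values: np.ndarray
    defined: bool
    n_mapped: int

    @classmethod
    def undefined(cls, bin_size: int) -> "EnrichmentProfile":
        empty = np.empty(0)
        return cls(bin_size, np.empty(0, dtype=int), empty, empty, empty,
                   defined=False, n_mapped=0)

    def to_dict(self) -> dict:
        return {
            "schema": {"name": "EnrichmentProfile", "version": 1},
            "bin_size": self.bin_size,
            "bin_starts": self.bin_starts,
            "observed": self.observed,
            "expected": self.expected,
            "fold_enrichment": self.values,
            "defined": self.defined,
            "n_mapped": self.n_mapped,
        }


def fold_enrichment(mapped: MappedMutations, bin_size: int = 1,
                    class_filter: str | None = None,
                    collapse_complement: bool = True) -> EnrichmentProfile:
    """Fold-enrichment profile (observed/expected) across offset bins."""
    if bin_size < 1:
        raise DataError(f"bin_size must be >= 1, got {bin_size}")
    flt = parse_class_filter(class_filter)
    offsets = [
        off for m, _w, off in mapped
        if mutation_matches_class(m, flt, collapse_complement)
    ]
    if not offsets:
        return EnrichmentProfile.undefined(bin_size)

    # positions each bin covers, accumulated over windows
    position_weight: Counter[int] = Counter()
    for w in mapped.windows:
        hw = w.half_width
        first = math.floor(-hw / bin_size) * bin_size
        for b in range(first, hw + 1, bin_size):
            cover = min(b + bin_size, hw + 1) - max(b, -hw)
            if cover > 0:
                position_weight[b] += cover
    bin_starts = np.array(sorted(position_weight), dtype=int)
    weights = np.array([position_weight[b] for b in bin_starts], dtype=float)

    observed_counts: Counter[int] = Counter(
        math.floor(off / bin_size) * bin_size for off in offsets
    )
    observed = np.array([observed_counts.get(b, 0) for b in bin_starts], dtype=float)
    total = observed.sum()
    expected = total * weights / weights.sum()
    values = observed / expected
    return EnrichmentProfile(
        bin_size=bin_size,
        bin_starts=bin_starts,
        observed=observed,
        expected=expected,
        values=values,
        defined=True,
        n_mapped=int(total),
    )


# --------------------------------------------------------------------------
# Region intersection (cumulative views)
# --------------------------------------------------------------------------

def merge_intervals(regions: Iterable[GenomicRegion]) -> dict[str, list[tuple[int, int]]]:
    """Merge overlapping/adjacent intervals, per chromosome, sorted."""
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for r in regions:
        by_chrom[r.chrom].append((r.start, r.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = [ivs[0]]
        for s, e in ivs[1:]:
            ps, pe = out[-1]
            if s <= pe:
                out[-1] = (ps, max(pe, e))
            else:
                out.append((s, e))
        merged[chrom] = out
    return merged


def intersect_mutations(dataset, region_set: RegionSet) -> list[Mutation]:
    """Mutations whose position lies inside some region (half-open containment).

    A mutation covered by several overlapping regions is returned once.
    """
    merged = merge_intervals(region_set)
    arrays = {
        chrom: (np.array([s for s, _ in ivs]), np.array([e for _, e in ivs]))
        for chrom, ivs in merged.items()
    }
    selected: list[Mutation] = []
    for m in _as_mutations(dataset):
        se = arrays.get(m.chrom)
        if se is None:
            continue
        starts, ends = se
        idx = int(np.searchsorted(starts, m.pos, side="right")) - 1
        if idx >= 0 and m.pos < ends[idx]:
            selected.append(m)
    return selected


# --------------------------------------------------------------------------
# Per-donor summaries
# --------------------------------------------------------------------------

@dataclass
class DonorSummary:
    """Per-donor mutation counts by class, with Ti/Tv and per-class stats."""

    level: str                            # "base_change" or "trinucleotide"
    classes: tuple[str, ...]
    donors: tuple[str, ...]
    counts: dict[str, list[int]]          # donor -> counts per class
    ti: dict[str, int]
    tv: dict[str, int]
    stats: dict[str, dict[str, float]]    # class -> min/max/median over donors
    n_unclassifiable: int = 0

    def to_dict(self) -> dict:
        return {
            "schema": {"name": "DonorSummary", "version": 1},
            "level": self.level,
            "classes": list(self.classes),
            "donors": list(self.donors),
            "counts": self.counts,
            "ti": self.ti,
            "tv": self.tv,
            "stats": self.stats,
            "n_unclassifiable": self.n_unclassifiable,
        }


def donor_summary(mutations: Iterable[Mutation], dataset: MutationDataset,
                  level: str = "base_change",
                  reference=None) -> DonorSummary:
    """Summarise mutation counts per donor.

    ``level`` selects the six collapsed base-change classes or the 96
    trinucleotide channels (the latter needs a reference genome). Donors
    present in the dataset but without mutations in the input are reported
    with zero counts. Ti/Tv are computed from base changes regardless of
    level, so Ti + Tv equals each donor's total SNV count.
    """
    mutations = list(mutations)
    donors = tuple(sorted(dataset.donors))
    if level == "base_change":
        classes = SUBSTITUTION_LABELS
        class_index = {c: i for i, c in enumerate(classes)}

        def classify(m: Mutation) -> int | None:
            return class_index[collapse_substitution(m.ref, m.alt)]

    elif level == "trinucleotide":
        if reference is None:
            raise DataError("trinucleotide-level summary requires a reference genome")
        from .trinuc_context import classify_mutation

        classes = CHANNELS

        def classify(m: Mutation) -> int | None:
            ch = classify_mutation(m, reference)
            return None if ch is None else ch.index

    else:
        raise DataError(f"unknown summary level {level!r}")

    counts = {d: [0] * len(classes) for d in donors}
    ti = {d: 0 for d in donors}
    tv = {d: 0 for d in donors}
    n_unclassifiable = 0
    for m in mutations:
        if m.donor_id not in counts:
            continue
        if collapse_substitution(m.ref, m.alt) in TRANSITION_CLASSES:
            ti[m.donor_id] += 1
        else:
            tv[m.donor_id] += 1
        idx = classify(m)
        if idx is None:
            n_unclassifiable += 1
            continue
        counts[m.donor_id][idx] += 1

    stats: dict[str, dict[str, float]] = {}
    if donors:
        mat = np.array([counts[d] for d in donors], dtype=float)
        for j, cls in enumerate(classes):
            col = mat[:, j]
            stats[cls] = {
                "min": float(col.min()),
                "max": float(col.max()),
                "median": float(np.median(col)),
            }
    return DonorSummary(
        level=level,
        classes=classes,
        donors=donors,
        counts=counts,
        ti=ti,
        tv=tv,
        stats=stats,
        n_unclassifiable=n_unclassifiable,
    )


# --------------------------------------------------------------------------
# Donor-filter predicates
# --------------------------------------------------------------------------
#
# Grammar:
#   expr   := term ( OR term )*
#   term   := factor ( AND factor )*
#   factor := '(' expr ')' | comparison
#   comparison := field op value | field IN '{' value (',' value)* '}'
#   op     := '=' | '!=' | '<' | '>' | '<=' | '>='
#
# A comparison on a field a donor lacks matches nothing (the donor is
# excluded by any comparison on a missing field).

_TOKEN_RE = re.compile(
    r"\s*(?:"
    r"(?P<lparen>\()|(?P<rparen>\))|(?P<lbrace>\{)|(?P<rbrace>\})|(?P<comma>,)"
    r"|(?P<op><=|>=|!=|=|<|>)"
    r"|(?P<string>'[^']*'|\"[^\"]*\")"
    r"|(?P<word>[A-Za-z_][A-Za-z0-9_.]*)"
    r"|(?P<number>-?\d+(?:\.\d+)?)"
    r")"
)


class _Token(NamedTuple):
    kind: str
    value: str
    pos: int


def _tokenize(text: str) -> list[_Token]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.lastgroup is None:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise PredicateSyntaxError(
                f"unexpected character {stripped[0]!r}", len(text) - len(stripped)
            )
        kind = m.lastgroup
        value = m.group(kind)
        start = m.end() - len(value)
        if kind == "word" and value.upper() in ("AND", "OR", "IN"):
            kind = value.upper()
        tokens.append(_Token(kind, value, start))
        pos = m.end()
    tokens.append(_Token("eof", "", len(text)))
    return tokens


def _as_number(text: str) -> float | None:
    try:
        return float(text)
    except ValueError:
        return None


class Comparison(NamedTuple):
    fld: str
    op: str
    value: str

    def fields(self) -> set[str]:
        return {self.fld}

    def match(self, meta: dict[str, str]) -> bool:
        v = meta.get(self.fld)
        if v is None:
            return False
        if self.op == "=":
            return v == self.value or (
                (a := _as_number(v)) is not None
                and (b := _as_number(self.value)) is not None
                and a == b
            )
        if self.op == "!=":
            return not Comparison(self.fld, "=", self.value).match(meta)
        a, b = _as_number(v), _as_number(self.value)
        if a is None or b is None:
            return False
        return {"<": a < b, ">": a > b, "<=": a <= b, ">=": a >= b}[self.op]


class Membership(NamedTuple):
    fld: str
    values: tuple[str, ...]

    def fields(self) -> set[str]:
        return {self.fld}

    def match(self, meta: dict[str, str]) -> bool:
        v = meta.get(self.fld)
        return v is not None and v in self.values


class BoolOp(NamedTuple):
    op: str  # "AND" | "OR"
    parts: tuple

    def fields(self) -> set[str]:
        out: set[str] = set()
        for p in self.parts:
            out |= p.fields()
        return out

    def match(self, meta: dict[str, str]) -> bool:
        if self.op == "AND":
            return all(p.match(meta) for p in self.parts)
        return any(p.match(meta) for p in self.parts)


class _Parser:
    def __init__(self, text: str):
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> _Token:
        return self.tokens[self.i]

    def advance(self) -> _Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, kind: str) -> _Token:
        tok = self.peek()
        if tok.kind != kind:
            raise PredicateSyntaxError(
                f"expected {kind}, found {tok.value or 'end of input'!r}", tok.pos
            )
        return self.advance()

    def parse(self):
        node = self.expr()
        tok = self.peek()
        if tok.kind != "eof":
            raise PredicateSyntaxError(f"unexpected {tok.value!r}", tok.pos)
        return node

    def expr(self):
        parts = [self.term()]
        while self.peek().kind == "OR":
            self.advance()
            parts.append(self.term())
        return parts[0] if len(parts) == 1 else BoolOp("OR", tuple(parts))

    def term(self):
        parts = [self.factor()]
        while self.peek().kind == "AND":
            self.advance()
            parts.append(self.factor())
        return parts[0] if len(parts) == 1 else BoolOp("AND", tuple(parts))

    def factor(self):
        tok = self.peek()
        if tok.kind == "lparen":
            self.advance()
            node = self.expr()
            self.expect("rparen")
            return node
        return self.comparison()

    def value_token(self) -> str:
        tok = self.peek()
        if tok.kind == "string":
            self.advance()
            return tok.value[1:-1]
        if tok.kind in ("word", "number"):
            self.advance()
            return tok.value
        raise PredicateSyntaxError(
            f"expected a value, found {tok.value or 'end of input'!r}", tok.pos
        )

    def comparison(self):
        tok = self.expect("word")
        fld = tok.value
        nxt = self.peek()
        if nxt.kind == "IN":
            self.advance()
            self.expect("lbrace")
            values = [self.value_token()]
            while self.peek().kind == "comma":
                self.advance()
                values.append(self.value_token())
            self.expect("rbrace")
            return Membership(fld, tuple(values))
        if nxt.kind == "op":
            self.advance()
            return Comparison(fld, nxt.value, self.value_token())
        raise PredicateSyntaxError(
            f"expected an operator after {fld!r}", nxt.pos
        )


def parse_predicate(text: str):
    """Parse a donor-filter predicate into a matchable AST."""
    if not text or not text.strip():
        raise PredicateSyntaxError("empty predicate", 0)
    return _Parser(text).parse()


def filter_donors(dataset: MutationDataset, predicate: str) -> MutationDataset:
    """Restrict a dataset to donors matching a metadata predicate.

    Fields referenced by the predicate but absent from every donor's
    metadata trigger a warning and match no donor. The number of matching
    donors is ``len(result.donors)``.
    """
    ast = parse_predicate(predicate)
    known = {k for meta in dataset.donors.values() for k in meta}
    for fld in sorted(ast.fields() - known):
        warnings.warn(
            f"donor-filter field {fld!r} is unknown; it matches no donor",
            stacklevel=2,
        )
    selected = {d for d, meta in dataset.donors.items() if ast.match(meta)}
    return MutationDataset(
        name=f"{dataset.name} | {predicate}",
        mutations=[m for m in dataset.mutations if m.donor_id in selected],
        donors={d: dict(dataset.donors[d]) for d in sorted(selected)},
    )
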