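"""96-channel classification, spectra, trinucleotide accounting and the
region adjustment of mutational signatures.

The adjustment rescales each signature's channel probability by the ratio
of the relative trinucleotide frequency in the region set R to that in the
whole genome G:

    c_t = freq_R(t) / freq_G(t),      s'_k(j) = c_{t(j)} * s_k(j),

followed by renormalisation so the adjusted signature sums to one. A
trinucleotide that is over-represented in R offers more mutation
opportunity there, so its channels are up-weighted before refitting.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .channels import (
    CHANNELS,
    CHANNEL_TO_TRINUC,
    PURINES,
    TRINUCLEOTIDES,
    channel_of,
    collapsed_trinuc_codes,
    complement,
)
from .exceptions import DataError, DegenerateSignatureError, RefMismatchError
from .io_formats import (
    GenomicRegion,
    Mutation,
    ReferenceGenome,
    RegionSet,
    Signature,
    SignatureCatalog,
)
from .region_windows import merge_intervals


@dataclass(frozen=True, slots=True)
class TrinucChannel:
    """One of the 96 substitution-in-context channels (pyrimidine-referenced)."""

    five_prime: str
    ref_base: str
    alt_base: str
    three_prime: str

    @property
    def label(self) -> str:
        return f"{self.five_prime}[{self.ref_base}>{self.alt_base}]{self.three_prime}"

    @property
    def display_label(self) -> str:
        return self.label.replace(">", "→")

    @property
    def trinucleotide(self) -> str:
        return f"{self.five_prime}{self.ref_base}{self.three_prime}"

    @property
    def index(self) -> int:
        return channel_of(self.five_prime, self.ref_base, self.alt_base,
                          self.three_prime)


def classify_mutation(mutation: Mutation,
                      reference: ReferenceGenome) -> TrinucChannel | None:
    """Assign a mutation to its trinucleotide channel.

    Returns None when the mutation is unclassifiable (missing flank at a
    chromosome end, or N in the context). Raises RefMismatchError when the
    mutation's declared ref base disagrees with the genome.
    """
    length = reference.chrom_length(mutation.chrom)
    pos = mutation.pos
    if pos < 1 or pos > length - 2:
        return None
    context = reference.get_sequence(mutation.chrom, pos - 1, pos + 2)
    if context[1] != mutation.ref:
        raise RefMismatchError(
            f"{mutation.chrom}:{pos}: mutation ref {mutation.ref!r} "
            f"!= reference base {context[1]!r}"
        )
    if "N" in context:
        return None
    five, ref, three = context[0], context[1], context[2]
    alt = mutation.alt
    if ref in PURINES:
        five, ref, alt, three = (
            complement(three), complement(ref), complement(alt), complement(five)
        )
    return TrinucChannel(five, ref, alt, three)


@dataclass
class TrinucSpectrum:
    """96-channel mutation counts with derived fractions ⟨m_j⟩."""

    counts: np.ndarray
    n_unclassifiable: int = 0
    n_ref_mismatch: int = 0
    channel_order: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (96,):
            raise DataError(f"spectrum must have 96 channels, got {counts.shape}")
        if (counts < 0).any():
            raise DataError("spectrum counts must be non-negative")
        self.counts = counts

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray | None:
        """Channel fractions, or None for an empty spectrum."""
        total = self.total
        if total == 0:
            return None
        return self.counts / total

    def to_dict(self) -> dict:
        return {
            "schema": {"name": "TrinucSpectrum", "version": 1},
            "channels": list(self.channel_order),
            "counts": self.counts,
            "total": self.total,
            "fractions": self.fractions,
            "n_unclassifiable": self.n_unclassifiable,
            "n_ref_mismatch": self.n_ref_mismatch,
        }


def spectrum(mutations: Iterable[Mutation],
             reference: ReferenceGenome) -> TrinucSpectrum:
    """Count mutations per channel; unclassifiable events are tallied aside.

    Mutations whose declared ref base mismatches the genome are skipped with
    a warning (public catalogs contain liftover noise) and counted
    separately.
    """
    counts = np.zeros(96, dtype=np.int64)
    n_unclassifiable = 0
    n_mismatch = 0
    for m in mutations:
        try:
            channel = classify_mutation(m, reference)
        except RefMismatchError:
            n_mismatch += 1
            continue
        if channel is None:
            n_unclassifiable += 1
            continue
        counts[channel.index] += 1
    if n_mismatch:
        warnings.warn(
            f"skipped {n_mismatch} mutation(s) whose ref base mismatched the genome",
            stacklevel=2,
        )
    return TrinucSpectrum(counts, n_unclassifiable, n_mismatch)


@dataclass
class TrinucFrequencies:
    """Relative frequencies of the 32 pyrimidine-centred trinucleotides."""

    counts: np.ndarray
    labels: tuple[str, ...] = TRINUCLEOTIDES

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (32,):
            raise DataError(f"expected 32 trinucleotide counts, got {counts.shape}")
        if (counts < 0).any():
            raise DataError("trinucleotide counts must be non-negative")
        if counts.sum() == 0:
            raise DataError("no trinucleotides counted (all intervals too short?)")
        self.counts = counts

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.total

    def to_dict(self) -> dict:
        return {
            "schema": {"name": "TrinucFrequencies", "version": 1},
            "trinucleotides": list(self.labels),
            "counts": self.counts,
            "frequencies": self.frequencies,
            "total": self.total,
        }


def trinuc_frequencies(intervals, reference: ReferenceGenome) -> TrinucFrequencies:
    """Trinucleotide composition of a set of intervals.

    Overlapping intervals are merged first so opportunity is not counted
    twice; 3-mers must lie fully inside an interval; purine-centred 3-mers
    are collapsed onto their reverse complement; 3-mers containing N are
    skipped. Intervals shorter than 3 bp contribute nothing (warned).
    """
    if isinstance(intervals, RegionSet):
        intervals = intervals.regions
    intervals = list(intervals)
    if not intervals:
        raise DataError("no intervals given")
    counts = np.zeros(32, dtype=np.int64)
    n_short = 0
    for chrom, merged in merge_intervals(intervals).items():
        for start, end in merged:
            if end - start < 3:
                n_short += 1
                continue
            codes = collapsed_trinuc_codes(reference.get_sequence(chrom, start, end))
            valid = codes[codes >= 0]
            counts += np.bincount(valid, minlength=32)
    if n_short:
        warnings.warn(
            f"{n_short} merged interval(s) shorter than 3 bp contribute no "
            "trinucleotides",
            stacklevel=2,
        )
    return TrinucFrequencies(counts)


def genome_frequencies(reference: ReferenceGenome) -> TrinucFrequencies:
    """Trinucleotide composition of the whole reference genome."""
    intervals = [
        GenomicRegion(chrom, 0, reference.chrom_length(chrom))
        for chrom in reference.chroms
    ]
    return trinuc_frequencies(intervals, reference)


@dataclass
class CorrectionFactors:
    """Per-trinucleotide opportunity correction factors c_t = freq_R / freq_G."""

    factors: np.ndarray
    labels: tuple[str, ...] = TRINUCLEOTIDES

    def __post_init__(self) -> None:
        factors = np.asarray(self.factors, dtype=float)
        if factors.shape != (32,):
            raise DataError(f"expected 32 correction factors, got {factors.shape}")
        if (factors < 0).any():
            raise DataError("correction factors must be non-negative")
        self.factors = factors

    @property
    def channel_factors(self) -> np.ndarray:
        """The 96-vector c_j = c_{t(j)} mapped onto channels."""
        return self.factors[CHANNEL_TO_TRINUC]

    def to_dict(self) -> dict:
        return {
            "schema": {"name": "CorrectionFactors", "version": 1},
            "trinucleotides": list(self.labels),
            "factors": self.factors,
        }


def correction_factors(region_freqs: TrinucFrequencies,
                       genome_freqs: TrinucFrequencies) -> CorrectionFactors:
    """Compute c_t = region frequency / genome frequency for each trinucleotide.

    A trinucleotide absent from both tables gets c_t = 1; absent from the
    genome but present in the regions is an error (the regions are part of
    the genome, so this indicates inconsistent inputs).
    """
    r = region_freqs.frequencies
    g = genome_freqs.frequencies
    factors = np.ones(32, dtype=float)
    nonzero = g > 0
    factors[nonzero] = r[nonzero] / g[nonzero]
    bad = (~nonzero) & (r > 0)
    if bad.any():
        names = [TRINUCLEOTIDES[i] for i in np.flatnonzero(bad)]
        raise DataError(
            f"trinucleotide(s) {names} present in regions but absent from genome"
        )
    return CorrectionFactors(factors)


def adjust_signature(signature: Signature,
                     factors: CorrectionFactors) -> Signature:
    """Region-adjust one signature: s'(j) = c_j s(j), then renormalise."""
    channel_factors = factors.channel_factors
    if (channel_factors == 1.0).all():
        return signature  # identical composition: adjustment is exactly a no-op
    weighted = channel_factors * signature.probs
    total = weighted.sum()
    if total <= 0:
        raise DegenerateSignatureError(signature.id)
    return Signature(signature.id, weighted / total)


def adjust_catalog(catalog: SignatureCatalog,
                   factors: CorrectionFactors) -> SignatureCatalog:
    """Region-adjust every signature in a catalog."""
    return SignatureCatalog(
        [adjust_signature(s, factors) for s in catalog],
        channel_order=catalog.channel_order,
    )
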