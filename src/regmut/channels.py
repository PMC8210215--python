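"""Canonical encoding of the 96 single-base-substitution channels.

A channel is a base substitution together with its immediate 5' and 3'
neighbours, collapsed so that the mutated (reference) base is a pyrimidine:
a G>A event on the forward strand is recorded as the C>T event on the
opposite strand, with the flanks reverse-complemented accordingly.

Canonical order (the COSMIC ordering): six substitution blocks
C>A, C>G, C>T, T>A, T>C, T>G; within each block the 16 flank contexts are
sorted by the 5' base and then the 3' base, A < C < G < T.
"""
from __future__ import annotations

import re

import numpy as np

BASES = "ACGT"
PYRIMIDINES = "CT"
PURINES = "AG"

#: The six pyrimidine-referenced substitution classes, in canonical order.
SUBSTITUTIONS: tuple[tuple[str, str], ...] = (
    ("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G"),
)
SUBSTITUTION_LABELS: tuple[str, ...] = tuple(f"{r}>{a}" for r, a in SUBSTITUTIONS)

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMP)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMP)


def _build_channels() -> tuple[str, ...]:
    labels = []
    for ref, alt in SUBSTITUTIONS:
        for five in BASES:
            for three in BASES:
                labels.append(f"{five}[{ref}>{alt}]{three}")
    return tuple(labels)


#: The 96 channel labels ("A[C>A]A" dialect) in canonical order.
CHANNELS: tuple[str, ...] = _build_channels()
CHANNEL_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(CHANNELS)}

#: The 32 pyrimidine-centred trinucleotides: C-centred block then T-centred
#: block, flanks sorted A < C < G < T (5' first).
TRINUCLEOTIDES: tuple[str, ...] = tuple(
    f"{five}{center}{three}"
    for center in PYRIMIDINES
    for five in BASES
    for three in BASES
)
TRINUC_INDEX: dict[str, int] = {t: i for i, t in enumerate(TRINUCLEOTIDES)}

#: Map channel index -> index of the trinucleotide t(j) it alters.
CHANNEL_TO_TRINUC: np.ndarray = np.array(
    [TRINUC_INDEX[lab[0] + lab[2] + lab[-1]] for lab in CHANNELS], dtype=np.intp
)

_CHANNEL_RE = re.compile(
    r"^([ACGT])\[([ACGT])(?:>|->|→)([ACGT])\]([ACGT])$"
)


def parse_channel_label(label: str) -> int:
    """Parse a channel label in either the "A[C>A]A" or "A[C→A]A" dialect.

    Returns the canonical channel index. Raises ``ValueError`` for anything
    that is not one of the 96 channels (including purine-referenced labels,
    which are not part of the canonical set).
    """
    m = _CHANNEL_RE.match(label.strip().upper())
    if m is None:
        raise ValueError(f"not a trinucleotide channel label: {label!r}")
    five, ref, alt, three = m.groups()
    canonical = f"{five}[{ref}>{alt}]{three}"
    idx = CHANNEL_INDEX.get(canonical)
    if idx is None:
        raise ValueError(f"not a canonical (pyrimidine-referenced) channel: {label!r}")
    return idx


def display_label(index: int) -> str:
    """Channel label in the arrow dialect used for display ("A[C→A]A")."""
    lab = CHANNELS[index]
    return lab.replace(">", "→")


def channel_of(five: str, ref: str, alt: str, three: str) -> int:
    """Canonical channel index for a substitution in its context.

    Purine-referenced events are collapsed to the opposite strand.
    """
    if ref in PURINES:
        five, ref, alt, three = (
            complement(three), complement(ref), complement(alt), complement(five)
        )
    return CHANNEL_INDEX[f"{five}[{ref}>{alt}]{three}"]


def collapse_trinuc(trinuc: str) -> str:
    """Pyrimidine-centred representative of a trinucleotide."""
    return trinuc if trinuc[1] in PYRIMIDINES else revcomp(trinuc)


def collapse_substitution(ref: str, alt: str) -> str:
    """Pyrimidine-referenced substitution class label ("C>T", ...)."""
    if ref in PURINES:
        ref, alt = complement(ref), complement(alt)
    return f"{ref}>{alt}"


# --- fast numeric helpers used by frequency counting and simulation -------

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def encode_bases(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes A=0 C=1 G=2 T=3, other = -1."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def collapsed_trinuc_codes(seq: str) -> np.ndarray:
    """Collapsed trinucleotide index for every internal position of ``seq``.

    Returns an array of length ``len(seq) - 2`` where entry ``i`` is the
    index (into :data:`TRINUCLEOTIDES`) of the pyrimidine-collapsed 3-mer
    centred at ``seq[i + 1]``, or -1 if the 3-mer contains a non-ACGT base.
    """
    codes = encode_bases(seq)
    if codes.size < 3:
        return np.empty(0, dtype=np.intp)
    five, center, three = codes[:-2], codes[1:-1], codes[2:]
    valid = (five >= 0) & (center >= 0) & (three >= 0)
    # pyrimidine centres: C=1 -> block 0, T=3 -> block 1
    is_pyr = (center == 1) | (center == 3)
    block = np.where(center == 1, 0, 1)
    idx_fwd = block * 16 + five * 4 + three
    # purine centres: complement (code -> 3 - code) and swap flanks
    block_rc = np.where(center == 2, 0, 1)  # G -> C block, A -> T block
    idx_rc = block_rc * 16 + (3 - three) * 4 + (3 - five)
    out = np.where(is_pyr, idx_fwd, idx_rc)
    out[~valid] = -1
    return out.astype(np.intp)
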