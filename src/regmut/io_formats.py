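"""Readers and writers for every external format the tool touches.

All coordinates are 0-based half-open internally; conversion to and from
the 1-based conventions of mutation TSV/VCF files happens only here.
Strand is never stored: region sets are plain BED3 intervals.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .channels import BASES, CHANNELS, parse_channel_label
from .exceptions import DataError, ParseError

SCHEMA_VERSION = 1

_VALID_BASES = set(BASES)


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class GenomicRegion:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise DataError("region chromosome name must be non-empty")
        if self.end <= self.start:
            raise DataError(
                f"region {self.chrom}:{self.start}-{self.end} is empty or inverted"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class RegionSet:
    """A named, ordered collection of genomic regions."""

    name: str
    regions: tuple[GenomicRegion, ...]

    def __init__(self, name: str, regions: Iterable[GenomicRegion]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "regions", tuple(regions))
        if not self.regions:
            raise DataError(f"region set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def chroms(self) -> set[str]:
        return {r.chrom for r in self.regions}

    def validate_against(self, reference: "ReferenceGenome") -> None:
        """Check every region's chromosome exists and fits in the reference."""
        for r in self.regions:
            if r.chrom not in reference:
                raise DataError(f"region chromosome {r.chrom!r} not in reference")
            if r.end > reference.chrom_length(r.chrom):
                raise DataError(
                    f"region {r.chrom}:{r.start}-{r.end} exceeds chromosome length"
                )


@dataclass(frozen=True, slots=True)
class Mutation:
    """A somatic single-nucleotide variant; ``pos`` is the 0-based altered base."""

    chrom: str
    pos: int
    ref: str
    alt: str
    donor_id: str

    def __post_init__(self) -> None:
        if self.ref not in _VALID_BASES or self.alt not in _VALID_BASES:
            raise DataError(
                f"ref/alt must be single bases in ACGT, got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise DataError(f"ref equals alt ({self.ref}) at {self.chrom}:{self.pos}")


@dataclass
class MutationDataset:
    """A catalog of SNVs plus a donor_id -> metadata table.

    Every mutation's donor appears in ``donors``; donors without metadata
    carry an empty mapping. ``n_skipped`` counts non-SNV input records
    dropped while reading.
    """

    name: str
    mutations: list[Mutation]
    donors: dict[str, dict[str, str]] = field(default_factory=dict)
    n_skipped: int = 0

    def __post_init__(self) -> None:
        for m in self.mutations:
            self.donors.setdefault(m.donor_id, {})

    def __len__(self) -> int:
        return len(self.mutations)

    def mutations_of(self, donor_id: str) -> list[Mutation]:
        return [m for m in self.mutations if m.donor_id == donor_id]


@dataclass(frozen=True)
class Signature:
    """A mutational signature: 96 channel probabilities summing to one."""

    id: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.shape != (96,):
            raise DataError(
                f"signature {self.id!r} must have 96 channels, got {probs.shape}"
            )
        if (probs < 0).any():
            raise DataError(f"signature {self.id!r} has negative probabilities")
        if abs(probs.sum() - 1.0) > 1e-8:
            raise DataError(
                f"signature {self.id!r} probabilities sum to {probs.sum():.10f}, not 1"
            )

    @classmethod
    def from_unnormalized(cls, id: str, weights: np.ndarray) -> "Signature":
        w = np.asarray(weights, dtype=float)
        s = w.sum()
        if s <= 0:
            raise DataError(f"signature {id!r} has zero total mass")
        return cls(id, w / s)


@dataclass(frozen=True)
class SignatureCatalog:
    """An ordered set of signatures sharing the canonical channel order."""

    signatures: tuple[Signature, ...]
    channel_order: tuple[str, ...] = CHANNELS

    def __init__(self, signatures: Iterable[Signature],
                 channel_order: tuple[str, ...] = CHANNELS):
        object.__setattr__(self, "signatures", tuple(signatures))
        object.__setattr__(self, "channel_order", tuple(channel_order))
        if not self.signatures:
            raise DataError("signature catalog is empty")
        ids = [s.id for s in self.signatures]
        if len(set(ids)) != len(ids):
            raise DataError("signature ids are not unique")

    def __len__(self) -> int:
        return len(self.signatures)

    def __iter__(self):
        return iter(self.signatures)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.signatures)

    @property
    def matrix(self) -> np.ndarray:
        """96 x K matrix of signature probabilities (one column per signature)."""
        return np.column_stack([s.probs for s in self.signatures])


# --------------------------------------------------------------------------
# Reference genome access
# --------------------------------------------------------------------------

class ReferenceGenome:
    """Uppercase random access to a reference, backed by pyfaidx or a dict."""

    def __init__(self, backend):
        self._backend = backend
        if isinstance(backend, dict):
            self._lengths = {c: len(s) for c, s in backend.items()}
        else:  # pyfaidx.Fasta
            self._lengths = {name: len(backend[name]) for name in backend.keys()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        from pyfaidx import Fasta

        return cls(Fasta(str(path)))

    @classmethod
    def from_dict(cls, sequences: Mapping[str, str]) -> "ReferenceGenome":
        return cls({c: s.upper() for c, s in sequences.items()})

    @property
    def chroms(self) -> list[str]:
        return list(self._lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def chrom_length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise DataError(f"unknown chromosome {chrom!r}") from None

    def get_sequence(self, chrom: str, start: int, end: int) -> str:
        """Uppercase sequence of ``chrom[start:end]`` (0-based half-open)."""
        length = self.chrom_length(chrom)
        if not (0 <= start < end <= length):
            raise DataError(
                f"coordinates {chrom}:{start}-{end} out of range (length {length})"
            )
        if isinstance(self._backend, dict):
            return self._backend[chrom][start:end]
        return str(self._backend[chrom][start:end]).upper()


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Open an (indexable) FASTA file for random access."""
    return ReferenceGenome.from_fasta(path)


def write_fasta(sequences: Mapping[str, str], path: str | Path,
                line_width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")


# --------------------------------------------------------------------------
# BED
# --------------------------------------------------------------------------

_BED_SKIP_PREFIXES = ("track", "browser", "#")


def read_bed(path: str | Path, name: str | None = None) -> RegionSet:
    """Read a BED3+ file; only the first three (mandatory) fields are used.

    BED is already 0-based half-open, so coordinates are preserved as-is.
    ``track``/``browser``/comment lines are skipped; extra columns ignored.
    """
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(_BED_SKIP_PREFIXES):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected at least 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates {parts[1]!r}/{parts[2]!r}"
                ) from None
            if end <= start:
                raise ParseError(
                    f"{path}:{lineno}: empty or inverted interval {start}-{end}"
                )
            regions.append(GenomicRegion(parts[0], start, end))
    if not regions:
        raise ParseError(f"{path}: no regions found")
    return RegionSet(name or Path(path).stem, regions)


def write_bed(region_set: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in region_set:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


# --------------------------------------------------------------------------
# Mutation catalogs
# --------------------------------------------------------------------------

_TSV_HEADER_NAMES = {"chrom", "chromosome", "#chrom", "chr"}


def read_mutations(
    path: str | Path,
    format: str = "tsv",
    name: str | None = None,
    donor_metadata_path: str | Path | None = None,
    donor_info_key: str | None = None,
    donor_sample: str | None = None,
) -> MutationDataset:
    """Read an SNV catalog from a TSV table or a VCF subset.

    TSV columns are chrom, pos (1-based), ref, alt, donor_id. VCF positions
    are 1-based per the standard; the donor is taken from ``donor_info_key``
    in INFO, or is the name of the ``donor_sample`` column (a single-sample
    VCF defaults to its sample name). Positions are normalised to 0-based.
    Non-SNV records (indels, multi-allelic sites) are skipped and counted.
    """
    if format == "tsv":
        mutations, skipped = _read_mutations_tsv(path)
    elif format == "vcf":
        mutations, skipped = _read_mutations_vcf(path, donor_info_key, donor_sample)
    else:
        raise DataError(f"unknown mutation format {format!r} (expected tsv or vcf)")
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} non-SNV record(s)", stacklevel=2)
    donors: dict[str, dict[str, str]] = {}
    if donor_metadata_path is not None:
        donors = read_donor_metadata(donor_metadata_path)
    return MutationDataset(
        name=name or Path(str(path)).stem,
        mutations=mutations,
        donors=donors,
        n_skipped=skipped,
    )


def _read_mutations_tsv(path: str | Path) -> tuple[list[Mutation], int]:
    mutations: list[Mutation] = []
    skipped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            if lineno == 1 and parts[0].lower() in _TSV_HEADER_NAMES:
                continue
            try:
                pos = int(parts[1])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer position {parts[1]!r}"
                ) from None
            ref, alt = parts[2].upper(), parts[3].upper()
            if (
                len(ref) != 1 or len(alt) != 1
                or ref not in _VALID_BASES or alt not in _VALID_BASES
                or ref == alt
            ):
                skipped += 1
                continue
            mutations.append(Mutation(parts[0], pos - 1, ref, alt, parts[4]))
    return mutations, skipped


def _read_mutations_vcf(
    path: str | Path,
    donor_info_key: str | None,
    donor_sample: str | None,
) -> tuple[list[Mutation], int]:
    import pysam

    mutations: list[Mutation] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if donor_sample is not None and samples and donor_sample not in samples:
            raise DataError(f"sample {donor_sample!r} not present in {path}")
        fallback_donor = donor_sample
        if fallback_donor is None and donor_info_key is None:
            if len(samples) == 1:
                fallback_donor = samples[0]
            else:
                raise DataError(
                    "VCF donor assignment needs donor_info_key or donor_sample"
                )
        for rec in vcf:
            alts = rec.alts or ()
            ref = (rec.ref or "").upper()
            if len(alts) != 1:  # multi-allelic records are not expanded
                skipped += 1
                continue
            alt = alts[0].upper()
            if (
                len(ref) != 1 or len(alt) != 1
                or ref not in _VALID_BASES or alt not in _VALID_BASES
                or ref == alt
            ):
                skipped += 1
                continue
            if donor_info_key is not None:
                donor = rec.info.get(donor_info_key)
                if donor is None:
                    skipped += 1
                    continue
                donor = str(donor)
            else:
                donor = fallback_donor
            mutations.append(Mutation(rec.chrom, rec.pos - 1, ref, alt, donor))
    return mutations, skipped


def write_mutations_tsv(dataset: MutationDataset, path: str | Path) -> None:
    """Write a catalog back to TSV with 1-based positions."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tdonor_id\n")
        for m in dataset.mutations:
            fh.write(f"{m.chrom}\t{m.pos + 1}\t{m.ref}\t{m.alt}\t{m.donor_id}\n")


def read_donor_metadata(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a donor metadata table: TSV with a header, first column donor_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 1:
        raise ParseError(f"{path}: empty donor table")
    id_col = df.columns[0]
    donors: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        meta = {
            k: v for k, v in row.items()
            if k != id_col and isinstance(v, str) and v != ""
        }
        donors[str(row[id_col])] = meta
    return donors


def write_donor_metadata(donors: Mapping[str, Mapping[str, str]],
                         path: str | Path) -> None:
    fields = sorted({k for meta in donors.values() for k in meta})
    with open(path, "w") as fh:
        fh.write("donor_id\t" + "\t".join(fields) + "\n")
        for donor_id in donors:
            meta = donors[donor_id]
            fh.write(donor_id + "\t" + "\t".join(meta.get(f, "") for f in fields) + "\n")


# --------------------------------------------------------------------------
# Signature catalogs (COSMIC SBS tab-separated matrix dialect)
# --------------------------------------------------------------------------

def read_signature_catalog(path: str | Path) -> SignatureCatalog:
    """Read a COSMIC-style 96-row signature matrix.

    Rows are channel labels ("A[C>A]A", arrow dialect also accepted), one
    column per signature. Rows are reordered to the canonical channel order;
    columns off unity by at most 1e-3 are renormalised with a warning.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != 96:
        raise DataError(f"{path}: expected 96 channel rows, found {df.shape[0]}")
    if df.shape[1] < 1:
        raise DataError(f"{path}: no signature columns")
    try:
        order = [parse_channel_label(str(lab)) for lab in df.index]
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None
    if len(set(order)) != 96:
        raise DataError(f"{path}: duplicate channel labels")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise DataError(f"{path}: non-numeric entries in signature matrix")
    if (values < 0).any():
        raise DataError(f"{path}: negative signature entries")
    reordered = np.empty_like(values)
    reordered[order, :] = values
    signatures = []
    for k, sig_id in enumerate(df.columns):
        col = reordered[:, k]
        total = col.sum()
        if abs(total - 1.0) > 1e-3:
            raise DataError(
                f"{path}: column {sig_id!r} sums to {total:.6f} (off by more than 1e-3)"
            )
        if abs(total - 1.0) > 1e-8:
            warnings.warn(
                f"{path}: column {sig_id!r} renormalized from {total:.6f}",
                stacklevel=2,
            )
        signatures.append(Signature(str(sig_id), col / total))
    return SignatureCatalog(signatures)


def write_signature_catalog(catalog: SignatureCatalog, path: str | Path) -> None:
    df = pd.DataFrame(
        catalog.matrix, index=list(CHANNELS), columns=list(catalog.ids)
    )
    df.index.name = "Type"
    df.to_csv(path, sep="\t")


# --------------------------------------------------------------------------
# JSON results
# --------------------------------------------------------------------------

def _jsonable(obj):
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if obj is None or isinstance(obj, (str, int, float, bool)):
        return obj
    raise DataError(f"cannot serialize {type(obj).__name__} to JSON")


def result_payload(result, schema_name: str | None = None) -> dict:
    """Convert a result object into a deterministic, versioned JSON payload."""
    payload = _jsonable(result)
    if not isinstance(payload, dict):
        payload = {"value": payload}
    payload.setdefault(
        "schema",
        {"name": schema_name or type(result).__name__, "version": SCHEMA_VERSION},
    )
    return payload


def write_json(result, path: str | Path, schema_name: str | None = None) -> dict:
    """Write any result object as deterministic JSON; returns the payload."""
    payload = result_payload(result, schema_name)
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return payload


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
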