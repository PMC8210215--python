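"""Simulation of genomes, region sets, donors and mutation catalogs with
known ground truth.

The mutation generator is site-constrained: it first decides whether a
mutation falls in the region set or in the rest of the genome (Bernoulli
with odds enrichment_factor * q : (1 - q), where q is the regions' share
of valid trinucleotide sites), then draws the mutation channel from the
exposure-weighted mixture of signatures adjusted to that compartment's
trinucleotide content, and finally places the mutation uniformly among the
compartment's positions whose trinucleotide matches the channel. Under
this model the in-region mutation spectrum is exactly the exposure-
weighted mixture of region-adjusted signatures — the generative model the
refitting estimator assumes — so parameter recovery exercises the solver
and the adjustment, not model mismatch. Channels with no available site in
the chosen compartment are resampled and counted.

All randomness flows from ``SimulationConfig.seed`` through per-stage
child seeds, so every artifact is bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .channels import (
    BASES,
    CHANNELS,
    CHANNEL_TO_TRINUC,
    PYRIMIDINES,
    collapsed_trinuc_codes,
    complement,
)
from .exceptions import DataError
from .io_formats import (
    GenomicRegion,
    Mutation,
    MutationDataset,
    ReferenceGenome,
    RegionSet,
    Signature,
    SignatureCatalog,
    write_bed,
    write_donor_metadata,
    write_fasta,
    write_json,
    write_mutations_tsv,
    write_signature_catalog,
)
from .region_windows import Window, merge_intervals
from .trinuc_context import CorrectionFactors, adjust_catalog

# rng stream salts, one per generation stage
_SALT_GENOME = 0
_SALT_REGIONS = 1
_SALT_MUTATIONS = 2
_SALT_METADATA = 3
_SALT_SIGNATURES = 4

_THERAPIES = ("chemotherapy", "surgery", "radiation", "no treatment")


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic dataset.

    Defaults describe a desk-scale cohort: a 100 kb random genome, 40
    binding-site-sized regions, 20 donors with 2000 mutations each — large
    enough for stable spectra, small enough to simulate in seconds.
    """

    genome_length: int = 100_000
    base_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_regions: int = 40
    region_size: int = 21
    min_spacing: int = 200
    n_donors: int = 20
    mutations_per_donor: int = 2000
    true_exposures: tuple[float, ...] | None = None
    in_region_enrichment_factor: float = 1.0
    seed: int = 0
    chrom_name: str = "chr1"
    edge_margin: int = 1200   # keep regions clear of chromosome ends

    def __post_init__(self) -> None:
        if self.genome_length < 1000:
            raise DataError("genome_length must be at least 1000 bp")
        w = np.asarray(self.base_weights, dtype=float)
        if w.shape != (4,) or (w < 0).any() or w.sum() <= 0:
            raise DataError("base_weights must be 4 non-negative weights, not all zero")
        if self.in_region_enrichment_factor < 0:
            raise DataError("in_region_enrichment_factor must be >= 0")
        if self.true_exposures is not None:
            e = np.asarray(self.true_exposures, dtype=float)
            if (e < 0).any() or abs(e.sum() - 1.0) > 1e-6:
                raise DataError("true_exposures must lie on the probability simplex")

    def rng(self, salt: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, salt])


def make_genome(config: SimulationConfig,
                out_fasta: str | Path | None = None) -> ReferenceGenome:
    """Draw an i.i.d. random genome from the configured base composition."""
    rng = config.rng(_SALT_GENOME)
    w = np.asarray(config.base_weights, dtype=float)
    p = w / w.sum()
    seq = "".join(rng.choice(list(BASES), size=config.genome_length, p=p))
    genome = ReferenceGenome.from_dict({config.chrom_name: seq})
    if out_fasta is not None:
        write_fasta({config.chrom_name: seq}, out_fasta)
    return genome


def make_regions(
    config: SimulationConfig,
    genome: ReferenceGenome,
    motif: str | None = None,
    out_bed: str | Path | None = None,
) -> tuple[RegionSet, ReferenceGenome]:
    """Place non-overlapping, sorted regions; optionally plant a motif.

    When ``motif`` is given, each region's sequence is overwritten with
    repeats of the motif (truncated to the region size), which skews the
    region set's trinucleotide content; the modified genome is returned
    alongside the regions.
    """
    rng = config.rng(_SALT_REGIONS)
    chrom = config.chrom_name
    length = genome.chrom_length(chrom)
    n, size, spacing = config.n_regions, config.region_size, config.min_spacing
    margin = min(config.edge_margin, max(0, (length - n * size) // 4))
    free = length - 2 * margin - n * size - (n - 1) * spacing
    if n < 1 or free < 0:
        raise DataError(
            f"cannot pack {n} regions of {size} bp with {spacing} bp spacing "
            f"into {length} bp"
        )
    gaps = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1)))
    regions = []
    pos = margin
    for i in range(n):
        pos += gaps[i] + (spacing if i > 0 else 0)
        regions.append(GenomicRegion(chrom, pos, pos + size))
        pos += size
    region_set = RegionSet("synthetic_regions", regions)
    if motif is not None:
        motif = motif.upper()
        if not set(motif) <= set(BASES):
            raise DataError(f"motif must be an ACGT string, got {motif!r}")
        seq = list(genome.get_sequence(chrom, 0, length))
        fill = (motif * (size // len(motif) + 1))[:size]
        for r in regions:
            seq[r.start:r.end] = fill
        genome = ReferenceGenome.from_dict({chrom: "".join(seq)})
    if out_bed is not None:
        write_bed(region_set, out_bed)
    return region_set, genome


def make_signature_catalog(n_signatures: int, seed: int = 0,
                           concentration: float = 0.08) -> SignatureCatalog:
    """Random sparse synthetic signatures (Dirichlet over the 96 channels)."""
    if n_signatures < 1:
        raise DataError("need at least one signature")
    rng = np.random.default_rng([seed, _SALT_SIGNATURES])
    sigs = []
    for k in range(n_signatures):
        probs = rng.dirichlet(np.full(96, concentration))
        sigs.append(Signature.from_unnormalized(f"SYN{k + 1:02d}", probs))
    return SignatureCatalog(sigs)


class _SiteIndex(NamedTuple):
    """Genome positions of valid trinucleotide sites, split by compartment."""

    region_sites: list[tuple[np.ndarray, np.ndarray]]  # per trinuc: (chrom_idx, pos)
    flank_sites: list[tuple[np.ndarray, np.ndarray]]
    region_counts: np.ndarray   # 32
    flank_counts: np.ndarray    # 32
    chrom_names: list[str]


def _build_site_index(genome: ReferenceGenome,
                      region_set: RegionSet) -> _SiteIndex:
    merged = merge_intervals(region_set)
    chrom_names = list(genome.chroms)
    region_sites = [([], []) for _ in range(32)]
    flank_sites = [([], []) for _ in range(32)]
    for ci, chrom in enumerate(chrom_names):
        length = genome.chrom_length(chrom)
        codes = collapsed_trinuc_codes(genome.get_sequence(chrom, 0, length))
        positions = np.arange(1, length - 1)
        valid = codes >= 0
        in_region = np.zeros(length - 2, dtype=bool)
        for start, end in merged.get(chrom, []):
            # a site is in-region when its whole 3-mer lies inside the region
            lo, hi = max(start + 1, 1), min(end - 1, length - 1)
            if hi > lo:
                in_region[lo - 1:hi - 1] = True
        for t in range(32):
            mask = valid & (codes == t)
            for target, sel in (
                (region_sites[t], mask & in_region),
                (flank_sites[t], mask & ~in_region),
            ):
                pos = positions[sel]
                target[0].append(np.full(pos.size, ci, dtype=np.intp))
                target[1].append(pos)

    def finalize(parts):
        return [
            (np.concatenate(cs) if cs else np.empty(0, dtype=np.intp),
             np.concatenate(ps) if ps else np.empty(0, dtype=np.intp))
            for cs, ps in parts
        ]

    region_final = finalize(region_sites)
    flank_final = finalize(flank_sites)
    return _SiteIndex(
        region_sites=region_final,
        flank_sites=flank_final,
        region_counts=np.array([p.size for _, p in region_final]),
        flank_counts=np.array([p.size for _, p in flank_final]),
        chrom_names=chrom_names,
    )


def _compartment_mixture(exposures: np.ndarray, catalog: SignatureCatalog,
                         comp_counts: np.ndarray,
                         genome_counts: np.ndarray) -> np.ndarray:
    """Exposure-weighted mixture of signatures adjusted to a compartment."""
    comp_freq = comp_counts / comp_counts.sum()
    genome_freq = genome_counts / genome_counts.sum()
    factors = np.ones(32)
    nz = genome_freq > 0
    factors[nz] = comp_freq[nz] / genome_freq[nz]
    adjusted = adjust_catalog(catalog, CorrectionFactors(factors))
    return adjusted.matrix @ exposures


def simulate_mutations(
    config: SimulationConfig,
    genome: ReferenceGenome,
    regions: RegionSet,
    catalog: SignatureCatalog,
    out_tsv: str | Path | None = None,
    out_truth_json: str | Path | None = None,
    out_donors_tsv: str | Path | None = None,
) -> tuple[MutationDataset, dict]:
    """Draw a donor cohort's mutation catalog with known ground truth."""
    rng = config.rng(_SALT_MUTATIONS)
    K = len(catalog)
    if config.true_exposures is None:
        exposures = np.full(K, 1.0 / K)
    else:
        exposures = np.asarray(config.true_exposures, dtype=float)
        if exposures.shape != (K,):
            raise DataError(
                f"true_exposures has {exposures.size} entries for {K} signatures"
            )

    index = _build_site_index(genome, regions)
    genome_counts = index.region_counts + index.flank_counts
    if genome_counts.sum() == 0:
        raise DataError("genome has no valid trinucleotide sites")
    q = index.region_counts.sum() / genome_counts.sum()
    f = config.in_region_enrichment_factor
    p_in = (f * q) / (f * q + (1.0 - q)) if (f * q + (1.0 - q)) > 0 else 0.0

    mix_region = _compartment_mixture(
        exposures, catalog, index.region_counts, genome_counts
    )
    mix_flank = _compartment_mixture(
        exposures, catalog, index.flank_counts, genome_counts
    )
    comp_counts = (index.region_counts, index.flank_counts)
    comp_sites = (index.region_sites, index.flank_sites)
    # zero out channels whose trinucleotide has no site in the compartment
    available = [
        counts[CHANNEL_TO_TRINUC] > 0 for counts in comp_counts
    ]

    n_resampled = 0

    def draw_channels(mixture: np.ndarray, avail: np.ndarray,
                      n: int) -> np.ndarray:
        nonlocal n_resampled
        if n == 0:
            return np.empty(0, dtype=np.intp)
        if not (mixture[avail] > 0).any():
            raise DataError(
                "no simulatable channel: the mixture's support has no sites"
            )
        channels = rng.choice(96, size=n, p=mixture)
        bad = ~avail[channels]
        while bad.any():
            n_resampled += int(bad.sum())
            channels[bad] = rng.choice(96, size=int(bad.sum()), p=mixture)
            bad = ~avail[channels]
        return channels

    mutations: list[Mutation] = []
    per_donor_counts: dict[str, dict[str, int]] = {}
    donor_ids = [f"D{d + 1:03d}" for d in range(config.n_donors)]
    channel_alt = [CHANNELS[j][4] for j in range(96)]
    channel_ref = [CHANNELS[j][2] for j in range(96)]
    for donor_id in donor_ids:
        n_total = config.mutations_per_donor
        n_in = int(rng.binomial(n_total, p_in)) if n_total else 0
        counts = {"in_region": n_in, "flank": n_total - n_in}
        per_donor_counts[donor_id] = counts
        for comp, n_comp, mixture in (
            (0, n_in, mix_region), (1, n_total - n_in, mix_flank)
        ):
            channels = draw_channels(mixture, available[comp], n_comp)
            for t in np.unique(channels):
                t_idx = int(CHANNEL_TO_TRINUC[t])
                chrom_idx, positions = comp_sites[comp][t_idx]
                picks = rng.integers(0, positions.size, size=int((channels == t).sum()))
                for site in picks:
                    chrom = index.chrom_names[int(chrom_idx[site])]
                    pos = int(positions[site])
                    base = genome.get_sequence(chrom, pos, pos + 1)
                    if base in PYRIMIDINES:
                        ref, alt = channel_ref[t], channel_alt[t]
                    else:
                        ref = base
                        alt = complement(channel_alt[t])
                    mutations.append(Mutation(chrom, pos, ref, alt, donor_id))

    mutations.sort(key=lambda m: (m.chrom, m.pos, m.donor_id))
    meta_rng = config.rng(_SALT_METADATA)
    donors = {
        d: {
            "donor_sex": str(meta_rng.choice(["M", "F"])),
            "donor_age": str(int(meta_rng.integers(30, 81))),
            "first_therapy_type": str(meta_rng.choice(_THERAPIES)),
        }
        for d in donor_ids
    }
    dataset = MutationDataset("synthetic_cohort", mutations, donors)
    truth = {
        "schema": {"name": "SimulationTruth", "version": 1},
        "seed": config.seed,
        "exposures": dict(zip(catalog.ids, exposures.tolist())),
        "in_region_enrichment_factor": f,
        "p_in_region": p_in,
        "region_site_fraction": q,
        "per_donor_counts": per_donor_counts,
        "n_resampled": n_resampled,
        "n_donors": config.n_donors,
        "mutations_per_donor": config.mutations_per_donor,
    }
    if out_tsv is not None:
        write_mutations_tsv(dataset, out_tsv)
    if out_donors_tsv is not None:
        write_donor_metadata(donors, out_donors_tsv)
    if out_truth_json is not None:
        write_json(truth, out_truth_json, schema_name="SimulationTruth")
    return dataset, truth


class SimulationBundle(NamedTuple):
    genome: ReferenceGenome
    regions: RegionSet
    catalog: SignatureCatalog
    dataset: MutationDataset
    truth: dict


def simulate_study(
    config: SimulationConfig,
    catalog: SignatureCatalog | None = None,
    n_signatures: int = 3,
    motif: str | None = None,
    out_dir: str | Path | None = None,
) -> SimulationBundle:
    """Generate a full synthetic study (genome, regions, catalog, mutations).

    With ``out_dir`` set, writes genome.fa, regions.bed, mutations.tsv,
    donors.tsv, signatures.tsv and truth.json in the dialects the readers
    accept.
    """
    if catalog is None:
        catalog = make_signature_catalog(n_signatures, seed=config.seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    genome = make_genome(config)
    regions, genome = make_regions(config, genome, motif=motif)
    dataset, truth = simulate_mutations(
        config, genome, regions, catalog,
        out_tsv=out / "mutations.tsv" if out else None,
        out_truth_json=out / "truth.json" if out else None,
        out_donors_tsv=out / "donors.tsv" if out else None,
    )
    if out is not None:
        chrom = config.chrom_name
        write_fasta(
            {chrom: genome.get_sequence(chrom, 0, genome.chrom_length(chrom))},
            out / "genome.fa",
        )
        write_bed(regions, out / "regions.bed")
        write_signature_catalog(catalog, out / "signatures.tsv")
    return SimulationBundle(genome, regions, catalog, dataset, truth)


def simulate_uniform_window_mutations(
    windows: list[Window],
    n_per_window: int,
    rng: np.random.Generator,
    donor_id: str = "D001",
) -> list[Mutation]:
    """Place dummy C>T mutations uniformly across window positions.

    This is the null model of the local-enrichment permutation test and is
    used to check its calibration.
    """
    mutations = []
    for w in windows:
        offsets = rng.integers(-w.half_width, w.half_width + 1, size=n_per_window)
        for off in offsets:
            mutations.append(Mutation(w.chrom, int(w.center + off), "C", "T", donor_id))
    return mutations
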