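"""Channel classification, spectra, trinucleotide accounting, adjustment."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from regmut import (
    CorrectionFactors,
    DataError,
    DegenerateSignatureError,
    GenomicRegion,
    Mutation,
    RefMismatchError,
    ReferenceGenome,
    Signature,
    SignatureCatalog,
    TrinucFrequencies,
    adjust_catalog,
    adjust_signature,
    classify_mutation,
    correction_factors,
    genome_frequencies,
    spectrum,
    trinuc_frequencies,
)
from regmut.channels import (
    CHANNELS,
    CHANNEL_TO_TRINUC,
    TRINUCLEOTIDES,
    channel_of,
    collapse_trinuc,
    parse_channel_label,
    revcomp,
)

BASES = "ACGT"


# ----------------------------------------------------------------- channels

def test_channel_enumeration():
    assert len(CHANNELS) == 96
    assert len(set(CHANNELS)) == 96
    assert len(TRINUCLEOTIDES) == len(set(TRINUCLEOTIDES)) == 32
    # 6 substitution blocks of 16 contexts each, in COSMIC order
    assert CHANNELS[0] == "A[C>A]A" and CHANNELS[16] == "A[C>G]A"
    assert CHANNELS[95] == "T[T>G]T"


def test_parse_channel_label_dialects():
    assert parse_channel_label("A[C>A]A") == 0
    assert parse_channel_label("A[C→A]A") == 0
    assert parse_channel_label("a[c->a]a") == 0
    with pytest.raises(ValueError):
        parse_channel_label("A[A>C]A")  # purine-referenced, not canonical
    with pytest.raises(ValueError):
        parse_channel_label("ACA")


# ------------------------------------------------------------- classification

def test_classify_direct_and_reverse_complement():
    ref = ReferenceGenome.from_dict({"c": "ACGA"})
    ch = classify_mutation(Mutation("c", 1, "C", "T", "D"), ref)
    assert ch.label == "A[C>T]G"
    # G>A at pos 2 (context CGA) collapses to T[C>T]G
    ch = classify_mutation(Mutation("c", 2, "G", "A", "D"), ref)
    assert ch.label == "T[C>T]G"


def test_classify_boundaries_and_n_are_unclassifiable():
    ref = ReferenceGenome.from_dict({"c": "CCNCC"})
    assert classify_mutation(Mutation("c", 0, "C", "T", "D"), ref) is None
    assert classify_mutation(Mutation("c", 4, "C", "T", "D"), ref) is None
    assert classify_mutation(Mutation("c", 1, "C", "T", "D"), ref) is None  # N flank


def test_classify_ref_mismatch_raises():
    ref = ReferenceGenome.from_dict({"c": "ACGA"})
    with pytest.raises(RefMismatchError):
        classify_mutation(Mutation("c", 1, "T", "A", "D"), ref)


@given(
    st.sampled_from(BASES), st.sampled_from(BASES), st.sampled_from(BASES),
    st.sampled_from(BASES),
)
def test_classify_strand_involution(five, ref, alt, three):
    """The same physical event reaches the same channel from either strand."""
    if ref == alt:
        alt = BASES[(BASES.index(alt) + 1) % 4]
    fwd = channel_of(five, ref, alt, three)
    comp = dict(zip("ACGT", "TGCA"))
    rev = channel_of(comp[three], comp[ref], comp[alt], comp[five])
    assert fwd == rev


# ------------------------------------------------------------------- spectrum

def test_spectrum_counts_and_fractions():
    ref = ReferenceGenome.from_dict({"c": "AACGAACGAA"})
    muts = [Mutation("c", 2, "C", "T", "D"), Mutation("c", 6, "C", "T", "D")]
    sp = spectrum(muts, ref)
    assert sp.total == 2
    assert sp.counts[parse_channel_label("A[C>T]G")] == 2
    assert (sp.counts > 0).sum() == 1
    assert abs(sp.fractions.sum() - 1.0) < 1e-12


def test_spectrum_empty_and_unclassifiable():
    ref = ReferenceGenome.from_dict({"c": "ACGA"})
    sp = spectrum([], ref)
    assert sp.total == 0 and sp.fractions is None
    sp = spectrum([Mutation("c", 0, "A", "C", "D")], ref)
    assert sp.total == 0 and sp.n_unclassifiable == 1


def test_spectrum_skips_ref_mismatch_with_warning():
    ref = ReferenceGenome.from_dict({"c": "ACGA"})
    with pytest.warns(UserWarning, match="mismatch"):
        sp = spectrum([Mutation("c", 1, "G", "A", "D"),
                       Mutation("c", 1, "C", "T", "D")], ref)
    assert sp.total == 1 and sp.n_ref_mismatch == 1


# ----------------------------------------------------------- trinuc frequencies

def test_trinuc_frequencies_acgt_hand_enumeration():
    # "ACGT": 3-mers ACG and CGT (revcomp ACG) -> all mass on ACG
    ref = ReferenceGenome.from_dict({"c": "ACGT"})
    tf = trinuc_frequencies([GenomicRegion("c", 0, 4)], ref)
    assert tf.total == 2
    assert tf.frequencies[TRINUCLEOTIDES.index("ACG")] == 1.0


def test_trinuc_frequencies_homopolymer():
    ref = ReferenceGenome.from_dict({"c": "CCCC"})
    tf = genome_frequencies(ref)
    assert tf.frequencies[TRINUCLEOTIDES.index("CCC")] == 1.0


def test_trinuc_frequencies_additive_over_disjoint_intervals():
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list(BASES), size=400))
    ref = ReferenceGenome.from_dict({"c": seq})
    a = trinuc_frequencies([GenomicRegion("c", 0, 100)], ref)
    b = trinuc_frequencies([GenomicRegion("c", 200, 350)], ref)
    both = trinuc_frequencies(
        [GenomicRegion("c", 0, 100), GenomicRegion("c", 200, 350)], ref
    )
    np.testing.assert_array_equal(both.counts, a.counts + b.counts)


def test_trinuc_frequencies_merges_overlaps_and_skips_n():
    ref = ReferenceGenome.from_dict({"c": "ACGTNACGT"})
    merged = trinuc_frequencies(
        [GenomicRegion("c", 0, 6), GenomicRegion("c", 3, 9)], ref
    )
    single = trinuc_frequencies([GenomicRegion("c", 0, 9)], ref)
    np.testing.assert_array_equal(merged.counts, single.counts)
    assert merged.total == 4  # ACG, CGT from both ACGT islands; N 3-mers dropped


def test_trinuc_frequencies_short_interval_warns():
    ref = ReferenceGenome.from_dict({"c": "ACGTACGT"})
    with pytest.warns(UserWarning, match="shorter than 3"):
        tf = trinuc_frequencies(
            [GenomicRegion("c", 0, 2), GenomicRegion("c", 3, 8)], ref
        )
    assert tf.total == 3


def test_trinuc_frequencies_matches_brute_force_on_random_sequence():
    rng = np.random.default_rng(11)
    seq = "".join(rng.choice(list(BASES + "N"), p=[0.24] * 4 + [0.04], size=10_000))
    ref = ReferenceGenome.from_dict({"c": seq})
    tf = genome_frequencies(ref)
    brute = np.zeros(32, dtype=int)
    for i in range(len(seq) - 2):
        tri = seq[i:i + 3]
        if "N" in tri:
            continue
        brute[TRINUCLEOTIDES.index(collapse_trinuc(tri))] += 1
    np.testing.assert_array_equal(tf.counts, brute)


# ---------------------------------------------------------- correction factors

def _freqs(counts):
    return TrinucFrequencies(np.asarray(counts, dtype=int))


def test_correction_factors_identity_and_ratio():
    counts = np.arange(1, 33)
    assert np.allclose(correction_factors(_freqs(counts), _freqs(counts)).factors, 1.0)
    region = np.ones(32, dtype=int)
    region[0] = 4  # ACA over-represented
    genome = np.ones(32, dtype=int)
    cf = correction_factors(_freqs(region), _freqs(genome))
    ratio = (4 / 35) / (1 / 32)
    assert np.isclose(cf.factors[0], ratio)


def test_correction_factors_zero_rules():
    region = np.ones(32, dtype=int)
    region[3] = 0
    genome = np.ones(32, dtype=int)
    cf = correction_factors(_freqs(region), _freqs(genome))
    assert cf.factors[3] == 0.0
    genome[5] = 0
    region2 = np.ones(32, dtype=int)
    with pytest.raises(DataError, match="absent from genome"):
        correction_factors(_freqs(region2), _freqs(genome))


def test_correction_factors_monotone_in_region_count():
    genome = np.full(32, 100, dtype=int)
    lo = np.full(32, 10, dtype=int)
    hi = lo.copy()
    hi[7] += 15
    c_lo = correction_factors(_freqs(lo), _freqs(genome)).factors[7]
    c_hi = correction_factors(_freqs(hi), _freqs(genome)).factors[7]
    assert c_hi > c_lo


# --------------------------------------------------------------- adjustment

def test_adjust_signature_identity():
    sig = Signature("S", np.full(96, 1 / 96))
    adj = adjust_signature(sig, CorrectionFactors(np.ones(32)))
    np.testing.assert_allclose(adj.probs, sig.probs)


def test_adjust_signature_forced_arithmetic():
    probs = np.zeros(96)
    ja, jb = 0, 40  # channels with distinct underlying trinucleotides
    assert CHANNEL_TO_TRINUC[ja] != CHANNEL_TO_TRINUC[jb]
    probs[ja] = probs[jb] = 0.5
    factors = np.ones(32)
    factors[CHANNEL_TO_TRINUC[ja]] = 2.0
    adj = adjust_signature(Signature("S", probs), CorrectionFactors(factors))
    assert np.isclose(adj.probs[ja], 2 / 3) and np.isclose(adj.probs[jb], 1 / 3)
    assert abs(adj.probs.sum() - 1.0) < 1e-12


def test_adjust_signature_degenerate_error_names_signature():
    probs = np.zeros(96)
    probs[0] = 1.0
    factors = np.ones(32)
    factors[CHANNEL_TO_TRINUC[0]] = 0.0
    with pytest.raises(DegenerateSignatureError, match="S7"):
        adjust_signature(Signature("S7", probs), CorrectionFactors(factors))


@given(st.integers(0, 2**31 - 1))
def test_adjusted_signatures_sum_to_one(seed):
    rng = np.random.default_rng(seed)
    sig = Signature("S", rng.dirichlet(np.full(96, 0.2)))
    factors = CorrectionFactors(rng.uniform(0.1, 3.0, size=32))
    adj = adjust_signature(sig, factors)
    assert abs(adj.probs.sum() - 1.0) < 1e-9


def test_whole_genome_adjustment_is_identity():
    """Factors of the genome against itself are 1; adjustment is a no-op."""
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list(BASES), size=3000))
    ref = ReferenceGenome.from_dict({"c": seq})
    gf = genome_frequencies(ref)
    cf = correction_factors(gf, gf)
    np.testing.assert_array_equal(cf.factors, np.ones(32))
    cat = SignatureCatalog([Signature("S", rng.dirichlet(np.ones(96)))])
    adj = adjust_catalog(cat, cf)
    np.testing.assert_array_equal(adj.matrix, cat.matrix)
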