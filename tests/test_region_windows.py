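"""Windows, mapping, histograms, fold enrichment, donor summaries, predicates."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from regmut import (
    DataError,
    GenomicRegion,
    Mutation,
    MutationDataset,
    PredicateSyntaxError,
    RegionSet,
    Window,
    build_windows,
    donor_summary,
    filter_donors,
    fold_enrichment,
    histogram,
    intersect_mutations,
    map_mutations,
    region_center,
)
from regmut.region_windows import parse_predicate


def _rs(*triples):
    return RegionSet("r", [GenomicRegion(c, s, e) for c, s, e in triples])


# ----------------------------------------------------------------- centers

@pytest.mark.parametrize(
    "start,end,center",
    [(100, 200, 150), (100, 201, 150), (0, 1, 0), (7, 10, 8)],
)
def test_region_center_floor_formula(start, end, center):
    assert region_center(GenomicRegion("chr1", start, end)) == center


@given(st.integers(0, 10**6), st.integers(1, 10**4))
def test_region_center_inside_region(start, length):
    r = GenomicRegion("chr1", start, start + length)
    assert r.start <= region_center(r) < r.end


# ----------------------------------------------------------------- windows

@pytest.mark.parametrize(
    "largest,expected_hw", [(400, 1000), (1000, 1000), (3000, 3000),
                            (5000, 5000), (12000, 5000)]
)
def test_default_half_width_rule(largest, expected_hw):
    rs = _rs(("chr1", 10000, 10000 + largest), ("chr1", 30000, 30010))
    windows = build_windows(rs)
    assert all(w.half_width == expected_hw for w in windows)


def test_build_windows_explicit_half_width_and_target():
    rs = _rs(("chr1", 100, 119))
    (w,) = build_windows(rs, half_width=50)
    assert (w.center, w.start, w.end) == (109, 59, 160)
    assert (w.target_start, w.target_end) == (100, 119)
    assert w.length == 101


def test_build_windows_clips_target_to_window():
    rs = _rs(("chr1", 0, 12000))
    (w,) = build_windows(rs)  # capped at +-5000
    assert w.half_width == 5000
    assert w.target_start >= w.start and w.target_end <= w.end


def test_build_windows_rejects_bad_half_width():
    with pytest.raises(DataError):
        build_windows(_rs(("chr1", 0, 10)), half_width=0)


# ----------------------------------------------------------------- mapping

def test_map_mutations_offsets_and_boundary():
    rs = _rs(("chr1", 90, 111))
    windows = build_windows(rs, half_width=10)  # center 100, covers 90..110
    center = windows[0].center
    muts = [Mutation("chr1", center, "C", "T", "D1"),
            Mutation("chr1", center + 10, "C", "T", "D1"),
            Mutation("chr1", center + 11, "C", "T", "D1"),
            Mutation("chr2", center, "C", "T", "D1")]
    mapped = map_mutations(muts, windows)
    assert [p.offset for p in mapped] == [0, 10]


def test_map_mutations_overlapping_windows_emit_per_window():
    rs = _rs(("chr1", 95, 106), ("chr1", 100, 111))
    windows = build_windows(rs, half_width=20)
    mapped = map_mutations([Mutation("chr1", 102, "C", "T", "D1")], windows)
    assert len(mapped) == 2


def test_map_mutations_agrees_with_brute_force():
    rng = np.random.default_rng(5)
    regions = []
    pos = 0
    for _ in range(15):
        pos += int(rng.integers(10, 300))
        regions.append(GenomicRegion("chr1", pos, pos + int(rng.integers(5, 80))))
        pos = regions[-1].end
    windows = build_windows(RegionSet("r", regions), half_width=int(rng.integers(30, 200)))
    muts = [Mutation("chr1", int(p), "C", "T", "D1")
            for p in rng.integers(0, pos + 500, size=300)]
    mapped = map_mutations(muts, windows)
    brute = [
        (m, w, m.pos - w.center)
        for m in muts for w in windows
        if abs(m.pos - w.center) <= w.half_width
    ]
    assert sorted((id(m), w.center, o) for m, w, o in mapped) == \
        sorted((id(m), w.center, o) for m, w, o in brute)


# --------------------------------------------------------------- histograms

def _mapped_at_offsets(offsets, half_width=50, muts=None):
    w = Window("chr1", 1000, half_width, 990, 1011)
    muts = muts or [Mutation("chr1", 1000 + o, "C", "T", "D1") for o in offsets]
    return map_mutations(muts, [w])


def test_histogram_bin_size_one():
    hist = histogram(_mapped_at_offsets([-1, 0, 0]))
    assert hist.counts == {-1: 1, 0: 2}
    assert hist.n_mapped == 3


def test_histogram_bin_size_ten_groups_offsets():
    hist = histogram(_mapped_at_offsets(list(range(10))), bin_size=10)
    assert hist.counts == {0: 10}


def test_histogram_class_filter_collapses_reverse_complement():
    muts = [Mutation("chr1", 1000, "C", "T", "D1"),
            Mutation("chr1", 1001, "G", "A", "D1"),
            Mutation("chr1", 1002, "C", "A", "D1")]
    mapped = _mapped_at_offsets(None, muts=muts)
    assert histogram(mapped, class_filter="C>T").n_mapped == 2
    assert histogram(mapped, class_filter="C>T",
                     collapse_complement=False).n_mapped == 1
    assert histogram(mapped, class_filter="C>*").n_mapped == 3


def test_histogram_unknown_filter_token():
    with pytest.raises(DataError, match="class filter"):
        histogram(_mapped_at_offsets([0]), class_filter="Q>Z")


@given(st.lists(st.integers(-50, 50), min_size=1, max_size=60),
       st.integers(1, 7))
def test_histogram_conserves_counts(offsets, bin_size):
    hist = histogram(_mapped_at_offsets(offsets), bin_size=bin_size)
    assert sum(hist.counts.values()) == len(offsets) == hist.n_mapped


# ---------------------------------------------------------- fold enrichment

def test_fold_enrichment_uniform_is_one():
    w = Window("chr1", 100, 2, 99, 102)  # 5 positions
    muts = [Mutation("chr1", 100 + o, "C", "T", "D1") for o in (-2, -1, 0, 1, 2)]
    profile = fold_enrichment(map_mutations(muts, [w]), bin_size=1)
    np.testing.assert_allclose(profile.values, 1.0)


def test_fold_enrichment_concentrated_bin():
    # all mutations in one of B equally weighted bins: that bin reads B, rest 0
    w = Window("chr1", 1000, 14, 995, 1006)  # 29 positions, bins -14..14
    muts = [Mutation("chr1", 1000, "C", "T", "D1") for _ in range(6)]
    profile = fold_enrichment(map_mutations(muts, [w]), bin_size=1)
    occupied = profile.values[profile.bin_starts == 0]
    np.testing.assert_allclose(occupied, 29.0)
    assert (profile.values[profile.bin_starts != 0] == 0).all()


def test_fold_enrichment_empty_is_undefined():
    w = Window("chr1", 100, 10, 95, 106)
    profile = fold_enrichment(map_mutations([], [w]))
    assert not profile.defined


@given(st.lists(st.integers(-20, 20), min_size=1, max_size=40), st.integers(1, 9))
def test_fold_enrichment_weighted_mean_is_one(offsets, bin_size):
    w = Window("chr1", 500, 20, 495, 506)
    muts = [Mutation("chr1", 500 + o, "C", "T", "D1") for o in offsets]
    profile = fold_enrichment(map_mutations(muts, [w]), bin_size=bin_size)
    weights = profile.expected / profile.expected.sum()
    assert abs((profile.values * weights).sum() - 1.0) < 1e-9


# --------------------------------------------------------------- intersection

def test_intersect_half_open_and_dedup():
    rs = _rs(("chr1", 100, 119), ("chr1", 110, 130))
    inside = Mutation("chr1", 115, "C", "T", "D1")  # covered by both regions
    edge_in = Mutation("chr1", 100, "C", "T", "D1")
    edge_out = Mutation("chr1", 130, "C", "T", "D1")
    got = intersect_mutations([inside, edge_in, edge_out], rs)
    assert got == [inside, edge_in]


# --------------------------------------------------------------- donor summary

def test_donor_summary_collapse_and_titv(toy_dataset):
    muts = [Mutation("chr1", 10, "C", "T", "D1"),
            Mutation("chr1", 11, "G", "A", "D1"),
            Mutation("chr1", 12, "C", "A", "D2")]
    ds = MutationDataset("x", muts)
    summary = donor_summary(muts, ds)
    d1 = dict(zip(summary.classes, summary.counts["D1"]))
    assert d1["C>T"] == 2
    assert summary.ti["D1"] == 2 and summary.tv["D1"] == 0
    assert summary.ti["D2"] == 0 and summary.tv["D2"] == 1


def test_donor_summary_includes_zero_donors_and_stats():
    ds = MutationDataset("x", [], {"D1": {}, "D2": {}, "D3": {}})
    muts = [Mutation("chr1", 1, "C", "T", "D1")] * 1 + \
           [Mutation("chr1", 2, "C", "T", "D2")] * 2 + \
           [Mutation("chr1", 3, "C", "T", "D3")] * 9
    for m in muts:
        ds.mutations.append(m)
    summary = donor_summary(muts, ds)
    st_ct = summary.stats["C>T"]
    assert (st_ct["min"], st_ct["median"], st_ct["max"]) == (1, 2, 9)


@given(st.lists(st.sampled_from(
    [("C", "T"), ("G", "A"), ("C", "A"), ("T", "G"), ("A", "C"), ("T", "C")]),
    min_size=1, max_size=30))
def test_donor_summary_ti_tv_partition(changes):
    muts = [Mutation("chr1", i + 1, r, a, "D1") for i, (r, a) in enumerate(changes)]
    ds = MutationDataset("x", muts)
    summary = donor_summary(muts, ds)
    assert summary.ti["D1"] + summary.tv["D1"] == len(changes)


def test_donor_summary_trinucleotide_level(toy_reference, toy_dataset):
    summary = donor_summary(toy_dataset.mutations, toy_dataset,
                            level="trinucleotide", reference=toy_reference)
    assert len(summary.classes) == 96
    total = sum(sum(v) for v in summary.counts.values())
    assert total + summary.n_unclassifiable == len(toy_dataset)


# ----------------------------------------------------------- donor predicates

def test_filter_donors_simple_equality(toy_dataset):
    out = filter_donors(toy_dataset, "donor_sex = 'M'")
    assert sorted(out.donors) == ["D1", "D3"]
    assert all(m.donor_id in ("D1", "D3") for m in out.mutations)


def test_filter_donors_paper_style_predicate(toy_dataset):
    out = filter_donors(
        toy_dataset,
        "(donor_sex = 'M') AND (first_therapy_type IN {'chemotherapy', 'surgery'})",
    )
    assert sorted(out.donors) == ["D1"]


def test_filter_donors_parentheses_precedence(toy_dataset):
    # without parentheses AND binds tighter than OR
    a = filter_donors(toy_dataset, "donor_sex = 'F' OR donor_sex = 'M' AND donor_age < 50")
    assert sorted(a.donors) == ["D2"]
    b = filter_donors(toy_dataset, "(donor_sex = 'F' OR donor_sex = 'M') AND donor_age < 50")
    assert sorted(b.donors) == ["D2"]
    c = filter_donors(toy_dataset, "donor_sex = 'M' OR donor_sex = 'F' AND donor_age < 50")
    assert sorted(c.donors) == ["D1", "D2", "D3"]


def test_filter_donors_missing_metadata_excludes(toy_dataset):
    # D3 has no donor_age: excluded by any comparison on that field
    out = filter_donors(toy_dataset, "donor_age < 100")
    assert sorted(out.donors) == ["D1", "D2"]
    out = filter_donors(toy_dataset, "donor_age != 45")
    assert sorted(out.donors) == ["D1"]


def test_filter_donors_unknown_field_warns_and_matches_none(toy_dataset):
    with pytest.warns(UserWarning, match="unknown"):
        out = filter_donors(toy_dataset, "no_such_field = 'x'")
    assert len(out.donors) == 0 and len(out.mutations) == 0


def test_predicate_syntax_error_reports_position():
    with pytest.raises(PredicateSyntaxError) as exc:
        parse_predicate("donor_sex = 'M' AND (")
    assert "position" in str(exc.value)
    with pytest.raises(PredicateSyntaxError):
        parse_predicate("")
    with pytest.raises(PredicateSyntaxError):
        parse_predicate("donor_sex ~ 'M'")


def test_predicate_numeric_comparisons():
    ast = parse_predicate("age >= 50 AND age < 60")
    assert ast.match({"age": "55"})
    assert not ast.match({"age": "49"})
    assert not ast.match({"age": "not_a_number"})
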