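import pytest

import varcontext as vc
from varcontext.fixtures import EmbeddedRepeat, FixtureSpec, make_reference
from varcontext.io import ReferenceSequence, ReferenceSet
from varcontext.tandem import (
    RepeatUnit,
    _region_from_units,
    assemble_region,
    candidate_motifs,
    qc_and_trim,
    remove_redundancy,
    search_units,
    variant_site,
)

PRIMITIVE_MOTIFS = {1: "A", 2: "AT", 3: "AGC", 4: "AATC", 5: "AGCTC", 6: "AATGCC"}


def _snv_in(refs, pos):
    base = refs["chr_fix"].base(pos)
    alt = "G" if base != "G" else "T"
    norm = vc.normalize(vc.VariantRecord("chr_fix", pos, base, alt), refs)
    return norm, vc.aligned_positions(norm, refs)


def test_variant_site_brackets_the_affected_span(gc7):
    site = variant_site(gc7["deletion"], gc7["ann"])
    assert (site.left_boundary, site.right_boundary) == (122, 137)
    refs = ReferenceSet()
    refs["c"] = ReferenceSequence("c", "ACGT" * 20)
    snv = vc.normalize(vc.VariantRecord("c", 50, refs["c"].base(50), "A"), refs)
    site = variant_site(snv, vc.aligned_positions(snv, refs))
    assert (site.left_boundary, site.right_boundary) == (49, 51)


def test_variant_site_skips_n_alleles():
    refs = ReferenceSet()
    refs["c"] = ReferenceSequence("c", "ACGTNACGTACGT")
    v = vc.normalize(vc.VariantRecord("c", 5, "N", "A"), refs)
    assert variant_site(v, vc.aligned_positions(v, refs)) is None


def test_candidate_motif_enumeration_counts():
    refs = ReferenceSet()
    refs["c"] = ReferenceSequence("c", "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT" * 3)
    snv = vc.normalize(vc.VariantRecord("c", 50, refs["c"].base(50), "A"), refs)
    site = variant_site(snv, vc.aligned_positions(snv, refs))
    p1 = vc.TandemRepeatParams(min_unit=1, max_unit=1)
    assert [(w, s) for w, _, s in candidate_motifs(site, refs, p1)] == [
        (1, 49), (1, 50), (1, 51)
    ]
    p2 = vc.TandemRepeatParams(min_unit=2, max_unit=2)
    assert [s for _, _, s in candidate_motifs(site, refs, p2)] == [48, 49, 50, 51]


def test_candidate_motifs_clipped_at_contig_start():
    refs = ReferenceSet()
    refs["c"] = ReferenceSequence("c", "ACGTACGTACGT")
    v = vc.normalize(vc.VariantRecord("c", 1, "A", "G"), refs)
    site = variant_site(v, vc.aligned_positions(v, refs))
    p3 = vc.TandemRepeatParams(min_unit=3, max_unit=3)
    starts = [s for _, _, s in candidate_motifs(site, refs, p3)]
    assert min(starts) == 1  # windows before base 1 are omitted


def test_search_units_collects_perfect_run(gc7):
    refs = gc7["refs"]
    p = vc.TandemRepeatParams.perfect()
    units = search_units("GC", 123, "3'", refs, "chr_fix", p)
    assert len(units) == 6
    assert all(u.gap == 0 and u.mismatches == 0 for u in units)
    assert units[-1].end == 136
    # nothing 5' of the tract start
    assert search_units("GC", 123, "5'", refs, "chr_fix", p) == []


def test_search_units_finds_nothing_in_unique_sequence():
    refs = ReferenceSet()
    refs["c"] = ReferenceSequence("c", "TTAGACCTGATCAAGGCATTCAGGAC")
    p = vc.TandemRepeatParams.perfect()
    assert search_units("GC", 16, "3'", refs, "c", p) == []


def test_search_units_accepts_mismatched_unit_within_gap_reach():
    """(GCA)(GCA)(GCT)(GCA)(GCA) with unit similarity 2/3 and a fixed gap
    tolerance of 2: the mutated middle unit is accepted with one mismatch and
    the consensus recomputation leaves exactly one mismatched base."""
    seq = "TTGATCGGATTACAGTTCGAT" + "GCA" * 2 + "GCT" + "GCA" * 2 + "TTCGATAGGA"
    refs = ReferenceSet()
    refs["c"] = ReferenceSequence("c", seq)
    p = vc.TandemRepeatParams(
        similarity_threshold=2 / 3, max_gap=2, min_copy=3,
        min_alignment_score=10.0, min_match_pct=80.0,
    )
    units = search_units("GCA", 22, "3'", refs, "c", p)
    region = assemble_region("GCA", 22, [], units, refs, "c", p)
    assert region.copy_number == 5
    assert region.motif == "GCA"  # consensus over the five units
    assert region.mismatch_bases == 1 and region.gap_bases == 0
    assert sorted(u.mismatches for u in region.units) == [0, 0, 0, 0, 1]


def test_assembled_region_scores_follow_the_closed_identities(gc7):
    refs = gc7["refs"]
    p = vc.TandemRepeatParams.perfect()  # MS=2, MIS=-5, GS=-7
    units = search_units("GC", 123, "3'", refs, "chr_fix", p)
    region = assemble_region("GC", 123, [], units, refs, "chr_fix", p)
    assert (region.start, region.end, region.copy_number) == (123, 136, 7)
    assert (region.match_bases, region.mismatch_bases, region.gap_bases) == (14, 0, 0)
    assert region.alignment_score == 2 * 14 == 28
    assert region.repeat_score == 28 / 14 * 7 == 14


@pytest.fixture()
def ragged_gc():
    """(GC)6 tract followed by a 2 bp gap and a lone trailing GC unit."""
    seq = (
        "TACGTTAGGATCAATCGGATTACAGATTACAGATTACAGA"
        + "GC" * 6 + "TT" + "GC" + "ATTAGACCTG" * 5
    )
    refs = ReferenceSet()
    refs["c"] = ReferenceSequence("c", seq)
    return refs


def test_qc_passes_clean_region_untrimmed(gc7):
    refs = gc7["refs"]
    p = vc.TandemRepeatParams(min_copy=5, min_match_pct=100.0, min_alignment_score=20.0)
    units = search_units("GC", 123, "3'", refs, "chr_fix", p)
    region = assemble_region("GC", 123, [], units, refs, "chr_fix", p)
    kept = qc_and_trim([region], p)
    assert kept == [region]


def test_qc_trims_ragged_tail_to_the_perfect_core(ragged_gc):
    p = vc.TandemRepeatParams(min_copy=5, min_match_pct=100.0, min_alignment_score=20.0)
    units = search_units("GC", 41, "3'", ragged_gc, "c", p)
    cand = assemble_region("GC", 41, [], units, ragged_gc, "c", p)
    assert cand.copy_number == 7 and cand.match_pct < 100  # gapped tail fails QC
    kept = qc_and_trim([cand], p)
    assert len(kept) == 1
    core = kept[0]
    assert (core.start, core.end, core.copy_number) == (41, 52, 6)
    assert core.match_pct == 100.0 and core.gap_bases == 0
    assert core.alignment_score == 24.0


def test_qc_abandons_when_copy_floor_unreachable():
    refs = ReferenceSet()
    refs["c"] = ReferenceSequence("c", "TACGTTAGGATCAATCGGAT" + "GC" * 4 + "ATTAGACCTG" * 3)
    p = vc.TandemRepeatParams(min_copy=5, min_match_pct=100.0, min_alignment_score=20.0)
    units = search_units("GC", 21, "3'", refs, "c", p)
    cand = assemble_region("GC", 21, [], units, refs, "c", p)
    assert cand.copy_number == 4
    assert qc_and_trim([cand], p) == []


def test_redundancy_prefers_the_concise_motif():
    spec = FixtureSpec(length=200, seed=11, repeats=[EmbeddedRepeat("AT", 6, 50)])
    refs, _ = make_reference(spec)
    p = vc.TandemRepeatParams(min_copy=3, min_alignment_score=10.0)
    a = assemble_region("AT", 50, [], search_units("AT", 50, "3'", refs, "chr_fix", p),
                        refs, "chr_fix", p)
    b = assemble_region("ATAT", 50, [], search_units("ATAT", 50, "3'", refs, "chr_fix", p),
                        refs, "chr_fix", p)
    assert (a.copy_number, a.repeat_score) == (6, 12.0)
    assert (b.copy_number, b.repeat_score) == (3, 6.0)
    survivors = remove_redundancy([a, b], refs, "chr_fix")
    assert [s.motif for s in survivors] == ["AT"]


def test_redundancy_keeps_disjoint_and_exactly_half_overlapping():
    refs = ReferenceSet()
    refs["c"] = ReferenceSequence("c", "A" * 60)
    p = vc.TandemRepeatParams(min_copy=3)

    def homopolymer(start, end):
        units = [RepeatUnit(seq="A", start=i, end=i) for i in range(start, end + 1)]
        return _region_from_units("A", units, p)

    disjoint = remove_redundancy([homopolymer(1, 10), homopolymer(30, 40)], refs, "c")
    assert len(disjoint) == 2
    # overlap 6 / union 12 = exactly 0.5: strictly-greater rule keeps both
    half = remove_redundancy([homopolymer(1, 9), homopolymer(4, 12)], refs, "c")
    assert len(half) == 2


def test_full_pipeline_worked_deletion(gc7):
    regions = vc.annotate_variant_tr(
        gc7["deletion"], gc7["ann"], gc7["refs"], vc.TandemRepeatParams.perfect()
    )
    assert len(regions) == 1
    r = regions[0]
    assert (r.motif, r.start, r.end, r.copy_number) == ("GC", 123, 136, 7)
    assert r.gc_pct == 100.0
    assert r.copy_change == -1.0


def test_full_pipeline_homopolymer_and_negative_control():
    spec = FixtureSpec(length=240, seed=21, repeats=[EmbeddedRepeat("A", 12, 80)])
    refs, _ = make_reference(spec)
    norm, ann = _snv_in(refs, 85)
    regions = vc.annotate_variant_tr(norm, ann, refs, vc.TandemRepeatParams.perfect())
    assert [(r.motif, r.copy_number, r.start, r.end) for r in regions] == [
        ("A", 12, 80, 91)
    ]
    assert regions[0].copy_change == 0.0
    # no embedded repeat: nothing qualifies under the perfect profile
    plain = FixtureSpec(length=240, seed=22)
    refs2, _ = make_reference(plain)
    norm2, ann2 = _snv_in(refs2, 120)
    assert vc.annotate_variant_tr(norm2, ann2, refs2, vc.TandemRepeatParams.perfect()) == []


@pytest.mark.parametrize("w,motif", sorted(PRIMITIVE_MOTIFS.items()))
def test_survivor_is_rotation_independent_across_site_positions(w, motif):
    """Whatever in-tract position (hence anchor phase/rotation) seeds the
    search, the surviving region has the same span and copy number."""
    k = 8 if w <= 2 else 5
    spec = FixtureSpec(length=200 + w * k, seed=w, repeats=[EmbeddedRepeat(motif, k, 60)])
    refs, _ = make_reference(spec)
    params = vc.TandemRepeatParams(
        min_copy=3, min_alignment_score=2.0 * w * 3, min_match_pct=100.0
    )
    seen = set()
    for off in range(w):
        norm, ann = _snv_in(refs, 60 + w + off)
        regions = vc.annotate_variant_tr(norm, ann, refs, params)
        assert len(regions) == 1
        seen.add((regions[0].start, regions[0].end, regions[0].copy_number))
    assert seen == {(60, 60 + w * k - 1, k)}


def test_score_identities_hold_for_all_reported_regions(ragged_gc):
    """Every reported region satisfies the alignment/repeat score identities
    and the base-accounting identity exactly, recomputed from stored counts."""
    p = vc.TandemRepeatParams(
        min_copy=3, min_match_pct=80.0, min_alignment_score=10.0,
        match_score=3.0, mismatch_score=-4.0, gap_score=-6.0,
    )
    norm = vc.normalize(
        vc.VariantRecord("c", 45, ragged_gc["c"].base(45), "T"), ragged_gc
    )
    ann = vc.aligned_positions(norm, ragged_gc)
    regions = vc.annotate_variant_tr(norm, ann, ragged_gc, p)
    assert regions
    for r in regions:
        assert r.match_bases + r.mismatch_bases + r.gap_bases == r.length
        assert r.alignment_score == pytest.approx(
            3.0 * r.match_bases - 4.0 * r.mismatch_bases - 6.0 * r.gap_bases
        )
        assert r.repeat_score == pytest.approx(
            r.alignment_score / r.length * r.copy_number
        )


def test_raising_thresholds_never_adds_regions(ragged_gc):
    norm = vc.normalize(
        vc.VariantRecord("c", 45, ragged_gc["c"].base(45), "T"), ragged_gc
    )
    ann = vc.aligned_positions(norm, ragged_gc)
    counts = []
    for match_pct in (60.0, 80.0, 100.0):
        p = vc.TandemRepeatParams(
            min_copy=3, min_match_pct=match_pct, min_alignment_score=10.0
        )
        counts.append(len(vc.annotate_variant_tr(norm, ann, ragged_gc, p)))
    assert counts == sorted(counts, reverse=True)
    counts = []
    for min_align in (5.0, 15.0, 30.0):
        p = vc.TandemRepeatParams(
            min_copy=3, min_match_pct=80.0, min_alignment_score=min_align
        )
        counts.append(len(vc.annotate_variant_tr(norm, ann, ragged_gc, p)))
    assert counts == sorted(counts, reverse=True)


def test_params_validation():
    with pytest.raises(ValueError):
        vc.TandemRepeatParams(min_unit=3, max_unit=2)
    with pytest.raises(ValueError):
        vc.TandemRepeatParams(similarity_threshold=0.0)
    with pytest.raises(ValueError):
        vc.TandemRepeatParams(min_copy=1)
    p = vc.TandemRepeatParams(min_copy={1: 10, 2: 5, 3: 4})
    assert p.min_copy_for(1) == 10 and p.min_copy_for(6) == 4
    assert vc.TandemRepeatParams(max_gap=2).gap_limit(5) == 2
    assert vc.TandemRepeatParams().gap_limit(5) == 5
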