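"""Filtering thresholds, set logic, accumulation matrix, CNV merge, IO."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quadtract import (
    Variant,
    VariantCall,
    VariantKind,
    accumulation_matrix,
    filter_small_variants,
    merge_cnv_evidence,
    select_homozygous_deletions,
    subtract_background,
)
from quadtract.variants import read_variant_table, read_vcf, write_variant_table, write_vcf

from conftest import make_large_del, make_sbs


def call(depth=50, vf=0.95, bq=35, pos=100, alt="G", kind=VariantKind.SBS,
         size=1, **kw):
    return VariantCall("I", pos, "A", alt, kind, depth=depth,
                       variant_frequency=vf, base_quality=bq, size=size, **kw)


# ----------------------------------------------------------------------
# small-variant filter


@pytest.mark.parametrize(
    "depth,vf,bq,kept",
    [
        (6, 0.90, 30, True),    # every threshold at its inclusive side
        (5, 0.99, 40, False),   # depth strictly greater than 5
        (200, 0.95, 35, True),  # depth ceiling inclusive
        (201, 0.95, 35, False),
        (50, 0.89, 35, False),  # VF floor inclusive at 0.9
        (50, 0.95, 29, False),  # BQ floor inclusive at 30
    ],
)
def test_filter_boundaries(depth, vf, bq, kept):
    out = filter_small_variants([call(depth=depth, vf=vf, bq=bq)])
    assert (len(out) == 1) is kept


def test_filter_counts_mixed_violations():
    calls = [call(pos=i) for i in range(7)]
    calls += [call(pos=10, depth=5), call(pos=11, vf=0.5), call(pos=12, bq=10)]
    assert len(filter_small_variants(calls)) == 7


def test_filter_missing_field_names_field():
    bad = VariantCall("I", 5, "A", "T", VariantKind.SBS, depth=50,
                      variant_frequency=None, base_quality=35)
    with pytest.raises(ValueError, match="variant_frequency"):
        filter_small_variants([bad])


def test_one_variant_per_coordinate_keeps_highest_vf_then_smallest_alt():
    a = call(pos=7, vf=0.92, alt="T")
    b = call(pos=7, vf=0.98, alt="G")
    assert filter_small_variants([a, b]) == [b]
    c = call(pos=7, vf=0.98, alt="C")
    assert filter_small_variants([b, c]) == [c]  # tie -> smaller alt


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(
        st.builds(
            call,
            depth=st.integers(0, 250),
            vf=st.floats(0, 1),
            bq=st.integers(0, 45),
            pos=st.integers(0, 30),
            alt=st.sampled_from("CGT"),
        ),
        max_size=20,
    )
)
def test_filter_is_idempotent(calls):
    once = filter_small_variants(calls)
    assert filter_small_variants(once) == once


# ----------------------------------------------------------------------
# homozygous-deletion selection


@pytest.mark.parametrize(
    "a,b,size,kept",
    [
        (10, 0, 99, True),   # statistic 1.0
        (1, 1, 100, False),  # 0.5 is not > 0.5
        (3, 2, 21, True),    # 0.6, size just over the floor
        (7, 1, 20, False),   # size must exceed 20
    ],
)
def test_homozygous_deletion_selection(a, b, size, kept):
    c = VariantCall("I", 0, "<REGION>", "<DEL>", VariantKind.DEL_LARGE,
                    size=size, support_a=a, internal_b=b)
    assert (len(select_homozygous_deletions([c])) == 1) is kept


def test_unsupported_deletion_dropped_not_crash(caplog):
    c = VariantCall("I", 0, "<REGION>", "<DEL>", VariantKind.DEL_LARGE,
                    size=100, support_a=0, internal_b=0)
    assert select_homozygous_deletions([c]) == []


def test_negative_support_rejected():
    with pytest.raises(ValueError):
        VariantCall("I", 0, "<R>", "<D>", VariantKind.DEL_LARGE,
                    size=30, support_a=-1, internal_b=2)


# ----------------------------------------------------------------------
# background subtraction


def test_background_subtraction_shapes():
    sample = {make_sbs(i) for i in range(776)}
    background = [{make_sbs(i) for i in range(251)}]
    remaining = subtract_background(sample, background)
    assert len(remaining) == 525
    assert all(v.provenance == "background-subtracted" for v in remaining)


def test_background_subtraction_edge_cases():
    sample = {make_sbs(i) for i in range(5)}
    assert subtract_background(sample, []) == sample
    assert subtract_background(sample, [set(sample)]) == set()


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.sets(st.integers(0, 50), max_size=30),
    st.lists(st.sets(st.integers(0, 50), max_size=10), max_size=4),
)
def test_subtraction_is_monotone_in_backgrounds(sample_pos, bg_pos):
    sample = {make_sbs(p) for p in sample_pos}
    bgs = [{make_sbs(p) for p in s} for s in bg_pos]
    sizes = [len(subtract_background(sample, bgs[:i])) for i in range(len(bgs) + 1)]
    assert sizes == sorted(sizes, reverse=True)


# ----------------------------------------------------------------------
# accumulation matrix


def nested_sets(counts):
    """Cumulative nested SBS sets keyed by generation."""
    return {
        g: {make_sbs(i, generation=g) for i in range(n)}
        for g, n in counts.items()
    }


def test_accumulation_of_nested_substitution_sets():
    sets = nested_sets({170: 431, 270: 463, 470: 525})
    m = accumulation_matrix(sets, [VariantKind.SBS])
    assert m.new[VariantKind.SBS] == {170: 431, 270: 32, 470: 62}
    assert m.window_total(VariantKind.SBS, 170, 470) == 94
    assert all(not v for v in m.reversions[VariantKind.SBS].values())


def test_identical_sets_give_no_new_and_no_reversions():
    s = {make_sbs(i) for i in range(10)}
    m = accumulation_matrix({1: s, 2: set(s), 3: set(s)}, [VariantKind.SBS])
    assert m.new[VariantKind.SBS] == {1: 10, 2: 0, 3: 0}
    assert all(not v for v in m.reversions[VariantKind.SBS].values())


def test_duplication_loss_is_a_reversion_not_an_error():
    dup = Variant("V", 100, "<REGION>", "<DUP>", VariantKind.DUP, size=5000)
    m = accumulation_matrix({270: {dup}, 470: set()}, [VariantKind.DUP])
    assert m.new[VariantKind.DUP] == {270: 1, 470: 0}
    assert [v.key for v in m.reversions[VariantKind.DUP][470]] == [dup.key]


def test_unsorted_generations_rejected():
    with pytest.raises(ValueError, match="sorted"):
        accumulation_matrix({470: set(), 170: set()})


def test_large_deletions_match_across_generations_by_reciprocal_overlap():
    d170 = make_large_del(1000, 200)
    d470 = make_large_del(1005, 198)  # jittered breakpoints, same event
    far = make_large_del(5000, 200)
    m = accumulation_matrix(
        {170: {d170}, 470: {d470, far}}, [VariantKind.DEL_LARGE]
    )
    assert m.new[VariantKind.DEL_LARGE] == {170: 1, 470: 1}
    assert not m.reversions[VariantKind.DEL_LARGE][470]


def test_window_total_conservation():
    sets = nested_sets({170: 100, 270: 120, 470: 150})
    m = accumulation_matrix(sets, [VariantKind.SBS])
    assert (
        m.window_total(VariantKind.SBS, 170, 470)
        == m.new[VariantKind.SBS][270] + m.new[VariantKind.SBS][470]
        == 50
    )


# ----------------------------------------------------------------------
# CNV evidence merge


def interval_call(pos, size, contig="I"):
    return VariantCall(contig, pos, "<REGION>", "<DEL>", VariantKind.DEL_LARGE,
                       size=size, support_a=5, internal_b=0)


def test_cnv_merge_identical_and_disjoint():
    a = interval_call(100, 50)
    assert len(merge_cnv_evidence([a], [interval_call(100, 50)])) == 1
    assert len(merge_cnv_evidence([a], [interval_call(1000, 50)])) == 2


def test_cnv_merge_final_event_count():
    primary = [interval_call(i * 1000, 100) for i in range(183)]
    extra = [interval_call(500_000 + i * 1000, 100) for i in range(13)]
    overlapping = [interval_call(i * 1000 + 10, 95) for i in range(5)]
    merged = merge_cnv_evidence(primary, extra + overlapping)
    assert len(merged) == 196
    # primary breakpoints preferred for shared events
    assert all(
        any(p.key == m.key for p in primary) or m in extra for m in merged
    )


# ----------------------------------------------------------------------
# IO round trips


def test_tsv_round_trip(tmp_path):
    calls = [
        call(pos=3),
        VariantCall("II", 9, "<REGION>", "<DEL>", VariantKind.DEL_LARGE,
                    size=120, support_a=8, internal_b=1),
    ]
    path = tmp_path / "calls.tsv"
    write_variant_table(calls, path)
    assert read_variant_table(path) == calls


def test_vcf_round_trip(tmp_path):
    calls = [
        call(pos=3),
        VariantCall("I", 50, "ATTTT", "A", VariantKind.DEL_SMALL, depth=40,
                    variant_frequency=0.99, base_quality=38.0, size=4),
    ]
    path = tmp_path / "calls.vcf"
    write_vcf(calls, path, {"I": 1000, "II": 1000})
    back = read_vcf(path)
    assert [c.key for c in back] == [c.key for c in calls]
    assert back[0].depth == calls[0].depth
    assert back[0].variant_frequency == pytest.approx(0.95, abs=1e-6)


def test_tsv_missing_columns_rejected(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("contig\tpos\n1\t2\n")
    with pytest.raises(ValueError, match="missing columns"):
        read_variant_table(p)
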