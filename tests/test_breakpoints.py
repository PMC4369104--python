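"""Deletion initiation classification, tract census, size distribution."""

import random

import pytest

from quadtract import (
    Genome,
    MotifClass,
    annotate_genome,
    classify_deletion,
    classify_deletions,
    deleted_tract_census,
    initiating_site,
    revcomp,
    size_distribution,
    summarize_classifications,
)
from quadtract.motifs import GTract, expand_signature
from quadtract.simulate import deletion_initiating_at
from quadtract.variants import VariantKind


def planted_genome(*motifs, spacer=200):
    """Genome with the given G-oriented motif sequences planted on '+',
    separated by G/C-free spacers; returns (genome, [(start, end)])."""
    rng = random.Random(0)
    parts, coords, cursor = [], [], 0
    for seq in motifs:
        pad = "".join(rng.choices("AT", k=spacer))
        parts.append(pad)
        cursor += spacer
        coords.append((cursor, cursor + len(seq)))
        parts.append(seq)
        cursor += len(seq)
    parts.append("".join(rng.choices("AT", k=spacer)))
    return Genome({"I": "".join(parts)}), coords


# ----------------------------------------------------------------------
# initiating_site


def test_deletion_from_g_run_3prime_end():
    genome, [(s, e)] = planted_genome("G" * 20)
    ann = annotate_genome(genome)
    deletion = ("I", e - 99, e)  # removes tract plus 5' flank
    site, side = initiating_site(deletion, ann.strict, genome)
    assert (site.start, site.end) == (s, e)
    assert side == "g_run_3prime"


def test_deletion_far_from_motifs_has_no_site():
    genome, _ = planted_genome("G" * 20, spacer=400)
    ann = annotate_genome(genome)
    assert initiating_site(("I", 5, 60), ann.strict, genome) == (None, "none")


def test_c_run_mirror_initiates_at_5prime_end():
    genome, [(s, e)] = planted_genome("C" * 16)  # G-run on the minus strand
    ann = annotate_genome(genome)
    deletion = ("I", s, s + 99)  # extends 3'-ward on the forward strand
    site, side = initiating_site(deletion, ann.strict, genome)
    assert (site.start, site.end) == (s, e)
    assert side == "c_run_5prime"


def test_orientation_requirement_rejects_wrong_direction():
    genome, [(s, e)] = planted_genome("G" * 20, spacer=400)
    ann = annotate_genome(genome)
    wrong_way = ("I", e - 2, e + 150)  # extends 3'-ward of a plus-strand run
    site, _ = initiating_site(wrong_way, ann.strict, genome)
    assert site is None
    site, _ = initiating_site(wrong_way, ann.strict, genome,
                              require_orientation=False)
    assert site is not None


def test_tolerance_window_around_initiation_end():
    genome, [(s, e)] = planted_genome("G" * 20)
    ann = annotate_genome(genome)
    near = ("I", e - 60, e + 5)
    far = ("I", e - 60 + 9, e + 9)
    assert initiating_site(near, ann.strict, genome, tolerance=5)[0] is not None
    assert initiating_site(far, ann.strict, genome, tolerance=5)[0] is None


def test_deletion_outside_genome_is_a_coordinate_error():
    genome, _ = planted_genome("G" * 20)
    ann = annotate_genome(genome)
    with pytest.raises(IndexError):
        initiating_site(("I", 100, 10 ** 6), ann.strict, genome)


# ----------------------------------------------------------------------
# classify_deletion


@pytest.mark.parametrize(
    "sig,expected",
    [
        ("G_2NG_12", MotifClass.RELAXED_4TRACT),
        ("G_2NG_3N_6G_3", MotifClass.RELAXED_3TRACT),
    ],
)
def test_relaxed_layers_classify_in_priority_order(sig, expected):
    seq = expand_signature(sig).replace("N", "A")
    genome, [(s, e)] = planted_genome(seq)
    ann = annotate_genome(genome)
    cls = classify_deletion(("I", e - 80, e), ann, genome)
    assert cls.motif_class is expected


def test_no_motif_within_tolerance_is_non_g_rich():
    genome, _ = planted_genome("G" * 20, spacer=400)
    ann = annotate_genome(genome)
    cls = classify_deletion(("I", 10, 80), ann, genome)
    assert cls.motif_class is MotifClass.NON_G_RICH
    assert cls.initiating_site is None and cls.breakpoint_side == "none"


def test_planted_deletions_recover_their_truth_classes(rich_sim):
    cfg, genome, truth, _ = rich_sim
    ann = annotate_genome(genome)
    dels = [
        (e.contig, e.pos, e.pos + e.size)
        for e in truth.events
        if e.kind is VariantKind.DEL_LARGE
    ]
    expected = [
        e.motif_class
        for e in truth.events
        if e.kind is VariantKind.DEL_LARGE
    ]
    got = [c.motif_class for c in classify_deletions(dels, ann, genome)]
    assert got == expected
    assert len(dels) >= 10  # the check is only meaningful with events


def test_classification_counts_partition_and_order_invariance(rich_sim):
    cfg, genome, truth, _ = rich_sim
    ann = annotate_genome(genome)
    dels = [
        (e.contig, e.pos, e.pos + e.size)
        for e in truth.events
        if e.kind is VariantKind.DEL_LARGE
    ]
    fwd = summarize_classifications(classify_deletions(dels, ann, genome))
    rev = summarize_classifications(classify_deletions(dels[::-1], ann, genome))
    assert sum(fwd.counts.values()) == fwd.n_total == len(dels)
    assert fwd.n_g_rich == fwd.n_total - fwd.counts[MotifClass.NON_G_RICH]
    assert fwd.counts == rev.counts
    assert fwd.fraction_g_rich == rev.fraction_g_rich


def test_strand_mirror_leaves_classes_unchanged():
    seq = "G" * 20
    genome, [(s, e)] = planted_genome(seq)
    n = len(genome["I"])
    mirrored = Genome({"I": revcomp(genome["I"])})
    deletion = ("I", e - 99, e)
    m_deletion = ("I", n - e, n - (e - 99))
    a = classify_deletion(deletion, annotate_genome(genome), genome)
    b = classify_deletion(m_deletion, annotate_genome(mirrored), mirrored)
    assert a.motif_class is b.motif_class is MotifClass.MONO_TRACT


# ----------------------------------------------------------------------
# census and sizes


def synthetic_tracts(n, length=20, gap=500):
    return [
        GTract("I", i * gap, i * gap + length, "+") for i in range(n)
    ]


def test_deleted_tract_census_fraction():
    tracts = synthetic_tracts(954)
    deletions = [("I", t.start - 10, t.end + 10) for t in tracts[:126]]
    n_del, n_tot, frac = deleted_tract_census(tracts, deletions)
    assert (n_del, n_tot) == (126, 954)
    assert f"{frac:.1%}" == "13.2%"


def test_census_majority_overlap_rule():
    (tract,) = synthetic_tracts(1)
    forty_pct = [("I", tract.start, tract.start + 8)]  # 8/20 covered
    half = [("I", tract.start, tract.start + 10)]
    assert deleted_tract_census([tract], forty_pct)[0] == 0
    assert deleted_tract_census([tract], half)[0] == 1


def test_census_no_deletions_and_empty_tracts():
    tracts = synthetic_tracts(5)
    assert deleted_tract_census(tracts, []) == (0, 5, 0.0)
    with pytest.raises(ValueError):
        deleted_tract_census([], [("I", 0, 10)])


def test_size_distribution_boundary_is_strictly_below():
    hist, frac = size_distribution([100, 200, 299, 300, 5000], threshold=300)
    assert frac == pytest.approx(3 / 5)
    assert hist[0].sum() == 5


def test_size_distribution_prints_86_percent_for_106_of_123():
    # 106/123 is the only split of 123 G-rich deletion sizes whose
    # below-300 fraction rounds to 86%
    matches = [k for k in range(124) if round(100 * k / 123) == 86]
    assert matches == [106]
    sizes = [100] * 106 + [400] * 17
    _, frac = size_distribution(sizes)
    assert f"{frac:.0%}" == "86%"


def test_size_distribution_degenerate_inputs():
    assert size_distribution([]) == (None, None)
    _, frac = size_distribution([49] * 10)
    assert frac == 1.0


def test_initiating_deletion_helper_round_trips(toy):
    genome, truth = toy
    ann = annotate_genome(genome)
    for motif in truth.motifs:
        d = deletion_initiating_at(
            motif, size=120, jitter=2,
            contig_length=len(genome[motif.contig]),
        )
        cls = classify_deletion(d, ann, genome)
        assert cls.motif_class is motif.motif_class, (motif, d, cls)
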