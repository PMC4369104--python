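"""Motif scanner: homopolymer runs, signature scanning, classification."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quadtract import (
    Genome,
    MotifClass,
    RELAXED_3TRACT,
    RELAXED_4TRACT,
    STRICT_G4,
    SignatureSpec,
    classify_motif,
    expand_signature,
    find_homopolymer_tracts,
    find_mono_gc_tracts,
    revcomp,
    scan_signature,
)
from quadtract.motifs import _match_union
from quadtract.studydata import NON_STRICT_SIGNATURES, WORKED_STRICT_SEQUENCES

from _oracles import brute_force_runs, brute_force_signature_sites

dna = st.text(alphabet="ACGT", min_size=1, max_size=250)
g_rich_dna = st.text(alphabet="ACGTGGG", min_size=1, max_size=250)


def one_contig(seq):
    return Genome({"chr": seq})


# ----------------------------------------------------------------------
# homopolymer tracts


@pytest.mark.parametrize(
    "seq,min_len,expected",
    [
        ("GGGGG", 3, [(0, 5)]),
        ("ATATAT", 3, []),
        ("AA" + "G" * 20 + "TT", 15, [(2, 22)]),
        ("GGGTGGG", 3, [(0, 3), (4, 7)]),
    ],
)
def test_homopolymer_examples(seq, min_len, expected):
    tracts = find_homopolymer_tracts(one_contig(seq), "G", min_len)
    assert [(t.start, t.end) for t in tracts] == expected
    assert all(t.length == t.end - t.start for t in tracts)


def test_homopolymer_rejects_unknown_base():
    with pytest.raises(ValueError, match="Z"):
        find_homopolymer_tracts(one_contig("ACGT"), "Z", 3)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(seq=g_rich_dna, min_len=st.integers(1, 6))
def test_homopolymer_matches_bruteforce(seq, min_len):
    got = find_homopolymer_tracts(one_contig(seq), "G", min_len)
    assert [(t.start, t.end) for t in got] == brute_force_runs(seq, "G", min_len)


def test_mono_gc_complement_symmetry():
    tracts = find_mono_gc_tracts(one_contig("AT" + "C" * 16 + "TA"), min_len=15)
    assert len(tracts) == 1
    assert tracts[0].strand == "-" and tracts[0].length == 16


def test_mono_gc_boundary_is_strictly_greater_than_14():
    assert find_mono_gc_tracts(one_contig("A" + "G" * 14 + "T"), 15) == []
    assert len(find_mono_gc_tracts(one_contig("A" + "G" * 15 + "T"), 15)) == 1


def test_mono_gc_recovers_planted_counts(toy):
    genome, truth = toy
    planted = [m for m in truth.motifs if m.motif_class is MotifClass.MONO_TRACT]
    tracts = find_mono_gc_tracts(genome)
    assert len(tracts) == len(planted)
    assert {(t.contig, t.start, t.end) for t in tracts} == {
        (m.contig, m.start, m.end) for m in planted
    }


# ----------------------------------------------------------------------
# signature scanning


def test_literal_strict_pattern_is_one_site():
    sites = scan_signature(one_contig("GGGAGGGAGGGAGGG"), STRICT_G4)
    assert [(s.start, s.end) for s in sites] == [(0, 15)]


def test_g15_homopolymer_matches_strict_signature():
    # loops may be G, so G15 decomposes as G3.G.G3.G.G3.G.G3
    sites = scan_signature(one_contig("TT" + "G" * 15 + "AA"), STRICT_G4)
    assert [(s.start, s.end) for s in sites] == [(2, 17)]


@pytest.mark.parametrize("n", range(15, 26))
def test_every_long_mono_tract_is_a_strict_site(n):
    sites = scan_signature(one_contig("A" + "G" * n + "T"), STRICT_G4)
    assert [(s.start, s.end) for s in sites] == [(1, 1 + n)]


@pytest.mark.parametrize("sig,family", sorted(NON_STRICT_SIGNATURES.items()))
def test_non_strict_worked_loci_match_their_relaxed_family(sig, family):
    """The nine worked deletion-initiating loci that deviate from the
    strict signature each match exactly the relaxed family expected."""
    genome = one_contig("AT" + expand_signature(sig).replace("N", "A") + "TA")
    assert scan_signature(genome, STRICT_G4) == []
    in_r4 = len(scan_signature(genome, RELAXED_4TRACT)) == 1
    in_r3 = len(scan_signature(genome, RELAXED_3TRACT)) == 1
    if family is MotifClass.RELAXED_4TRACT:
        assert in_r4
    else:
        assert not in_r4 and in_r3


@pytest.mark.parametrize("spec", [STRICT_G4, RELAXED_4TRACT, RELAXED_3TRACT])
@settings(max_examples=150, deadline=None, derandomize=True)
@given(seq=g_rich_dna)
def test_scanner_equals_bruteforce_oracle(spec, seq):
    assert _match_union(seq, "G", spec) == brute_force_signature_sites(
        seq, "G", spec
    )


def test_loops_reject_ambiguity_bases():
    # N terminates runs and may not serve as loop: GGGNGGGAGGGAGGG has no
    # 4-tract chain through the N
    seq = "GGGNGGGAGGGAGGG"
    assert _match_union(seq, "G", STRICT_G4) == []
    assert brute_force_signature_sites(seq, "G", STRICT_G4) == []


@settings(max_examples=100, deadline=None, derandomize=True)
@given(seq=g_rich_dna)
def test_strand_symmetry(seq):
    """Scanning the reverse complement mirrors coordinates and flips strands."""
    if not seq:
        return
    fwd = scan_signature(one_contig(seq), STRICT_G4, collapse_strands=False)
    rev = scan_signature(one_contig(revcomp(seq)), STRICT_G4, collapse_strands=False)
    n = len(seq)
    mirrored = sorted(
        (n - s.end, n - s.start, {"+": "-", "-": "+"}[s.strand]) for s in rev
    )
    assert sorted((s.start, s.end, s.strand) for s in fwd) == mirrored


@settings(max_examples=100, deadline=None, derandomize=True)
@given(seq=g_rich_dna)
def test_merged_sites_do_not_overlap(seq):
    sites = scan_signature(one_contig(seq), RELAXED_3TRACT)
    for a, b in zip(sites, sites[1:]):
        assert a.end < b.start or a.contig != b.contig


def test_site_count_invariant_to_contig_order():
    seqs = {"a": "TTGGGAGGGAGGGAGGGTT", "b": "CCCTCCCTCCCTCCC", "c": "ATATAT"}
    fwd = scan_signature(Genome(seqs), STRICT_G4)
    rev = scan_signature(Genome(dict(reversed(list(seqs.items())))), STRICT_G4)
    assert len(fwd) == len(rev) == 2


def test_signature_string_reexpands_to_genomic_subsequence(toy):
    genome, _ = toy
    for site in scan_signature(genome, STRICT_G4):
        sub = genome.fetch(site.contig, site.start, site.end)
        expanded = expand_signature(site.signature_string)
        assert expanded == (revcomp(sub) if site.strand == "-" else sub)


def test_invalid_spec_rejected():
    with pytest.raises(ValueError):
        SignatureSpec(min_tract_len=1)
    with pytest.raises(ValueError):
        SignatureSpec(min_tract_len=3, min_loop=5, max_loop=2)
    with pytest.raises(ValueError):
        SignatureSpec(min_tract_len=3, n_tracts=2)


# ----------------------------------------------------------------------
# classification


@pytest.mark.parametrize("seq,expected", sorted(WORKED_STRICT_SEQUENCES.items()))
def test_worked_sequences_classify_correctly(seq, expected):
    genome = one_contig("AT" + seq + "TA")
    sites = scan_signature(genome, STRICT_G4)
    assert len(sites) == 1
    assert classify_motif(sites[0], genome) is expected


def test_pure_g15_is_mono_tract():
    genome = one_contig("A" + "G" * 15 + "T")
    (site,) = scan_signature(genome, STRICT_G4)
    assert classify_motif(site, genome) is MotifClass.MONO_TRACT


def test_classification_is_strand_agnostic():
    seq = "G" * 14 + "T" + "G" * 6 + "AGAA" + "G" * 3
    for variant in (seq, revcomp(seq)):
        genome = one_contig("AT" + variant + "TA")
        (site,) = scan_signature(genome, STRICT_G4)
        assert classify_motif(site, genome) is MotifClass.MONO_LIKE_LE2


@settings(max_examples=100, deadline=None, derandomize=True)
@given(seq=g_rich_dna)
def test_every_strict_site_gets_exactly_one_subclass(seq):
    genome = one_contig(seq)
    for site in scan_signature(genome, STRICT_G4):
        assert classify_motif(site, genome) in (
            MotifClass.MONO_TRACT,
            MotifClass.MONO_LIKE_LE2,
            MotifClass.INTERRUPTED_GE3,
        )


def test_planted_strict_sites_recover_their_classes(toy, toy_annotation):
    genome, truth = toy
    strict_planted = {
        (m.contig, m.start, m.end): m.motif_class
        for m in truth.motifs
        if m.motif_class
        in (MotifClass.MONO_TRACT, MotifClass.MONO_LIKE_LE2,
            MotifClass.INTERRUPTED_GE3)
    }
    found = {
        (s.contig, s.start, s.end): s.motif_class for s in toy_annotation.strict
    }
    assert found == strict_planted
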