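"""Synthetic MA-line generator: determinism, planted truth, event statistics."""

import numpy as np
import pytest

from quadtract import (
    MotifClass,
    SimulationConfig,
    VariantKind,
    annotate_genome,
    build_toy_genome,
    recover_parameters,
    simulate_line,
)
from quadtract.simulate import SimulatedTruth


def test_same_seed_gives_identical_genome_and_tables(tmp_path):
    cfg = SimulationConfig(seed=5, mu_sbs=1e-6, mu_del_g4=1e-3)
    g1, t1 = build_toy_genome(cfg)
    g2, t2 = build_toy_genome(cfg)
    assert dict(g1) == dict(g2)
    tables1 = simulate_line(g1, t1, cfg)
    tables2 = simulate_line(g2, t2, cfg)
    assert tables1 == tables2
    g1.to_fasta(tmp_path / "a.fasta")
    g2.to_fasta(tmp_path / "b.fasta")
    assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()


def test_zero_plants_scan_empty():
    cfg = SimulationConfig(
        seed=1, genome_length=30_000,
        plant_counts={}, n_genes=2,
    )
    genome, truth = build_toy_genome(cfg)
    ann = annotate_genome(genome)
    assert ann.strict == [] and ann.relaxed4 == [] and ann.relaxed3 == []
    assert ann.mono_tracts == []


def test_zero_rates_give_empty_tables():
    cfg = SimulationConfig(seed=2, mu_sbs=0, mu_indel=0, mu_del_g4=0,
                           mu_del_nong4=0, mu_dup=0)
    genome, truth = build_toy_genome(cfg)
    tables = simulate_line(genome, truth, cfg)
    assert all(calls == [] for calls in tables.values())
    assert truth.events == []


def test_sample_sets_are_nested_for_persistent_kinds(rich_sim):
    """Fixed variants persist: after quality filtering (which removes the
    decoy calls), every earlier sample is a subset of every later one."""
    from quadtract.variants import SMALL_KINDS, filter_small_variants

    _, _, _, tables = rich_sim
    keysets = {}
    for g, calls in tables.items():
        small = filter_small_variants([c for c in calls if c.kind in SMALL_KINDS])
        large = [c for c in calls if c.kind is VariantKind.DEL_LARGE]
        keysets[g] = {c.key for c in small + large}
    gens = sorted(keysets)
    for a, b in zip(gens, gens[1:]):
        assert keysets[a] <= keysets[b]


def test_all_deletions_carry_g_rich_truth_when_nong4_rate_zero():
    cfg = SimulationConfig(seed=3, genome_length=80_000, mu_del_g4=2e-3,
                           mu_del_nong4=0.0)
    genome, truth = build_toy_genome(cfg)
    simulate_line(genome, truth, cfg)
    dels = [e for e in truth.events if e.kind is VariantKind.DEL_LARGE]
    assert dels
    assert all(e.motif_class is not MotifClass.NON_G_RICH for e in dels)
    assert all(e.motif_id is not None for e in dels)


def test_mean_sbs_count_matches_poisson_expectation():
    cfg = SimulationConfig(seed=8, genome_length=50_000, mu_sbs=1e-6,
                           plant_counts={"MONO_TRACT": 3}, n_genes=0)
    genome, template = build_toy_genome(cfg)
    lam = cfg.mu_sbs * genome.total_length * cfg.total_generations
    counts = []
    for rep in range(30):
        truth = SimulatedTruth(motifs=template.motifs, genes=template.genes)
        rng = np.random.default_rng(1000 + rep)
        simulate_line(genome, truth, cfg, rng=rng)
        counts.append(sum(1 for e in truth.events if e.kind is VariantKind.SBS))
    se = np.sqrt(lam / len(counts))
    assert abs(np.mean(counts) - lam) <= 3 * se


def test_target_loss_bookkeeping_matches_census(rich_sim):
    from quadtract import deleted_tract_census, find_mono_gc_tracts

    cfg, genome, truth, _ = rich_sim
    mono_ids = {
        m.motif_id for m in truth.motifs
        if m.motif_class is MotifClass.MONO_TRACT
    }
    dead_mono = mono_ids & set(truth.motif_death_generation)
    tracts = find_mono_gc_tracts(genome)
    dels = [
        (e.contig, e.pos, e.pos + e.size)
        for e in truth.events
        if e.kind is VariantKind.DEL_LARGE
    ]
    n_del, n_tot, frac = deleted_tract_census(tracts, dels)
    assert n_tot == len(mono_ids)
    assert n_del == len(dead_mono)
    assert frac == pytest.approx(len(dead_mono) / len(mono_ids))


def test_parameter_recovery_within_two_standard_errors():
    cfg = SimulationConfig(seed=5, genome_length=120_000, mu_sbs=1e-6,
                           mu_del_g4=1e-3,
                           plant_counts={"MONO_TRACT": 50}, n_genes=0)
    df = recover_parameters(cfg, n_replicates=30)
    assert set(df["parameter"]) == {"mu_sbs", "mu_del_g4"}
    assert df["within_2se"].all()


def test_zero_rate_recovers_exactly_zero():
    cfg = SimulationConfig(seed=6, genome_length=40_000, mu_sbs=0.0,
                           plant_counts={"MONO_TRACT": 3}, n_genes=0,
                           mu_del_g4=0.0)
    df = recover_parameters(cfg, n_replicates=3)
    assert (df["mean_estimate"] == 0).all()


def test_infeasible_packing_reports_required_length():
    with pytest.raises(ValueError, match="at least"):
        build_toy_genome(SimulationConfig(seed=1, genome_length=2_000))


def test_decoy_calls_fail_the_filters(rich_sim):
    from quadtract.variants import filter_small_variants

    cfg, _, truth, tables = rich_sim
    last = tables[max(tables)]
    small = [c for c in last if c.kind is VariantKind.SBS]
    kept = filter_small_variants(small)
    truth_sbs = {
        (e.contig, e.pos) for e in truth.events if e.kind is VariantKind.SBS
    }
    assert len(small) - len(kept) == cfg.n_decoy_calls
    assert {(c.contig, c.pos) for c in kept} == truth_sbs


def test_background_variants_present_from_first_sample():
    cfg = SimulationConfig(seed=9, genome_length=60_000,
                           n_background_variants=12)
    genome, truth = build_toy_genome(cfg)
    tables = simulate_line(genome, truth, cfg)
    assert len(truth.background_variants) == 12
    first = {c.key for c in tables[min(tables)]}
    for v in truth.background_variants:
        assert v.key in first
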