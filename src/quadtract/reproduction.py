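"""Reproduction-mode analyses on synthetic inputs shaped by the
published summary counts of the study system (see ``studydata``).

The raw sequencing data behind those counts is not desk-scale
reproducible (it requires alignment and variant calling from an SRA
archive), but every *set-logic and arithmetic* step downstream of the
callers is.  This module constructs synthetic inputs with exactly the
published shapes -- nested per-generation variant sets, a planted
genome holding one motif per classified deletion, a monoG/C census
genome -- runs the real pipeline operations on them, and returns the
recomputed quantities.

Note on the non-G4 per-base deletion rate: the published per-gene
(4.9e-7) and per-base (5.0e-10) figures imply 3 genes and 15 deletions
respectively, while the window classification leaves 16 non-G-rich
deletions; the per-base figure is therefore not recomputed here (the
discrepancy is surfaced in the package documentation).
"""

from __future__ import annotations

import numpy as np

from . import studydata as sd
from .breakpoints import (
    classify_deletions,
    deleted_tract_census,
    summarize_classifications,
)
from .impact import GeneModel, variants_affecting_genes
from .motifs import MotifClass, annotate_genome, find_mono_gc_tracts
from .rates import (
    RateDenominators,
    indel_sbs_ratio,
    per_base_rate,
    per_gene_rate,
    per_site_rate,
    round_sig,
    tstv_ratio,
)
from .simulate import SimulationConfig, build_toy_genome, deletion_initiating_at
from .variants import Variant, VariantKind, accumulation_matrix, subtract_background


# ----------------------------------------------------------------------
# nested generation sets with the published cumulative counts


def _sbs(i: int, ref: str = "A", alt: str = "G") -> Variant:
    return Variant("I", i, ref, alt, VariantKind.SBS)


def _indel(i: int) -> Variant:
    return Variant("I", 10_000_000 + i * 40, "AT", "A", VariantKind.DEL_SMALL,
                   size=1)


def _large_del(i: int) -> Variant:
    return Variant("I", 20_000_000 + i * 20_000, "<REGION>", "<DEL>",
                   VariantKind.DEL_LARGE, size=150)


def _dup(name_pos: int, cn: int = 2, size: int = 50_000) -> Variant:
    return Variant("V", name_pos, "<REGION>", "<DUP>", VariantKind.DUP,
                   size=size, copy_number=cn)


def generation_sets() -> dict[int, set[Variant]]:
    """Per-generation fixed-variant sets with the published cumulative
    counts; substitutions/InDels/deletions are nested (no reversions),
    duplications follow the amplification-and-reversion history."""
    sets: dict[int, set[Variant]] = {}
    dup_history = {
        170: [_dup(1000, 2), _dup(200_000, 2), _dup(400_000, 2)],
        # the first block amplifies to three copies; two new loci appear
        270: [_dup(1000, 3), _dup(200_000, 2), _dup(400_000, 2),
              _dup(600_000, 2), _dup(800_000, 2)],
        # one duplication reverts to normal copy number
        470: [_dup(1000, 3), _dup(400_000, 2), _dup(600_000, 2),
              _dup(800_000, 2)],
    }
    for g in sd.SAMPLE_GENERATIONS:
        s: set[Variant] = set()
        s |= {_sbs(i) for i in range(sd.SBS_CUMULATIVE[g])}
        s |= {_indel(i) for i in range(sd.INDEL_CUMULATIVE[g])}
        s |= {_large_del(i) for i in range(sd.DELETION_CUMULATIVE[g])}
        s |= set(dup_history[g])
        sets[g] = s
    return sets


def background_subtraction_counts() -> tuple[int, int]:
    """776 called substitutions minus 251 background-strain keys -> 525."""
    sample = {_sbs(i) for i in range(sd.N_SBS_CALLED)}
    background = [{_sbs(i) for i in range(sd.N_SBS_BACKGROUND)}]
    return len(sample), len(subtract_background(sample, background))


# ----------------------------------------------------------------------
# planted-genome fixtures


def classification_fixture(seed: int = 0):
    """A genome planted with one motif per classified window deletion
    (93 monoG tracts, 11 monoG-like, 10 interrupted, 8 relaxed-4,
    1 relaxed-3) plus 16 non-G-rich deletions, and the deletions
    initiating at them.

    Deletion sizes are capped below the inter-motif spacing so each
    deletion's far breakpoint stays in motif-free background and the
    class assignment is determined by the initiating locus alone.
    Returns (genome, annotation, deletions, truth_classes).
    """
    counts = {
        cls.value: n
        for cls, n in sd.DELETION_CLASS_COUNTS.items()
        if cls is not MotifClass.NON_G_RICH
    }
    cfg = SimulationConfig(
        seed=seed,
        genome_length=60_000,
        plant_counts=counts,
        n_genes=0,
    )
    genome, truth = build_toy_genome(cfg)
    rng = np.random.default_rng(seed + 1)
    deletions, truth_classes = [], []
    for m in truth.motifs:
        size = int(rng.integers(49, 180))
        jitter = int(rng.integers(0, 3))
        deletions.append(
            deletion_initiating_at(m, size, jitter,
                                   contig_length=len(genome[m.contig]))
        )
        truth_classes.append(m.motif_class)
    # non-G-rich deletions in motif-free background
    n_placed = 0
    contig = truth.motifs[0].contig
    clen = len(genome[contig])
    while n_placed < sd.DELETION_CLASS_COUNTS[MotifClass.NON_G_RICH]:
        size = int(rng.integers(49, 200))
        pos = int(rng.integers(0, clen - size))
        if any(
            m.contig == contig and m.start - 30 < pos + size and pos < m.end + 30
            for m in truth.motifs
        ):
            continue
        deletions.append((contig, pos, pos + size))
        truth_classes.append(MotifClass.NON_G_RICH)
        n_placed += 1
    annotation = annotate_genome(genome)
    return genome, annotation, deletions, truth_classes


def census_fixture(seed: int = 0):
    """A genome with 954 planted monoG/C tracts of which 126 are removed
    by deletions; returns (n_deleted, n_total, fraction)."""
    cfg = SimulationConfig(
        seed=seed,
        genome_length=300_000,
        plant_counts={"MONO_TRACT": sd.N_MONO_TRACTS},
        n_genes=0,
    )
    genome, truth = build_toy_genome(cfg)
    tracts = find_mono_gc_tracts(genome)
    rng = np.random.default_rng(seed + 2)
    hit = rng.choice(len(truth.motifs), size=sd.N_MONO_TRACTS_DELETED,
                     replace=False)
    deletions = [
        (m.contig, max(0, m.start - 20), m.end + 2)
        for m in (truth.motifs[i] for i in hit)
    ]
    return deleted_tract_census(tracts, deletions)


def gene_impact_fixture():
    """Gene models and window deletions/duplications with the published
    impact shape: 18 deletions affect 19 genes (one spans two);
    duplications cover a 62-gene block plus 4 further genes (66 total).
    """
    del_genes = [
        GeneModel(f"dg{i}", "I", "+", exons=[(i * 10_000, i * 10_000 + 2_000)])
        for i in range(19)
    ]
    deletions = [
        Variant("I", i * 10_000 + 500, "<REGION>", "<DEL>",
                VariantKind.DEL_LARGE, size=300)
        for i in range(17)
    ]
    # one deletion spanning the last two genes
    deletions.append(
        Variant("I", 17 * 10_000 + 1_000, "<REGION>", "<DEL>",
                VariantKind.DEL_LARGE, size=11_000)
    )
    del_affected, _ = variants_affecting_genes(deletions, del_genes)

    block = [
        GeneModel(f"blk{i}", "V", "+", exons=[(1_000 + 500 * i, 1_300 + 500 * i)])
        for i in range(sd.N_GENES_IN_DUP_BLOCK)
    ]
    solo = [
        GeneModel(f"solo{i}", "II", "+", exons=[(500 * i, 500 * i + 300)])
        for i in range(10)
    ]
    dups = [
        Variant("V", 900, "<REGION>", "<DUP>", VariantKind.DUP,
                size=sd.N_GENES_IN_DUP_BLOCK * 500 + 500, copy_number=2),
        Variant("II", 0, "<REGION>", "<DUP>", VariantKind.DUP, size=800,
                copy_number=2),
        Variant("II", 1_000, "<REGION>", "<DUP>", VariantKind.DUP, size=800,
                copy_number=2),
    ]
    dup_affected, _ = variants_affecting_genes(dups, block + solo)
    minor = {g for g in dup_affected if not g.startswith("blk")}
    return {
        "genes_hit_by_deletions": len(del_affected),
        "n_deletions_hitting_genes": len(deletions),
        "genes_affected_by_duplications": len(dup_affected),
        "genes_duplicated_excluding_block": len(minor),
    }


def tstv_fixture() -> float:
    """The 94-substitution window set: 33 transitions, 61 transversions
    (the unique split of 94 printing as 0.54)."""
    sbs = [_sbs(i, "A", "G") for i in range(33)]
    sbs += [_sbs(1000 + i, "A", "C") for i in range(61)]
    return tstv_ratio(sbs)


# ----------------------------------------------------------------------
# the full reproduction report


def reproduce_all(seed: int = 0) -> dict:
    """Recompute the study's summary quantities from synthetic inputs.

    Every value is produced by running the package's operations; the
    published counts enter only as input shapes (set sizes, planted
    motif numbers, denominators).
    """
    out: dict[str, dict] = {}

    def put(name, value, n):
        out[name] = {"value": value, "n": n}

    # accumulation over the published nested sets
    matrix = accumulation_matrix(generation_sets())
    lo, hi = sd.WINDOW
    n_sbs = matrix.window_total(VariantKind.SBS, lo, hi)
    n_indel = matrix.window_total(VariantKind.DEL_SMALL, lo, hi)
    n_del = matrix.window_total(VariantKind.DEL_LARGE, lo, hi)
    n_dup = matrix.window_total(VariantKind.DUP, lo, hi)
    put("window_new_substitutions", n_sbs, n_sbs)
    put("window_new_indels", n_indel, n_indel)
    put("window_new_deletions", n_del, n_del)
    put("window_new_duplications", n_dup, n_dup)

    # background subtraction and CNV-evidence merge shapes
    n_called, n_unique = background_subtraction_counts()
    put("unique_substitutions_after_background", n_unique, n_called)

    # deletion classification on the planted genome
    genome, annotation, deletions, _ = classification_fixture(seed)
    classes = classify_deletions(deletions, annotation, genome)
    summary = summarize_classifications(classes)
    put("g_rich_deletion_fraction_pct",
        round(100 * summary.fraction_g_rich, 1), summary.n_total)
    put("deletions_initiating_in_strict_signature",
        summary.counts[MotifClass.MONO_TRACT]
        + summary.counts[MotifClass.MONO_LIKE_LE2]
        + summary.counts[MotifClass.INTERRUPTED_GE3],
        summary.n_total)
    put("deletions_at_mono_tracts", summary.counts[MotifClass.MONO_TRACT],
        summary.n_total)

    # monoG/C tract census
    n_deleted, n_tracts, frac = census_fixture(seed)
    put("deleted_mono_tract_fraction_pct", round(100 * frac, 1), n_tracts)

    # rates from the recomputed numerators and published denominators
    denom = RateDenominators(n_generations=sd.WINDOW_GENERATIONS)
    impact = gene_impact_fixture()
    put("substitution_rate_per_base_per_generation",
        round_sig(per_base_rate(n_sbs, denom).rate), n_sbs)
    put("indel_rate_per_base_per_generation",
        round_sig(per_base_rate(n_indel, denom).rate), n_indel)
    put("deletion_rate_per_gene_per_generation",
        round_sig(per_gene_rate(impact["genes_hit_by_deletions"], denom).rate),
        impact["genes_hit_by_deletions"])
    put("duplication_rate_per_gene_per_generation",
        round_sig(per_gene_rate(
            impact["genes_duplicated_excluding_block"], denom).rate),
        impact["genes_duplicated_excluding_block"])
    put("g4_deletion_rate_per_site_per_generation",
        round_sig(per_site_rate(summary.n_g_rich, sd.N_G4_SITES, denom).rate),
        summary.n_g_rich)
    ratio, per_indel = indel_sbs_ratio(n_indel, n_sbs)
    put("indel_to_substitution_ratio", round_sig(ratio), n_indel + n_sbs)
    put("substitutions_per_indel", round_sig(per_indel), n_indel + n_sbs)
    put("transition_transversion_ratio", round(tstv_fixture(), 2), n_sbs)
    put("genes_affected_by_duplications",
        impact["genes_affected_by_duplications"],
        impact["genes_affected_by_duplications"])
    put("genes_hit_by_deletions", impact["genes_hit_by_deletions"],
        impact["n_deletions_hitting_genes"])
    return out
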