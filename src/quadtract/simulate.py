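"""Synthetic mutation-accumulation line with planted G-rich motifs.

The generator emulates the downstream product of sequencing a
single-lineage MA experiment: a genome carrying known G-rich loci, and
per-sample-generation tables of fixed homozygous variants with ground
truth for every event.  Two deliberate simplifications:

* fixation is immediate -- each generation's events fix in the single
  surviving lineage; within-generation drift is not modelled;
* the background sequence is free of GG/CC dinucleotides, so no G-rich
  signature can arise by chance and planted motif truth is exact.  (A
  uniform background would contain relaxed two-guanine signatures with
  near certainty at any useful length.)

Every stochastic draw goes through a single numpy Generator seeded
from the config, so identical configs produce byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import Genome, revcomp
from .motifs import MONO_MIN_LEN_DEFAULT, MotifClass, annotate_genome
from .variants import Variant, VariantCall, VariantKind

MOTIF_SPACING = 200  # bp between planted features


@dataclass
class SimulationConfig:
    """Parameters of the toy genome and the MA line run over it.

    Rates default to the per-generation estimates of the study system
    (substitutions 3.1e-9/base, InDels 5.7e-10/base, quadruplex-site
    deletions 1.7e-4/site, non-G-rich deletions 5.0e-10/base,
    duplications 6.5e-7/gene); tests that need dense events pass
    inflated rates explicitly.  The deletion size model is lognormal
    with median 150 bp and sigma 0.64, clipped to [49, 10228] bp, which
    puts ~86% of draws under 300 bp.
    """

    genome_length: int = 100_000
    n_contigs: int = 1
    plant_counts: dict[str, int] = field(
        default_factory=lambda: {
            "MONO_TRACT": 10,
            "MONO_LIKE_LE2": 4,
            "INTERRUPTED_GE3": 4,
            "RELAXED_4TRACT": 4,
            "RELAXED_3TRACT": 4,
        }
    )
    minus_strand_fraction: float = 0.5
    n_genes: int = 8
    gene_length: int = 300  # CDS length, multiple of 3
    mu_sbs: float = 3.1e-9
    mu_indel: float = 5.7e-10
    mu_del_g4: float = 1.7e-4
    mu_del_nong4: float = 5.0e-10
    mu_dup: float = 6.5e-7
    dup_reversion_prob: float = 2e-3  # per existing duplication per generation
    del_size_log_median: float = 150.0
    del_size_sigma: float = 0.64
    del_size_min: int = 49
    del_size_max: int = 10_228
    mono_min_len: int = MONO_MIN_LEN_DEFAULT
    total_generations: int = 470
    sample_generations: tuple[int, ...] = (170, 270, 470)
    n_decoy_calls: int = 0  # extra non-fixed calls failing the depth/VF/BQ filters
    n_background_variants: int = 0  # pre-existing SBSs shared with the background strain
    seed: int = 0

    def __post_init__(self) -> None:
        for r in ("mu_sbs", "mu_indel", "mu_del_g4", "mu_del_nong4", "mu_dup"):
            if getattr(self, r) < 0:
                raise ValueError(f"{r} must be >= 0")
        sg = list(self.sample_generations)
        if sg != sorted(sg) or (sg and sg[-1] > self.total_generations):
            raise ValueError(
                "sample_generations must ascend and not exceed total_generations"
            )
        if self.gene_length % 3:
            raise ValueError("gene_length must be a multiple of 3")


@dataclass
class PlantedMotif:
    motif_id: int
    contig: str
    start: int
    end: int
    strand: str
    motif_class: MotifClass


@dataclass
class PlantedGene:
    gene_id: str
    contig: str
    start: int
    end: int
    strand: str


@dataclass
class TruthRecord:
    kind: VariantKind
    contig: str
    pos: int
    size: int
    generation: int
    motif_class: MotifClass | None = None  # deletions only
    motif_id: int | None = None


@dataclass
class SimulatedTruth:
    motifs: list[PlantedMotif]
    genes: list[PlantedGene]
    events: list[TruthRecord] = field(default_factory=list)
    background_variants: list[Variant] = field(default_factory=list)
    # per-motif generation of destruction (None = alive at end)
    motif_death_generation: dict[int, int] = field(default_factory=dict)

    def motif_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "motif_id": m.motif_id, "contig": m.contig, "start": m.start,
                    "end": m.end, "strand": m.strand,
                    "motif_class": m.motif_class.value,
                }
                for m in self.motifs
            ]
        )

    def event_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "kind": e.kind.value, "contig": e.contig, "pos": e.pos,
                    "size": e.size, "generation": e.generation,
                    "motif_class": e.motif_class.value if e.motif_class else None,
                    "motif_id": e.motif_id,
                }
                for e in self.events
            ]
        )


# ----------------------------------------------------------------------
# genome construction

_NOT_AFTER = {"G": "ACT", "C": "AGT"}


def _background(rng: np.random.Generator, n: int, prev: str = "A") -> str:
    """Random sequence without GG or CC dinucleotides (Markov constraint)."""
    out = np.empty(n, dtype="<U1")
    bases = np.array(list("ACGT"))
    draws = rng.integers(0, 4, size=n)
    redraw3 = rng.integers(0, 3, size=n)
    for i in range(n):
        b = bases[draws[i]]
        if prev in "GC" and b == prev:
            b = _NOT_AFTER[prev][redraw3[i]]
        out[i] = b
        prev = b
    return "".join(out)


def _motif_sequence(
    rng: np.random.Generator, motif_class: MotifClass, mono_min_len: int
) -> str:
    """A sequence whose strict/relaxed scan and classification equal the class."""
    if motif_class is MotifClass.MONO_TRACT:
        return "G" * int(rng.integers(mono_min_len, mono_min_len + 11))
    if motif_class is MotifClass.MONO_LIKE_LE2:
        # two interruption runs, no pure run reaching mono length
        a = int(rng.integers(10, mono_min_len))  # 10..14
        b = int(rng.integers(4, 8))
        c = int(rng.integers(3, 6))
        return "G" * a + "T" + "G" * b + "AGAA" + "G" * c
    if motif_class is MotifClass.INTERRUPTED_GE3:
        # three interruption runs; still a strict-signature match
        return (
            "G" * int(rng.integers(3, 6)) + "T"
            + "G" * int(rng.integers(3, 6)) + "AAGTTAT"
            + "G" * int(rng.integers(3, 6)) + "A"
            + "G" * int(rng.integers(3, 6))
        )
    if motif_class is MotifClass.RELAXED_4TRACT:
        # four GG tracts, single non-G loops; no 3-G run, so never strict
        loops = rng.choice(list("AT"), size=3)
        return "GG" + loops[0] + "GG" + loops[1] + "GG" + loops[2] + "GG"
    if motif_class is MotifClass.RELAXED_3TRACT:
        loops = rng.choice(list("AT"), size=2)
        return "GG" + loops[0] + "GG" + loops[1] + "GG"
    raise ValueError(f"cannot plant class {motif_class}")


def build_toy_genome(
    config: SimulationConfig,
) -> tuple[Genome, SimulatedTruth]:
    """Construct the planted genome and its ground truth.

    Motifs are planted with >= 200 bp spacing, padded with A/T so they
    never extend into the background; genes are planted as single-exon
    CDSs in background territory.  After assembly the genome is
    rejection-checked: a full scan must recover exactly the planted
    loci, else construction fails loudly.
    """
    rng = np.random.default_rng(config.seed)
    plant_list: list[MotifClass] = []
    for name, count in config.plant_counts.items():
        plant_list += [MotifClass(name)] * count
    motif_slot = MOTIF_SPACING + 40 + 40  # spacing + jittered gap + padded motif
    gene_slot = MOTIF_SPACING + 40 + config.gene_length + 2
    needed = (
        len(plant_list) * motif_slot
        + config.n_genes * gene_slot
        + MOTIF_SPACING * config.n_contigs
    )
    if needed > config.genome_length:
        raise ValueError(
            f"cannot pack {len(plant_list) + config.n_genes} features into "
            f"{config.genome_length} bp; "
            f"need at least {needed} bp"
        )

    contig_len = config.genome_length // config.n_contigs
    contig_ids = [f"ctg{i + 1}" for i in range(config.n_contigs)]
    # interleave features across contigs deterministically
    feature_kinds: list[tuple[str, MotifClass | None]] = [
        ("motif", c) for c in plant_list
    ] + [("gene", None)] * config.n_genes
    order = rng.permutation(len(feature_kinds))

    motifs: list[PlantedMotif] = []
    genes: list[PlantedGene] = []
    contig_seqs: dict[str, list[str]] = {}
    per_contig = np.array_split(np.asarray(order), config.n_contigs)

    motif_id = 0
    for cid, idxs in zip(contig_ids, per_contig):
        parts: list[str] = []
        cursor = 0
        for fi in idxs:
            kind, cls = feature_kinds[fi]
            gap = MOTIF_SPACING + int(rng.integers(0, 40))
            parts.append(_background(rng, gap, prev=parts[-1][-1] if parts else "A"))
            cursor += gap
            if kind == "motif":
                seq = _motif_sequence(rng, cls, config.mono_min_len)
                strand = "-" if rng.random() < config.minus_strand_fraction else "+"
                if strand == "-":
                    seq = revcomp(seq)
                # A/T pads isolate the motif from the background
                parts.append("AT")
                start = cursor + 2
                parts.append(seq)
                parts.append("TA")
                motifs.append(
                    PlantedMotif(motif_id, cid, start, start + len(seq), strand, cls)
                )
                motif_id += 1
                cursor += len(seq) + 4
            else:
                n_codons = config.gene_length // 3 - 2
                body = _background(rng, n_codons * 3, prev="T")
                # avoid in-frame stops so the CDS translates cleanly
                codons = [body[i : i + 3] for i in range(0, len(body), 3)]
                codons = ["TTC" if c in ("TAA", "TAG", "TGA") else c for c in codons]
                gene_seq = "ATG" + "".join(codons) + "TAA"
                parts.append("T")
                start = cursor + 1
                parts.append(gene_seq)
                parts.append("A")
                genes.append(
                    PlantedGene(
                        f"gene{len(genes) + 1}", cid, start, start + len(gene_seq), "+"
                    )
                )
                cursor += len(gene_seq) + 2
        tail = contig_len - cursor
        if tail < 0:
            raise ValueError(
                f"features overflow contig {cid}; increase genome_length"
            )
        parts.append(_background(rng, tail, prev=parts[-1][-1] if parts else "A"))
        contig_seqs[cid] = parts

    genome = Genome({cid: "".join(parts) for cid, parts in contig_seqs.items()})
    truth = SimulatedTruth(motifs=motifs, genes=genes)
    _verify_planted(genome, truth, config)
    return genome, truth


def _verify_planted(
    genome: Genome, truth: SimulatedTruth, config: SimulationConfig
) -> None:
    """Rejection check: the scan must find exactly the planted loci."""
    ann = annotate_genome(genome, config.mono_min_len)
    planted = {
        (m.contig, m.start, m.end) for m in truth.motifs
    }
    found = {
        (s.contig, s.start, s.end)
        for s in ann.strict + ann.relaxed4 + ann.relaxed3
    }
    stray = [iv for iv in found if iv not in planted]
    if stray:
        raise RuntimeError(
            f"background produced unplanted G-rich loci: {stray[:5]}"
        )


# ----------------------------------------------------------------------
# line simulation


def _draw_del_size(rng: np.random.Generator, config: SimulationConfig) -> int:
    s = rng.lognormal(np.log(config.del_size_log_median), config.del_size_sigma)
    return int(np.clip(round(s), config.del_size_min, config.del_size_max))


@dataclass
class _LineState:
    sbs: dict[tuple, Variant]
    indels: dict[tuple, Variant]
    deletions: list[Variant]
    dups: dict[str, int]  # gene_id -> extra copies
    deleted_mask: dict[str, np.ndarray]


def _passing_qc(rng: np.random.Generator) -> tuple[int, float, float]:
    depth = int(rng.integers(30, 120))
    vf = float(np.round(rng.uniform(0.93, 1.0), 3))
    bq = float(rng.integers(31, 41))
    return depth, vf, bq


def _failing_qc(rng: np.random.Generator) -> tuple[int, float, float]:
    mode = int(rng.integers(0, 3))
    depth, vf, bq = _passing_qc(rng)
    if mode == 0:
        depth = int(rng.integers(0, 6))  # depth not > 5
    elif mode == 1:
        vf = float(np.round(rng.uniform(0.1, 0.7), 3))
    else:
        bq = float(rng.integers(5, 30))
    return depth, vf, bq


def simulate_line(
    genome: Genome,
    truth: SimulatedTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[int, list[VariantCall]]:
    """Run the MA line and emit per-sample-generation call tables.

    Per generation, Poisson counts of each event type are drawn; every
    event fixes immediately and persists (duplications may revert).  A
    destroyed locus cannot be hit again, and no event lands inside
    already-deleted sequence.  Ground truth accumulates on ``truth``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    lengths = genome.lengths()
    contigs = list(genome)
    total_len = genome.total_length
    state = _LineState(
        sbs={}, indels={}, deletions=[], dups={},
        deleted_mask={cid: np.zeros(n, dtype=bool) for cid, n in lengths.items()},
    )
    motif_by_id = {m.motif_id: m for m in truth.motifs}
    live_motifs = set(motif_by_id)
    sample_tables: dict[int, list[VariantCall]] = {}

    # optional pre-existing variants shared with the background strain
    for _ in range(config.n_background_variants):
        cid, pos, ref, alt = _draw_sbs(rng, genome, contigs, lengths, state)
        v = Variant(cid, pos, ref, alt, VariantKind.SBS,
                    first_generation_observed=0, provenance="called")
        state.sbs[v.key] = v
        truth.background_variants.append(v)

    def _position_ok(cid: str, start: int, end: int) -> bool:
        return not state.deleted_mask[cid][start:end].any()

    for gen in range(1, config.total_generations + 1):
        # --- substitutions
        for _ in range(rng.poisson(config.mu_sbs * total_len)):
            drawn = _draw_sbs(rng, genome, contigs, lengths, state)
            if drawn is None:
                continue
            cid, pos, ref, alt = drawn
            v = Variant(cid, pos, ref, alt, VariantKind.SBS,
                        first_generation_observed=gen)
            if v.key in state.sbs:
                continue
            state.sbs[v.key] = v
            truth.events.append(TruthRecord(VariantKind.SBS, cid, pos, 1, gen))

        # --- small InDels (kept out of planted motifs: these events do not
        # arise from quadruplex instability in this model)
        for _ in range(rng.poisson(config.mu_indel * total_len)):
            size = int(rng.integers(1, 21))
            ins = bool(rng.integers(0, 2))
            placed = _place_interval(
                rng, genome, contigs, lengths, state, truth,
                size=1 if ins else size, avoid_motifs=True, margin=10,
            )
            if placed is None:
                continue
            cid, pos = placed
            if ins:
                ref = genome.fetch(cid, pos, pos + 1)
                alt = ref + "".join(
                    rng.choice(list("ACGT"), size=size)
                )
                kind = VariantKind.INS
            else:
                ref = genome.fetch(cid, pos, min(pos + size + 1, lengths[cid]))
                alt = ref[0]
                kind = VariantKind.DEL_SMALL
            v = Variant(cid, pos, ref, alt, kind, size,
                        first_generation_observed=gen)
            if v.key in state.indels:
                continue
            state.indels[v.key] = v
            truth.events.append(TruthRecord(kind, cid, pos, size, gen))

        # --- deletions initiating at G-rich loci
        if live_motifs:
            n_del = rng.poisson(config.mu_del_g4 * len(live_motifs))
            for _ in range(n_del):
                if not live_motifs:
                    break
                mid = int(rng.choice(sorted(live_motifs)))
                m = motif_by_id[mid]
                size = max(
                    _draw_del_size(rng, config), m.end - m.start + 10
                )
                jitter = int(rng.integers(0, 3))
                mask = state.deleted_mask[m.contig]
                if m.strand in "+.":
                    d_end = min(m.end + jitter, lengths[m.contig])
                    while d_end > m.end and mask[d_end - 1]:
                        d_end -= 1
                    d_start = max(0, d_end - size)
                    # stop at previously deleted sequence (it is already gone)
                    hit = np.flatnonzero(mask[d_start:d_end])
                    if hit.size:
                        d_start = d_start + int(hit[-1]) + 1
                else:  # C-run on forward: initiate at 5' end, extend 3'-ward
                    d_start = max(0, m.start - jitter)
                    while d_start < m.start and mask[d_start]:
                        d_start += 1
                    d_end = min(d_start + size, lengths[m.contig])
                    hit = np.flatnonzero(mask[d_start:d_end])
                    if hit.size:
                        d_end = d_start + int(hit[0])
                if d_end - d_start < 21:  # nothing left to delete beside the tract
                    continue
                _apply_deletion(
                    state, truth, m.contig, d_start, d_end, gen,
                    motif_class=m.motif_class, motif_id=mid,
                )
                # collateral destruction: large deletions can span neighbours
                killed = {
                    om for om in live_motifs
                    if motif_by_id[om].contig == m.contig
                    and motif_by_id[om].start < d_end
                    and d_start < motif_by_id[om].end
                }
                for om in killed:
                    truth.motif_death_generation.setdefault(om, gen)
                live_motifs -= killed

        # --- non-G-rich deletions
        for _ in range(rng.poisson(config.mu_del_nong4 * total_len)):
            size = int(rng.integers(49, 300))
            placed = _place_interval(
                rng, genome, contigs, lengths, state, truth,
                size=size, avoid_motifs=True, margin=TOLERANCE_MARGIN,
            )
            if placed is None:
                continue
            cid, pos = placed
            _apply_deletion(
                state, truth, cid, pos, pos + size, gen,
                motif_class=MotifClass.NON_G_RICH, motif_id=None,
            )

        # --- duplications over planted genes (with amplification/reversion)
        if truth.genes:
            for _ in range(rng.poisson(config.mu_dup * len(truth.genes))):
                g = truth.genes[int(rng.integers(0, len(truth.genes)))]
                state.dups[g.gene_id] = state.dups.get(g.gene_id, 0) + 1
                truth.events.append(
                    TruthRecord(VariantKind.DUP, g.contig, g.start,
                                g.end - g.start, gen)
                )
            for gid in [g for g, n in list(state.dups.items()) if n > 0]:
                if rng.random() < config.dup_reversion_prob:
                    state.dups[gid] = 0

        if gen in config.sample_generations:
            sample_tables[gen] = _emit_calls(rng, genome, truth, state, config)

    return sample_tables


TOLERANCE_MARGIN = 20  # keep random events clear of motif initiation ends


def _draw_sbs(rng, genome, contigs, lengths, state):
    for _ in range(20):
        cid = contigs[int(rng.integers(0, len(contigs)))]
        pos = int(rng.integers(0, lengths[cid]))
        if state.deleted_mask[cid][pos]:
            continue
        ref = genome.fetch(cid, pos, pos + 1)
        if ref == "N":
            continue
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        return cid, pos, ref, alt
    return None


def _place_interval(rng, genome, contigs, lengths, state, truth,
                    size, avoid_motifs, margin):
    for _ in range(50):
        cid = contigs[int(rng.integers(0, len(contigs)))]
        if lengths[cid] <= size + 2:
            continue
        pos = int(rng.integers(1, lengths[cid] - size - 1))
        if state.deleted_mask[cid][pos : pos + size].any():
            continue
        if avoid_motifs and any(
            m.contig == cid
            and m.start - margin < pos + size
            and pos < m.end + margin
            for m in truth.motifs
        ):
            continue
        if "N" in genome.fetch(cid, pos, pos + size + 1):
            continue
        return cid, pos
    return None


def _apply_deletion(state, truth, cid, start, end, gen, motif_class, motif_id):
    state.deleted_mask[cid][start:end] = True
    v = Variant(cid, start, "<REGION>", "<DEL>", VariantKind.DEL_LARGE,
                size=end - start, first_generation_observed=gen)
    state.deletions.append(v)
    truth.events.append(
        TruthRecord(VariantKind.DEL_LARGE, cid, start, end - start, gen,
                    motif_class=motif_class, motif_id=motif_id)
    )
    if motif_id is not None:
        truth.motif_death_generation.setdefault(motif_id, gen)


def _emit_calls(rng, genome, truth, state, config) -> list[VariantCall]:
    calls: list[VariantCall] = []
    for v in list(state.sbs.values()) + list(state.indels.values()):
        depth, vf, bq = _passing_qc(rng)
        calls.append(VariantCall(
            v.contig, v.pos, v.ref, v.alt, v.kind,
            depth=depth, variant_frequency=vf, base_quality=bq, size=v.size,
        ))
    for v in state.deletions:
        a = int(rng.integers(5, 40))
        calls.append(VariantCall(
            v.contig, v.pos, v.ref, v.alt, v.kind,
            depth=a, variant_frequency=1.0, base_quality=40.0, size=v.size,
            support_a=a, internal_b=int(rng.integers(0, max(1, a // 3))),
        ))
    for gid, extra in state.dups.items():
        if extra <= 0:
            continue
        g = next(g for g in truth.genes if g.gene_id == gid)
        calls.append(VariantCall(
            g.contig, g.start, "<REGION>", "<DUP>", VariantKind.DUP,
            depth=60, variant_frequency=1.0, base_quality=40.0,
            size=g.end - g.start, copy_number=1 + extra,
        ))
    for _ in range(config.n_decoy_calls):
        drawn = _draw_sbs(rng, genome, list(genome), genome.lengths(), state)
        if drawn is None:
            continue
        cid, pos, ref, alt = drawn
        depth, vf, bq = _failing_qc(rng)
        calls.append(VariantCall(
            cid, pos, ref, alt, VariantKind.SBS,
            depth=depth, variant_frequency=vf, base_quality=bq,
        ))
    calls.sort(key=lambda c: (c.contig, c.pos, c.alt))
    return calls


def deletion_initiating_at(
    motif: PlantedMotif,
    size: int,
    jitter: int = 0,
    contig_length: int | None = None,
) -> tuple[str, int, int]:
    """Construct a deletion interval that initiates at a planted motif.

    Forward-strand motifs are removed together with 5'-flanking
    sequence (right breakpoint at the tract's 3' end, +/- jitter);
    minus-strand motifs mirror.  ``size`` is floored so the whole
    motif is always removed.
    """
    size = max(size, motif.end - motif.start + jitter + 1)
    if motif.strand in "+.":
        d_end = motif.end + jitter
        if contig_length is not None:
            d_end = min(d_end, contig_length)
        return motif.contig, max(0, d_end - size), d_end
    d_start = max(0, motif.start - jitter)
    d_end = d_start + size
    if contig_length is not None:
        d_end = min(d_end, contig_length)
    return motif.contig, d_start, d_end


# ----------------------------------------------------------------------
# parameter recovery


def recover_parameters(
    config: SimulationConfig,
    n_replicates: int = 20,
    genome: Genome | None = None,
    truth_template: SimulatedTruth | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Monte-Carlo check that the rate estimators recover configured rates.

    One genome is built (or supplied) and the line is simulated
    ``n_replicates`` times.  Per replicate, the substitution rate is
    estimated as events/(bases x generations) and the per-quadruplex-
    site deletion rate as events/site-generations of exposure, where a
    destroyed site stops accumulating exposure (target-loss
    correction).  Returns configured vs mean estimate with Monte-Carlo
    standard errors.
    """
    if genome is None:
        genome, truth_template = build_toy_genome(config)
    assert truth_template is not None
    base_seed = config.seed if seed is None else seed
    total_len = genome.total_length
    gens = config.total_generations
    n_motifs = len(truth_template.motifs)

    mu_sbs_hat, mu_del_hat = [], []
    for rep in range(n_replicates):
        truth = SimulatedTruth(
            motifs=truth_template.motifs, genes=truth_template.genes
        )
        rng = np.random.default_rng((base_seed + 7919 * (rep + 1)) % 2**31)
        simulate_line(genome, truth, config, rng=rng)
        ev = truth.events
        n_sbs = sum(1 for e in ev if e.kind is VariantKind.SBS)
        mu_sbs_hat.append(n_sbs / (total_len * gens))
        n_g4del = sum(
            1 for e in ev
            if e.kind is VariantKind.DEL_LARGE and e.motif_id is not None
        )
        exposure = sum(
            truth.motif_death_generation.get(m.motif_id, gens)
            for m in truth_template.motifs
        )
        if n_motifs:
            mu_del_hat.append(n_g4del / exposure if exposure else 0.0)

    rows = [_mc_row("mu_sbs", config.mu_sbs, mu_sbs_hat)]
    if n_motifs:
        rows.append(_mc_row("mu_del_g4", config.mu_del_g4, mu_del_hat))
    return pd.DataFrame(rows)


def _mc_row(name: str, configured: float, estimates: list[float]) -> dict:
    arr = np.asarray(estimates)
    se = arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else np.nan
    return {
        "parameter": name,
        "configured": configured,
        "mean_estimate": float(arr.mean()),
        "mc_standard_error": float(se),
        "n_replicates": len(arr),
        "within_2se": bool(abs(arr.mean() - configured) <= 2 * se)
        if np.isfinite(se) and se > 0 else None,
    }


# ----------------------------------------------------------------------
# output writers


def write_simulation_outputs(
    outdir: str | Path,
    genome: Genome,
    truth: SimulatedTruth,
    config: SimulationConfig,
    sample_tables: dict[int, list[VariantCall]],
) -> None:
    from .variants import write_variant_table, write_vcf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome.to_fasta(outdir / "genome.fasta")
    truth.motif_table().to_csv(outdir / "truth_motifs.tsv", sep="\t", index=False)
    truth.event_table().to_csv(outdir / "truth_events.tsv", sep="\t", index=False)
    with open(outdir / "truth_motifs.bed", "w") as fh:
        for m in truth.motifs:
            fh.write(
                f"{m.contig}\t{m.start}\t{m.end}\t{m.motif_class.value}\t0\t"
                f"{m.strand}\n"
            )
    with open(outdir / "truth_genes.bed", "w") as fh:
        for g in truth.genes:
            fh.write(f"{g.contig}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
    for gen, calls in sample_tables.items():
        write_variant_table(calls, outdir / f"variants_F{gen}.tsv")
        write_vcf(calls, outdir / f"variants_F{gen}.vcf", genome.lengths())
    from dataclasses import asdict

    cfg = asdict(config)
    cfg["sample_generations"] = list(config.sample_generations)
    with open(outdir / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
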