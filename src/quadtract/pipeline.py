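"""End-to-end orchestration: scan -> filter -> classify -> rates.

Two modes share one report shape: ``simulate`` builds a planted genome
and MA line first; ``analyze`` consumes a FASTA plus per-generation
variant tables.  Every stage writes its intermediate table so each
number in the report can be audited against a file, and identical
inputs and config produce identical reports (timestamps are not
recorded; provenance is config echo plus input checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from . import breakpoints as bp
from . import motifs as mf
from . import rates as rt
from . import variants as vr
from .genome import Genome

log = logging.getLogger("quadtract.pipeline")


class FilterThresholds(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_depth_exclusive: int = 5
    max_depth: int = 200
    min_vf: float = 0.9
    min_bq: float = 30.0
    min_del_size_exclusive: int = 20

    @field_validator("min_vf")
    @classmethod
    def _vf_range(cls, v: float) -> float:
        if not (0.0 <= v <= 1.0):
            raise ValueError("min_vf must be within [0, 1]")
        return v


class Denominators(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: Literal["published", "measured"] = "measured"
    genome_bases: int | None = None  # None + measured mode -> FASTA length
    n_genes: int = rt.PUBLISHED_N_GENES
    n_generations: int | None = None  # None -> window span


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: Literal["simulate", "analyze"] = "simulate"
    outdir: str = "quadtract_out"
    seed: int = 0
    generations: list[int] = Field(default_factory=lambda: [170, 270, 470])
    window: tuple[int, int] | None = None  # default: first..last generation
    tolerance: int = bp.TOLERANCE_DEFAULT
    require_orientation: bool = True
    mono_min_len: int = mf.MONO_MIN_LEN_DEFAULT
    census_min_overlap: float = 0.5
    size_threshold: int = 300
    filters: FilterThresholds = Field(default_factory=FilterThresholds)
    denominators: Denominators = Field(default_factory=Denominators)
    # analyze-mode inputs
    fasta: str | None = None
    variant_tables: dict[str, str] = Field(default_factory=dict)  # "170" -> path
    background_tables: list[str] = Field(default_factory=list)
    # simulate-mode knobs (forwarded to SimulationConfig)
    simulation: dict = Field(default_factory=dict)
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.generations != sorted(self.generations):
            raise ValueError("generations must be ascending")
        if self.window is not None:
            lo, hi = self.window
            if lo >= hi:
                raise ValueError(f"window {lo}:{hi} is not ordered")
            if lo not in self.generations or hi not in self.generations:
                raise ValueError("window endpoints must be sampled generations")
        return self

    @property
    def window_or_default(self) -> tuple[int, int]:
        return self.window or (self.generations[0], self.generations[-1])


def validate_config(path: str | Path) -> RunConfig:
    """Schema-check a JSON config file; unknown keys are rejected."""
    with open(path) as fh:
        data = json.load(fh)
    cfg = RunConfig.model_validate(data)
    if cfg.mode == "analyze":
        missing = [
            p for p in [cfg.fasta, *cfg.variant_tables.values(),
                        *cfg.background_tables]
            if p is None or not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"referenced inputs do not exist: {missing}")
    return cfg


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage(name: str, n_in: int | None = None, n_out: int | None = None) -> None:
    log.info("stage=%s n_in=%s n_out=%s", name, n_in, n_out)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the report dict (also written as JSON)."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance: dict = {"config": json.loads(config.model_dump_json())}

    try:
        # ---- stage: inputs / simulation
        if config.mode == "simulate":
            from .simulate import (
                SimulationConfig,
                build_toy_genome,
                simulate_line,
                write_simulation_outputs,
            )

            sim_cfg = SimulationConfig(
                **{"seed": config.seed, **config.simulation}
            )
            genome, truth = build_toy_genome(sim_cfg)
            tables = simulate_line(genome, truth, sim_cfg)
            write_simulation_outputs(outdir / "sim", genome, truth, sim_cfg, tables)
            gen_calls = {g: tables.get(g, []) for g in sim_cfg.sample_generations}
            generations = list(sim_cfg.sample_generations)
            backgrounds = (
                [set(truth.background_variants)]
                if truth.background_variants else []
            )
            _stage("simulate", None, sum(len(v) for v in gen_calls.values()))
        else:
            genome = Genome.from_fasta(config.fasta)
            provenance["input_checksums"] = {
                str(p): _checksum(Path(p))
                for p in [config.fasta, *config.variant_tables.values(),
                          *config.background_tables]
            }
            gen_calls = {}
            for g_str, path in config.variant_tables.items():
                path = Path(path)
                if path.suffix in (".vcf", ".bcf") or str(path).endswith(".vcf.gz"):
                    gen_calls[int(g_str)] = vr.read_vcf(path)
                else:
                    gen_calls[int(g_str)] = vr.read_variant_table(path)
            generations = sorted(gen_calls)
            gen_calls = {g: gen_calls[g] for g in generations}
            backgrounds = [
                {vr.Variant.from_call(c) for c in vr.read_variant_table(p)}
                for p in config.background_tables
            ]
            _stage("load", len(gen_calls), None)

        # ---- stage: motif annotation
        annotation = mf.annotate_genome(genome, config.mono_min_len)
        mf.write_motifs_bed(
            annotation.strict + annotation.relaxed4 + annotation.relaxed3,
            outdir / "motifs.bed",
        )
        mf.write_motifs_tsv(
            annotation.strict + annotation.relaxed4 + annotation.relaxed3,
            outdir / "motifs.tsv",
        )
        _stage(
            "motif_scan",
            genome.total_length,
            len(annotation.strict) + len(annotation.relaxed4)
            + len(annotation.relaxed3),
        )

        # ---- stage: filtering per generation
        f = config.filters
        gen_sets: dict[int, set[vr.Variant]] = {}
        for g, calls in gen_calls.items():
            small = [c for c in calls if c.kind in vr.SMALL_KINDS]
            large_del = [c for c in calls if c.kind is vr.VariantKind.DEL_LARGE]
            dups = [c for c in calls if c.kind is vr.VariantKind.DUP]
            kept_small = vr.filter_small_variants(
                small, f.min_depth_exclusive, f.max_depth, f.min_vf, f.min_bq
            )
            kept_del = vr.select_homozygous_deletions(
                large_del, f.min_del_size_exclusive
            )
            kept = kept_small + kept_del + dups
            vr.write_variant_table(kept, outdir / f"filtered_F{g}.tsv")
            variants = {vr.Variant.from_call(c, g) for c in kept}
            variants = vr.subtract_background(variants, backgrounds)
            gen_sets[g] = variants
            _stage(f"filter_F{g}", len(calls), len(variants))

        # ---- stage: accumulation
        matrix = vr.accumulation_matrix(gen_sets)
        matrix.to_frame().to_csv(outdir / "accumulation_matrix.tsv", sep="\t")
        lo, hi = config.window_or_default
        window_totals = {
            k.value: matrix.window_total(k, lo, hi) for k in matrix.kinds
        }
        _stage("accumulate", sum(len(s) for s in gen_sets.values()), None)

        # ---- stage: deletion classification
        window_dels = matrix.window_variants(vr.VariantKind.DEL_LARGE, lo, hi)
        del_ivs = [(v.contig, v.start, v.end) for v in window_dels]
        classifications = bp.classify_deletions(
            del_ivs, annotation, genome, config.tolerance,
            config.require_orientation,
        )
        bp.write_classifications_tsv(
            classifications, outdir / "deletion_classes.tsv"
        )
        summary = bp.summarize_classifications(
            classifications, config.size_threshold
        )
        census = (
            bp.deleted_tract_census(
                annotation.mono_tracts, del_ivs, config.census_min_overlap
            )
            if annotation.mono_tracts
            else (0, 0, None)
        )
        _stage("classify", len(del_ivs), summary.n_g_rich)

        # ---- stage: rates
        n_gen = config.denominators.n_generations or (hi - lo)
        genome_bases = config.denominators.genome_bases or (
            rt.PUBLISHED_GENOME_BASES
            if config.denominators.mode == "published"
            else genome.total_length
        )
        n_strict_sites = len(annotation.strict)
        denom = rt.RateDenominators(
            genome_bases=genome_bases,
            n_genes=config.denominators.n_genes,
            n_g4_sites=n_strict_sites or None,
            n_generations=n_gen,
        )
        n_sbs = window_totals["SBS"]
        n_indel = window_totals["INS"] + window_totals["DEL_SMALL"]
        sbs_vars = matrix.window_variants(vr.VariantKind.SBS, lo, hi)
        spectrum = rt.mutation_spectrum(sbs_vars)
        tstv = rt.tstv_ratio(sbs_vars) if sbs_vars else None
        ratio, per_indel = (
            rt.indel_sbs_ratio(n_indel, n_sbs) if n_sbs else (None, None)
        )
        rates_block = {
            "sbs_per_base": rt.per_base_rate(n_sbs, denom).rate,
            "sbs_per_base_display": rt.per_base_rate(n_sbs, denom).display,
            "indel_per_base": rt.per_base_rate(n_indel, denom).rate,
            "indel_per_base_display": rt.per_base_rate(n_indel, denom).display,
            "g4_deletion_per_site": (
                rt.per_site_rate(summary.n_g_rich, n_strict_sites, denom).rate
                if n_strict_sites else None
            ),
            "tstv": tstv,
            "indel_sbs_ratio": ratio,
            "substitutions_per_indel": per_indel,
        }
        _stage("rates", None, None)

        report = {
            "generations": generations,
            "window": [lo, hi],
            "accumulation": {
                "new_counts": {
                    k.value: matrix.new[k] for k in matrix.kinds
                },
                "window_totals": window_totals,
                "reversions": {
                    k.value: {
                        g: len(vs) for g, vs in matrix.reversions[k].items()
                    }
                    for k in matrix.kinds
                },
            },
            "classification": summary.to_dict(),
            "deleted_tract_census": {
                "n_deleted": census[0],
                "n_total": census[1],
                "fraction": census[2],
            },
            "rates": rates_block,
            "spectrum": dict(spectrum),
            "provenance": provenance,
        }
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=str)
        return report
    except Exception as err:  # annotate failures with the active stage
        (outdir / "INCOMPLETE").write_text(f"pipeline failed: {err}\n")
        raise
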