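"""Variant call filtering, background subtraction, and cross-generation
accumulation bookkeeping.

The filters mirror a short-read MA-line calling workflow: small-variant
calls (substitutions and InDels <= 20 bp) are kept when read depth is
in (5, 200], variant frequency >= 0.9 (fixed in the line) and base
quality >= 30; candidate large deletions (> 20 bp) are kept when the
breakpoint homozygosity statistic a/(a+b) exceeds 0.5, where a counts
unique reads supporting the breakpoints and b reads mapping inside the
putatively deleted region.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

SMALL_INDEL_MAX = 20  # InDels <= 20 bp are "small"; deletions > 20 bp are "large"


class VariantKind(str, enum.Enum):
    SBS = "SBS"
    INS = "INS"
    DEL_SMALL = "DEL_SMALL"
    DEL_LARGE = "DEL_LARGE"
    DUP = "DUP"


SMALL_KINDS = {VariantKind.SBS, VariantKind.INS, VariantKind.DEL_SMALL}
INTERVAL_KINDS = {VariantKind.DEL_LARGE, VariantKind.DUP}


@dataclass(frozen=True)
class VariantCall:
    """A raw call as emitted by a caller (or the simulator)."""

    contig: str
    pos: int  # 0-based coordinate of the reference-anchor base
    ref: str
    alt: str
    kind: VariantKind
    depth: int | None = None
    variant_frequency: float | None = None
    base_quality: float | None = None
    size: int = 1
    support_a: int | None = None
    internal_b: int | None = None
    copy_number: int | None = None

    def __post_init__(self) -> None:
        if self.variant_frequency is not None and not (
            0.0 <= self.variant_frequency <= 1.0
        ):
            raise ValueError(f"variant_frequency outside [0,1]: {self}")
        if self.kind is not VariantKind.SBS and self.size < 1:
            raise ValueError(f"size must be >= 1 for {self.kind}: {self}")
        for f_ in ("support_a", "internal_b"):
            v = getattr(self, f_)
            if v is not None and v < 0:
                raise ValueError(f"negative {f_} in {self}")

    @property
    def start(self) -> int:
        return self.pos

    @property
    def end(self) -> int:
        """Half-open end of the affected reference interval."""
        if self.kind in (VariantKind.SBS, VariantKind.INS):
            return self.pos + 1
        return self.pos + self.size

    @property
    def key(self) -> tuple:
        return (self.contig, self.pos, self.ref, self.alt, self.kind, self.size)


@dataclass(frozen=True)
class Variant:
    """A fixed homozygous variant, keyed and tagged with first observation."""

    contig: str
    pos: int
    ref: str
    alt: str
    kind: VariantKind
    size: int = 1
    copy_number: int | None = None  # DUP only; copy state is part of identity
    # metadata: excluded from equality/hash so set logic keys on the variant itself
    first_generation_observed: int | None = field(default=None, compare=False)
    provenance: str = field(default="called", compare=False)

    @property
    def key(self) -> tuple:
        return (self.contig, self.pos, self.ref, self.alt, self.kind, self.size)

    @property
    def start(self) -> int:
        return self.pos

    @property
    def end(self) -> int:
        if self.kind in (VariantKind.SBS, VariantKind.INS):
            return self.pos + 1
        return self.pos + self.size

    @classmethod
    def from_call(cls, call: VariantCall, generation: int | None = None) -> "Variant":
        return cls(
            call.contig, call.pos, call.ref, call.alt, call.kind, call.size,
            copy_number=call.copy_number,
            first_generation_observed=generation,
        )


# ----------------------------------------------------------------------
# filtering


def _require(call: VariantCall, fields: tuple[str, ...]) -> None:
    for f_ in fields:
        if getattr(call, f_) is None:
            raise ValueError(f"missing required field {f_!r} in record {call}")


def filter_small_variants(
    calls: list[VariantCall],
    min_depth_exclusive: int = 5,
    max_depth: int = 200,
    min_vf: float = 0.9,
    min_bq: float = 30,
) -> list[VariantCall]:
    """Apply the fixed-variant thresholds, then deduplicate per coordinate.

    Keeps calls with depth > min_depth_exclusive and <= max_depth,
    variant frequency >= min_vf and base quality >= min_bq.  When
    several surviving calls share one (contig, pos) coordinate, the
    highest-VF record is kept (ties: lexicographically smallest alt),
    so each coordinate corresponds to one variant.  Order-preserving.
    """
    kept: list[VariantCall] = []
    for call in calls:
        _require(call, ("depth", "variant_frequency", "base_quality"))
        if (
            call.depth > min_depth_exclusive
            and call.depth <= max_depth
            and call.variant_frequency >= min_vf
            and call.base_quality >= min_bq
        ):
            kept.append(call)
    best: dict[tuple[str, int], VariantCall] = {}
    for call in kept:
        coord = (call.contig, call.pos)
        prev = best.get(coord)
        if prev is None or (
            (-call.variant_frequency, call.alt)
            < (-prev.variant_frequency, prev.alt)
        ):
            best[coord] = call
    chosen = set(id(c) for c in best.values())
    return [c for c in kept if id(c) in chosen]


def select_homozygous_deletions(
    calls: list[VariantCall], min_size_exclusive: int = SMALL_INDEL_MAX
) -> list[VariantCall]:
    """Fixed large deletions: a/(a+b) > 0.5 (strict) and size > 20 bp (strict)."""
    kept = []
    for call in calls:
        _require(call, ("support_a", "internal_b"))
        a, b = call.support_a, call.internal_b
        if a + b == 0:
            log.warning("deletion with no supporting reads dropped: %s", call.key)
            continue
        if a / (a + b) > 0.5 and call.size > min_size_exclusive:
            kept.append(call)
    return kept


def subtract_background(
    sample: set[Variant], backgrounds: list[set[Variant]]
) -> set[Variant]:
    """Remove variants whose key appears in any background strain set."""
    bg_keys = {v.key for bg in backgrounds for v in bg}
    return {
        replace(v, provenance="background-subtracted")
        for v in sample
        if v.key not in bg_keys
    }


# ----------------------------------------------------------------------
# cross-generation accumulation


def _reciprocal_overlap(a: Variant, b: Variant) -> float:
    if a.contig != b.contig:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return min(inter / (a.end - a.start), inter / (b.end - b.start))


def _matches_any(
    v: Variant, others: set[Variant], min_reciprocal_overlap: float = 0.9
) -> bool:
    """Cross-generation identity.

    Small variants match by exact key; large deletions by reciprocal
    overlap >= 0.9 (breakpoint re-estimation jitters between sequencing
    batches).  A duplication is accounted for when a same-locus
    duplication of at least its copy number exists, so amplification
    (copy 2 -> 3) registers as a new event and an amplified locus does
    not register as a reversion of its earlier copy state.
    """
    if v.kind in SMALL_KINDS:
        return any(v.key == o.key for o in others if o.kind == v.kind)
    if v.kind is VariantKind.DUP:
        return any(
            _reciprocal_overlap(v, o) >= min_reciprocal_overlap
            and (o.copy_number or 2) >= (v.copy_number or 2)
            for o in others
            if o.kind is VariantKind.DUP
        )
    return any(
        _reciprocal_overlap(v, o) >= min_reciprocal_overlap
        for o in others
        if o.kind == v.kind
    )


@dataclass
class AccumulationMatrix:
    """New-variant counts per kind x sampled generation, plus reversions.

    ``new[kind][g]`` counts variants first seen at generation g;
    ``new_variants[kind][g]`` holds them; ``reversions[kind][g]`` holds
    variants present at the previous sample point but absent at g
    (expected only for duplications, which can revert to normal copy
    number).
    """

    generations: list[int]
    kinds: list[VariantKind]
    new: dict[VariantKind, dict[int, int]]
    new_variants: dict[VariantKind, dict[int, list[Variant]]]
    reversions: dict[VariantKind, dict[int, list[Variant]]]

    def window_total(self, kind: VariantKind, g_start: int, g_end: int) -> int:
        """New variants accumulated after g_start, up to and including g_end."""
        return sum(
            n for g, n in self.new[kind].items() if g_start < g <= g_end
        )

    def window_variants(
        self, kind: VariantKind, g_start: int, g_end: int
    ) -> list[Variant]:
        out = []
        for g, vs in self.new_variants[kind].items():
            if g_start < g <= g_end:
                out.extend(vs)
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {k.value: {g: self.new[k].get(g, 0) for g in self.generations}
             for k in self.kinds}
        ).T
        df.columns = [f"F{g}" for g in self.generations]
        return df


def accumulation_matrix(
    generation_sets: dict[int, set[Variant]],
    kinds: list[VariantKind] | None = None,
    min_reciprocal_overlap: float = 0.9,
) -> AccumulationMatrix:
    """Count variants new at each sampled generation, per kind.

    Generations must be supplied in ascending order.  A variant is
    "new" at generation g_k if it is absent from the g_{k-1} set
    (everything at the first sample point is new).  Variants present at
    g_{k-1} but absent at g_k are reported as reversions, not errors.
    """
    gens = list(generation_sets)
    if gens != sorted(gens):
        raise ValueError(f"generations not sorted ascending: {gens}")
    kinds = kinds or list(VariantKind)
    new: dict[VariantKind, dict[int, int]] = {k: {} for k in kinds}
    newv: dict[VariantKind, dict[int, list[Variant]]] = {k: {} for k in kinds}
    rev: dict[VariantKind, dict[int, list[Variant]]] = {k: {} for k in kinds}
    prev: set[Variant] = set()
    for g in gens:
        cur = generation_sets[g]
        for k in kinds:
            cur_k = {v for v in cur if v.kind == k}
            prev_k = {v for v in prev if v.kind == k}
            fresh = sorted(
                (v for v in cur_k
                 if not _matches_any(v, prev_k, min_reciprocal_overlap)),
                key=lambda v: (v.contig, v.pos),
            )
            gone = sorted(
                (v for v in prev_k
                 if not _matches_any(v, cur_k, min_reciprocal_overlap)),
                key=lambda v: (v.contig, v.pos),
            )
            new[k][g] = len(fresh)
            newv[k][g] = fresh
            rev[k][g] = gone
        prev = cur
    return AccumulationMatrix(gens, kinds, new, newv, rev)


# ----------------------------------------------------------------------
# orthogonal CNV evidence


def merge_cnv_evidence(
    primary_calls: list[VariantCall],
    orthogonal_calls: list[VariantCall],
    min_reciprocal_overlap: float = 0.5,
) -> list[VariantCall]:
    """Union of breakpoint-resolved and array-derived interval calls.

    Two calls describe the same event when their reciprocal overlap is
    at least the threshold; the merged event keeps the primary
    (breakpoint-refined) coordinates when available.
    """
    out = list(primary_calls)
    for oc in orthogonal_calls:
        dup = any(
            pc.kind == oc.kind
            and _reciprocal_overlap(
                Variant.from_call(pc), Variant.from_call(oc)
            ) >= min_reciprocal_overlap
            for pc in primary_calls
        )
        if not dup:
            out.append(oc)
    out.sort(key=lambda c: (c.contig, c.pos))
    return out


# ----------------------------------------------------------------------
# IO: TSV dialect and VCF

_TSV_COLUMNS = [
    "contig", "pos", "ref", "alt", "kind", "depth", "variant_frequency",
    "base_quality", "size", "support_a", "internal_b", "copy_number",
]


def write_variant_table(calls: list[VariantCall], path: str | Path) -> None:
    rows = []
    for c in calls:
        rows.append({
            "contig": c.contig, "pos": c.pos, "ref": c.ref, "alt": c.alt,
            "kind": c.kind.value, "depth": c.depth,
            "variant_frequency": c.variant_frequency,
            "base_quality": c.base_quality, "size": c.size,
            "support_a": c.support_a, "internal_b": c.internal_b,
            "copy_number": c.copy_number,
        })
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def _opt_int(v):
    return None if pd.isna(v) else int(v)


def _opt_float(v):
    return None if pd.isna(v) else float(v)


def read_variant_table(path: str | Path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t")
    missing = set(["contig", "pos", "ref", "alt", "kind"]) - set(df.columns)
    if missing:
        raise ValueError(f"variant table {path} missing columns: {sorted(missing)}")
    calls = []
    for row in df.itertuples(index=False):
        calls.append(VariantCall(
            contig=str(row.contig), pos=int(row.pos), ref=str(row.ref),
            alt=str(row.alt), kind=VariantKind(row.kind),
            depth=_opt_int(getattr(row, "depth", None)),
            variant_frequency=_opt_float(getattr(row, "variant_frequency", None)),
            base_quality=_opt_float(getattr(row, "base_quality", None)),
            size=_opt_int(getattr(row, "size", 1)) or 1,
            support_a=_opt_int(getattr(row, "support_a", None)),
            internal_b=_opt_int(getattr(row, "internal_b", None)),
            copy_number=_opt_int(getattr(row, "copy_number", None)),
        ))
    return calls


_VCF_KIND = {  # INFO/KIND tag <-> VariantKind; inferred from alleles if absent
    k.value: k for k in VariantKind
}


def _infer_kind(ref: str, alt: str) -> tuple[VariantKind, int]:
    if len(ref) == 1 and len(alt) == 1:
        return VariantKind.SBS, 1
    if len(alt) > len(ref):
        return VariantKind.INS, len(alt) - len(ref)
    size = len(ref) - len(alt)
    return (
        VariantKind.DEL_SMALL if size <= SMALL_INDEL_MAX else VariantKind.DEL_LARGE,
        size,
    )


def read_vcf(path: str | Path) -> list[VariantCall]:
    """Read calls from VCF 4.x.

    Field mapping: INFO/DP -> depth; INFO/AF or INFO/FREQ -> variant
    frequency; INFO/BQ -> base quality; INFO/KIND and INFO/SVLEN
    override the allele-inferred kind/size; INFO/SUPA / INFO/SUPB carry
    the deletion breakpoint-support counts.
    """
    import pysam

    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alt = rec.alts[0] if rec.alts else rec.ref
            info = dict(rec.info)
            kind_tag = info.get("KIND")
            if kind_tag is not None:
                kind = _VCF_KIND[str(kind_tag)]
                size = abs(int(info.get("SVLEN", [1])[0]
                               if isinstance(info.get("SVLEN"), tuple)
                               else info.get("SVLEN", 1)))
            else:
                kind, size = _infer_kind(rec.ref, alt)
            vf_val = info.get("AF", info.get("FREQ"))
            if isinstance(vf_val, tuple):
                vf_val = vf_val[0]
            calls.append(VariantCall(
                contig=rec.chrom, pos=rec.pos - 1, ref=rec.ref, alt=alt,
                kind=kind,
                depth=info.get("DP"),
                variant_frequency=float(vf_val) if vf_val is not None else None,
                base_quality=float(info["BQ"]) if "BQ" in info else None,
                size=size,
                support_a=info.get("SUPA"),
                internal_b=info.get("SUPB"),
                copy_number=info.get("CN"),
            ))
    return calls


def write_vcf(
    calls: list[VariantCall], path: str | Path, contig_lengths: dict[str, int]
) -> None:
    """Write calls as a minimal VCF 4.2 with the INFO fields read_vcf expects."""
    import pysam

    header = pysam.VariantHeader()
    for cid, length in contig_lengths.items():
        header.contigs.add(cid, length=length)
    for line in (
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Variant frequency">',
        '##INFO=<ID=BQ,Number=1,Type=Float,Description="Mean base quality">',
        '##INFO=<ID=KIND,Number=1,Type=String,Description="Variant kind">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Event size">',
        '##INFO=<ID=SUPA,Number=1,Type=Integer,Description="Breakpoint-supporting reads">',
        '##INFO=<ID=SUPB,Number=1,Type=Integer,Description="Reads inside deleted region">',
        '##INFO=<ID=CN,Number=1,Type=Integer,Description="Copy number">',
    ):
        header.add_line(line)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in sorted(calls, key=lambda c: (c.contig, c.pos)):
            kw = (
                {"stop": c.pos + c.size} if c.kind in INTERVAL_KINDS else {}
            )
            rec = out.new_record(
                contig=c.contig, start=c.pos,
                alleles=(c.ref, c.alt or c.ref), **kw,
            )
            rec.info["KIND"] = c.kind.value
            rec.info["SVLEN"] = c.size
            if c.depth is not None:
                rec.info["DP"] = c.depth
            if c.variant_frequency is not None:
                rec.info["AF"] = c.variant_frequency
            if c.base_quality is not None:
                rec.info["BQ"] = c.base_quality
            if c.support_a is not None:
                rec.info["SUPA"] = c.support_a
            if c.internal_b is not None:
                rec.info["SUPB"] = c.internal_b
            if c.copy_number is not None:
                rec.info["CN"] = c.copy_number
            out.write(rec)
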