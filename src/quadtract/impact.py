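"""Lightweight variant-to-gene impact counting.

Replaces a full annotation engine with transparent interval and codon
logic: a gene is *affected* when a substitution or small InDel
overlaps one of its exons, or a large deletion/duplication overlaps
its span.  Coding effects are computed by translating the CDS on the
coding strand with the standard nuclear genetic code.  Splice-site and
UTR semantics are deliberately out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq
from intervaltree import IntervalTree

from .genome import Genome, revcomp
from .variants import Variant, VariantKind

log = logging.getLogger(__name__)


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    def cds_sequence(self, genome: Genome) -> str:
        parts = [genome.fetch(self.contig, s, e) for s, e in sorted(self.cds)]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass(frozen=True)
class ImpactRecord:
    variant_key: tuple
    gene_id: str
    effect: str  # intergenic/intronic/synonymous/missense/nonsense/
    #              frameshift/inframe_indel/gene_deleted/gene_duplicated/exonic


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene models from GFF3 (gene/mRNA/exon/CDS features).

    One model per gene; exons and CDS of all isoforms are pooled (the
    union is what "affected" queries need).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons, cds = [], []
        for child in db.children(g, featuretype="exon"):
            exons.append((child.start - 1, child.end))
        for child in db.children(g, featuretype="CDS"):
            cds.append((child.start - 1, child.end))
        if not exons:
            exons = [(g.start - 1, g.end)]
        genes.append(
            GeneModel(g.id, g.seqid, g.strand, sorted(exons), sorted(set(cds)))
        )
    return genes


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig}\tquadtract\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.contig}\tquadtract\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={g.gene_id}\n"
                )
            for s, e in g.cds:
                fh.write(
                    f"{g.contig}\tquadtract\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"Parent={g.gene_id}\n"
                )


# ----------------------------------------------------------------------


def variants_affecting_genes(
    variants: list[Variant], genes: list[GeneModel]
) -> tuple[set[str], list[ImpactRecord]]:
    """Distinct affected genes and one record per (variant, gene) overlap.

    Substitutions and small InDels must overlap an exon; large
    deletions and duplications need only overlap the gene span.
    """
    gene_contigs = {g.contig for g in genes}
    var_contigs = {v.contig for v in variants}
    unmatched = sorted(var_contigs - gene_contigs)
    if variants and genes and unmatched:
        raise ValueError(
            f"variant contigs absent from gene models: {unmatched}"
        )
    exon_trees: dict[str, IntervalTree] = {}
    span_trees: dict[str, IntervalTree] = {}
    for i, g in enumerate(genes):
        span_trees.setdefault(g.contig, IntervalTree()).addi(g.start, g.end, i)
        for s, e in g.exons:
            exon_trees.setdefault(g.contig, IntervalTree()).addi(s, e, i)
    affected: set[str] = set()
    records: list[ImpactRecord] = []
    for v in variants:
        trees = exon_trees if v.kind in (
            VariantKind.SBS, VariantKind.INS, VariantKind.DEL_SMALL
        ) else span_trees
        tree = trees.get(v.contig)
        if tree is None:
            continue
        hit_gene_idx = sorted({iv.data for iv in tree.overlap(v.start, v.end)})
        for i in hit_gene_idx:
            g = genes[i]
            affected.add(g.gene_id)
            if v.kind is VariantKind.DEL_LARGE and v.start <= g.start and v.end >= g.end:
                effect = "gene_deleted"
            elif v.kind is VariantKind.DUP:
                effect = "gene_duplicated"
            else:
                effect = "exonic"
            records.append(ImpactRecord(v.key, g.gene_id, effect))
    return affected, records


_STOP = "*"


def classify_cds_effect(
    variant: Variant, gene: GeneModel, genome: Genome
) -> str:
    """Coding effect of a variant overlapping the gene's CDS.

    Substitutions are translated in place (synonymous / missense /
    nonsense); coding InDels are frameshift when size % 3 != 0, else
    in-frame; a deletion covering the whole gene is gene_deleted.
    A CDS whose pooled length is not a multiple of three is translated
    on its longest in-frame prefix and flagged via a log warning.
    """
    if variant.kind is VariantKind.DUP:
        return "gene_duplicated"
    if variant.kind is VariantKind.DEL_LARGE:
        if variant.start <= gene.start and variant.end >= gene.end:
            return "gene_deleted"
        return "frameshift" if variant.size % 3 else "inframe_indel"
    if variant.kind in (VariantKind.INS, VariantKind.DEL_SMALL):
        return "frameshift" if variant.size % 3 else "inframe_indel"

    # SBS: locate the base within the spliced CDS
    cds = sorted(gene.cds)
    offset = None
    acc = 0
    for s, e in cds:
        if s <= variant.pos < e:
            offset = acc + (variant.pos - s)
            break
        acc += e - s
    if offset is None:
        return "intronic"
    seq = "".join(genome.fetch(gene.contig, s, e) for s, e in cds)
    alt_seq = seq[:offset] + variant.alt.upper() + seq[offset + 1 :]
    if gene.strand == "-":
        seq, alt_seq = revcomp(seq), revcomp(alt_seq)
    usable = len(seq) - len(seq) % 3
    if len(seq) % 3:
        log.warning(
            "CDS length of %s not divisible by 3; translating prefix",
            gene.gene_id,
        )
    ref_aa = str(Seq(seq[:usable]).translate())
    alt_aa = str(Seq(alt_seq[:usable]).translate())
    if ref_aa == alt_aa:
        return "synonymous"
    changed = [
        (a, b) for a, b in zip(ref_aa, alt_aa) if a != b
    ]
    if any(b == _STOP for _, b in changed):
        return "nonsense"
    return "missense"
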