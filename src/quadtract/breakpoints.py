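"""Deletion breakpoint-initiation classification.

In helicase-deficient lines, large deletions characteristically
*initiate* at a G-rich locus: the breakpoint sits at the 3' end of a
G-tract (or, mirrored, the 5' end of a C-tract) and the deleted
segment extends into the tract's 5'-flanking DNA, removing the tract
almost completely.  Each deletion > 20 bp is assigned exactly one
class by checking annotation layers in priority order: strict
quadruplex signature (subclassified into monoG tract / monoG-like /
interrupted), then relaxed four-tract, then relaxed three-tract
signatures, else non-G-rich.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome import Genome
from .motifs import (
    CLASS_PRIORITY,
    GTract,
    MotifAnnotation,
    MotifClass,
    MotifSite,
)

TOLERANCE_DEFAULT = 5  # bp slack around the initiation end of a tract


@dataclass
class DeletionClassification:
    contig: str
    start: int
    end: int
    motif_class: MotifClass
    initiating_site: MotifSite | None
    breakpoint_side: str  # g_run_3prime | c_run_5prime | none

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def is_g_rich(self) -> bool:
        return self.motif_class is not MotifClass.NON_G_RICH


def _candidate(
    del_start: int,
    del_end: int,
    site: MotifSite,
    tolerance: int,
    require_orientation: bool,
) -> tuple[int, str] | None:
    """Distance from breakpoint to initiation end and side label, or None.

    Forward-strand G-run: initiation end is the site's right (3') end;
    the deletion's right breakpoint must lie inside the site or within
    ``tolerance`` of that end, the deletion extending 5'-ward
    (leftward) past the site start.  Reverse (a C-run on forward) is
    the mirror.  Collapsed double-stranded sites accept either side.
    """
    best: tuple[int, str] | None = None
    if site.strand in "+.":
        near_3prime = site.start < del_end <= site.end + tolerance
        if require_orientation:
            if near_3prime and del_start < site.start:
                best = (abs(del_end - site.end), "g_run_3prime")
        else:
            # any breakpoint inside the motif qualifies
            left_inside = site.start <= del_start < site.end
            if near_3prime or left_inside:
                dists = [abs(del_end - site.end)] if near_3prime else []
                if left_inside:
                    dists.append(abs(del_start - site.end))
                best = (min(dists), "g_run_3prime")
    if site.strand in "-.":
        near_5prime = site.start - tolerance <= del_start < site.end
        cand: tuple[int, str] | None = None
        if require_orientation:
            if near_5prime and del_end > site.end:
                cand = (abs(del_start - site.start), "c_run_5prime")
        else:
            right_inside = site.start < del_end <= site.end
            if near_5prime or right_inside:
                dists = [abs(del_start - site.start)] if near_5prime else []
                if right_inside:
                    dists.append(abs(del_end - site.start))
                cand = (min(dists), "c_run_5prime")
        if cand is not None and (best is None or cand[0] < best[0]):
            best = cand
    return best


def initiating_site(
    deletion: tuple[str, int, int],
    motifs: list[MotifSite],
    genome: Genome | None = None,
    tolerance: int = TOLERANCE_DEFAULT,
    require_orientation: bool = True,
) -> tuple[MotifSite | None, str]:
    """The motif at which a deletion initiates, if any.

    When several motifs qualify, the one whose initiation end is
    nearest the breakpoint wins; exact ties go to the
    higher-priority (more specific) class.
    """
    contig, del_start, del_end = deletion
    if del_end <= del_start:
        raise ValueError("deletion end must exceed start")
    if genome is not None:
        if contig not in genome:
            raise IndexError(f"unknown contig {contig!r}")
        if del_start < 0 or del_end > len(genome[contig]):
            raise IndexError(
                f"deletion {del_start}..{del_end} outside contig {contig!r}"
            )
    best_site: MotifSite | None = None
    best_rank: tuple[int, int] | None = None
    best_side = "none"
    for site in motifs:
        if site.contig != contig:
            continue
        cand = _candidate(del_start, del_end, site, tolerance, require_orientation)
        if cand is None:
            continue
        dist, side = cand
        prio = CLASS_PRIORITY.get(site.motif_class, len(CLASS_PRIORITY))
        rank = (dist, prio)
        if best_rank is None or rank < best_rank:
            best_rank, best_site, best_side = rank, site, side
    return best_site, (best_side if best_site is not None else "none")


def classify_deletion(
    deletion: tuple[str, int, int],
    annotation: MotifAnnotation,
    genome: Genome | None = None,
    tolerance: int = TOLERANCE_DEFAULT,
    require_orientation: bool = True,
) -> DeletionClassification:
    """Assign one initiation class, checking strict, then relaxed-4, then
    relaxed-3 annotation layers."""
    contig, s, e = deletion
    for layer in (annotation.strict, annotation.relaxed4, annotation.relaxed3):
        site, side = initiating_site(
            deletion, layer, genome, tolerance, require_orientation
        )
        if site is not None:
            return DeletionClassification(contig, s, e, site.motif_class, site, side)
    return DeletionClassification(contig, s, e, MotifClass.NON_G_RICH, None, "none")


def classify_deletions(
    deletions: list[tuple[str, int, int]],
    annotation: MotifAnnotation,
    genome: Genome | None = None,
    tolerance: int = TOLERANCE_DEFAULT,
    require_orientation: bool = True,
) -> list[DeletionClassification]:
    return [
        classify_deletion(d, annotation, genome, tolerance, require_orientation)
        for d in deletions
    ]


# ----------------------------------------------------------------------
# summaries


@dataclass
class ClassificationSummary:
    counts: dict[MotifClass, int]
    n_total: int
    n_g_rich: int
    fraction_g_rich: float | None
    size_histogram: tuple[np.ndarray, np.ndarray] | None
    fraction_below_threshold: float | None
    size_threshold: int

    def to_dict(self) -> dict:
        hist = None
        if self.size_histogram is not None:
            counts, edges = self.size_histogram
            hist = {"counts": counts.tolist(), "bin_edges": edges.tolist()}
        return {
            "counts": {c.value: n for c, n in self.counts.items()},
            "n_total": self.n_total,
            "n_g_rich": self.n_g_rich,
            "fraction_g_rich": self.fraction_g_rich,
            "size_histogram": hist,
            "fraction_below_threshold": self.fraction_below_threshold,
            "size_threshold": self.size_threshold,
        }


def size_distribution(
    sizes: list[int],
    threshold: int = 300,
    bins: list[int] | None = None,
) -> tuple[tuple[np.ndarray, np.ndarray] | None, float | None]:
    """Deletion size histogram and the fraction strictly below ``threshold``."""
    if not sizes:
        return None, None
    arr = np.asarray(sizes)
    if bins is None:
        bins = [21, 50, 100, 200, 300, 500, 1000, 5000, int(max(arr.max(), 10228)) + 1]
    hist = np.histogram(arr, bins=bins)
    return hist, float((arr < threshold).mean())


def summarize_classifications(
    classifications: list[DeletionClassification],
    size_threshold: int = 300,
    g_rich_sizes_only: bool = True,
) -> ClassificationSummary:
    counts = Counter(c.motif_class for c in classifications)
    full = {c: counts.get(c, 0) for c in MotifClass}
    n_total = len(classifications)
    n_g_rich = n_total - full[MotifClass.NON_G_RICH]
    sizes = [
        c.size for c in classifications
        if c.is_g_rich or not g_rich_sizes_only
    ]
    hist, frac_below = size_distribution(sizes, size_threshold)
    return ClassificationSummary(
        counts=full,
        n_total=n_total,
        n_g_rich=n_g_rich,
        fraction_g_rich=(n_g_rich / n_total) if n_total else None,
        size_histogram=hist,
        fraction_below_threshold=frac_below,
        size_threshold=size_threshold,
    )


def deleted_tract_census(
    mono_tracts: list[GTract],
    deletions: list[tuple[str, int, int]],
    min_overlap_fraction: float = 0.5,
) -> tuple[int, int, float]:
    """How many monoG/C tracts have been destroyed by deletions.

    A tract counts as deleted when some deletion covers at least
    ``min_overlap_fraction`` of it (majority-overlap rule; observed
    deletions remove tracts almost completely, so the rule is not
    sensitive near its default).
    """
    n_total = len(mono_tracts)
    if n_total == 0:
        raise ValueError("no tracts: deleted fraction undefined")
    n_deleted = 0
    for t in mono_tracts:
        need = min_overlap_fraction * t.length
        for contig, ds, de in deletions:
            if contig != t.contig:
                continue
            inter = min(de, t.end) - max(ds, t.start)
            if inter >= need and inter > 0:
                n_deleted += 1
                break
    return n_deleted, n_total, n_deleted / n_total


# ----------------------------------------------------------------------
# IO


def write_classifications_tsv(
    classifications: list[DeletionClassification], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "contig\tstart\tend\tsize\tclass\tinitiating_site\tside\n"
        )
        for c in classifications:
            site = (
                f"{c.initiating_site.start + 1}..{c.initiating_site.end}"
                if c.initiating_site
                else "."
            )
            fh.write(
                f"{c.contig}\t{c.start + 1}\t{c.end}\t{c.size}\t"
                f"{c.motif_class.value}\t{site}\t{c.breakpoint_side}\n"
            )


def read_deletions_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out
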