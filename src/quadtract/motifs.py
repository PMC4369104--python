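"""Scanning and classification of G-rich loci.

Three families of loci are handled, all defined on whichever strand
carries the guanine runs (a C-run on the forward strand is a G-run on
the reverse strand):

* homopolymer ``monoG/C`` tracts -- maximal pure G (or C) runs; tracts
  longer than 14 bp have the highest quadruplex-forming potential;
* the strict quadruplex signature ``G3+ N1-7 G3+ N1-7 G3+ N1-7 G3+``
  (four runs of three or more guanines separated by loops of one to
  seven nucleotides of any type, including G);
* relaxed signatures with two-guanine tracts, in four-tract
  (``G2+ N1-7 x4``) and three-tract (``G2+ N1-7 x3``) forms.

A *site* is the union of every substring matching a signature, with
overlapping or bookended matches merged into one maximal interval, so
that one biological locus is counted once.  Because loop nucleotides
may themselves be guanine, a pure G15 homopolymer matches the strict
signature (G3.G.G3.G.G3.G.G3) and long homopolymers never fragment
into several sites.

The scanner computes the exact union of all matching substrings with a
dynamic program over tract chain ends (window minima of earliest match
starts), not a greedy regex, so its output is provably the merged set
of every match.
"""

from __future__ import annotations

import enum
import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import Genome, revcomp

MONO_MIN_LEN_DEFAULT = 15  # "larger than 14 bp" -> strictly greater


class MotifClass(str, enum.Enum):
    """Initiation-relevant classes, in priority order (most specific first)."""

    MONO_TRACT = "MONO_TRACT"
    MONO_LIKE_LE2 = "MONO_LIKE_LE2"
    INTERRUPTED_GE3 = "INTERRUPTED_GE3"
    RELAXED_4TRACT = "RELAXED_4TRACT"
    RELAXED_3TRACT = "RELAXED_3TRACT"
    NON_G_RICH = "NON_G_RICH"


CLASS_PRIORITY = {c: i for i, c in enumerate(MotifClass)}


@dataclass(frozen=True)
class SignatureSpec:
    """Quadruplex signature: n_tracts runs of >= min_tract_len G separated by loops."""

    min_tract_len: int
    min_loop: int = 1
    max_loop: int = 7
    n_tracts: int = 4

    def __post_init__(self) -> None:
        if self.min_tract_len < 2:
            raise ValueError("min_tract_len must be >= 2")
        if not (1 <= self.min_loop <= self.max_loop):
            raise ValueError("need 1 <= min_loop <= max_loop")
        if self.n_tracts < 3:
            raise ValueError("n_tracts must be >= 3")

    @property
    def min_span(self) -> int:
        """Shortest possible match (all tracts minimal, all loops minimal)."""
        return (
            self.n_tracts * self.min_tract_len
            + (self.n_tracts - 1) * self.min_loop
        )


STRICT_G4 = SignatureSpec(min_tract_len=3, n_tracts=4)
RELAXED_4TRACT = SignatureSpec(min_tract_len=2, n_tracts=4)
RELAXED_3TRACT = SignatureSpec(min_tract_len=2, n_tracts=3)

NAMED_SPECS = {
    "strict": STRICT_G4,
    "relaxed4": RELAXED_4TRACT,
    "relaxed3": RELAXED_3TRACT,
}


@dataclass(frozen=True)
class GTract:
    """A run of guanines: pure homopolymer (n_interruption_runs == 0) or not."""

    contig: str
    start: int
    end: int
    strand: str  # strand on which the run is guanine
    n_interruption_runs: int = 0
    interruption_bases: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class MotifSite:
    """A merged G-rich locus on a genome.

    ``strand`` is '+' when the guanine runs lie on the forward strand,
    '-' when they are C-runs on forward (G on reverse), and '.' when
    overlapping sites from both strands were collapsed into one
    double-stranded locus.
    """

    contig: str
    start: int
    end: int
    strand: str
    motif_class: MotifClass | None = None
    signature_string: str = ""
    member_tracts: list[GTract] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


# ----------------------------------------------------------------------
# homopolymer tracts


def find_homopolymer_tracts(
    genome: Genome, base: str, min_len: int, strand: str = "+"
) -> list[GTract]:
    """All maximal runs of ``base`` of length >= min_len, in coordinate order.

    ``strand`` only labels the output tracts (a C-run is recorded as a
    G-run on the minus strand by the monoG/C caller).
    """
    base = base.upper()
    if base not in "ACGT":
        raise ValueError(f"unknown base symbol: {base!r}")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    pat = re.compile(f"{base}{{{min_len},}}")
    out: list[GTract] = []
    for cid, seq in genome.items():
        for m in pat.finditer(seq):
            out.append(GTract(cid, m.start(), m.end(), strand))
    return out


def find_mono_gc_tracts(
    genome: Genome, min_len: int = MONO_MIN_LEN_DEFAULT
) -> list[GTract]:
    """monoG/C census: G-runs (+) and C-runs (reported as G-runs on -) >= min_len."""
    tracts = find_homopolymer_tracts(genome, "G", min_len, "+")
    tracts += find_homopolymer_tracts(genome, "C", min_len, "-")
    tracts.sort(key=lambda t: (t.contig, t.start, t.end))
    return tracts


# ----------------------------------------------------------------------
# signature scanning


def _run_lengths_ending(is_b: np.ndarray) -> np.ndarray:
    # rl[i] = length of base-run ending at position i (inclusive)
    c = np.cumsum(is_b)
    reset = np.where(~is_b, c, 0)
    return c - np.maximum.accumulate(reset)


def _match_union(seq: str, base: str, spec: SignatureSpec) -> list[tuple[int, int]]:
    """Merged union of every substring of ``seq`` matching ``spec`` with
    runs of ``base``.

    DP over chain ends: M_j[b] = earliest possible match start of a chain
    of j tracts whose j-th tract ends exactly at b.  A tract ending at b
    may start anywhere in the base-run ending at b (length >= min tract);
    the previous chain end must sit min_loop..max_loop bases before the
    tract start, with no N inside the loop.
    """
    n = len(seq)
    if n < spec.min_span:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_b = arr == ord(base)
    rl_inc = _run_lengths_ending(is_b)  # run length ending at i, inclusive

    is_n = arr == ord("N")
    # last_n[i] = index of last N at position <= i, or -1
    last_n = np.maximum.accumulate(np.where(is_n, np.arange(n), -1))

    t, lmin, lmax, k = (
        spec.min_tract_len,
        spec.min_loop,
        spec.max_loop,
        spec.n_tracts,
    )
    INF = n + 1
    # candidate chain-end positions b (exclusive): a tract of >= t can end there
    cand = np.flatnonzero(rl_inc >= t) + 1
    if cand.size == 0:
        return []
    RL = np.zeros(n + 1, dtype=np.int64)
    RL[1:] = rl_inc

    M = np.full(n + 1, INF, dtype=np.int64)
    M[cand] = cand - RL[cand]  # earliest first-tract start

    for _ in range(k - 1):
        M2 = np.full(n + 1, INF, dtype=np.int64)
        for b in cand:
            run_start = b - RL[b]
            hi = b - t - lmin  # latest previous chain end
            lo = run_start - lmax  # earliest previous chain end
            if run_start > 0:
                # loop spanning [x, run_start) must be N-free
                lo = max(lo, int(last_n[run_start - 1]) + 1)
            lo = max(lo, 0)
            if lo <= hi:
                m = M[lo : hi + 1].min()
                if m < INF:
                    M2[b] = m
        M = M2

    ends = cand[M[cand] < INF]
    if ends.size == 0:
        return []
    intervals = sorted((int(M[b]), int(b)) for b in ends)
    return merge_intervals(intervals)


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or bookended sorted intervals."""
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _compress(seq: str) -> str:
    """Compact signature text: homopolymer runs >= 2 as 'X_n', singles literal."""
    out = []
    for ch, grp in itertools.groupby(seq):
        m = len(list(grp))
        out.append(f"{ch}_{m}" if m >= 2 else ch)
    return "".join(out)


def expand_signature(sig: str) -> str:
    """Inverse of the compact signature text (G-strand orientation)."""
    out = []
    for m in re.finditer(r"([A-Za-z])(?:_(\d+))?", sig):
        out.append(m.group(1).upper() * int(m.group(2) or 1))
    return "".join(out)


def _member_tracts(
    genome: Genome, contig: str, start: int, end: int, min_len: int
) -> list[GTract]:
    sub = genome.fetch(contig, start, end)
    tracts = []
    for strand, b in (("+", "G"), ("-", "C")):
        for m in re.finditer(f"{b}{{{min_len},}}", sub):
            tracts.append(GTract(contig, start + m.start(), start + m.end(), strand))
    tracts.sort(key=lambda t: t.start)
    return tracts


def _site_signature(genome: Genome, contig: str, start: int, end: int, strand: str) -> str:
    sub = genome.fetch(contig, start, end)
    if strand == "-":
        sub = revcomp(sub)  # present in G-run orientation
    return _compress(sub)


def scan_signature(
    genome: Genome,
    spec: SignatureSpec,
    collapse_strands: bool = True,
) -> list[MotifSite]:
    """Find every merged signature site on both strands of the genome.

    The C-pattern on the forward strand is the G-pattern on the reverse
    strand; both are scanned in forward coordinates.  With
    ``collapse_strands`` (the default, used for genome-wide site
    counts), a forward and a reverse site that overlap are merged into
    one double-stranded site (strand '.').
    """
    sites: list[MotifSite] = []
    for cid, seq in genome.items():
        per_strand: list[tuple[str, tuple[int, int]]] = []
        for strand, b in (("+", "G"), ("-", "C")):
            for iv in _match_union(seq, b, spec):
                per_strand.append((strand, iv))
        if collapse_strands:
            ivs = sorted(iv for _, iv in per_strand)
            merged = merge_intervals(ivs)
            for s, e in merged:
                strands = {
                    st for st, (ms, me) in per_strand if ms < e and s < me
                }
                strand = strands.pop() if len(strands) == 1 else "."
                sites.append(
                    MotifSite(
                        cid,
                        s,
                        e,
                        strand,
                        signature_string=_site_signature(genome, cid, s, e, strand),
                        member_tracts=_member_tracts(
                            genome, cid, s, e, spec.min_tract_len
                        ),
                    )
                )
        else:
            for strand, (s, e) in sorted(per_strand, key=lambda x: x[1]):
                sites.append(
                    MotifSite(
                        cid,
                        s,
                        e,
                        strand,
                        signature_string=_site_signature(genome, cid, s, e, strand),
                        member_tracts=_member_tracts(
                            genome, cid, s, e, spec.min_tract_len
                        ),
                    )
                )
    sites.sort(key=lambda s: (s.contig, s.start, s.end))
    return sites


# ----------------------------------------------------------------------
# classification of strict-signature sites


_G_TRACT_RE = re.compile("G{2,}")


def _classify_g_oriented(sub: str, mono_min_len: int) -> MotifClass:
    tracts = [m.span() for m in _G_TRACT_RE.finditer(sub)]
    if any(e - s >= mono_min_len for s, e in tracts):
        return MotifClass.MONO_TRACT
    # interruption runs = segments between consecutive G-tracts; an
    # isolated single G inside a segment does not split it
    n_interruptions = sum(
        1 for (_, e1), (s2, _) in zip(tracts, tracts[1:]) if s2 > e1
    )
    if n_interruptions <= 2:
        return MotifClass.MONO_LIKE_LE2
    return MotifClass.INTERRUPTED_GE3


def classify_motif(
    site: MotifSite,
    genome: Genome,
    mono_min_len: int = MONO_MIN_LEN_DEFAULT,
) -> MotifClass:
    """Subclassify a strict-signature site.

    MONO_TRACT if it contains a pure G-run of >= mono_min_len;
    otherwise MONO_LIKE_LE2 when at most two maximal non-G runs
    interrupt the homopolymer, INTERRUPTED_GE3 when three or more do.
    Interruptions are counted as *runs*, not nucleotides: the published
    example G14-T-G6-AGAA-G3 has five interrupting bases but two
    interruption runs and is monoG-like.
    """
    sub = genome.fetch(site.contig, site.start, site.end)
    if site.strand == "-":
        candidates = [revcomp(sub)]
    elif site.strand == "+":
        candidates = [sub]
    else:  # collapsed double-stranded site: use the better orientation
        candidates = [sub, revcomp(sub)]
    cls = min(
        (_classify_g_oriented(c, mono_min_len) for c in candidates),
        key=lambda c: CLASS_PRIORITY[c],
    )
    return cls


# ----------------------------------------------------------------------
# genome-wide annotation


@dataclass
class MotifAnnotation:
    """Layered annotation used by the deletion classifier.

    ``strict`` sites carry their subclass; ``relaxed4`` / ``relaxed3``
    are the full match sets of the corresponding signatures (a locus
    may appear in several layers; the classifier checks layers in
    priority order).
    """

    strict: list[MotifSite]
    relaxed4: list[MotifSite]
    relaxed3: list[MotifSite]
    mono_tracts: list[GTract]

    def all_sites(self) -> list[MotifSite]:
        return self.strict + self.relaxed4 + self.relaxed3


def annotate_genome(
    genome: Genome, mono_min_len: int = MONO_MIN_LEN_DEFAULT
) -> MotifAnnotation:
    strict = scan_signature(genome, STRICT_G4)
    for s in strict:
        s.motif_class = classify_motif(s, genome, mono_min_len)
    relaxed4 = scan_signature(genome, RELAXED_4TRACT)
    for s in relaxed4:
        s.motif_class = MotifClass.RELAXED_4TRACT
    relaxed3 = scan_signature(genome, RELAXED_3TRACT)
    for s in relaxed3:
        s.motif_class = MotifClass.RELAXED_3TRACT
    mono = find_mono_gc_tracts(genome, mono_min_len)
    return MotifAnnotation(strict, relaxed4, relaxed3, mono)


def site_count_sensitivity(
    genome: Genome, specs: dict[str, SignatureSpec] | None = None
) -> "pd.DataFrame":
    """Site counts under alternative merging/strand conventions.

    Published genome-wide site counts depend on unstated conventions
    (whether overlapping forward/reverse matches collapse into one
    site, whether bookended matches merge).  This table reports the
    count per signature under each convention so a calibration against
    a reference genome can identify which convention was used.
    """
    import pandas as pd

    specs = specs or NAMED_SPECS
    rows = []
    for name, spec in specs.items():
        collapsed = scan_signature(genome, spec, collapse_strands=True)
        per_strand = scan_signature(genome, spec, collapse_strands=False)
        rows.append(
            {
                "signature": name,
                "sites_strand_collapsed": len(collapsed),
                "sites_per_strand": len(per_strand),
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# output writers


def write_motifs_bed(sites: list[MotifSite], path: str | Path) -> None:
    """BED6+ (0-based half-open): contig, start, end, signature, 0, strand, class."""
    with open(path, "w") as fh:
        for s in sites:
            cls = s.motif_class.value if s.motif_class else "."
            fh.write(
                f"{s.contig}\t{s.start}\t{s.end}\t{s.signature_string}\t0\t"
                f"{s.strand}\t{cls}\n"
            )


def write_motifs_tsv(sites: list[MotifSite], path: str | Path) -> None:
    """TSV mirror with 1-based inclusive coordinates (locus reporting style)."""
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tstrand\tmotif_class\tsignature\n")
        for s in sites:
            cls = s.motif_class.value if s.motif_class else "."
            fh.write(
                f"{s.contig}\t{s.start + 1}\t{s.end}\t{s.strand}\t{cls}\t"
                f"{s.signature_string}\n"
            )


def read_motifs_bed(path: str | Path) -> list[MotifSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            cls = None if len(f) < 7 or f[6] == "." else MotifClass(f[6])
            sites.append(
                MotifSite(
                    f[0], int(f[1]), int(f[2]), f[5],
                    motif_class=cls, signature_string=f[3],
                )
            )
    return sites
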