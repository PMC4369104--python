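# Methods

This note documents the models, conventions and numerical choices
behind `quadtract`, in the order the pipeline applies them.

## Signature scanning

A quadruplex signature is parameterised as `SignatureSpec(min_tract_len
t, min_loop..max_loop, n_tracts k)`; the shipped specs are strict
(t=3, loops 1–7, k=4), relaxed-4 (t=2, k=4) and relaxed-3 (t=2, k=3).
A substring matches when it can be decomposed into k runs of ≥ t
guanines separated by loops of 1–7 nucleotides *of any type, including
guanine*. Two consequences of the loop-may-be-G convention are load-
bearing:

* a pure G15 homopolymer matches the strict signature
  (G3·G·G3·G·G3·G·G3 needs 4×3 + 3×1 = 15 guanines), so every monoG
  tract > 14 bp is also a strict site;
* `G2 N G12` does **not** match the strict signature (G12 supplies only
  12 of the 15 guanines four 3-G tracts with gaps require), which is
  why that locus belongs to the relaxed-4 family only.

**Site definition.** The scanner reports the union of *all* matching
substrings, with overlapping or bookended matches merged, so one locus
is one site. This is computed exactly by a DP over chain ends:
`M_j[b]` is the earliest possible match start of a j-tract chain whose
j-th tract ends at position b; the transition is a window minimum over
previous chain ends `[b − runlen(b) − max_loop, b − t − min_loop]`,
with the window floor raised past the last ambiguity base (N may not
appear in a loop, and N terminates G-runs). The union of
`[M_k[b], b)` over all candidate ends, merged, is provably the union
of all matches, because every match ending at b is contained in
`[M_k[b], b)` and that interval is itself a match. The test suite
checks exact equivalence with an independent brute-force enumerator
(regex fullmatch over every substring) on randomized sequences.

**Strands.** The C-pattern on the forward strand is the G-pattern on
the reverse; both are scanned in forward coordinates. For genome-wide
*site counts*, overlapping forward/reverse sites collapse into one
double-stranded site (strand `.`), since a G-run is a C-run on the
other strand and counting it twice would double-count one locus;
per-strand records are retained for breakpoint orientation. The
`site_count_sensitivity` table reports counts under both conventions
because published genome-wide counts rarely state theirs; calibrating
against a specific reference genome requires that genome's FASTA,
which this repository does not ship — on planted synthetic genomes the
collapsed convention recovers the planted counts exactly, and that is
what the acceptance checks verify.

**monoG/C tracts.** "Larger than 14 bp" is read literally: minimum
length 15, strict inequality. Classification of strict sites counts
interruption *runs*, not nucleotides: the site's sequence (in G-run
orientation) is split on G-runs of length ≥ 2, and the segments
between consecutive runs are the interruptions — an isolated single
guanine inside an interruption (as in `AGAA`) does not split it. A
site is MONO_TRACT if it contains a pure G-run ≥ 15, MONO_LIKE_LE2
with ≤ 2 interruption runs, INTERRUPTED_GE3 otherwise. The worked
sequences G20 / G14·T·G6·AGAA·G3 / GGGtGGGGaagttatGGGaGGG land in the
three classes respectively.

**Coordinates.** 0-based half-open internally and in BED output;
1-based inclusive in TSV report mirrors.

## Variant filtering

Thresholds follow the fixed-homozygous-variant convention for a
sequenced MA line: depth > 5 (strict) and ≤ 200 (inclusive), variant
frequency ≥ 0.9, base quality ≥ 30. Per-coordinate deduplication keeps
the highest-VF record, ties broken toward the lexicographically
smallest alternate allele (the convention is ours; the requirement is
only that each coordinate yields one variant). Large deletions are
accepted when a/(a+b) > 0.5 (a = unique breakpoint-supporting reads,
b = reads inside the deleted region) and size > 20 bp, both strict;
calls with a+b = 0 are dropped with a log warning. InDels ≤ 20 bp are
"small"; events > 20 bp are structural.

**Cross-generation identity.** Substitutions and small InDels match by
exact (contig, pos, ref, alt, kind) key. Large deletions match by
reciprocal overlap ≥ 0.9, absorbing breakpoint re-estimation jitter
between sequencing batches of different depth and read length.
Duplications carry their copy number as part of their identity: an
amplification (copy 2 → 3) of an existing duplication counts as a new
event, while the earlier copy state is not reported as a reversion; a
locus returning to normal copy number is a reversion. Substitutions,
InDels and deletions never revert (and the simulator never reverts
them), so a non-empty reversion report for those kinds indicates an
input problem.

Orthogonal CNV evidence (e.g. array-derived intervals) merges into the
breakpoint-resolved call set by reciprocal overlap ≥ 0.5, keeping the
breakpoint-refined coordinates for shared events.

## Deletion initiation classification

A deletion initiates at a motif when its breakpoint lies inside the
motif or within `tolerance` (default 5 bp) of the motif's initiation
end — the 3′ end for a forward G-run, with the deletion extending
5′-ward past the motif start; mirrored for C-runs. The 5 bp default
reflects that observed deletions remove the tract "almost completely":
small breakpoint slack is biological and technical, and classification
on simulator output is insensitive to the value between 3 and 10 bp
(the simulator jitters breakpoints by ≤ 2 bp). Orientation enforcement
is the default and can be disabled (`require_orientation=False`
accepts any breakpoint inside the motif).

Layers are checked in order strict → relaxed-4 → relaxed-3 → none, so
a locus matching several signatures classifies by the most specific
one; within a layer the motif whose initiation end is nearest the
breakpoint wins, ties toward the more specific class.

A monoG/C tract counts as *deleted* when a deletion covers ≥ 50% of it
(majority overlap rather than 1-bp touch, again motivated by
near-complete tract removal). The size summary reports the fraction of
deletions strictly below 300 bp.

## Rate estimation

All estimators are MA point estimates `events / (targets ×
generations)` with no selection correction (the near-neutral fixation
assumption of bottlenecked MA lines is taken as given). Denominators
are either the reproduction-mode constants (10⁸ bases, 20,400 genes,
300 generations) or measured from the input FASTA and window. Display
is round-half-even at two significant figures via `decimal`; the six
standard rate strings reproduce from their printed numerators.
Ts/Tv returns `None` (not an error) when a set has no transversions,
which small synthetic sets can. The spectrum is strand-collapsed into
the six classes A:T→{T:A, C:G, G:C} and G:C→{A:T, T:A, C:G}.

One published inconsistency is surfaced rather than resolved: the
non-G4 per-base deletion rate of 5.0 × 10⁻¹⁰ back-computes to 15
events over 3 × 10¹⁰ base-generations, while the window classification
leaves 16 non-G-rich deletions (139 − 123). The per-gene figure
(3 genes → 4.9 × 10⁻⁷) is internally consistent and is the one the
reproduction module recomputes.

## Gene impact

A gene is *affected* when a substitution or small InDel overlaps an
exon, or a structural event overlaps the gene span; splice-site and
UTR semantics are deliberately out of scope, so exact agreement with a
full annotation engine's gene totals on real data is not claimed.
Coding effects translate the pooled CDS on the coding strand with the
standard nuclear code (synonymous / missense / nonsense for
substitutions; frameshift vs in-frame by size mod 3 for InDels; whole-
gene deletion detection). A CDS whose length is not a multiple of
three is translated on its longest in-frame prefix and flagged.

## Synthetic MA lines

The generator's defaults are the study conditions: rates
μ_sbs = 3.1 × 10⁻⁹/base, μ_indel = 5.7 × 10⁻¹⁰/base,
μ_del_G4 = 1.7 × 10⁻⁴/site, μ_del_nonG4 = 5.0 × 10⁻¹⁰/base,
μ_dup = 6.5 × 10⁻⁷/gene, all per generation; 470 generations sampled
at 170/270/470. At these rates a desk-scale genome accumulates almost
nothing, which is itself faithful; tests and examples that need dense
events pass inflated rates explicitly (e.g. 10⁻⁶ substitutions/base on
a 1 Mb genome, the scale used for parameter recovery).

**Background sequence** is drawn with a Markov constraint that forbids
GG and CC dinucleotides. This is deliberate: a uniform background of
any useful length contains relaxed two-guanine signatures with
near-certainty, so rejection sampling against "no accidental motif"
would not terminate. The cost is realism — real intergenic sequence
has G-runs — so planted-truth recovery results demonstrate scanner and
classifier *correctness*, not false-positive behaviour on natural
base composition (the randomized oracle-equivalence tests cover
arbitrary composition). Planted motifs are spaced ≥ 200 bp, padded
with A/T so they cannot extend, and the assembled genome is
rejection-checked by a full scan that must recover exactly the planted
loci.

**Line model.** One surviving lineage; per generation, Poisson event
counts per type; every event fixes immediately and persists.
Deletions at G-rich loci remove the tract plus 5′-flanking sequence
with sizes from a lognormal (median 150 bp, σ = 0.64, clipped to
[49, 10228] bp — ≈ 86% of draws below 300 bp); a deletion truncates at
previously deleted sequence rather than being discarded, and destroyed
loci (including collateral neighbours) stop being targets, with their
death generation recorded. Emitted call tables carry synthetic
depth/VF/BQ fields that pass the filters; optional decoy calls violate
one threshold each, and optional background-strain variants exercise
subtraction. All randomness flows through one seeded numpy generator;
identical configs give byte-identical output.

**Parameter recovery** estimates μ_sbs as events/(bases × generations)
and μ_del_G4 as events divided by live site-generations of exposure
(target-loss correction: a destroyed site stops accruing exposure).
Means over replicates agree with configured values within two
Monte-Carlo standard errors at the scales tested (100 replicates,
1 Mb, 50 sites).

## Pipeline

`run_pipeline` always writes stage intermediates (motif BED/TSV,
filtered tables, accumulation matrix, classification TSV, report
JSON), so every reported number is auditable against a file; reports
contain a config echo and input checksums but no timestamps, making
runs byte-reproducible. Config validation is strict (unknown keys
rejected; window endpoints must be sampled generations; VF within
[0, 1]).

## Problem sizes used in checks

Oracle equivalence runs on 1,000 random G-enriched sequences, mostly
40–400 bp with every 50th up to 2,000 bp — the O(n²)-substring oracle,
not the scanner, is the binding cost. The census fixture plants 954
tracts on a ~300 kb genome; the classification fixture plants 123
motifs (93/11/10/8/1 across classes) on 60 kb with deletion sizes
capped below the inter-motif spacing so each class assignment is
determined by its initiating locus alone. The recovery study uses one
1 Mb genome scanned once and 100 simulated replicates over it.

## Known limitations

* No thermodynamic G4 scoring, RNA quadruplexes, or experimental
  G4-seq support — pattern matching only.
* Genome-wide site counts for a specific reference genome require that
  FASTA; no reference sequence ships with the package.
* No read-level simulation (FASTQ/BAM), heterozygosity, or selection;
  fixation is immediate by construction.
* Gene impact simplifies splice/UTR semantics; duplication impact
  assumes tandem amplification of the spanned genes.
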