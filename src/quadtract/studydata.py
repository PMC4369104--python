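"""Reference inputs for the C. elegans dog-1/FANCJ; mdf-1/MAD1
mutation-accumulation study system.

These are the published summary counts, denominators and worked
breakpoint sequences for a line propagated 470 generations with
samples frozen at generations 170 and 270.  They serve as *inputs*
for reproduction-mode analyses (the cumulative variant counts define
nested generation sets; the denominators feed the rate estimators;
the worked sequences exercise the motif classifier).
"""

from __future__ import annotations

from .motifs import MotifClass

SAMPLE_GENERATIONS = (170, 270, 470)
WINDOW = (170, 470)
WINDOW_GENERATIONS = 300

# cumulative fixed-variant counts at each sampled generation
SBS_CUMULATIVE = {170: 431, 270: 463, 470: 525}
INDEL_CUMULATIVE = {170: 133, 270: 141, 470: 150}
DELETION_CUMULATIVE = {170: 57, 270: 102, 470: 196}

# raw substitution calls at F470 before background-strain subtraction
N_SBS_CALLED = 776
N_SBS_BACKGROUND = 251  # shared with wild-type reference strains
N_SBS_UNIQUE = 525

# large-deletion evidence merge: breakpoint-resolved + array-only calls
N_DELETIONS_BREAKPOINT = 183
N_DELETIONS_ARRAY_ONLY = 13
N_DELETIONS_TOTAL = 196

# denominators
GENOME_BASES = 100_000_000
N_GENES = 20_400
N_G4_SITES = 2_372  # strict-signature sites genome-wide
N_MONO_TRACTS = 954  # monoG/C tracts > 14 bp genome-wide
N_MONO_TRACTS_DELETED = 126

# window (F170-F470) classification of the 139 accumulated deletions
DELETION_CLASS_COUNTS = {
    MotifClass.MONO_TRACT: 93,
    MotifClass.MONO_LIKE_LE2: 11,
    MotifClass.INTERRUPTED_GE3: 10,
    MotifClass.RELAXED_4TRACT: 8,
    MotifClass.RELAXED_3TRACT: 1,
    MotifClass.NON_G_RICH: 16,
}
N_DELETIONS_WINDOW = 139
N_DELETIONS_G_RICH = 123
N_DELETIONS_STRICT = 114

# gene impact of the window variants
N_GENES_HIT_BY_DELETIONS = 19  # by 18 deletions (one spans two genes)
N_DELETIONS_HITTING_GENES = 18
N_GENES_DUPLICATED_MINOR = 4  # excluding the 62-gene tandem block
N_GENES_IN_DUP_BLOCK = 62

# deletion size distribution at G-rich loci
DELETION_SIZE_RANGE = (49, 10_228)
FRACTION_BELOW_300 = 0.86

# worked breakpoint sequences (strict-signature loci), expanded
WORKED_STRICT_SEQUENCES = {
    "G" * 20: MotifClass.MONO_TRACT,
    "G" * 14 + "T" + "G" * 6 + "AGAA" + "G" * 3: MotifClass.MONO_LIKE_LE2,
    "GGGTGGGGAAGTTATGGGAGGG": MotifClass.INTERRUPTED_GE3,
}

# the nine deletion-initiating loci that deviate from the strict
# signature, as compact signature strings with the relaxed family each
# belongs to (eight four-tract, one three-tract)
NON_STRICT_SIGNATURES = {
    "G_2NG_12": MotifClass.RELAXED_4TRACT,
    "G_3NG_3NG_3N_2G_2": MotifClass.RELAXED_4TRACT,
    "G_2NG_2NG_2NG_2NG_2NG_2NG_2NG_2NG_2": MotifClass.RELAXED_4TRACT,
    "G_2N_3G_2N_5G_2N_2G_2": MotifClass.RELAXED_4TRACT,
    "G_2NG_14NG_2": MotifClass.RELAXED_4TRACT,
    "G_11": MotifClass.RELAXED_4TRACT,
    "G_14": MotifClass.RELAXED_4TRACT,
    "G_3NG_3NG_3N_5G_2NG_2NG_3": MotifClass.RELAXED_4TRACT,
    "G_2NG_3N_6G_3": MotifClass.RELAXED_3TRACT,
}

# two-significant-figure rate displays expected from the counts above
EXPECTED_RATE_DISPLAYS = {
    "sbs_per_base": "3.1 × 10^-9",
    "indel_per_base": "5.7 × 10^-10",
    "deletion_per_gene": "3.1 × 10^-6",
    "deletion_per_g4_site": "1.7 × 10^-4",
    "duplication_per_gene": "6.5 × 10^-7",
    "deletion_non_g4_per_gene": "4.9 × 10^-7",
}
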