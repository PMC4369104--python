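"""Scan a small genome for quadruplex signatures and monoG/C tracts.

Builds a two-contig genome containing a G20 homopolymer, an interrupted
G-rich locus and a C-strand tract, scans it with the strict signature
(four runs of >= 3 G separated by 1-7 nt loops) and the monoG/C caller,
and prints each site with its class.
"""

from quadtract import (
    Genome, STRICT_G4, classify_motif, find_mono_gc_tracts, scan_signature,
)

genome = Genome({
    # separator longer than the 7-nt loop limit keeps the loci distinct
    "chrA": "TTTATT" + "G" * 20 + "TTATAATTAT" + "GGGTGGGGAAGTTATGGGAGGG" + "ATATTA",
    "chrB": "ATTATA" + "C" * 16 + "TATTAT",
})

print("strict-signature sites (merged, both strands):")
for site in scan_signature(genome, STRICT_G4):
    cls = classify_motif(site, genome)
    print(f"  {site.contig}:{site.start + 1}..{site.end} ({site.strand}) "
          f"{cls.value:15s} {site.signature_string}")

print("\nmonoG/C tracts larger than 14 bp:")
for t in find_mono_gc_tracts(genome):
    print(f"  {t.contig}:{t.start + 1}..{t.end} ({t.strand}) length {t.length}")

# The C16 run is reported as a G-run on the minus strand: a guanine
# tract always exists on one of the two strands of a G/C homopolymer.
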