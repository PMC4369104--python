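"""Mutation-rate estimates from the published window counts.

Feeds the 300-generation window numerators (94 substitutions, 17
InDels, 19 deletion-hit genes, 123 quadruplex-site deletions, 4
duplicated genes) through the per-base / per-gene / per-site
estimators and prints the two-significant-figure displays.
"""

from quadtract import (
    RateDenominators, indel_sbs_ratio, per_base_rate, per_gene_rate,
    per_site_rate,
)

denom = RateDenominators(genome_bases=100_000_000, n_genes=20_400,
                         n_generations=300)

print("substitutions:", per_base_rate(94, denom).display, "/base/generation")
print("small InDels: ", per_base_rate(17, denom).display, "/base/generation")
print("deletions:    ", per_gene_rate(19, denom).display, "/gene/generation")
print("duplications: ", per_gene_rate(4, denom).display, "/gene/generation")
print("G4-site deletions:", per_site_rate(123, 2372, denom).display,
      "/site/generation")
ratio, per_indel = indel_sbs_ratio(17, 94)
print(f"InDel:SBS ratio {ratio:.2f} (one InDel per {per_indel:.1f} substitutions)")

# The ~3e5-fold gap between the per-site deletion rate (1.7e-4) and the
# per-base background deletion rate (~5e-10) is what makes quadruplex-
# forming loci deletion hotspots when the protective helicase is absent.
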