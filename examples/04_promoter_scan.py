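"""Scan promoters for cis-element motifs and score positional enrichment.

Positions are TSS-relative (upstream negative).  Enrichment among
upregulated genes is tested in the proximal windows (around -500 and
[-150, +50)); motif density in [-1200, +500) classifies genes as low (<8
copies), high (8-10), or very high (>=11) - the selection rule for
hub-motif-dense network genes.
"""

from coldregulon import MotifDef, SynthConfig, density_table, generate_dataset, positional_enrichment, scan_motifs

cfg = SynthConfig(n_genes=200, regulon_size=25, de_fraction=0.3, seed=31)
_, _, _, promoters, truth = generate_dataset(cfg)

motifs = [MotifDef("BRRE", "CGTGYG", "BL"), MotifDef("DRE/CRT", "RCCGAC", "DREB")]
hits = scan_motifs(promoters, motifs)
print(f"{len(hits)} motif occurrences across {len(promoters)} promoters")

genes = {p.gene_id for p in promoters}
scores = positional_enrichment(hits, set(truth.regulon_members), genes)
for s in scores:
    print(f"  {s.motif:8s} {s.window:10s} fg {s.fg_hit_genes}/{s.fg_genes} "
          f"bg {s.bg_hit_genes}/{s.bg_genes}  p={s.p_value:.3g}  high_score={s.high_score}")

dens = density_table(hits, "BRRE", sorted(genes))
print("\nBRRE density classes:", dens["density_class"].value_counts().to_dict())
# The planted motif (BRRE) is flagged as positionally enriched among the
# regulon genes; the unplanted control (DRE/CRT) is not.  Exactly the
# regulon promoters reach the high density class.
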