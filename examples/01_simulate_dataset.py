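"""Generate a paired two-genotype synthetic cold-stress dataset.

The generator plants differentially expressed genes, one hub-coupled regulon
(intact in genotype A, fragmented into blocks in genotype B), promoter motifs
at controlled densities, and an ortholog map with many-to-one paralog cases.
"""

from coldregulon import SynthConfig, generate_dataset

config = SynthConfig(n_genes=300, regulon_size=30, de_fraction=0.4, seed=11)
counts_a, counts_b, pairs, promoters, truth = generate_dataset(config)

print(f"genotype A counts: {counts_a.counts.shape[0]} genes x {counts_a.counts.shape[1]} samples")
print(f"genotype B counts: {counts_b.counts.shape[0]} genes x {counts_b.counts.shape[1]} samples")
print(f"ortholog candidate pairs (incl. planted paralogs): {len(pairs)}")
print(f"promoters emitted: {len(promoters)} of length {len(promoters[0].sequence)}")
print(f"planted DE genes in A: {len(truth.de_genes_by_genotype['A'])}")
print(f"regulon: {len(truth.regulon_members)} genes around hub {truth.hub_id}, "
      f"fragmented into {len(truth.fragmented_blocks)} blocks in genotype B")
print(f"motif copies planted per regulon promoter: {dict(config.motif_densities)}")
# Counts are negative-binomial draws around latent per-timepoint means; the
# truth record carries every planted label for downstream recovery checks.
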