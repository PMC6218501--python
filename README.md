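# coldregulon

Tools for comparing the cold-stress transcriptional networks of two related
plant genotypes — typically a cultivated reference and a wild relative — from
paired RNA-seq time courses and promoter sequences. The motivating question
is whether two genotypes with similar cold tolerance rely on the same
regulatory wiring: the package quantifies how concordant their
differential-expression responses are over orthologous loci, which
cis-elements are positionally enriched in the promoters of cold-upregulated
genes, and whether a hub-centered regulon (e.g. the brassinosteroid
BES1/BRRE regulon) that is intact in one genotype appears *fragmented* in
the other.

## What it computes

Given gene-level count matrices (two genotypes × five timepoints × three
replicates), promoter sequences, and transcript alignment hit tables:

1. **Ortholog pairing** — per query locus keep the longest alignment; when
   several queries claim one target, keep the most stable mapping
   (identity × query coverage). The result is a one-to-one map.
2. **Differential expression** — median-of-ratios size factors;
   per-gene NB dispersion α (method of moments, shrunk 50/50 to the
   genome-wide median); per-timepoint likelihood-ratio test of stress vs
   0 h under the negative binomial (variance μ(1+αμ)), χ² with 1 df.
   A gene is *up* (resp. *down*) if log₂FC > 2 (< −2) with p < 0.01 at any
   stress timepoint. Directional concordance over ortholog pairs:
   100·|up_A ∩ up_B| / |up_A| and the reverse.
3. **Temporal clustering** — NB model-based K-means (K = 8) on per-timepoint
   profiles: each gene joins the cluster whose mean temporal shape, scaled
   to the gene's abundance, maximizes its NB log-likelihood.
4. **Cis-element analysis** — strand-aware TSS-relative promoter windows
   ([−3000, +2000) by default); IUPAC motif scanning on both strands;
   one-sided hypergeometric enrichment among upregulated genes in the
   proximal windows (around −500 and [−150, +50)); motif density in
   [−1200, +500) classified low (<8 copies), high (8–10), very high (≥11).
5. **Regulon networks** — genes that are both hub-motif-dense and
   cold-upregulated are joined by edges where the Pearson correlation of
   their 4-point log₂FC profiles is ≥ r_min (default 0.8). BFS tiers from
   the hub give the primary/secondary/tertiary organization; connected
   components and the hub-coupled fraction quantify fragmentation; the core
   regulon is the hub plus direct neighbors at r ≥ r_core (default 0.9).
6. **Phenotype metrics** — electrolyte leakage index
   ELI = mean(stress)/mean(control) with a one-sided t-test injury flag,
   and the 0–10 standard evaluation score for recovery.

A synthetic-data module generates the full paired design with planted ground
truth (DE genes, cluster shapes, an intact-vs-fragmented regulon, promoter
motifs at exact densities, many-to-one paralogs), so every stage is testable
without downloads.

## Worked example

```bash
python examples/05_regulon_network.py
```

```
genotype A: 30 nodes, 432 edges, 1 component(s), hub degree 28, hub-coupled fraction 1.00, core size 26
  tiers: {'secondary': 1, 'primary': 28, 'hub': 1}
genotype B: 30 nodes, 135 edges, 3 component(s), hub degree 9, hub-coupled fraction 0.33, core size 10
  tiers: {'unlinked': 20, 'primary': 9, 'hub': 1}
```

The planted regulon is recovered intact in genotype A — a single connected
component with all members coupled to the hub — while the orthologous gene
set in genotype B splits into three components, only one of which contains
the hub. That is the qualitative network contrast the pipeline is built to
detect. The other scripts in `examples/` walk through dataset simulation,
ortholog pairing, differential expression and concordance, promoter
scanning, and phenotype scoring, each printing the numbers it computes.

The whole pipeline also runs behind one command:

```bash
coldregulon all --outdir out --seed 7      # or: python -m coldregulon.cli
```

which writes all stage tables (TSV), networks (GraphML + edge lists), and a
deterministic `summary.json` keyed by a config hash.

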