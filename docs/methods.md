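# Methods

This note documents the models, estimators, and design choices behind
`coldregulon`, and what the synthetic validation does and does not
demonstrate about real data.

## Count model and differential expression

Counts are modeled as negative binomial with mean μ and dispersion α, so
Var = μ(1 + αμ); α = 0 is the Poisson limit. Library depth is removed by
median-of-ratios size factors: the reference is the per-gene geometric mean
across samples over genes with all-positive counts, each sample's factor is
its median ratio to that reference, and factors are rescaled to unit
geometric mean. The rescaling makes normalization exactly idempotent
(re-normalizing a normalized matrix returns factors of 1) without changing
any ratio between samples. If no gene is all-positive the code falls back to
total-count scaling with a logged warning.

Dispersion is estimated per gene by the method of moments,
α̂ = max(0, (s² − m)/m²), within each (genotype, timepoint) condition with
≥2 replicates, averaged over conditions with positive mean, then shrunk
50/50 toward the genome-wide median. The shrinkage stabilizes 3-replicate
estimates without importing an external fitting framework; the 0.5 weight is
a deliberate midpoint between fully pooled and fully gene-wise estimation.
With single replicates everywhere, timepoints within a genotype are pooled
as pseudo-replicates (crude, logged).

Each stress timepoint is tested against 0 h with a likelihood-ratio test:
shared mean vs separate group means, plug-in α̂, statistic referred to χ²₁.
Normalized counts are continuous, so the NB likelihood uses its
gamma-function extension; α is floored at 1e-8 so the Poisson limit needs no
separate branch. Fold changes use a 0.5 pseudocount,
log₂FC = log₂((m_t + ½)/(m_0 + ½)), keeping low-count genes bounded. Genes
with all-zero counts in both groups return (0, 1). The test is exactly
antisymmetric under group swap (log₂FC negates, p unchanged).

A gene is classified *up* if any stress timepoint has log₂FC > 2 at
p < 0.01, *down* analogously; a gene qualifying in both directions at
different timepoints takes the class of its largest-|log₂FC| significant
event, so every gene gets exactly one class. The thresholds (4-fold, raw
p < 0.01) are configurable; p-values are raw by design, with FDR adjustment
available but off by default. Measured on 2,000 simulated null genes
(α = 0.1, 3 vs 3), the full plug-in procedure's type-I error at p < 0.01
sits near 0.02–0.03 — modestly liberal relative to nominal, as expected for
plug-in dispersion at n = 3, and the calibration suite asserts it stays
within [0.002, 0.03].

## NB model-based K-means

Temporal profiles (per-timepoint means of normalized counts) are clustered
by an alternating scheme: each gene joins the cluster whose mean *shape*
(unit-sum profile over timepoints, scaled by the gene's total abundance)
maximizes the gene's NB log-likelihood; cluster shapes are then re-estimated
from pooled member counts. The pooled update is the Poisson M-step, not the
exact NB one, so each cluster's update is guarded: a candidate shape is
accepted only if its members' log-likelihood does not decrease. This makes
the total log-likelihood non-decreasing across iterations by construction.
Initialization is k-means++ on row-standardized log profiles (seeded, hence
fully reproducible); empty clusters are re-seeded from the worst-fit gene.
K = 8 by default. On 8 planted temporal shapes (50 genes each, α = 0.1) the
labels recover truth with ARI ≥ 0.98.

## Promoter windows and motif statistics

Coordinates are TSS-relative, upstream negative, half-open. Extraction takes
[−3000, +2000) around the TSS (GFF3 1-based inclusive converted to 0-based
half-open); minus-strand genes take the mirrored genomic slice
reverse-complemented, so TSS-relative position −p always maps to genomic
tss + p on the gene's strand. Contig-edge truncation is flagged, not fatal.

Motifs are IUPAC strings supplied in config; shipped defaults are standard
PLACE-style consensus sequences (BRRE = CGTGYG, E-box = CANNTG,
ABRE-like = ACGTGKC, DRE/CRT = RCCGAC, as1/ocs = TGACG, Myb2 = YAACKG,
hex-3 = ACGTCA, GARE = TAACARA). GS2 and JRRE ship unset and error at use —
they are intentionally never guessed. Scanning reports every overlapping
occurrence on both strands; an occurrence on the minus strand is positioned
at its own 5′-most base; a span matching both strands (palindrome) is
reported once, on +. Sequence `N` matches nothing.

Positional enrichment is a one-sided hypergeometric test per motif per
window on genes-with-≥1-in-window-hit, upregulated (foreground) vs all
expressed (background); score = −log₁₀ p, and a motif is flagged
high-scoring when p < 0.01 in either proximal window. The "around −500"
window is quantified as [−650, −350) — a 300-base window centered on −500;
its width is a package choice and is configurable, as is the core-promoter
window [−150, +50). Density counts occurrences in [−1200, +500) and maps
<8 / 8–10 / ≥11 copies to low / high / very high. Window bounds are
configurable because reasonable analyses vary them.

## Regulon assembly and fragmentation

The network gene set is the intersection of hub-motif-dense (high or very
high) and cold-upregulated genes — density acts as the specificity filter,
which matters because the co-expression measure is a Pearson correlation of
4-point log₂FC profiles: with only four dimensions, an r ≥ 0.8 cutoff admits
roughly 10% spurious adjacency for unrelated profiles, so correlation alone
cannot provide specificity. Defaults r_min = 0.8 (network edges) and
r_core = 0.9 (core regulon) encode "tightly co-expressed" with an adjustable
stringency axis; an option to correlate on per-replicate normalized log
expression (15 dimensions) exists and is off by default to mirror the
fold-change framing. Constant profiles have undefined correlation and
contribute no edges.

Tiers are BFS depths from the hub (1 = primary, 2 = secondary,
3 = tertiary, deeper collapsed to tertiary); unreachable nodes are kept and
labeled `unlinked` — they are the fragmented remainder. Fragmentation is
summarized by connected-component count, largest-component fraction, hub
degree, and hub-coupled fraction (|component(hub)|/|nodes|); `intact` means
one component. GraphML export carries tier and class attributes and an edge
`length` of 1 − r for layout tools.

Planted-regulon recovery is scored as the hub plus all hub-coupled
(tier ≤ 3) members of the assembled network versus planted membership —
connectivity to the hub, not direct adjacency, because at four profile
dimensions direct-neighbor recall is dominated by estimation noise rather
than the planted structure.

## Ortholog pairing

Best hit per query = maximal alignment length, ties by higher identity then
smallest target id. Many-to-one resolution keeps, per contested target, the
claimant with maximal stability = identity × query coverage (ties: longer
alignment, then smallest query id). "Stability" is operationalized this way
because it is monotone in both axes a curator would consult; the composed
map is injective in both directions. Reciprocal-best filtering is *not*
applied (kept as an extension point). The bundled k-mer-seeded ungapped
aligner exists only as plumbing for synthetic sequences and is not a
substitute for a genome-scale aligner on real data.

## Phenotype metrics

ELI = mean stress leakage / mean control leakage; the injury flag requires
ELI > 1 and a one-sided Welch t-test (stress > control) at p < 0.05. The
t-test is the package's choice of significance procedure for this ratio.
SES = round(10 × recovery fraction), half-up; it is treated as a derived
score from a measured recovery fraction. Measured over 1,000 equal-mean
simulations, the flag's false-positive rate is ≈5% (asserted ≤7%).

## Synthetic data: what it emulates and what it does not

The generator mirrors the experimental design the pipeline expects: two
genotypes, timepoints
0/24/48/72/168 h, three replicates, NB counts around latent per-gene mean
profiles, log-uniform size factors in [0.7, 1.4] to exercise normalization,
dispersion 0.1, planted effect size log₂FC = 3 at each DE gene's peak
timepoint (exact in the latent means), a 50% planted DE overlap between
genotypes, a 40-gene regulon whose members share one latent ramp profile
(pairwise correlation ≥ 0.95, enforced by shrinking the jitter until the
emitted profiles satisfy it) in genotype A and split into 3 blocks with
near-orthogonal peak profiles (pairwise correlation ≤ 0.2 by construction)
in genotype B, promoters of 5 kb representing [−3000, +2000) with 9 motif
copies per regulon gene (3 of them in [−600, −400) so positional enrichment
is detectable), and 5% planted many-to-one paralog pairs. The 168 h fifth
timepoint is the default, with a config override, because sampling schedules
vary; timepoint counts other than five are supported by interpolating the
shape templates. Regulon genes draw baselines from [100, 1000] (vs [30, 300]
for background genes), reflecting that tightly co-expressed regulatory
targets are modeled as clearly measurable.

Two deliberate exactness devices: promoter backgrounds are scrubbed of
accidental occurrences of configured motifs (so planted densities are exact
and density tests are deterministic rather than statistical), and
`generate_dataset` with dispersion 0 emits rounded latent means as a
zero-noise debugging mode, while `simulate_counts` with α = 0 draws Poisson
(its documented limit).

The generator does **not** emulate read-level artifacts (mapping bias,
multi-mapping, isoforms), gene-length effects, correlated replicates, batch
effects, GC content, or realistic promoter base composition (backgrounds are
i.i.d. uniform). Passing the validation suite therefore demonstrates that
the estimators and rules recover what they claim under the stated NB model
and planted geometry — not that they are robust to every artifact of real
RNA-seq. Known limitation: with several motifs planted simultaneously, a
motif occurrence created entirely inside another motif's planted span is
protected from scrubbing, so multi-motif densities can exceed their nominal
counts by rare coincidences; single-motif densities are exact.

## Validation problem sizes

The standard conditions used by the test suite and `scripts/acceptance.py`:
2,000 genes for null calibration; 1,000 simulations for the ELI flag;
8 × 50 genes for cluster recovery; 2,000 genes (50% DE) for concordance
recovery; 40 regulon + 400 background genes for regulon recovery; 100 seeded
runs of a 200-gene end-to-end design for the intact-vs-fragmented contrast.
These sizes were chosen to make Monte-Carlo error small relative to each
acceptance band.
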