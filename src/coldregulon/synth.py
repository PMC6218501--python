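"""Paired two-genotype synthetic cold-stress datasets with planted truth.

The generator emulates the study design the pipeline targets: two genotypes
(A, the focal wild species; B, the reference cultivar), five timepoints
(0/24/48/72/168 h of cold), three replicates of negative-binomial counts,
planted differentially expressed genes, and one hub-coupled regulon that is
intact in genotype A but fragmented into weakly correlated blocks in
genotype B.  Promoter sequences carry hub-binding motifs planted at exact,
controlled densities (accidental background occurrences of configured motifs
are scrubbed, so density tests are exact rather than statistical), and the
ortholog table contains planted many-to-one paralog cases.  Every output is
a pure function of (config, seed).

Latent temporal structure is expressed as log2 fold-change shapes relative
to 0 h, scaled so each planted gene's largest |log2FC| equals the configured
effect size exactly; genotype-B regulon blocks use mutually near-orthogonal
peak shapes (pairwise correlation ≤ 0.2) so fragmentation is detectable by
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cis import PromoterRegion
from .expression import CountMatrix
from .orthologs import OrthologPair
from .seqs import IUPAC, instantiate_iupac, revcomp

logger = logging.getLogger(__name__)

__all__ = ["SynthConfig", "SynthTruth", "generate_dataset", "simulate_counts", "plant_motifs"]

DEFAULT_TIMEPOINTS = (0, 24, 48, 72, 168)

# Canonical temporal shapes (log2FC over the four stress timepoints, scaled
# to max |1|).  Shape 1 is flat (non-responsive); 2 is the shared regulon
# ramp; 2-5 are up, 6-8 down.
CLUSTER_SHAPES: dict[int, tuple[float, ...]] = {
    1: (0.0, 0.0, 0.0, 0.0),
    2: (0.15, 0.5, 0.85, 1.0),
    3: (1.0, 0.8, 0.5, 0.2),
    4: (0.0, 0.1, 0.5, 1.0),
    5: (0.3, 1.0, 0.6, 0.2),
    6: (-0.15, -0.5, -0.85, -1.0),
    7: (-1.0, -0.8, -0.5, -0.2),
    8: (-0.3, -1.0, -0.6, -0.2),
}
DE_SHAPES = tuple(s for s in CLUSTER_SHAPES if s != 1)
REGULON_SHAPE = 2

# Peak shapes for fragmented genotype-B regulon blocks: one-hot vectors and
# their negatives have pairwise correlation -1/3 or -1, both ≤ 0.2.
_FRAGMENT_SHAPES = [tuple(1.0 if j == i else 0.0 for j in range(4)) for i in range(4)]
_FRAGMENT_SHAPES += [tuple(-v for v in s) for s in _FRAGMENT_SHAPES]

_BASE_TO_INT = {b: i for i, b in enumerate("ACGT")}
_INT_TO_BASE = np.array(list("ACGT"))


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults mirror the emulated study design."""

    n_genes: int = 500
    n_tf: int = 100
    timepoints_hr: tuple[int, ...] = DEFAULT_TIMEPOINTS
    n_replicates: int = 3
    dispersion: float = 0.1
    lib_size_range: tuple[float, float] = (0.7, 1.4)
    de_fraction: float = 0.3
    de_log2fc: float = 3.0
    de_overlap: float = 0.5
    regulon_size: int = 40
    regulon_corr: float = 0.95
    fragment_into: int = 3
    promoter_len: int = 5000
    promoter_start: int = -3000
    motif_densities: Mapping[str, int] = field(default_factory=lambda: {"CGTGYG": 9})
    focus_window: tuple[int, int] = (-600, -400)
    focus_copies: int = 3
    plant_window: tuple[int, int] = (-1200, 500)
    baseline_range: tuple[float, float] = (30.0, 300.0)
    regulon_baseline_range: tuple[float, float] = (100.0, 1000.0)
    many_to_one_fraction: float = 0.05
    jitter_sd: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if 0 not in self.timepoints_hr:
            raise ValueError("timepoints must include 0 h")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.regulon_size > self.de_fraction * self.n_genes:
            raise ValueError(
                "regulon_size exceeds the number of planted DE genes "
                f"({self.regulon_size} > {self.de_fraction * self.n_genes:.0f})"
            )
        if not 0.0 < self.regulon_corr <= 1.0:
            raise ValueError("regulon_corr must be in (0, 1]")
        if not 1 <= self.fragment_into <= len(_FRAGMENT_SHAPES):
            raise ValueError(f"fragment_into must be in 1..{len(_FRAGMENT_SHAPES)}")
        if self.promoter_len <= 0:
            raise ValueError("promoter_len must be positive")
        lo, hi = self.promoter_start, self.promoter_start + self.promoter_len
        for name, (wlo, whi) in (("plant", self.plant_window), ("focus", self.focus_window)):
            if wlo < lo or whi > hi:
                raise ValueError(f"{name}_window ({wlo}, {whi}) outside promoter window ({lo}, {hi})")


@dataclass
class SynthTruth:
    """Planted ground truth for recovery tests."""

    de_genes_by_genotype: dict[str, set[str]]
    up_genes_by_genotype: dict[str, set[str]]
    cluster_labels: dict[str, int]
    regulon_members: set[str]
    hub_id: str
    fragmented_blocks: list[set[str]]
    planted_motif_positions: dict[tuple[str, str], list[int]]
    ortholog_of: dict[str, str]  # locus_a -> locus_b
    tf_genes: set[str]
    latent_log2fc: dict[str, pd.DataFrame]  # genotype -> genes × stress timepoints

    def validate(self) -> None:
        assert self.hub_id in self.regulon_members
        blocks = [g for b in self.fragmented_blocks for g in b]
        assert sorted(blocks) == sorted(self.regulon_members)


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------


def simulate_counts(
    mean_profile: Sequence[float],
    dispersion: float,
    size_factors: Sequence[float],
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """NB counts around a per-timepoint mean profile.

    ``size_factors`` has one entry per sample; when it is longer than the
    mean profile, each timepoint mean is tiled across
    ``len(size_factors)/len(mean_profile)`` consecutive replicates.  Sample j
    at timepoint t draws NB with mean ``s_j·μ_t`` and variance
    ``s_j·μ_t(1+α·s_j·μ_t)``; α=0 degenerates to Poisson.
    """
    mu = np.asarray(mean_profile, dtype=float)
    s = np.asarray(size_factors, dtype=float)
    if not np.all(np.isfinite(mu)) or (mu < 0).any():
        raise ValueError("means must be finite and non-negative")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if len(s) % len(mu) != 0:
        raise ValueError("len(size_factors) must be a multiple of len(mean_profile)")
    reps = len(s) // len(mu)
    m = np.repeat(mu, reps) * s
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if dispersion == 0:
        return rng.poisson(m).astype(np.int64)
    r = 1.0 / dispersion
    p = r / (r + np.maximum(m, 1e-300))
    out = np.where(m > 0, rng.negative_binomial(r, np.clip(p, 1e-12, 1.0)), 0)
    return out.astype(np.int64)


# ---------------------------------------------------------------------------
# Motif planting and background scrubbing (integer-coded sequences)
# ---------------------------------------------------------------------------


def _allowed_table(motif: str) -> np.ndarray:
    """motif_len × 4 boolean table: table[j, base] == base allowed at j."""
    table = np.zeros((len(motif), 4), dtype=bool)
    for j, letter in enumerate(motif.upper()):
        for b in IUPAC[letter]:
            table[j, _BASE_TO_INT[b]] = True
    return table


def _match_positions(codes: np.ndarray, motif: str) -> np.ndarray:
    """Start offsets of all IUPAC matches of ``motif`` in an int-coded sequence."""
    m = len(motif)
    if len(codes) < m:
        return np.empty(0, dtype=int)
    table = _allowed_table(motif)
    ok = np.ones(len(codes) - m + 1, dtype=bool)
    for j in range(m):
        ok &= table[j][codes[j : len(codes) - m + 1 + j]]
    return np.flatnonzero(ok)


def _scrub(
    codes: np.ndarray,
    motifs: Sequence[str],
    protected: np.ndarray,
    rng: np.random.Generator,
    max_rounds: int = 500,
) -> None:
    """Re-randomize bases creating accidental motif matches on either strand,
    never touching protected (planted) spans.  In place."""
    patterns = []
    for motif in motifs:
        patterns.append(motif.upper())
        rc = revcomp(motif.upper())
        if rc != motif.upper():
            patterns.append(rc)
    for _ in range(max_rounds):
        dirty_bases: list[int] = []
        for pat in patterns:
            for i in _match_positions(codes, pat):
                span = np.arange(i, i + len(pat))
                mutable = span[~protected[span]]
                if len(mutable):  # fully protected spans are planted copies
                    dirty_bases.extend(mutable.tolist())
        if not dirty_bases:
            return
        idx = np.unique(np.array(dirty_bases, dtype=int))
        codes[idx] = rng.integers(0, 4, size=len(idx))
    raise RuntimeError("motif scrubbing did not converge")


def plant_motifs(
    sequence: str,
    motif: str,
    n_copies: int,
    window: tuple[int, int],
    seed: int | np.random.Generator = 0,
    promoter_start: int = -3000,
    scrub_background: bool = False,
) -> tuple[str, list[int]]:
    """Plant non-overlapping motif copies inside a TSS-relative window.

    Degenerate IUPAC positions are instantiated uniformly at random.  With
    ``scrub_background`` any accidental (non-planted) occurrence of the motif
    created or present elsewhere is re-randomized away, making the planted
    copy count exact.  Returns the modified sequence and the planted
    TSS-relative positions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_copies == 0:
        return sequence, []
    m = len(motif)
    lo, hi = window[0] - promoter_start, window[1] - promoter_start
    if lo < 0 or hi > len(sequence):
        raise ValueError(f"window {window} does not fit inside the sequence")
    if n_copies * m > hi - lo:
        raise ValueError(f"window too small for {n_copies} copies of {motif!r}")
    positions = _nonoverlapping_positions(lo, hi, m, n_copies, rng)
    codes = np.array([_BASE_TO_INT.get(b, 0) for b in sequence.upper()], dtype=np.int8)
    protected = np.zeros(len(codes), dtype=bool)
    for pos in positions:
        inst = instantiate_iupac(motif, rng)
        codes[pos : pos + m] = [_BASE_TO_INT[b] for b in inst]
        protected[pos : pos + m] = True
    if scrub_background:
        _scrub(codes, [motif], protected, rng)
    return "".join(_INT_TO_BASE[codes]), [p + promoter_start for p in positions]


def _nonoverlapping_positions(
    lo: int, hi: int, m: int, n: int, rng: np.random.Generator
) -> list[int]:
    """n sorted non-overlapping start positions for an m-mer in [lo, hi-m]."""
    slack = (hi - lo) - n * m
    gaps = np.sort(rng.integers(0, slack + 1, size=n)) if slack > 0 else np.zeros(n, int)
    return [int(lo + g + i * m) for i, g in enumerate(gaps)]


# ---------------------------------------------------------------------------
# Full dataset generation
# ---------------------------------------------------------------------------


def generate_dataset(
    config: SynthConfig,
    with_promoters: bool = True,
) -> tuple[CountMatrix, CountMatrix, list[OrthologPair], list[PromoterRegion], SynthTruth]:
    """Generate the full paired synthetic dataset with planted ground truth.

    Returns count matrices for genotypes A and B, an ortholog pair list (with
    planted many-to-one paralog cases whose true partner has the higher
    stability), genotype-A promoter regions carrying the planted motifs, and
    the :class:`SynthTruth` record.  With ``dispersion=0`` the counts are the
    rounded latent means (documented zero-noise debugging mode); otherwise
    counts are NB draws.  ``with_promoters=False`` skips sequence synthesis
    for count-only experiments.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes_a = [f"GA{i:05d}" for i in range(n)]
    genes_b = [f"GB{i:05d}" for i in range(n)]
    idx_of = {g: i for i, g in enumerate(genes_a)}
    stress = [t for t in config.timepoints_hr if t != 0]
    n_stress = len(stress)

    # --- planted DE structure -------------------------------------------
    n_de = int(round(config.de_fraction * n))
    de_a = list(rng.choice(genes_a, size=n_de, replace=False))
    de_a_set = set(de_a)
    regulon = sorted(rng.choice(de_a, size=config.regulon_size, replace=False))
    regulon_set = set(regulon)
    hub = regulon[0]
    n_shared = min(max(int(round(config.de_overlap * n_de)), config.regulon_size), n_de)
    non_regulon_de = [g for g in de_a if g not in regulon_set]
    shared = regulon_set | set(
        rng.choice(non_regulon_de, size=n_shared - config.regulon_size, replace=False)
    )
    pool_b_only = [g for g in genes_a if g not in de_a_set]
    b_only = set(rng.choice(pool_b_only, size=min(n_de - n_shared, len(pool_b_only)), replace=False))
    de_b_in_a_ids = shared | b_only

    shapes_a: dict[str, int] = {}
    for g in genes_a:
        if g in regulon_set:
            shapes_a[g] = REGULON_SHAPE
        elif g in de_a_set:
            shapes_a[g] = int(rng.choice(DE_SHAPES))
        else:
            shapes_a[g] = 1
    shapes_b: dict[str, int] = {}
    for g in genes_a:  # keyed by the A locus; B uses the ortholog id
        if g in de_b_in_a_ids:
            shapes_b[g] = shapes_a[g] if shapes_a[g] != 1 else int(rng.choice(DE_SHAPES))
        else:
            shapes_b[g] = 1

    # Fragmented genotype-B regulon blocks (hub in block 0).
    block_sizes = np.full(config.fragment_into, len(regulon) // config.fragment_into)
    block_sizes[: len(regulon) % config.fragment_into] += 1
    members = [hub] + [g for g in regulon if g != hub]
    blocks: list[set[str]] = []
    start = 0
    for size in block_sizes:
        blocks.append(set(members[start : start + size]))
        start += size
    block_of = {g: bi for bi, block in enumerate(blocks) for g in block}

    # --- latent log2FC profiles -----------------------------------------
    shape_curve = {
        sid: _resample_shape(np.array(vec), n_stress) for sid, vec in CLUSTER_SHAPES.items()
    }
    frag_curve = [_resample_shape(np.array(vec), n_stress) for vec in _FRAGMENT_SHAPES]

    # Regulon jitter: draw once, then shrink until the emitted genotype-A
    # regulon profiles meet the target minimum pairwise correlation exactly.
    reg_jit = np.random.default_rng(rng.integers(2**31)).normal(
        0.0, 1.0, size=(len(regulon), n_stress)
    )
    base = shape_curve[REGULON_SHAPE] * config.de_log2fc
    peak = int(np.abs(base).argmax())
    reg_jit[:, peak] = 0.0
    sigma = config.jitter_sd
    for _ in range(60):
        profs = base[None, :] + sigma * reg_jit
        r = np.corrcoef(profs)
        if len(regulon) < 2 or r[np.triu_indices(len(regulon), 1)].min() >= config.regulon_corr:
            break
        sigma *= 0.5
    regulon_profiles = {g: profs[i] for i, g in enumerate(regulon)}

    gen_a = np.random.default_rng(rng.integers(2**31))
    gen_b = np.random.default_rng(rng.integers(2**31))

    def jittered(shape: np.ndarray, scale: float, gen: np.random.Generator) -> np.ndarray:
        prof = shape * config.de_log2fc
        if np.allclose(shape, 0.0):
            return prof
        jit = gen.normal(0.0, scale, size=n_stress)
        jit[int(np.abs(prof).argmax())] = 0.0  # planted peak |log2FC| stays exact
        return prof + jit

    latent: dict[str, dict[str, np.ndarray]] = {"A": {}, "B": {}}
    for g in genes_a:
        if g in regulon_set:
            latent["A"][g] = regulon_profiles[g]
            latent["B"][g] = jittered(frag_curve[block_of[g]], sigma, gen_b)
        else:
            latent["A"][g] = jittered(shape_curve[shapes_a[g]], config.jitter_sd, gen_a)
            latent["B"][g] = jittered(shape_curve[shapes_b[g]], config.jitter_sd, gen_b)

    # --- counts ----------------------------------------------------------
    mu0 = {}
    for g in genes_a:
        lo, hi = config.regulon_baseline_range if g in regulon_set else config.baseline_range
        mu0[g] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    matrices = {}
    for genotype, ids in (("A", genes_a), ("B", genes_b)):
        n_samples = len(config.timepoints_hr) * config.n_replicates
        lo, hi = config.lib_size_range
        sf = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))
        names, meta = [], []
        for t in config.timepoints_hr:
            for rep in range(1, config.n_replicates + 1):
                names.append(f"{genotype}_{t}h_r{rep}")
                meta.append((genotype, t, rep))
        count_rng = np.random.default_rng(rng.integers(2**31))
        rows = []
        for ga in genes_a:
            means = mu0[ga] * np.power(2.0, np.concatenate([[0.0], latent[genotype][ga]]))
            if config.dispersion == 0:
                rows.append(np.round(np.repeat(means, config.n_replicates) * sf).astype(np.int64))
            else:
                rows.append(simulate_counts(means, config.dispersion, sf, count_rng))
        counts = pd.DataFrame(np.vstack(rows), index=ids, columns=names)
        samples = pd.DataFrame(meta, index=names, columns=["genotype", "timepoint_hr", "replicate"])
        matrices[genotype] = CountMatrix(counts, samples)

    # --- ortholog pairs with planted many-to-one paralogy ----------------
    pairs = []
    n_paralog = int(round(config.many_to_one_fraction * n))
    paralog_targets = list(rng.choice(genes_a, size=n_paralog, replace=False))
    for ga, gb in zip(genes_a, genes_b):
        length = int(rng.integers(600, 2400))
        pairs.append(
            OrthologPair(ga, gb, length, float(rng.uniform(0.95, 1.0) * rng.uniform(0.9, 1.0)))
        )
    for j, ga in enumerate(paralog_targets):
        gb = genes_b[idx_of[ga]]
        length = int(rng.integers(400, 1500))
        pairs.append(
            OrthologPair(
                f"GA_par{j:04d}",
                gb,
                length,
                float(rng.uniform(0.75, 0.92) * rng.uniform(0.6, 0.9)),
            )
        )

    # --- promoters (genotype A, the focal species) -----------------------
    if with_promoters:
        motif_rng = np.random.default_rng(rng.integers(2**31))
        promoters, planted = _build_promoters(config, genes_a, regulon_set, motif_rng)
    else:
        promoters, planted = [], {}

    def _is_up(g: str, genotype: str) -> bool:
        if genotype == "B" and g in block_of:
            return max(frag_curve[block_of[g]]) > 0
        sid = shapes_a[g] if genotype == "A" else shapes_b[g]
        return max(CLUSTER_SHAPES[sid]) > 0

    truth = SynthTruth(
        de_genes_by_genotype={
            "A": de_a_set,
            "B": {genes_b[idx_of[g]] for g in de_b_in_a_ids},
        },
        up_genes_by_genotype={
            "A": {g for g in de_a if _is_up(g, "A")},
            "B": {genes_b[idx_of[g]] for g in de_b_in_a_ids if _is_up(g, "B")},
        },
        cluster_labels={g: shapes_a[g] for g in genes_a},
        regulon_members=regulon_set,
        hub_id=hub,
        fragmented_blocks=blocks,
        planted_motif_positions=planted,
        ortholog_of=dict(zip(genes_a, genes_b)),
        tf_genes=set(genes_a[: config.n_tf]),
        latent_log2fc={
            gt: pd.DataFrame({g: latent[gt][g] for g in genes_a}, index=stress).T
            for gt in ("A", "B")
        },
    )
    truth.validate()
    return matrices["A"], matrices["B"], pairs, promoters, truth


def _resample_shape(vec: np.ndarray, n_stress: int) -> np.ndarray:
    if len(vec) == n_stress:
        return vec.astype(float)
    x_old = np.linspace(0.0, 1.0, len(vec))
    x_new = np.linspace(0.0, 1.0, n_stress)
    return np.interp(x_new, x_old, vec)


def _build_promoters(
    config: SynthConfig,
    genes: Sequence[str],
    regulon: set[str],
    rng: np.random.Generator,
) -> tuple[list[PromoterRegion], dict[tuple[str, str], list[int]]]:
    start = config.promoter_start
    window = (start, start + config.promoter_len)
    motifs = list(config.motif_densities)
    promoters: list[PromoterRegion] = []
    planted: dict[tuple[str, str], list[int]] = {}
    for g in genes:
        codes = rng.integers(0, 4, size=config.promoter_len).astype(np.int8)
        protected = np.zeros(config.promoter_len, dtype=bool)
        if g in regulon:
            occupied: list[tuple[int, int]] = []
            for motif, copies in config.motif_densities.items():
                m = len(motif)
                n_focus = min(config.focus_copies, copies)
                pos = _nonoverlapping_positions(
                    config.focus_window[0] - start, config.focus_window[1] - start, m, n_focus, rng
                )
                guard = 0
                while len(pos) < copies:
                    cand = int(
                        rng.integers(
                            config.plant_window[0] - start,
                            config.plant_window[1] - start - m + 1,
                        )
                    )
                    if all(cand + m <= a or cand >= b for a, b in occupied) and all(
                        abs(cand - q) >= m for q in pos
                    ):
                        pos.append(cand)
                    guard += 1
                    if guard > 100000:
                        raise RuntimeError("could not place motif copies without overlap")
                for p in sorted(pos):
                    inst = instantiate_iupac(motif, rng)
                    codes[p : p + m] = [_BASE_TO_INT[b] for b in inst]
                    protected[p : p + m] = True
                    occupied.append((p, p + m))
                planted[(g, motif)] = sorted(p + start for p in pos)
        _scrub(codes, motifs, protected, rng)
        promoters.append(
            PromoterRegion(
                gene_id=g,
                strand="+",
                tss_genomic=-start,
                window=window,
                sequence="".join(_INT_TO_BASE[codes]),
            )
        )
    return promoters, planted
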