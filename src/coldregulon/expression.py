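"""Count normalization, NB differential expression, and profile clustering.

The count model throughout is the negative binomial with mean μ and
dispersion α (variance μ(1+αμ); α=0 is the Poisson limit).  Stages:

* median-of-ratios size factors (geometric-mean reference over genes with
  all-positive counts), the standard bulk RNA-seq normalization;
* per-gene method-of-moments dispersion, averaged across conditions and
  shrunk 50/50 toward the genome-wide median to stabilize 3-replicate
  estimates;
* a per-timepoint likelihood-ratio test of stress vs 0 h (shared-mean vs
  separate-means NB with plug-in α, χ² with 1 df) and the up/down/unchanged
  response rule |log2FC| > 2 with p < 0.01 at any stress timepoint;
* cross-genotype concordance of response classes over ortholog pairs;
* NB model-based K-means over temporal profiles: each gene joins the cluster
  whose mean *shape* (scaled to the gene's own abundance) maximizes its NB
  log-likelihood, with k-means++-style seeding on standardized log profiles.

Fold changes use a 0.5 pseudocount so low-count genes stay bounded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy
from scipy.stats import chi2

from .orthologs import OrthologPair

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "ConcordanceTable",
    "ClusterAssignment",
    "normalize",
    "estimate_dispersion",
    "de_test",
    "de_table",
    "classify_response",
    "ortholog_concordance",
    "nb_kmeans",
    "family_saturation",
]

RESPONSE_CLASSES = ("up", "down", "unchanged")
_ALPHA_FLOOR = 1e-8


@dataclass
class CountMatrix:
    """Gene × sample integer counts with genotype/timepoint/replicate metadata.

    ``counts`` is indexed by gene id with one column per sample; ``samples``
    is indexed by sample name with columns genotype, timepoint_hr, replicate.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("counts columns and sample metadata rows must align")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        for gt, grp in self.samples.groupby("genotype"):
            if (grp["timepoint_hr"] == 0).sum() < 1:
                raise ValueError(f"genotype {gt} has no 0 h sample")

    @property
    def timepoints(self) -> list[int]:
        return sorted(self.samples["timepoint_hr"].unique())

    def subset_genotype(self, genotype: str) -> "CountMatrix":
        keep = self.samples.index[self.samples["genotype"] == genotype]
        return CountMatrix(self.counts[keep], self.samples.loc[keep])


# ---------------------------------------------------------------------------
# Normalization and dispersion
# ---------------------------------------------------------------------------


def normalize(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios size factors and the normalized matrix.

    The reference is the per-gene geometric mean across samples over genes
    with all-positive counts; each sample's size factor is the median ratio
    to that reference, rescaled so the factors have unit geometric mean
    (which makes normalization exactly idempotent).  If no gene is
    all-positive, falls back to total-count scaling (factors proportional to
    library size, geometric mean 1) with a logged warning.
    """
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("every sample must have positive total counts")
    vals = counts.to_numpy(dtype=float)
    allpos = (vals > 0).all(axis=1)
    if allpos.any():
        ref = np.exp(np.log(vals[allpos]).mean(axis=1))
        factors = np.median(vals[allpos] / ref[:, None], axis=0)
        factors = factors / np.exp(np.mean(np.log(factors)))
    else:
        logger.warning(
            "no gene has all-positive counts; falling back to total-count size factors"
        )
        t = totals.to_numpy(dtype=float)
        factors = t / np.exp(np.mean(np.log(t)))
    size_factors = pd.Series(factors, index=counts.columns, name="size_factor")
    return counts / size_factors, size_factors


def estimate_dispersion(
    norm: pd.DataFrame,
    samples: pd.DataFrame,
    shrink: float = 0.5,
) -> pd.Series:
    """Per-gene NB dispersion α by method of moments, shrunk to the median.

    Within each (genotype, timepoint) condition with ≥2 replicates the raw
    estimate is ``max(0, (s² − m) / m²)``; raw values are averaged across
    conditions with positive mean, then blended ``shrink`` toward the
    genome-wide median.  With single replicates everywhere, timepoints within
    a genotype are pooled as pseudo-replicates (logged fallback).
    """
    conditions = [
        grp.index
        for _, grp in samples.groupby(["genotype", "timepoint_hr"])
        if len(grp) >= 2
    ]
    if not conditions:
        logger.warning(
            "single replicate everywhere; pooling timepoints within genotype "
            "for a crude global dispersion"
        )
        conditions = [grp.index for _, grp in samples.groupby("genotype") if len(grp) >= 2]
        if not conditions:
            raise ValueError("cannot estimate dispersion from a single sample")

    raw_sum = np.zeros(len(norm))
    raw_n = np.zeros(len(norm))
    for cols in conditions:
        x = norm[cols].to_numpy(dtype=float)
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        ok = m > 0
        raw = np.zeros(len(norm))
        raw[ok] = np.maximum(0.0, (v[ok] - m[ok]) / m[ok] ** 2)
        raw_sum[ok] += raw[ok]
        raw_n[ok] += ok[ok]
    raw_mean = np.divide(raw_sum, raw_n, out=np.zeros_like(raw_sum), where=raw_n > 0)
    observed = raw_n > 0
    med = float(np.median(raw_mean[observed])) if observed.any() else 0.0
    alpha = np.where(observed, (1 - shrink) * raw_mean + shrink * med, med)
    return pd.Series(alpha, index=norm.index, name="alpha")


# ---------------------------------------------------------------------------
# NB likelihood-ratio differential-expression test
# ---------------------------------------------------------------------------


def _nb_loglik(x: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB log-likelihood, continuous in x (gamma-function extension).

    Shapes broadcast; ``alpha`` is floored at 1e-8 so the Poisson limit is
    reached numerically without a separate branch.
    """
    a = np.maximum(alpha, _ALPHA_FLOOR)
    r = 1.0 / a
    mu = np.maximum(mu, 1e-10)
    return (
        gammaln(x + r)
        - gammaln(r)
        - gammaln(x + 1.0)
        + r * np.log(r / (r + mu))
        + xlogy(x, mu / (r + mu))
    )


def de_test(
    norm: pd.DataFrame,
    samples: pd.DataFrame,
    genotype: str,
    timepoint: int,
    alpha: pd.Series,
    pseudocount: float = 0.5,
    baseline: int = 0,
) -> pd.DataFrame:
    """Stress-vs-0 h test for one genotype and one stress timepoint.

    Returns a frame with ``log2fc`` = log2((mean_t + c)/(mean_0 + c)) and
    ``p`` from the NB likelihood ratio (χ², 1 df) of separate group means vs
    a shared mean, with plug-in per-gene α.  Genes with all-zero counts in
    both groups get (0, 1).
    """
    meta = samples[samples["genotype"] == genotype]
    cols0 = meta.index[meta["timepoint_hr"] == baseline]
    cols1 = meta.index[meta["timepoint_hr"] == timepoint]
    if len(cols0) == 0 or len(cols1) == 0:
        raise ValueError(f"genotype {genotype}: missing samples at {baseline} h or {timepoint} h")

    x0 = norm[cols0].to_numpy(dtype=float)
    x1 = norm[cols1].to_numpy(dtype=float)
    m0, m1 = x0.mean(axis=1), x1.mean(axis=1)
    log2fc = np.log2((m1 + pseudocount) / (m0 + pseudocount))

    a = alpha.reindex(norm.index).to_numpy(dtype=float)[:, None]
    pooled = np.concatenate([x0, x1], axis=1)
    mu_shared = pooled.mean(axis=1)[:, None]
    ll0 = _nb_loglik(pooled, mu_shared, a).sum(axis=1)
    ll1 = _nb_loglik(x0, m0[:, None], a).sum(axis=1) + _nb_loglik(x1, m1[:, None], a).sum(axis=1)
    stat = np.maximum(0.0, 2.0 * (ll1 - ll0))
    p = chi2.sf(stat, df=1)

    allzero = (pooled.sum(axis=1) == 0)
    log2fc[allzero] = 0.0
    p[allzero] = 1.0
    return pd.DataFrame({"log2fc": log2fc, "p": p}, index=norm.index)


def classify_response(
    log2fc: Sequence[float],
    p: Sequence[float],
    lfc_threshold: float = 2.0,
    p_threshold: float = 0.01,
) -> str:
    """Response class from per-timepoint fold changes and p-values.

    up if any timepoint has log2fc > threshold at p < p_threshold; down
    analogously.  A gene qualifying in both directions at different
    timepoints takes the class of its largest-|log2fc| significant event.
    """
    events = [
        (abs(l), l)
        for l, pv in zip(log2fc, p)
        if pv < p_threshold and abs(l) > lfc_threshold
    ]
    if not events:
        return "unchanged"
    _, best = max(events, key=lambda e: e[0])
    return "up" if best > 0 else "down"


def de_table(
    norm: pd.DataFrame,
    samples: pd.DataFrame,
    genotype: str,
    alpha: pd.Series,
    lfc_threshold: float = 2.0,
    p_threshold: float = 0.01,
    pseudocount: float = 0.5,
    fdr: bool = False,
) -> pd.DataFrame:
    """Full per-gene DE table for one genotype: log2fc_i, p_i, response_class.

    Stress timepoints are the sorted non-zero timepoints, numbered 1..T in
    the column names (the s1..s4 / o1..o4 fold-change notation).  With
    ``fdr`` the p-values are Benjamini-Hochberg adjusted across genes within
    each timepoint before thresholding; the default is raw p-values.
    """
    meta = samples[samples["genotype"] == genotype]
    stress = sorted(t for t in meta["timepoint_hr"].unique() if t != 0)
    out = pd.DataFrame(index=norm.index)
    for i, t in enumerate(stress, start=1):
        res = de_test(norm, samples, genotype, t, alpha, pseudocount=pseudocount)
        out[f"log2fc_{i}"] = res["log2fc"]
        out[f"p_{i}"] = _bh_adjust(res["p"].to_numpy()) if fdr else res["p"]
    lfc_cols = [f"log2fc_{i}" for i in range(1, len(stress) + 1)]
    p_cols = [f"p_{i}" for i in range(1, len(stress) + 1)]
    out["response_class"] = [
        classify_response(row[lfc_cols], row[p_cols], lfc_threshold, p_threshold)
        for _, row in out.iterrows()
    ]
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    n = len(p)
    order = np.argsort(p)
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# Cross-genotype concordance
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceTable:
    """3×3 response-class contingency over ortholog pairs plus the two
    directional concordance percentages the comparison hinges on."""

    table: pd.DataFrame
    n_pairs: int
    n_excluded: int
    pct_a_up_also_b: float
    pct_b_up_also_a: float


def ortholog_concordance(
    classes_a: Mapping[str, str],
    classes_b: Mapping[str, str],
    pairs: Sequence[OrthologPair],
) -> ConcordanceTable:
    """Cross-tabulate response classes of ortholog pairs.

    Directional percentages: of A-upregulated genes with a classified
    ortholog, the percent whose ortholog is B-upregulated, and vice versa.
    Pairs missing a class on either side are excluded and counted.
    """
    if not pairs:
        logger.warning("empty ortholog pair list; concordance table is empty")
    table = pd.DataFrame(0, index=list(RESPONSE_CLASSES), columns=list(RESPONSE_CLASSES))
    n_excluded = 0
    up_a = up_b = both_up = 0
    for pair in pairs:
        ca = classes_a.get(pair.locus_a)
        cb = classes_b.get(pair.locus_b)
        if ca not in RESPONSE_CLASSES or cb not in RESPONSE_CLASSES:
            n_excluded += 1
            continue
        table.loc[ca, cb] += 1
        up_a += ca == "up"
        up_b += cb == "up"
        both_up += (ca == "up") and (cb == "up")
    n_pairs = int(table.to_numpy().sum())
    pct_ab = 100.0 * both_up / up_a if up_a else float("nan")
    pct_ba = 100.0 * both_up / up_b if up_b else float("nan")
    return ConcordanceTable(table, n_pairs, n_excluded, pct_ab, pct_ba)


# ---------------------------------------------------------------------------
# NB model-based K-means on temporal profiles
# ---------------------------------------------------------------------------


@dataclass
class ClusterAssignment:
    labels: pd.Series  # gene -> 1..K
    cluster_profiles: pd.DataFrame  # K × timepoints, plain member averages
    log_likelihood: float
    n_iterations: int
    ll_trace: list[float] = field(default_factory=list)


def nb_kmeans(
    profiles: pd.DataFrame,
    k: int = 8,
    alpha: float | pd.Series = 0.1,
    seed: int = 0,
    max_iter: int = 100,
) -> ClusterAssignment:
    """NB model-based K-means over per-timepoint expression profiles.

    Each gene is assigned to the cluster whose mean temporal *shape* (unit-sum
    profile scaled to the gene's total abundance) maximizes the gene's NB
    log-likelihood; cluster shapes are then re-estimated from pooled member
    counts.  Initialization is k-means++-style on standardized log profiles.
    The total log-likelihood is non-decreasing across iterations (a shape
    update that would decrease it is rejected and iteration stops); identical
    seed gives identical labels.  Empty clusters are re-seeded from the
    worst-fit gene.
    """
    y = profiles.to_numpy(dtype=float)
    n_genes, n_t = y.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_genes:
        raise ValueError(f"k={k} exceeds the number of genes ({n_genes})")
    if n_t < 2:
        raise ValueError("profiles need at least 2 timepoints")
    a = (
        alpha.reindex(profiles.index).to_numpy(dtype=float)
        if isinstance(alpha, pd.Series)
        else np.full(n_genes, float(alpha))
    )[:, None, None]
    totals = y.sum(axis=1)

    assign = _kmeanspp_assign(y, k, seed) if k > 1 else np.zeros(n_genes, dtype=int)
    shapes = _shapes_from_assignment(y, assign, k)

    def ll_matrix(shp: np.ndarray) -> np.ndarray:
        mu = totals[:, None, None] * shp[None, :, :]  # G × K × T
        return _nb_loglik(y[:, None, :], mu, a).sum(axis=2)  # G × K

    trace: list[float] = []
    n_iter = 0
    prev_assign = assign
    for n_iter in range(1, max_iter + 1):
        ll_gk = ll_matrix(shapes)
        assign = ll_gk.argmax(axis=1)
        # Re-seed empty clusters from the worst-fit gene, then re-assign.
        reseeded = False
        for c in range(k):
            if not (assign == c).any():
                worst = int(ll_gk.max(axis=1).argmin())
                logger.info("cluster %d empty; re-seeded from gene index %d", c + 1, worst)
                shapes[c] = _unit_shape(y[worst])
                reseeded = True
        if reseeded:
            ll_gk = ll_matrix(shapes)
            assign = ll_gk.argmax(axis=1)
        trace.append(float(ll_gk[np.arange(n_genes), assign].sum()))
        # Per-cluster guarded shape update: pooled-count candidate accepted
        # only if the member log-likelihood does not decrease, so the total
        # likelihood is non-decreasing across iterations.
        improved = False
        for c in range(k):
            members = assign == c
            if not members.any():
                continue
            cand = _unit_shape(y[members].sum(axis=0))
            ym, am, nm = y[members], a[members, 0, :], totals[members, None]
            old = _nb_loglik(ym, nm * shapes[c][None, :], am).sum()
            new = _nb_loglik(ym, nm * cand[None, :], am).sum()
            if new >= old - 1e-9:
                if new > old + 1e-9:
                    improved = True
                shapes[c] = cand
        if (assign == prev_assign).all() and not improved and n_iter > 1:
            break
        prev_assign = assign

    labels = pd.Series(assign + 1, index=profiles.index, name="cluster")
    means = pd.DataFrame(
        [y[assign == c].mean(axis=0) if (assign == c).any() else np.zeros(n_t) for c in range(k)],
        index=pd.RangeIndex(1, k + 1, name="cluster"),
        columns=profiles.columns,
    )
    return ClusterAssignment(labels, means, trace[-1], n_iter, trace)


def _unit_shape(profile: np.ndarray) -> np.ndarray:
    s = np.maximum(profile, 0.0) + 1e-10
    return s / s.sum()


def _shapes_from_assignment(
    y: np.ndarray, assign: np.ndarray, k: int, fallback: np.ndarray | None = None
) -> np.ndarray:
    shapes = np.empty((k, y.shape[1]))
    for c in range(k):
        members = assign == c
        if members.any():
            shapes[c] = _unit_shape(y[members].sum(axis=0))
        elif fallback is not None:
            shapes[c] = fallback[c]
        else:
            shapes[c] = np.full(y.shape[1], 1.0 / y.shape[1])
    return shapes


def _kmeanspp_assign(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    from sklearn.cluster import kmeans_plusplus

    z = np.log1p(y)
    mu = z.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (z - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    centers, _ = kmeans_plusplus(z, n_clusters=k, random_state=seed)
    d = ((z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return d.argmin(axis=1)


# ---------------------------------------------------------------------------
# Transcription-factor family saturation
# ---------------------------------------------------------------------------


def family_saturation(
    norm: pd.DataFrame,
    samples: pd.DataFrame,
    families: Mapping[str, str],
    genotype: str | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Cumulative family expression per timepoint and max fold-induction.

    Per family, normalized expression is averaged over replicates at each
    timepoint and summed across member genes; the maximum fold-induction is
    ``max_t (cum_t + c)/(cum_0 + c)``, a saturation diagnostic for large
    transcription-factor families.  Families with no genes present in the
    matrix are omitted with a warning.
    """
    meta = samples if genotype is None else samples[samples["genotype"] == genotype]
    timepoints = sorted(meta["timepoint_hr"].unique())
    per_tp = pd.DataFrame(
        {
            t: norm[meta.index[meta["timepoint_hr"] == t]].mean(axis=1)
            for t in timepoints
        }
    )
    fam = pd.Series({g: f for g, f in families.items() if g in norm.index}, name="family")
    missing = set(families.values()) - set(fam.values)
    for name in sorted(missing):
        logger.warning("family %s has no genes in the matrix; omitted", name)
    if fam.empty:
        return pd.DataFrame(columns=[*timepoints, "max_fold_induction"])
    cum = per_tp.loc[fam.index].groupby(fam).sum()
    c = pseudocount
    ratios = (cum.add(c)).div(cum[0] + c, axis=0)
    out = cum.copy()
    out["max_fold_induction"] = ratios.max(axis=1)
    return out
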