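"""Promoter extraction, IUPAC motif scanning, and positional enrichment.

Coordinates are TSS-relative throughout: the transcription start site is 0,
upstream positions are negative, and windows are half-open ``[start, end)``.
The default extraction window is [−3000, +2000), matching the convention of
scanning both the proximal promoter and the 5' transcribed region.  Scanning
covers both strands of the gene-oriented sequence; positional enrichment flags
motifs over-represented among upregulated genes in the proximal windows
(around −500, or the core-promoter interval [−150, +50)), which is where
functionally relevant cis-elements concentrate.  Motif density in the
[−1200, +500) window is classified low (<8 copies), high (8–10), or very high
(≥11) — the rule used to select brassinosteroid-response-element (BRRE) dense
genes for network assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .seqs import iupac_regex, revcomp, validate_iupac

__all__ = [
    "PromoterRegion",
    "MotifDef",
    "MotifHit",
    "MotifScore",
    "DensityClass",
    "DEFAULT_MOTIFS",
    "DEFAULT_ENRICHMENT_WINDOWS",
    "DENSITY_WINDOW",
    "extract_promoters",
    "scan_motifs",
    "positional_enrichment",
    "motif_density",
    "density_table",
    "spatial_map",
]

EXTRACTION_WINDOW = (-3000, 2000)
DENSITY_WINDOW = (-1200, 500)
DEFAULT_ENRICHMENT_WINDOWS: dict[str, tuple[int, int]] = {
    "around-500": (-650, -350),
    "core": (-150, 50),
}


@dataclass
class PromoterRegion:
    """A TSS-anchored promoter sequence oriented 5'→3' on the gene strand."""

    gene_id: str
    strand: str
    tss_genomic: int
    window: tuple[int, int]
    sequence: str
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if len(self.sequence) != self.window[1] - self.window[0]:
            raise ValueError(
                f"{self.gene_id}: sequence length {len(self.sequence)} does not match "
                f"window {self.window}"
            )

    def index_of(self, tss_relative_pos: int) -> int:
        """Array index of a TSS-relative position within ``sequence``."""
        return tss_relative_pos - self.window[0]


@dataclass(frozen=True)
class MotifDef:
    """A named IUPAC motif with a cis-element class tag."""

    name: str
    iupac: str | None
    class_tag: str = ""

    def require_sequence(self) -> str:
        if not self.iupac:
            raise ValueError(
                f"motif {self.name!r} has no IUPAC sequence configured; "
                "supply one explicitly (it is intentionally never guessed)"
            )
        validate_iupac(self.iupac)
        return self.iupac.upper()


# Shipped defaults from standard promoter-element usage (PLACE-style
# consensus sequences).  GS2 and JRRE are intentionally unset: no published
# consensus is shipped, so they must be user-supplied or they error at use.
DEFAULT_MOTIFS: tuple[MotifDef, ...] = (
    MotifDef("BRRE", "CGTGYG", "BL"),
    MotifDef("E-box", "CANNTG", "BL"),
    MotifDef("ABRE-like", "ACGTGKC", "ABA"),
    MotifDef("DRE/CRT", "RCCGAC", "DREB"),
    MotifDef("as1/ocs", "TGACG", "ROS"),
    MotifDef("Myb2", "YAACKG", "ROS"),
    MotifDef("hex-3", "ACGTCA", "ABA"),
    MotifDef("GARE", "TAACARA", "GA"),
    MotifDef("GS2", None, "ZT"),
    MotifDef("JRRE", None, "JA"),
)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; ``position`` is the TSS-relative offset of the
    occurrence's 5'-most base measured on the gene strand."""

    gene_id: str
    motif: str
    position: int
    strand: str


@dataclass(frozen=True)
class MotifScore:
    motif: str
    window: str
    fg_hit_genes: int
    fg_genes: int
    bg_hit_genes: int
    bg_genes: int
    p_value: float
    score: float
    high_score: bool = False


@dataclass(frozen=True)
class DensityClass:
    gene_id: str
    motif: str
    window: tuple[int, int]
    count: int
    density_class: str


# ---------------------------------------------------------------------------
# Promoter extraction
# ---------------------------------------------------------------------------


def extract_promoters(
    genome_fasta: str,
    gff3_path: str,
    window: tuple[int, int] = EXTRACTION_WINDOW,
    feature_type: str = "gene",
    logger=None,
) -> list[PromoterRegion]:
    """Extract strand-aware TSS-relative promoter windows from a genome.

    GFF3 coordinates (1-based, inclusive) are converted to 0-based half-open.
    For a + strand gene with 0-based TSS ``t`` the genomic slice is
    ``[t+start, t+end)``; for a − strand gene the mirrored slice
    ``[t-end+1, t-start+1)`` is taken and reverse-complemented so that
    TSS-relative position −p maps to genomic ``t+p``.  Regions clipped at a
    contig edge are truncated and flagged; genes on missing contigs are
    skipped with a warning.
    """
    import gffutils
    from Bio import SeqIO

    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(genome_fasta, "fasta")}
    db = gffutils.create_db(
        gff3_path, ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    start, end = window
    out: list[PromoterRegion] = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if feat.seqid not in contigs:
            _warn(logger, f"gene {gene_id}: contig {feat.seqid} absent from genome; skipped")
            continue
        contig = contigs[feat.seqid]
        if feat.strand == "+":
            tss = feat.start - 1  # 0-based
            lo, hi = tss + start, tss + end
            clo, chi = max(0, lo), min(len(contig), hi)
            seq = contig[clo:chi]
            got = (clo - tss, chi - tss)
        elif feat.strand == "-":
            tss = feat.end - 1  # 0-based coordinate of the − strand TSS
            lo, hi = tss - end + 1, tss - start + 1
            clo, chi = max(0, lo), min(len(contig), hi)
            seq = revcomp(contig[clo:chi])
            got = (tss - chi + 1, tss - clo + 1)
        else:
            _warn(logger, f"gene {gene_id}: strandless feature; skipped")
            continue
        out.append(
            PromoterRegion(
                gene_id=gene_id,
                strand=feat.strand,
                tss_genomic=tss,
                window=got,
                sequence=seq,
                truncated=got != (start, end),
            )
        )
    return out


def _warn(logger, msg: str) -> None:
    if logger is not None:
        logger.warning(msg)
    else:
        import logging

        logging.getLogger(__name__).warning(msg)


# ---------------------------------------------------------------------------
# Motif scanning
# ---------------------------------------------------------------------------


def scan_motifs(
    promoters: Iterable[PromoterRegion],
    motifs: Sequence[MotifDef] = DEFAULT_MOTIFS,
    skip_unset: bool = False,
) -> list[MotifHit]:
    """All occurrences of each motif, both strands, overlapping hits included.

    A − strand hit spanning gene-strand offsets ``[i, i+m)`` is reported at
    position ``i+m−1`` (its own 5'-most base).  When a span matches on both
    strands (palindromic occurrence), only the + hit is kept.  Output is
    sorted by (gene, position, motif, strand).
    """
    compiled = []
    for m in motifs:
        if not m.iupac and skip_unset:
            continue
        seq = m.require_sequence()
        compiled.append((m.name, len(seq), iupac_regex(seq), iupac_regex(revcomp(seq))))

    hits: list[MotifHit] = []
    for prom in promoters:
        seq = prom.sequence.upper()
        offset = prom.window[0]
        for name, mlen, fwd, rev in compiled:
            fwd_spans = {match.start() for match in _finditer_overlapping(fwd, seq)}
            rev_spans = {match.start() for match in _finditer_overlapping(rev, seq)}
            for i in fwd_spans:
                hits.append(MotifHit(prom.gene_id, name, offset + i, "+"))
            for i in rev_spans - fwd_spans:  # palindromic spans keep + only
                hits.append(MotifHit(prom.gene_id, name, offset + i + mlen - 1, "-"))
    hits.sort(key=lambda h: (h.gene_id, h.position, h.motif, h.strand))
    return hits


def _finditer_overlapping(pattern, seq: str):
    pos = 0
    while True:
        match = pattern.search(seq, pos)
        if match is None:
            return
        yield match
        pos = match.start() + 1


# ---------------------------------------------------------------------------
# Positional enrichment (window-restricted one-sided hypergeometric test)
# ---------------------------------------------------------------------------


def positional_enrichment(
    hits: Iterable[MotifHit],
    foreground: set[str],
    background: set[str],
    windows: Mapping[str, tuple[int, int]] = DEFAULT_ENRICHMENT_WINDOWS,
    p_threshold: float = 0.01,
    flag_windows: Sequence[str] = ("around-500", "core"),
) -> list[MotifScore]:
    """Score positional motif enrichment among upregulated genes.

    For each motif and window, genes carrying ≥1 in-window hit are counted in
    the foreground (upregulated) and background (all expressed) sets, and a
    one-sided hypergeometric tail probability is computed (drawing
    ``len(foreground)`` genes from the background, observing the foreground
    hit count).  ``score = −log10 p``; a motif is flagged high-scoring when
    p < ``p_threshold`` in either designated proximal window.
    """
    foreground = set(foreground)
    background = set(background)
    if not foreground:
        raise ValueError("foreground gene set is empty")
    if not foreground <= background:
        raise ValueError("foreground must be a subset of background")

    hit_list = [h for h in hits if h.gene_id in background]
    motif_names = sorted({h.motif for h in hit_list})
    raw: dict[tuple[str, str], dict] = {}
    for motif in motif_names:
        for wname, (lo, hi) in windows.items():
            in_window = {
                h.gene_id for h in hit_list if h.motif == motif and lo <= h.position < hi
            }
            k = len(in_window & foreground)
            big_k = len(in_window)
            n, big_n = len(foreground), len(background)
            p = float(hypergeom.sf(k - 1, big_n, big_k, n)) if k > 0 else 1.0
            p = min(max(p, np.nextafter(0, 1)), 1.0)
            raw[(motif, wname)] = dict(
                fg_hit_genes=k, fg_genes=n, bg_hit_genes=big_k, bg_genes=big_n, p_value=p
            )

    scores: list[MotifScore] = []
    for motif in motif_names:
        flagged = any(
            raw[(motif, w)]["p_value"] < p_threshold for w in flag_windows if (motif, w) in raw
        )
        for wname in windows:
            r = raw[(motif, wname)]
            scores.append(
                MotifScore(
                    motif=motif,
                    window=wname,
                    p_value=r["p_value"],
                    score=-float(np.log10(r["p_value"])),
                    high_score=flagged,
                    fg_hit_genes=r["fg_hit_genes"],
                    fg_genes=r["fg_genes"],
                    bg_hit_genes=r["bg_hit_genes"],
                    bg_genes=r["bg_genes"],
                )
            )
    return scores


# ---------------------------------------------------------------------------
# Density classes and spatial maps
# ---------------------------------------------------------------------------


def classify_density(count: int) -> str:
    if count >= 11:
        return "very_high"
    if count >= 8:
        return "high"
    return "low"


def motif_density(
    gene_hits: Iterable[MotifHit],
    motif: str,
    window: tuple[int, int] = DENSITY_WINDOW,
) -> DensityClass:
    """Copy count of one motif in the density window, with its class.

    All hits for exactly one gene are expected; copies on either strand count
    when the reported (5'-most) position lies inside the half-open window.
    """
    gene_hits = [h for h in gene_hits if h.motif == motif]
    genes = {h.gene_id for h in gene_hits}
    if len(genes) > 1:
        raise ValueError(f"hits span multiple genes: {sorted(genes)}")
    gene_id = genes.pop() if genes else ""
    lo, hi = window
    count = sum(lo <= h.position < hi for h in gene_hits)
    return DensityClass(gene_id, motif, window, count, classify_density(count))


def density_table(
    hits: Iterable[MotifHit],
    motif: str,
    genes: Iterable[str],
    window: tuple[int, int] = DENSITY_WINDOW,
) -> pd.DataFrame:
    """Per-gene density classes for one motif over a gene list (zero-filled)."""
    lo, hi = window
    counts: dict[str, int] = {g: 0 for g in genes}
    for h in hits:
        if h.motif == motif and h.gene_id in counts and lo <= h.position < hi:
            counts[h.gene_id] += 1
    rows = [
        dict(gene_id=g, motif=motif, count=c, density_class=classify_density(c))
        for g, c in counts.items()
    ]
    return pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)


def spatial_map(
    hits: Iterable[MotifHit],
    genes: Sequence[str],
    window: tuple[int, int] = DENSITY_WINDOW,
    logger=None,
) -> dict[str, pd.DataFrame]:
    """Per-gene ordered tracks of in-window motif occurrences for plotting.

    Every requested gene gets a track (possibly empty); rows are sorted by
    position, then motif, then strand.
    """
    lo, hi = window
    by_gene: dict[str, list[MotifHit]] = {g: [] for g in genes}
    for h in hits:
        if h.gene_id in by_gene and lo <= h.position < hi:
            by_gene[h.gene_id].append(h)
    tracks = {}
    for g in genes:
        rows = sorted(by_gene[g], key=lambda h: (h.position, h.motif, h.strand))
        tracks[g] = pd.DataFrame(
            [dict(position=h.position, motif=h.motif, strand=h.strand) for h in rows],
            columns=["position", "motif", "strand"],
        )
    return tracks
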