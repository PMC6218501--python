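"""Plain-text readers/writers for the pipeline's tables and sequences.

Counts travel as TSV with sample names encoding genotype_timepoint_replicate
(``A_24h_r1``); promoters as FASTA with the strand and TSS-relative window in
the header; alignment hits and ortholog pairs as simple TSV tables.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .cis import MotifHit, PromoterRegion
from .expression import CountMatrix
from .orthologs import AlignmentHit, OrthologPair

_SAMPLE_RE = re.compile(r"^(?P<genotype>[^_]+)_(?P<tp>\d+)h_r(?P<rep>\d+)$")


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_counts(path: str | Path) -> CountMatrix:
    counts = pd.read_csv(path, sep="\t", index_col="gene_id")
    meta = []
    for name in counts.columns:
        m = _SAMPLE_RE.match(name)
        if m is None:
            raise ValueError(
                f"sample name {name!r} does not encode genotype_timepoint_replicate "
                "(expected e.g. A_24h_r1)"
            )
        meta.append((m["genotype"], int(m["tp"]), int(m["rep"])))
    samples = pd.DataFrame(
        meta, index=counts.columns, columns=["genotype", "timepoint_hr", "replicate"]
    )
    return CountMatrix(counts, samples)


def write_promoters(promoters: Iterable[PromoterRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in promoters:
            fh.write(
                f">{p.gene_id} strand={p.strand} window={p.window[0]}:{p.window[1]} "
                f"truncated={int(p.truncated)}\n"
            )
            for i in range(0, len(p.sequence), 80):
                fh.write(p.sequence[i : i + 80] + "\n")


def read_promoters(path: str | Path) -> list[PromoterRegion]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(kv.split("=", 1) for kv in rec.description.split()[1:])
        lo, hi = (int(x) for x in fields["window"].split(":"))
        out.append(
            PromoterRegion(
                gene_id=rec.id,
                strand=fields.get("strand", "+"),
                tss_genomic=-lo,
                window=(lo, hi),
                sequence=str(rec.seq).upper(),
                truncated=bool(int(fields.get("truncated", "0"))),
            )
        )
    return out


def write_hits(hits: Iterable[MotifHit], path: str | Path) -> None:
    pd.DataFrame(
        [dict(gene_id=h.gene_id, motif=h.motif, position=h.position, strand=h.strand) for h in hits],
        columns=["gene_id", "motif", "position", "strand"],
    ).to_csv(path, sep="\t", index=False)


def read_hits(path: str | Path) -> list[MotifHit]:
    df = pd.read_csv(path, sep="\t")
    return [
        MotifHit(r.gene_id, r.motif, int(r.position), r.strand) for r in df.itertuples(index=False)
    ]


def write_alignment_hits(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    pd.DataFrame(
        [
            dict(
                query=h.query_id,
                target=h.target_id,
                aln_length=h.aln_length,
                identity=h.identity,
                coverage=h.query_coverage,
            )
            for h in hits
        ],
        columns=["query", "target", "aln_length", "identity", "coverage"],
    ).to_csv(path, sep="\t", index=False)


def read_alignment_hits(path: str | Path) -> list[AlignmentHit]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        AlignmentHit(r.query, r.target, int(r.aln_length), float(r.identity), float(r.coverage))
        for r in df.itertuples(index=False)
    ]


def write_pairs(pairs: Sequence[OrthologPair], path: str | Path) -> None:
    pd.DataFrame(
        [
            dict(locus_a=p.locus_a, locus_b=p.locus_b, aln_length=p.aln_length, stability=p.stability)
            for p in pairs
        ],
        columns=["locus_a", "locus_b", "aln_length", "stability"],
    ).to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> list[OrthologPair]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        OrthologPair(r.locus_a, r.locus_b, int(r.aln_length), float(r.stability))
        for r in df.itertuples(index=False)
    ]
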