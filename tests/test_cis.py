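"""Promoter extraction coordinates, motif scanning, enrichment, density, maps."""

import numpy as np
import pytest

from coldregulon.cis import (
    MotifDef,
    PromoterRegion,
    classify_density,
    density_table,
    extract_promoters,
    motif_density,
    positional_enrichment,
    scan_motifs,
    spatial_map,
)
from coldregulon.seqs import revcomp

from oracles import hypergeom_tail, naive_scan, rc


def make_promoter(seq, gene="g1", start=-3000):
    return PromoterRegion(gene, "+", -start, (start, start + len(seq)), seq)


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


class TestExtractPromoters:
    def _write(self, tmp_path, contig, features):
        fasta = tmp_path / "genome.fa"
        fasta.write_text(">chr1\n" + contig + "\n")
        gff = tmp_path / "models.gff3"
        lines = ["##gff-version 3"]
        for gid, start, end, strand in features:
            lines.append(
                f"chr1\ttest\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}"
            )
        gff.write_text("\n".join(lines) + "\n")
        return str(fasta), str(gff)

    def test_plus_strand_coordinate_arithmetic(self, tmp_path):
        rng = np.random.default_rng(0)
        contig = "".join("ACGT"[i] for i in rng.integers(0, 4, 20000))
        fasta, gff = self._write(tmp_path, contig, [("gA", 10001, 10300, "+")])
        (prom,) = extract_promoters(fasta, gff, window=(-3000, 2000))
        assert prom.sequence == contig[7000:12000]
        assert not prom.truncated
        assert prom.index_of(0) == 3000

    def test_minus_strand_mirror_on_toy_contig(self, tmp_path):
        rng = np.random.default_rng(1)
        contig = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        # - strand gene occupying 1-based [21, 31]: 0-based TSS = 30
        fasta, gff = self._write(tmp_path, contig, [("gM", 21, 31, "-")])
        (prom,) = extract_promoters(fasta, gff, window=(-10, 5))
        tss = 30
        assert prom.sequence == revcomp(contig[tss - 4 : tss + 11])
        # TSS-relative -10 maps to genomic tss+10
        idx = prom.index_of(-10)
        assert prom.sequence[idx] == rc(contig[tss + 10])

    def test_truncation_flagged_near_contig_edge(self, tmp_path):
        contig = "ACGT" * 200
        fasta, gff = self._write(tmp_path, contig, [("gE", 101, 160, "+")])
        (prom,) = extract_promoters(fasta, gff, window=(-3000, 2000))
        assert prom.truncated
        assert prom.window[0] == -100  # clipped at the contig start

    def test_missing_contig_skipped(self, tmp_path, caplog):
        fasta = tmp_path / "genome.fa"
        fasta.write_text(">chr1\nACGTACGTACGT\n")
        gff = tmp_path / "m.gff3"
        gff.write_text("##gff-version 3\nchrX\tt\tgene\t5\t8\t.\t+\t.\tID=gX\n")
        with caplog.at_level("WARNING"):
            assert extract_promoters(str(fasta), str(gff), window=(-2, 2)) == []
        assert "chrX" in caplog.text


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


class TestScanMotifs:
    def test_single_forward_hit_at_minus_500(self):
        seq = ["A"] * 5000
        idx = -500 + 3000
        seq[idx : idx + 6] = "CGTGTG"
        hits = scan_motifs([make_promoter("".join(seq))], [MotifDef("BRRE", "CGTGYG")])
        assert [(h.position, h.strand) for h in hits] == [(-500, "+")]

    def test_minus_strand_hit_reported_at_its_five_prime_base(self):
        seq = ["A"] * 100
        seq[40:46] = "CACACG"  # revcomp of CGTGTG
        hits = scan_motifs(
            [make_promoter("".join(seq), start=-50)], [MotifDef("BRRE", "CGTGYG")]
        )
        assert [(h.position, h.strand) for h in hits] == [(-50 + 45, "-")]

    def test_palindromic_span_reported_once_on_plus(self):
        seq = "AAAA" + "ACGCGT" + "AAAA"  # ACGCGT is its own reverse complement
        hits = scan_motifs([make_promoter(seq, start=0)], [MotifDef("pal", "ACGCGT")])
        assert len(hits) == 1 and hits[0].strand == "+"

    def test_sequence_n_never_matches(self):
        hits = scan_motifs([make_promoter("CGTGNG", start=0)], [MotifDef("BRRE", "CGTGYG")])
        assert hits == []

    def test_unset_motif_errors_at_use(self):
        with pytest.raises(ValueError, match="no IUPAC sequence"):
            scan_motifs([make_promoter("ACGT" * 10, start=0)], [MotifDef("GS2", None)])

    def test_matches_naive_scan_on_random_promoters(self):
        rng = np.random.default_rng(2)
        motifs = [MotifDef("BRRE", "CGTGYG"), MotifDef("E-box", "CANNTG"), MotifDef("DRE", "RCCGAC")]
        for _ in range(30):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
            prom = make_promoter(seq, start=-1000)
            hits = scan_motifs([prom], motifs)
            for m in motifs:
                got = sorted(
                    (h.position, h.strand) for h in hits if h.motif == m.name
                )
                assert got == sorted(naive_scan(seq, m.iupac, offset=-1000))

    def test_strand_symmetry_of_hit_counts(self):
        rng = np.random.default_rng(3)
        motifs = [MotifDef("BRRE", "CGTGYG"), MotifDef("Myb2", "YAACKG")]
        for _ in range(10):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1500))
            fwd_hits = scan_motifs([make_promoter(seq, start=0)], motifs)
            rev_hits = scan_motifs([make_promoter(revcomp(seq), start=0)], motifs)
            assert len(fwd_hits) == len(rev_hits)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


class TestPositionalEnrichment:
    def test_foreground_equals_background_is_null(self):
        seq = ["A"] * 5000
        seq[2500:2506] = "CGTGTG"
        promoters = [make_promoter("".join(seq), gene=f"g{i}") for i in range(10)]
        hits = scan_motifs(promoters, [MotifDef("BRRE", "CGTGYG")])
        genes = {p.gene_id for p in promoters}
        scores = positional_enrichment(hits, genes, genes)
        assert all(s.p_value == 1.0 and s.score == 0.0 for s in scores)

    def test_empty_foreground_errors(self):
        with pytest.raises(ValueError):
            positional_enrichment([], set(), {"g1"})

    def test_matches_exact_tail_sum(self):
        rng = np.random.default_rng(4)
        from coldregulon.cis import MotifHit

        for _ in range(100):
            n_bg = int(rng.integers(30, 200))
            bg = {f"g{i}" for i in range(n_bg)}
            fg = set(rng.choice(sorted(bg), size=rng.integers(5, n_bg // 2 + 5), replace=False))
            hit_genes = set(rng.choice(sorted(bg), size=rng.integers(1, n_bg), replace=False))
            hits = [MotifHit(g, "M", -500, "+") for g in hit_genes]
            (score,) = [
                s
                for s in positional_enrichment(
                    hits, fg, bg, windows={"around-500": (-650, -350)}, flag_windows=("around-500",)
                )
            ]
            expected = hypergeom_tail(
                len(hit_genes & fg), n_bg, len(hit_genes), len(fg)
            )
            assert score.p_value == pytest.approx(expected, abs=1e-9)

    def test_planted_signal_flagged_and_control_not(self, small_dataset):
        cfg, (_, _, _, promoters, truth) = small_dataset
        motifs = [MotifDef("BRRE", "CGTGYG"), MotifDef("control", "TAACARA")]
        hits = scan_motifs(promoters, motifs)
        genes = {p.gene_id for p in promoters}
        scores = positional_enrichment(hits, set(truth.regulon_members), genes)
        flagged = {s.motif for s in scores if s.high_score}
        assert "BRRE" in flagged
        assert "control" not in flagged


# ---------------------------------------------------------------------------
# density and spatial maps
# ---------------------------------------------------------------------------


class TestDensity:
    @pytest.mark.parametrize(
        "count,expected",
        [(0, "low"), (7, "low"), (8, "high"), (10, "high"), (11, "very_high"), (25, "very_high")],
    )
    def test_density_class_boundaries(self, count, expected):
        assert classify_density(count) == expected

    def test_in_window_counting(self):
        from coldregulon.cis import MotifHit

        hits = [MotifHit("g1", "BRRE", p, "+") for p in (-1300, -1200, -100, 499, 500)]
        dc = motif_density(hits, "BRRE", window=(-1200, 500))
        assert dc.count == 3 and dc.density_class == "low"

    def test_window_nesting_monotone(self, small_dataset):
        cfg, (_, _, _, promoters, truth) = small_dataset
        hits = scan_motifs(promoters[:30], [MotifDef("BRRE", "CGTGYG")])
        genes = [p.gene_id for p in promoters[:30]]
        narrow = density_table(hits, "BRRE", genes, window=(-1200, 500))
        wide = density_table(hits, "BRRE", genes, window=(-3000, 2000))
        assert (narrow["count"].to_numpy() <= wide["count"].to_numpy()).all()


class TestSpatialMap:
    def test_geneless_track_present_and_rows_sorted(self):
        from coldregulon.cis import MotifHit

        hits = [
            MotifHit("g1", "BRRE", -100, "+"),
            MotifHit("g1", "ABRE", -900, "-"),
            MotifHit("g1", "BRRE", -400, "+"),
        ]
        tracks = spatial_map(hits, ["g1", "g2"], window=(-1200, 500))
        assert list(tracks["g2"].columns) == ["position", "motif", "strand"]
        assert tracks["g2"].empty
        assert tracks["g1"]["position"].tolist() == [-900, -400, -100]

    def test_row_counts_agree_with_density(self, small_dataset):
        cfg, (_, _, _, promoters, truth) = small_dataset
        hits = scan_motifs(promoters[:20], [MotifDef("BRRE", "CGTGYG")])
        genes = [p.gene_id for p in promoters[:20]]
        tracks = spatial_map(hits, genes, window=(-1200, 500))
        dens = density_table(hits, "BRRE", genes, window=(-1200, 500)).set_index("gene_id")
        for g in genes:
            assert len(tracks[g]) == dens.loc[g, "count"]
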