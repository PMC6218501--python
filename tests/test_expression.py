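"""Normalization, dispersion, NB LRT, response classes, concordance, clustering."""

import numpy as np
import pandas as pd
import pytest

from coldregulon.expression import (
    CountMatrix,
    classify_response,
    de_table,
    de_test,
    estimate_dispersion,
    family_saturation,
    nb_kmeans,
    normalize,
    ortholog_concordance,
)
from coldregulon.orthologs import OrthologPair

from oracles import classify_oracle, median_of_ratios


def _frame(arr, prefix="s"):
    arr = np.asarray(arr)
    return pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


class TestNormalize:
    def test_identical_samples_unit_factors(self):
        df = _frame([[10, 10], [5, 5], [80, 80]])
        _, sf = normalize(df)
        assert np.allclose(sf, 1.0)

    def test_doubled_library_scales_proportionally(self):
        df = _frame([[10, 20], [5, 10], [80, 160]])
        _, sf = normalize(df)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)

    def test_matches_independent_median_of_ratios(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            counts = rng.integers(0, 400, size=(500, 6)).astype(float)
            counts[rng.uniform(size=counts.shape) < 0.1] = 0
            df = _frame(counts)
            _, sf = normalize(df)
            expected = median_of_ratios(counts.tolist())
            assert np.allclose(sf.to_numpy(), expected, atol=1e-12)

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        df = _frame(rng.integers(1, 300, size=(200, 5)).astype(float) * [1, 2, 0.5, 3, 1.2])
        norm, _ = normalize(df)
        _, sf2 = normalize(norm)
        assert np.allclose(sf2, 1.0, atol=1e-9)

    def test_fallback_when_no_allpositive_gene(self, caplog):
        df = _frame([[0, 4], [6, 0]])
        with caplog.at_level("WARNING"):
            _, sf = normalize(df)
        assert "total-count" in caplog.text
        assert np.allclose(sf.prod(), 1.0)


class TestDispersion:
    def test_equal_replicates_give_zero_raw_alpha(self, two_group_samples):
        df = pd.DataFrame(
            np.tile([[100.0], [40.0]], (1, 6)), columns=two_group_samples.index
        )
        alpha = estimate_dispersion(df, two_group_samples)
        assert np.allclose(alpha, 0.0)

    def test_moment_arithmetic(self):
        # m=100, s2=1100 -> raw alpha exactly 0.10 before shrinkage
        m, s2 = 100.0, 1100.0
        assert (s2 - m) / m**2 == pytest.approx(0.10)

    def test_recovers_planted_alpha(self, two_group_samples):
        rng = np.random.default_rng(4)
        mu = np.exp(rng.uniform(np.log(50), np.log(500), 2000))
        r = 1 / 0.1
        counts = rng.negative_binomial(r, r / (r + mu[:, None]), size=(2000, 6)).astype(float)
        df = pd.DataFrame(counts, columns=two_group_samples.index)
        alpha = estimate_dispersion(df, two_group_samples)
        assert 0.07 <= float(np.median(alpha)) <= 0.13


class TestDETest:
    def test_identical_groups_null(self, two_group_samples):
        df = pd.DataFrame(np.tile([[50.0]], (1, 6)), columns=two_group_samples.index)
        res = de_test(df, two_group_samples, "A", 24, pd.Series([0.1], index=df.index))
        assert res["log2fc"].iloc[0] == 0.0
        assert res["p"].iloc[0] > 0.9

    def test_all_zero_gene(self, two_group_samples):
        df = pd.DataFrame(np.zeros((1, 6)), columns=two_group_samples.index)
        res = de_test(df, two_group_samples, "A", 24, pd.Series([0.1], index=df.index))
        assert res["log2fc"].iloc[0] == 0.0 and res["p"].iloc[0] == 1.0

    def test_label_swap_negates_log2fc_and_preserves_p(self, two_group_samples):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            rng.integers(0, 400, size=(300, 6)).astype(float), columns=two_group_samples.index
        )
        alpha = estimate_dispersion(df, two_group_samples)
        fwd = de_test(df, two_group_samples, "A", 24, alpha)
        swapped = two_group_samples.copy()
        swapped["timepoint_hr"] = swapped["timepoint_hr"].map({0: 24, 24: 0})
        rev = de_test(df, swapped, "A", 24, alpha)
        assert np.allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)
        assert np.allclose(fwd["p"], rev["p"], atol=1e-12)

    def test_power_on_planted_effect(self, two_group_samples):
        rng = np.random.default_rng(7)
        mu0 = np.full(500, 50.0)
        r = 1 / 0.1
        c0 = rng.negative_binomial(r, r / (r + mu0[:, None]), size=(500, 3))
        c1 = rng.negative_binomial(r, r / (r + 8 * mu0[:, None]), size=(500, 3))
        df = pd.DataFrame(np.hstack([c0, c1]).astype(float), columns=two_group_samples.index)
        alpha = estimate_dispersion(df, two_group_samples)
        res = de_test(df, two_group_samples, "A", 24, alpha)
        power = ((res["log2fc"].abs() > 2) & (res["p"] < 0.01)).mean()
        assert power >= 0.8


class TestClassify:
    def test_flat_gene_unchanged(self):
        assert classify_response([0.1, -0.3, 0.2, 0.0], [0.6, 0.8, 0.7, 0.9]) == "unchanged"

    def test_single_up_event(self):
        assert classify_response([0, 2.5, 0, 0], [0.9, 0.001, 0.9, 0.9]) == "up"

    def test_conflict_resolved_by_largest_magnitude(self):
        assert classify_response([2.5, -3.1, 0, 0], [0.001, 0.001, 0.9, 0.9]) == "down"

    def test_exhaustive_truth_table_matches_oracle(self):
        lfcs = [-3.0, -2.5, 0.0, 2.5, 3.0]
        ps = [0.001, 0.5]
        rng = np.random.default_rng(8)
        for _ in range(500):
            l = [float(rng.choice(lfcs)) for _ in range(4)]
            p = [float(rng.choice(ps)) for _ in range(4)]
            assert classify_response(l, p) == classify_oracle(l, p)


class TestConcordance:
    PAIRS = [OrthologPair(f"a{i}", f"b{i}", 100, 1.0) for i in range(6)]

    def test_identical_classifications_are_fully_concordant(self):
        classes = {f"a{i}": "up" for i in range(6)}
        classes_b = {f"b{i}": "up" for i in range(6)}
        conc = ortholog_concordance(classes, classes_b, self.PAIRS)
        assert conc.pct_a_up_also_b == 100.0
        assert conc.pct_b_up_also_a == 100.0

    def test_disjoint_up_sets_give_zero(self):
        ca = {f"a{i}": ("up" if i < 3 else "unchanged") for i in range(6)}
        cb = {f"b{i}": ("unchanged" if i < 3 else "up") for i in range(6)}
        conc = ortholog_concordance(ca, cb, self.PAIRS)
        assert conc.pct_a_up_also_b == 0.0

    def test_missing_classes_counted_as_excluded(self):
        ca = {f"a{i}": "up" for i in range(5)}
        cb = {f"b{i}": "up" for i in range(6)}
        conc = ortholog_concordance(ca, cb, self.PAIRS)
        assert conc.n_excluded == 1 and conc.n_pairs == 5

    def test_invariant_under_gene_relabeling(self):
        rng = np.random.default_rng(9)
        classes = ["up", "down", "unchanged"]
        ca = {f"a{i}": classes[rng.integers(3)] for i in range(50)}
        cb = {f"b{i}": classes[rng.integers(3)] for i in range(50)}
        pairs = [OrthologPair(f"a{i}", f"b{i}", 10, 1.0) for i in range(50)]
        conc1 = ortholog_concordance(ca, cb, pairs)
        renamed_a = {f"x{k[1:]}": v for k, v in ca.items()}
        pairs2 = [OrthologPair(f"x{i}", f"b{i}", 10, 1.0) for i in range(50)]
        conc2 = ortholog_concordance(renamed_a, cb, pairs2)
        assert conc1.table.to_numpy().tolist() == conc2.table.to_numpy().tolist()
        assert conc1.pct_a_up_also_b == conc2.pct_a_up_also_b


class TestNBKMeans:
    def test_k1_returns_profile_average(self):
        rng = np.random.default_rng(10)
        prof = _frame(rng.uniform(5, 200, size=(30, 5)))
        res = nb_kmeans(prof, k=1, alpha=0.1, seed=0)
        assert (res.labels == 1).all()
        assert np.allclose(res.cluster_profiles.iloc[0], prof.mean(axis=0))

    def test_two_separated_shapes_perfectly_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(11)
        rows, truth = [], []
        for shape, label in (([1, 1, 4, 4, 4], 0), ([4, 4, 1, 1, 1], 1)):
            for _ in range(30):
                mu0 = rng.uniform(50, 300)
                rows.append([rng.poisson(mu0 * s * (1 + 0.05)) for s in shape])
                truth.append(label)
        res = nb_kmeans(_frame(np.array(rows, float)), k=2, alpha=0.05, seed=1)
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_monotone_likelihood_and_seed_determinism(self):
        rng = np.random.default_rng(12)
        prof = _frame(rng.uniform(1, 300, size=(120, 5)))
        r1 = nb_kmeans(prof, k=4, alpha=0.1, seed=5)
        r2 = nb_kmeans(prof, k=4, alpha=0.1, seed=5)
        assert (r1.labels == r2.labels).all()
        assert all(b >= a - 1e-6 for a, b in zip(r1.ll_trace, r1.ll_trace[1:]))

    def test_k_larger_than_gene_count_rejected(self):
        prof = _frame(np.ones((3, 5)))
        with pytest.raises(ValueError):
            nb_kmeans(prof, k=10, alpha=0.1, seed=0)


class TestFamilySaturation:
    def _setup(self):
        idx = [f"A_{t}h_r{r}" for t in (0, 24, 48) for r in (1, 2)]
        samples = pd.DataFrame(
            [("A", t, r) for t in (0, 24, 48) for r in (1, 2)],
            index=idx,
            columns=["genotype", "timepoint_hr", "replicate"],
        )
        rng = np.random.default_rng(13)
        norm = pd.DataFrame(
            rng.uniform(0, 200, size=(30, 6)), columns=idx, index=[f"g{i}" for i in range(30)]
        )
        return norm, samples

    def test_single_gene_family_equals_gene_curve(self):
        norm, samples = self._setup()
        fam = family_saturation(norm, samples, {"g0": "WRKY"})
        expected = [
            norm.loc["g0", samples.index[samples["timepoint_hr"] == t]].mean()
            for t in (0, 24, 48)
        ]
        assert np.allclose(fam.loc["WRKY", [0, 24, 48]], expected)

    def test_flat_family_has_unit_fold_induction(self):
        idx = [f"A_{t}h_r{r}" for t in (0, 24, 48) for r in (1, 2)]
        samples = pd.DataFrame(
            [("A", t, r) for t in (0, 24, 48) for r in (1, 2)],
            index=idx,
            columns=["genotype", "timepoint_hr", "replicate"],
        )
        norm = pd.DataFrame(np.full((3, 6), 50.0), columns=idx, index=["g0", "g1", "g2"])
        fam = family_saturation(norm, samples, {g: "NAC" for g in norm.index})
        assert fam.loc["NAC", "max_fold_induction"] == pytest.approx(1.0)

    def test_sums_match_bruteforce_for_random_annotation(self):
        norm, samples = self._setup()
        rng = np.random.default_rng(14)
        families = {g: f"F{rng.integers(5)}" for g in norm.index}
        fam = family_saturation(norm, samples, families)
        for fname in set(families.values()):
            genes = [g for g, f in families.items() if f == fname]
            for t in (0, 24, 48):
                cols = samples.index[samples["timepoint_hr"] == t]
                expected = sum(norm.loc[g, cols].mean() for g in genes)
                assert fam.loc[fname, t] == pytest.approx(expected)


def test_count_matrix_validation():
    idx = ["A_0h_r1", "A_24h_r1"]
    samples = pd.DataFrame(
        [("A", 0, 1), ("A", 24, 1)], index=idx, columns=["genotype", "timepoint_hr", "replicate"]
    )
    CountMatrix(pd.DataFrame([[1, 2]], columns=idx, index=["g0"]), samples)
    with pytest.raises(ValueError):
        CountMatrix(pd.DataFrame([[-1, 2]], columns=idx, index=["g0"]), samples)
    with pytest.raises(ValueError):
        CountMatrix(pd.DataFrame([[0.5, 2]], columns=idx, index=["g0"]), samples)
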