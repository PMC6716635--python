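"""Wilcoxon tests against enumeration/permutation oracles; DEG-set calling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from samgepc.deg_calling import (
    call_degs,
    compare_detection_counts,
    rank_sum_p_matrix,
    signed_rank_p_matrix,
    signed_rank_p_rows,
    wilcoxon_rank_sum_p,
    wilcoxon_signed_rank_p,
)
from samgepc.io_model import ExpressionMatrix, Platform, pair_samples
from samgepc.phenotyping import classify_response
from tests.test_phenotyping import make_clinical


# ---------------------------------------------------------------------------
# independent oracles


def signed_rank_enumeration_p(d: np.ndarray) -> float:
    """Exact two-sided p by enumerating all 2^n sign assignments."""
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    t_obs = ranks[d > 0].sum()
    ts = np.array(
        [ranks[np.array(signs, bool)].sum() for signs in itertools.product([0, 1], repeat=n)]
    )
    p = 2 * min((ts <= t_obs).mean(), (ts >= t_obs).mean())
    return min(1.0, p)


def rank_sum_enumeration_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p by enumerating all C(n, nx) group labelings."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nx = len(x)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    us = np.array(
        [
            ranks[list(idx)].sum() - nx * (nx + 1) / 2
            for idx in itertools.combinations(range(len(pooled)), nx)
        ]
    )
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)


# ---------------------------------------------------------------------------
# scalar tests


class TestSignedRank:
    def test_all_positive_n6_exact(self):
        # every sign assignment enumerable: 2 of 64 are as extreme
        p = wilcoxon_signed_rank_p(np.zeros(6), np.arange(1.0, 7.0))
        assert p == pytest.approx(2 / 64)

    def test_all_zero_differences_give_missing(self):
        assert np.isnan(wilcoxon_signed_rank_p([1.0] * 6, [1.0] * 6))

    def test_under_four_pairs_give_missing(self):
        assert np.isnan(wilcoxon_signed_rank_p([1, 2, 3], [2, 3, 4]))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("n", [5, 6, 7, 8])
    def test_exact_path_matches_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.3, 1.0, n)
        p = wilcoxon_signed_rank_p(np.zeros(n), d)
        assert p == pytest.approx(signed_rank_enumeration_p(d))

    def test_large_n_matches_permutation_oracle(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0.35, 1.0, 30)
        p = wilcoxon_signed_rank_p(np.zeros(30), d)
        ranks = stats.rankdata(np.abs(d))
        mu = 30 * 31 / 4
        t_obs = ranks[d > 0].sum()
        signs = rng.random((100_000, 30)) < 0.5
        ts = (signs * ranks).sum(axis=1)
        p_perm = (np.abs(ts - mu) >= abs(t_obs - mu) - 1e-9).mean()
        assert abs(p - p_perm) < 0.005


class TestRankSum:
    def test_extreme_separation_n3v3(self):
        # 2 of the C(6,3)=20 labelings are as extreme
        assert wilcoxon_rank_sum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(2 / 20)

    def test_identical_groups_give_p_one(self):
        assert wilcoxon_rank_sum_p([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError, match="nonempty"):
            wilcoxon_rank_sum_p([], [1, 2, 3])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_path_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(0.5, 1, 5), rng.normal(0, 1, 5)
        assert wilcoxon_rank_sum_p(x, y) == pytest.approx(rank_sum_enumeration_p(x, y))

    def test_large_n_matches_permutation_oracle(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(0.5, 1, 31), rng.normal(0, 1, 16)
        p = wilcoxon_rank_sum_p(x, y)
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        nx = len(x)
        mu = nx * len(y) / 2
        u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
        us = np.empty(100_000)
        for i in range(100_000):
            perm = rng.permutation(len(pooled))[:nx]
            us[i] = ranks[perm].sum() - nx * (nx + 1) / 2
        p_perm = (np.abs(us - mu) >= abs(u_obs - mu) - 1e-9).mean()
        assert abs(p - p_perm) < 0.005

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0.5, 1, 20), rng.normal(0, 1, 15)
        assert wilcoxon_rank_sum_p(x, y) == wilcoxon_rank_sum_p(np.exp(x), np.exp(y))


class TestMatrixPaths:
    def test_signed_rank_matrix_matches_scipy_approx(self):
        rng = np.random.default_rng(5)
        base = rng.normal(5, 1, (50, 31))
        locf = base + rng.normal(0.1, 0.5, (50, 31))
        p_vec = signed_rank_p_matrix(base, locf)
        for i in range(50):
            ref = stats.wilcoxon(
                locf[i] - base[i], correction=True, method="approx"
            ).pvalue
            assert p_vec[i] == pytest.approx(ref, rel=1e-9)

    def test_signed_rank_rows_exact_matches_scalar(self):
        rng = np.random.default_rng(6)
        base = rng.normal(5, 1, (30, 12))
        locf = base + rng.normal(0.3, 0.5, (30, 12))
        p_vec = signed_rank_p_rows(base, locf)
        for i in range(30):
            assert p_vec[i] == pytest.approx(wilcoxon_signed_rank_p(base[i], locf[i]))

    def test_rank_sum_matrix_matches_scipy(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0.3, 1, (40, 31))
        y = rng.normal(0, 1, (40, 16))
        p_vec = rank_sum_p_matrix(x, y)
        for i in range(40):
            ref = stats.mannwhitneyu(
                x[i], y[i], alternative="two-sided", method="asymptotic"
            ).pvalue
            assert p_vec[i] == pytest.approx(ref, rel=1e-9)

    def test_type_one_error_near_nominal(self):
        """Fully null data: the fraction of p < 0.05 stays in [0.04, 0.06]."""
        rng = np.random.default_rng(13)
        base = rng.normal(5, 1, (10_000, 31))
        locf = rng.normal(5, 1, (10_000, 31))
        p = signed_rank_p_rows(base, locf)
        assert 0.04 <= (p < 0.05).mean() <= 0.06


class TestDetectionCounts:
    def test_genome_scale_rates_differ(self):
        # 573/19,672 vs 1,724/15,364 detections: overwhelmingly different
        assert compare_detection_counts(573, 19672, 1724, 15364) < 1e-4

    def test_equal_proportions_give_p_one(self):
        assert compare_detection_counts(10, 100, 10, 100) == pytest.approx(1.0)

    def test_fisher_path_matches_hypergeometric_enumeration(self):
        # (1 of 10) vs (9 of 10): enumerate the hypergeometric table set
        p = compare_detection_counts(1, 10, 9, 10)
        pmf = [stats.hypergeom.pmf(k, 20, 10, 10) for k in range(11)]
        p_enum = sum(q for q in pmf if q <= pmf[1] + 1e-12)
        assert p == pytest.approx(p_enum)
        assert p == pytest.approx(0.001093, abs=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compare_detection_counts(1, 0, 1, 10)
        with pytest.raises(ValueError):
            compare_detection_counts(11, 10, 1, 10)


class TestCallDegs:
    def _study(self):
        """Six patients, two genes: g_up clearly upregulated on qPCR, g_flat null."""
        patients = [f"P{i}" for i in range(1, 7)]
        cols = {}
        rng = np.random.default_rng(0)
        for j, p in enumerate(patients):
            noise = rng.normal(0, 0.02, 3)
            cols[f"{p}_baseline"] = [26.0 + noise[0], 24.0 + noise[1], 20.0]
            noise = rng.normal(0, 0.02, 3)
            cols[f"{p}_m12"] = [24.5 + noise[0], 24.0 + noise[1], 20.0]
        em = ExpressionMatrix(
            Platform.QPCR,
            pd.DataFrame(cols, index=pd.Index(["g_up", "g_flat", "GAPDH"], name="gene_id")),
        )
        clin = make_clinical({p: (25.0, 35.0, None) for p in patients[:4]}
                             | {p: (25.0, 26.0, None) for p in patients[4:]})
        pheno = classify_response(clin)
        view = pair_samples(em, {p: "m12" for p in patients})
        return em, view, pheno

    def test_qpcr_direction_comes_from_fold_change(self):
        em, view, pheno = self._study()
        ds = call_degs(em, view, pheno, "R_change", cohort="test")
        # Ct falls 26 → 24.5: upregulation despite the inverted Ct scale
        rec = ds.records.loc["g_up"]
        assert rec["direction"] == "up"
        assert rec["fold_change"] > 1

    def test_reference_gene_excluded_from_records(self):
        em, view, pheno = self._study()
        ds = call_degs(em, view, pheno, "R_change")
        assert "GAPDH" not in ds.records.index
        assert ds.universe_size == 2

    def test_repeated_runs_bit_identical(self):
        em, view, pheno = self._study()
        a = call_degs(em, view, pheno, "RvsNR")
        b = call_degs(em, view, pheno, "RvsNR")
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_invalid_alpha_rejected(self):
        em, view, pheno = self._study()
        for alpha in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError, match="alpha"):
                call_degs(em, view, pheno, "R_change", alpha)

    def test_significant_subset_respects_alpha_and_direction(self):
        em, view, pheno = self._study()
        ds = call_degs(em, view, pheno, "R_change", alpha=0.2)
        sig = ds.significant
        assert (sig["p_value"] < 0.2).all()
        assert sig["direction"].notna().all()
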