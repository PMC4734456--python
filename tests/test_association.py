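"""Joint batch-interaction association machinery: design construction,
PERMANOVA pseudo-F, distance-based R², and the α-diversity LRT."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kstest

from microdemog.association_overall import (
    DesignSpec,
    alpha_lrt,
    build_design,
    distance_r2,
    permanova_joint,
)
from microdemog.data_model import DistanceMatrix, SampleMetadata, ValidationError
from microdemog.synthetic_data import simulate_null_distance

from conftest import two_group_metadata


def euclidean_dm(y, ids):
    d = squareform(pdist(np.asarray(y, dtype=float)[:, None]))
    return DistanceMatrix(ids, d)


def classical_joint_f(y, Z, X):
    """Ordinary ANOVA joint F of the X block after Z, via OLS residuals."""
    y = np.asarray(y, dtype=float)

    def rss(M):
        beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        r = y - M @ beta
        return float(r @ r)

    full = np.hstack([Z, X])
    p = np.linalg.matrix_rank(full) - np.linalg.matrix_rank(Z)
    rank_f = np.linalg.matrix_rank(full)
    return ((rss(Z) - rss(full)) / p) / (rss(full) / (len(y) - rank_f))


class TestBuildDesign:
    def test_binary_covariate_two_batches_has_two_df(self, tiny_meta):
        rng = np.random.default_rng(0)
        meta = two_group_metadata(40, rng)
        d = build_design(meta, DesignSpec("sex"))
        assert d.p == 2  # main effect + interaction

    def test_continuous_single_batch_one_df(self):
        rng = np.random.default_rng(1)
        meta = two_group_metadata(20, rng, n_batches=2)
        df = meta.data.copy()
        df["batch"] = "b1"
        d = build_design(SampleMetadata(df), DesignSpec("bmi"))
        assert d.p == 1
        assert d.x_obs.shape[1] == 1  # no interaction possible

    def test_covariate_constant_within_batch_fully_aliased(self):
        rng = np.random.default_rng(2)
        meta = two_group_metadata(20, rng)
        df = meta.data.copy()
        df["alcohol"] = np.where(df["batch"] == "batch1", "Y", "N")
        d = build_design(SampleMetadata(df), DesignSpec("alcohol"))
        assert d.p == 0
        assert len(d.dropped_columns) == d.x_obs.shape[1]

    def test_constant_covariate_rejected(self):
        rng = np.random.default_rng(3)
        meta = two_group_metadata(20, rng)
        df = meta.data.copy()
        df["tobacco"] = "N"
        with pytest.raises(ValidationError, match="degenerate covariate"):
            build_design(SampleMetadata(df), DesignSpec("tobacco"))


class TestPermanova:
    def test_perfectly_separated_clusters_min_p(self):
        rng = np.random.default_rng(4)
        n = 24
        meta = two_group_metadata(n, rng)
        df = meta.data.copy()
        df["alcohol"] = ["Y", "N"] * (n // 2)
        meta = SampleMetadata(df)
        # two tight clusters exactly aligned with alcohol
        y = np.where(df["alcohol"] == "Y", 0.0, 10.0) + rng.normal(0, 1e-4, n)
        D = euclidean_dm(y, meta.sample_ids)
        res = permanova_joint(D, meta, DesignSpec("alcohol"), n_perm=99, seed=0)
        assert res.p_value == pytest.approx(1.0 / 100.0)
        assert res.statistic > 1e4

    def test_zero_permutations_rejected(self):
        D = simulate_null_distance(10, seed=0)
        meta = two_group_metadata(10, np.random.default_rng(0))
        with pytest.raises(ValueError):
            permanova_joint(D, meta, DesignSpec("sex"), n_perm=0)

    def test_equals_classical_anova_f_on_euclidean_distances(self):
        rng = np.random.default_rng(5)
        for rep in range(5):
            n = 16
            meta = two_group_metadata(n, rng)
            y = rng.normal(size=n)
            D = euclidean_dm(y, meta.sample_ids)
            for cov in ("sex", "bmi"):
                res = permanova_joint(D, meta, DesignSpec(cov), n_perm=1, seed=rep)
                d = build_design(meta, DesignSpec(cov))
                want = classical_joint_f(y, d.Z, d.x_obs)
                assert res.statistic == pytest.approx(want, abs=1e-8)

    def test_cross_check_scikit_bio_single_factor(self):
        import skbio

        rng = np.random.default_rng(6)
        n = 18
        meta = two_group_metadata(n, rng)
        df = meta.data.copy()
        df["batch"] = "b1"  # single batch: plain one-way PERMANOVA
        meta = SampleMetadata(df)
        D = simulate_null_distance(n, seed=3)
        D = DistanceMatrix(meta.sample_ids, D.values)
        res = permanova_joint(D, meta, DesignSpec("sex"), n_perm=10, seed=0)
        sk = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(D.values, meta.sample_ids),
            grouping=df["sex"].to_numpy(), permutations=9)
        assert res.statistic == pytest.approx(sk["test statistic"], abs=1e-10)

    def test_invariant_to_sample_reordering(self):
        rng = np.random.default_rng(7)
        n = 20
        meta = two_group_metadata(n, rng)
        D = simulate_null_distance(n, seed=5)
        D = DistanceMatrix(meta.sample_ids, D.values)
        res = permanova_joint(D, meta, DesignSpec("bmi"), n_perm=5, seed=1)
        perm = rng.permutation(n)
        ids2 = [meta.sample_ids[i] for i in perm]
        res2 = permanova_joint(D.select_samples(ids2), meta.select_samples(ids2),
                               DesignSpec("bmi"), n_perm=5, seed=1)
        assert res2.statistic == pytest.approx(res.statistic, abs=1e-10)
        assert res2.r2 == pytest.approx(res.r2, abs=1e-12)

    def test_p_value_reproducible_for_fixed_seed(self):
        n = 20
        meta = two_group_metadata(n, np.random.default_rng(8))
        D = simulate_null_distance(n, seed=2)
        D = DistanceMatrix(meta.sample_ids, D.values)
        p1 = permanova_joint(D, meta, DesignSpec("race"), n_perm=200, seed=9).p_value
        p2 = permanova_joint(D, meta, DesignSpec("race"), n_perm=200, seed=9).p_value
        assert p1 == p2

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(10)
        ps = []
        for rep in range(60):
            n = 24
            meta = two_group_metadata(n, rng)
            D = simulate_null_distance(n, seed=10_000 + rep)
            D = DistanceMatrix(meta.sample_ids, D.values)
            ps.append(permanova_joint(D, meta, DesignSpec("sex"),
                                      n_perm=59, seed=rep).p_value)
        assert 0.30 <= np.mean(ps) <= 0.70


class TestDistanceR2:
    def test_r2_decomposition_sums_to_one(self):
        rng = np.random.default_rng(11)
        n = 22
        meta = two_group_metadata(n, rng)
        D = simulate_null_distance(n, seed=4)
        D = DistanceMatrix(meta.sample_ids, D.values)
        from microdemog.association_overall import _orth, _trace_proj
        from microdemog.diversity_beta import gower_center

        d = build_design(meta, DesignSpec("alcohol"))
        G = gower_center(D).values
        tr_g = np.trace(G)
        Qz = _orth(d.Z)
        tr_batch = _trace_proj(G, Qz)
        xr = d.x_obs - Qz @ (Qz.T @ d.x_obs)
        tr_full = tr_batch + _trace_proj(G, _orth(xr))
        r2_batch = tr_batch / tr_g
        r2_joint, _ = distance_r2(D, meta, DesignSpec("alcohol"))
        r2_resid = (tr_g - tr_full) / tr_g
        assert r2_batch + r2_joint + r2_resid == pytest.approx(1.0, abs=1e-10)

    def test_adjustment_arithmetic(self):
        # R^2 = 0, n = 100, p = 1  ->  adjusted = -1/98
        r2, n, p = 0.0, 100, 1
        assert 1 - (1 - r2) * (n - 1) / (n - p - 1) == pytest.approx(-1 / 98)

    def test_adjusted_below_raw_and_consistent(self):
        rng = np.random.default_rng(12)
        n = 30
        meta = two_group_metadata(n, rng)
        D = simulate_null_distance(n, seed=6)
        D = DistanceMatrix(meta.sample_ids, D.values)
        spec = DesignSpec("bmi")
        r2, r2_adj = distance_r2(D, meta, spec)
        d = build_design(meta, spec)
        assert r2_adj <= r2 <= 1.0
        assert r2_adj == pytest.approx(1 - (1 - r2) * (n - 1) / (n - d.p - 1))

    def test_marginal_scope_differs_but_close_under_null(self):
        rng = np.random.default_rng(13)
        n = 30
        meta = two_group_metadata(n, rng)
        D = simulate_null_distance(n, seed=7)
        D = DistanceMatrix(meta.sample_ids, D.values)
        r2_seq, _ = distance_r2(D, meta, DesignSpec("sex"), scope="sequential")
        r2_marg, _ = distance_r2(D, meta, DesignSpec("sex"), scope="marginal")
        assert 0 <= r2_seq <= 1 and 0 <= r2_marg <= 1

    def test_saturated_design_r2_one(self):
        # a categorical covariate with one level per sample spans everything
        rng = np.random.default_rng(14)
        n = 8
        meta = two_group_metadata(n, rng)
        df = meta.data.copy()
        df["batch"] = "b1"
        df["race"] = [f"lvl{i}" for i in range(n)]  # saturated
        meta = SampleMetadata(df)
        D = simulate_null_distance(n, seed=8)
        D = DistanceMatrix(meta.sample_ids, D.values)
        from microdemog.association_overall import _orth, _trace_proj
        from microdemog.diversity_beta import gower_center

        d = build_design(meta, DesignSpec("race"))
        G = gower_center(D).values
        Qz = _orth(d.Z)
        xr = d.x_obs - Qz @ (Qz.T @ d.x_obs)
        tr_full = _trace_proj(G, Qz) + _trace_proj(G, _orth(xr))
        assert tr_full / np.trace(G) == pytest.approx(1.0, abs=1e-10)


class TestAlphaLRT:
    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(15)
        ps = []
        n = 200
        for rep in range(500):
            meta = two_group_metadata(n, rng)
            y = pd.Series(rng.normal(size=n), index=meta.sample_ids)
            ps.append(alpha_lrt(y, meta, DesignSpec("bmi")).p_value)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_exact_fit_flagged(self):
        rng = np.random.default_rng(16)
        meta = two_group_metadata(30, rng)
        y = pd.Series(2.0 * meta["bmi"].to_numpy() + 1.0, index=meta.sample_ids)
        res = alpha_lrt(y, meta, DesignSpec("bmi"))
        assert "exact_fit" in res.flags

    def test_batch_only_signal_keeps_nominal_level_for_x(self):
        rng = np.random.default_rng(17)
        n = 120
        rejections = 0
        reps = 300
        for _ in range(reps):
            meta = two_group_metadata(n, rng)
            y = pd.Series(
                np.where(meta["batch"] == "batch1", 0.0, 3.0) + rng.normal(size=n),
                index=meta.sample_ids)
            if alpha_lrt(y, meta, DesignSpec("sex")).p_value < 0.05:
                rejections += 1
        assert rejections / reps < 0.12  # near-nominal despite strong batch signal

    def test_missing_covariate_values_dropped(self):
        rng = np.random.default_rng(18)
        meta = two_group_metadata(30, rng)
        df = meta.data.copy()
        df.loc[df.index[:5], "bmi"] = np.nan
        meta = SampleMetadata(df)
        y = pd.Series(rng.normal(size=30), index=meta.sample_ids)
        res = alpha_lrt(y, meta, DesignSpec("bmi"))
        assert res.n == 25
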