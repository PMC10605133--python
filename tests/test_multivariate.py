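"""Normalisation, scaling, PCA (with eigendecomposition oracle), ellipses
and heatmap clustering (with a hand-worked complete-linkage dendrogram)."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidkit.errors import ZeroMedianError
from lipidkit.multivariate import (
    confidence_ellipse,
    heatmap_select_cluster,
    normalize_median,
    pca,
    scale,
)
from lipidkit.profile import compare_groups
from lipidkit.quantify import SampleMeta


def _frame(arr, prefix="v"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"s{j}" for j in range(arr.shape[1])],
    )


class TestMedianNormalize:
    def test_equal_medians_identity(self):
        df = _frame([[1, 1], [2, 2], [3, 3]])
        pd.testing.assert_frame_equal(normalize_median(df), df)

    def test_removes_sample_scale_factor(self, rng):
        df = _frame(rng.uniform(0.5, 5, (20, 6)))
        scaled = df.copy()
        scaled["s2"] *= 2.0
        out = normalize_median(scaled)
        exp = normalize_median(df)
        ratio = out["s2"] / exp["s2"]
        assert np.allclose(ratio, ratio.iloc[0])
        meds = out.median(axis=0)
        assert np.allclose(meds, meds.iloc[0])

    def test_zero_median_raises(self):
        df = _frame([[0, 1], [0, 2], [1, 3]])
        with pytest.raises(ZeroMedianError):
            normalize_median(df)


class TestScale:
    def test_constant_row_maps_to_zero(self):
        df = _frame([[5, 5, 5], [1, 2, 3]])
        for method in ("autoscale", "pareto"):
            out = scale(df, method).values
            assert np.allclose(out.loc["v0"], 0.0)

    def test_autoscale_unit_sd(self, rng):
        df = _frame(rng.normal(3, 2, (10, 8)))
        out = scale(df, "autoscale").values
        assert np.allclose(out.mean(axis=1), 0.0)
        assert np.allclose(out.std(axis=1, ddof=1), 1.0)

    def test_pareto_variance_equals_original_sd(self, rng):
        """After Pareto scaling the variance of each row equals its
        original standard deviation (var/sd = sd)."""
        df = _frame(rng.lognormal(0, 0.5, (15, 9)))
        out = scale(df, "pareto").values
        orig_sd = df.std(axis=1, ddof=1)
        assert np.allclose(out.var(axis=1, ddof=1), orig_sd)


class TestPCA:
    def test_single_direction_explains_everything(self):
        # two sample groups differing on one variable only, duplicated
        df = _frame([[1, 1, 1, 5, 5, 5], [2, 2, 2, 2, 2, 2]])
        res = pca(scale(df, "none"))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        """Explained variances equal the eigenvalues of the sample
        covariance computed independently, random 20x8 matrix."""
        df = _frame(rng.normal(0, 1, (20, 8)))
        scaled = scale(df, "pareto")
        res = pca(scaled)
        X = scaled.values.to_numpy().T
        cov = np.cov(X, rowvar=False)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(res.explained_variance, evals[: res.n_components], atol=1e-8)
        assert np.allclose(
            res.explained_variance_ratio,
            evals[: res.n_components] / evals.sum(),
            atol=1e-8,
        )

    def test_reconstruction_with_all_components(self, rng):
        df = _frame(rng.normal(0, 1, (12, 7)))
        scaled = scale(df, "autoscale")
        res = pca(scaled)
        X = scaled.values.to_numpy().T
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T + X.mean(axis=0)
        assert np.allclose(recon, X, atol=1e-8)

    def test_loadings_orthonormal(self, rng):
        df = _frame(rng.normal(0, 1, (15, 9)))
        res = pca(scale(df, "pareto"))
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(res.n_components), atol=1e-10)

    def test_explained_fractions_sorted_and_bounded(self, rng):
        df = _frame(rng.normal(0, 1, (15, 9)))
        r = pca(scale(df, "pareto")).explained_variance_ratio
        assert np.all(np.diff(r) <= 1e-12)
        assert r.sum() <= 1.0 + 1e-9

    def test_sample_permutation_invariance(self, rng):
        df = _frame(rng.normal(0, 1, (10, 6)))
        perm = ["s3", "s0", "s5", "s1", "s4", "s2"]
        r1 = pca(scale(df, "pareto")).explained_variance_ratio
        r2 = pca(scale(df[perm], "pareto")).explained_variance_ratio
        assert np.allclose(r1, r2)

    def test_deterministic_sign_convention(self, rng):
        df = _frame(rng.normal(0, 1, (10, 6)))
        res = pca(scale(df, "pareto"))
        for col in res.loadings.columns:
            load = res.loadings[col]
            assert load.iloc[np.argmax(load.abs().to_numpy())] > 0


class TestEllipse:
    def test_isotropic_scores_give_circle(self, rng):
        pts = rng.normal(0, 1, (5000, 2))
        ell = confidence_ellipse(pts, level=0.95)
        a, b = ell.semi_axes
        assert a / b == pytest.approx(1.0, abs=0.1)
        # radius follows the chi-square quantile rule
        assert a == pytest.approx(np.sqrt(stats.chi2.ppf(0.95, 2)), abs=0.1)

    def test_axis_scaling_equivariance(self, rng):
        pts = rng.normal(0, 1, (500, 2))
        pts[:, 1] *= 0.2  # dominant axis 0, so the major axis is stable
        e1 = confidence_ellipse(pts)
        pts_scaled = pts.copy()
        pts_scaled[:, 0] *= 3.0
        e2 = confidence_ellipse(pts_scaled)
        assert max(e2.semi_axes) == pytest.approx(3 * max(e1.semi_axes), rel=0.02)

    def test_coverage_simulation(self, rng):
        """~95% of bivariate-normal points fall inside the 95% ellipse."""
        pts = rng.multivariate_normal([1, -2], [[2.0, 0.7], [0.7, 1.0]], 20000)
        ell = confidence_ellipse(pts, level=0.95)
        cover = float(ell.contains(pts).mean())
        assert cover == pytest.approx(0.95, abs=0.01)


class TestHeatmap:
    @staticmethod
    def _meta():
        return [SampleMeta(f"s{j}", "WT" if j < 3 else "HOM") for j in range(6)]

    def _cmp(self, df):
        meta = self._meta()
        df = df.copy()
        df.columns = [m.sample_id for m in meta]
        return df, compare_groups(df, meta)

    def test_k_clamped_to_item_count(self, rng):
        df, cmp_ = self._cmp(_frame(rng.lognormal(0, 0.3, (8, 6))))
        spec = heatmap_select_cluster(df, cmp_, k=50)
        assert len(spec.selected) == 8

    def test_hand_worked_complete_linkage(self):
        """Four 1-D points 0,1,5,7: complete linkage merges (0,1)@1,
        (2,3)@2, then everything at the max inter-cluster distance 7."""
        from scipy.cluster.hierarchy import linkage

        pts = np.array([[0.0], [1.0], [5.0], [7.0]])
        link = linkage(pts, method="complete")
        expected = np.array(
            [[0, 1, 1.0, 2], [2, 3, 2.0, 2], [4, 5, 7.0, 4]]
        )
        assert np.allclose(link, expected)

    def test_planted_effects_reach_top_k(self):
        """10 species with a strong planted shift all rank inside the
        top-20 most significant."""
        rng = np.random.default_rng(5)
        base = rng.lognormal(0, 0.05, (100, 6))
        planted = [f"PC {12 + i}:0_18:1" for i in range(10)]
        names = planted + [f"PE {12 + i}:0_18:1" for i in range(90)]
        base[:10, 3:] *= 4.0
        df = pd.DataFrame(base, index=names,
                          columns=[m.sample_id for m in self._meta()])
        _, cmp_ = self._cmp(df)
        spec = heatmap_select_cluster(df, cmp_, k=20)
        assert set(planted) <= set(spec.selected)

    def test_selection_deterministic_under_ties(self):
        df = _frame(np.ones((4, 6)) + np.arange(6) * 0.0)
        df += np.arange(4)[:, None] * 0.0  # all identical -> all ties
        df.iloc[:, :] = [[1, 2, 3, 1, 2, 3]] * 4
        df2, cmp_ = self._cmp(df)
        s1 = heatmap_select_cluster(df2, cmp_, k=2).selected
        s2 = heatmap_select_cluster(df2, cmp_, k=2).selected
        assert s1 == s2 == sorted(s1)
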