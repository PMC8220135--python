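"""Group-level GLM, smoothness estimation, and cluster correction."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from pasmap.inference import (
    ClusterTable,
    estimate_smoothness_fwhm,
    extract_cluster_means,
    grf_cluster_correct,
    one_sample_t,
    permutation_cluster_correct,
    two_sample_t_adjusted,
)
from pasmap.pas import PASMap
from pasmap.synthetic import default_grid, ellipsoid_mask
from pasmap.volumes import build_hemisphere_mask


def _fake_maps(mask, stack):
    """Wrap a (n, V) array of PAS values into PASMap objects on `mask`."""
    eligible = (mask.label == 1) | (mask.label == 2)
    maps = []
    for row in stack:
        maps.append(
            PASMap(
                fc_inter=row, fc_intra=np.zeros_like(row), pas=row,
                n_inter_used=np.ones(row.size, dtype=int),
                n_intra_used=np.ones(row.size, dtype=int),
                r_threshold=0.2, mask=mask, eligible=eligible,
            )
        )
    return maps


@pytest.fixture
def mask12():
    return build_hemisphere_mask(ellipsoid_mask(default_grid((12, 12, 12), 3.0)))


class TestOneSampleT:
    def test_matches_scipy_reference(self, mask12, rng):
        n_vox = int(((mask12.label == 1) | (mask12.label == 2)).sum())
        stack = rng.standard_normal((10, n_vox))
        sm = one_sample_t(_fake_maps(mask12, stack))
        ref = stats.ttest_1samp(stack, 0.0, axis=0)
        np.testing.assert_allclose(sm.t, ref.statistic, atol=1e-10)
        assert sm.df == 9

    def test_symmetric_pairs_give_zero(self, mask12, rng):
        n_vox = int(((mask12.label == 1) | (mask12.label == 2)).sum())
        half = rng.standard_normal((5, n_vox))
        stack = np.vstack([half, -half])
        sm = one_sample_t(_fake_maps(mask12, stack))
        np.testing.assert_allclose(sm.t, 0.0, atol=1e-8)

    def test_zero_variance_capped(self, mask12):
        n_vox = int(((mask12.label == 1) | (mask12.label == 2)).sum())
        stack = np.ones((4, n_vox))
        sm = one_sample_t(_fake_maps(mask12, stack))
        assert np.all(np.isfinite(sm.t))
        assert np.all(sm.t >= 1e5)

    def test_too_few_subjects(self, mask12):
        n_vox = int(((mask12.label == 1) | (mask12.label == 2)).sum())
        with pytest.raises(ValueError):
            one_sample_t(_fake_maps(mask12, np.zeros((2, n_vox))))


class TestTwoSampleAdjusted:
    def test_reduces_to_pooled_t_with_orthogonal_covariates(self, mask12, rng):
        n_vox = 50
        eligible_n = int(((mask12.label == 1) | (mask12.label == 2)).sum())
        stack = rng.standard_normal((20, eligible_n))
        groups = np.array(["patients"] * 10 + ["controls"] * 10)
        # covariates orthogonal to the group indicator and to the data
        cov = pd.DataFrame({"age": np.tile([-1.0, 1.0], 10)})
        sm = two_sample_t_adjusted(_fake_maps(mask12, stack), groups, cov)
        g = (groups == "patients")
        ref = stats.ttest_ind(stack[g], stack[~g], equal_var=True)
        # with a centered orthogonal covariate the group t matches the pooled
        # two-sample t closely (df differs by 1, slightly different variance)
        corr = np.corrcoef(sm.t[:n_vox], ref.statistic[:n_vox])[0, 1]
        assert corr > 0.999

    def test_matches_normal_equations_oracle(self, mask12, rng):
        eligible_n = int(((mask12.label == 1) | (mask12.label == 2)).sum())
        stack = rng.standard_normal((14, eligible_n))
        groups = np.array(["patients"] * 7 + ["controls"] * 7)
        age = rng.normal(30, 8, 14)
        fd = rng.normal(0.04, 0.01, 14)
        cov = pd.DataFrame({"age": age, "mean_fd": fd})
        sm = two_sample_t_adjusted(_fake_maps(mask12, stack), groups, cov)
        # independent per-voxel solve via lstsq on the same design
        X = np.column_stack([
            np.ones(14), (groups == "patients").astype(float),
            age - age.mean(), fd - fd.mean(),
        ])
        for v in rng.integers(0, eligible_n, 25):
            beta, res, *_ = np.linalg.lstsq(X, stack[:, v], rcond=None)
            resid = stack[:, v] - X @ beta
            sigma2 = resid @ resid / (14 - 4)
            se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
            assert sm.t[v] == pytest.approx(beta[1] / se, abs=1e-8)
        assert sm.df == 10

    def test_nan_voxels_excluded_listwise(self, mask12, rng):
        eligible_n = int(((mask12.label == 1) | (mask12.label == 2)).sum())
        stack = rng.standard_normal((12, eligible_n))
        stack[3, 7] = np.nan
        groups = np.array(["patients"] * 6 + ["controls"] * 6)
        sm = two_sample_t_adjusted(_fake_maps(mask12, stack), groups, None)
        assert np.isnan(sm.t[7])
        assert not sm.analyzed[7]

    def test_rank_deficiency_rejected(self, mask12, rng):
        eligible_n = int(((mask12.label == 1) | (mask12.label == 2)).sum())
        stack = rng.standard_normal((10, eligible_n))
        groups = np.array(["patients"] * 5 + ["controls"] * 5)
        cov = pd.DataFrame({"age": (groups == "patients").astype(float)})
        with pytest.raises(ValueError, match="rank"):
            two_sample_t_adjusted(_fake_maps(mask12, stack), groups, cov)


class TestSmoothness:
    def test_smoothed_noise_recovers_fwhm(self, rng):
        # residual maps smoothed at a known FWHM: the roughness estimator
        # should recover it within ~15% on a modest grid
        from pasmap.preprocess import FWHM_TO_SIGMA

        shape = (24, 24, 24)
        fwhm_true = 2.5  # voxels
        n_sub = 30
        resid = rng.standard_normal((n_sub, *shape))
        resid = ndimage.gaussian_filter(
            resid, sigma=(0, *([fwhm_true * FWHM_TO_SIGMA] * 3)), mode="wrap"
        )
        eligible = np.ones(shape, dtype=bool)
        flat = resid.reshape(n_sub, -1)
        fwhm = estimate_smoothness_fwhm(flat, eligible, np.ones(flat.shape[1], bool))
        assert np.allclose(fwhm, fwhm_true, rtol=0.15)

    def test_constant_residuals_rejected(self, mask12):
        eligible_n = int(((mask12.label == 1) | (mask12.label == 2)).sum())
        eligible = (mask12.label == 1) | (mask12.label == 2)
        with pytest.raises(ValueError, match="smoothness|constant"):
            estimate_smoothness_fwhm(
                np.ones((5, eligible_n)), eligible, np.ones(eligible_n, bool)
            )


class TestClusterCorrection:
    def _planted_stat(self, mask12, rng, shift=2.0):
        eligible = (mask12.label == 1) | (mask12.label == 2)
        eligible_n = int(eligible.sum())
        stack = rng.standard_normal((24, eligible_n))
        stack = ndimage.gaussian_filter1d(stack, 1.0, axis=1)  # mild smoothness
        groups = np.array(["patients"] * 12 + ["controls"] * 12)
        # plant a blob: a sphere of voxels shifted in patients
        world = mask12.geometry.world_coordinates()[eligible]
        blob = np.linalg.norm(world - np.array([-9.0, 0.0, 0.0]), axis=1) <= 6.0
        stack[:12, blob] += shift
        return stack, groups, blob

    def test_planted_cluster_detected(self, mask12, rng):
        stack, groups, blob = self._planted_stat(mask12, rng)
        sm = two_sample_t_adjusted(_fake_maps(mask12, stack), groups, None)
        ct = grf_cluster_correct(sm)
        assert len(ct) >= 1
        # the top cluster contains the planted blob's peak region
        top = ct.label_grid == 1
        eligible = (mask12.label == 1) | (mask12.label == 2)
        assert (top[eligible] & blob).sum() > 0
        assert ct.table.peak_t.iloc[0] > 0

    def test_empty_suprathreshold_set(self, mask12, rng):
        eligible_n = int(((mask12.label == 1) | (mask12.label == 2)).sum())
        stack = rng.standard_normal((20, eligible_n)) * 0.01
        stack += rng.standard_normal((20, 1)) * 0  # pure noise
        groups = np.array(["patients"] * 10 + ["controls"] * 10)
        sm = two_sample_t_adjusted(_fake_maps(mask12, stack), groups, None)
        # extremely strict voxel threshold -> no clusters survive
        ct = grf_cluster_correct(sm, voxel_p=1e-12)
        assert len(ct) == 0
        assert ct.table.columns.tolist() == [
            "location_label", "x", "y", "z", "n_voxels", "peak_t", "cluster_p"
        ]

    def test_connectivity_changes_merging_not_voxels(self, mask12, rng):
        stack, groups, _ = self._planted_stat(mask12, rng)
        sm = two_sample_t_adjusted(_fake_maps(mask12, stack), groups, None)
        n_by_conn = {}
        for conn in (6, 26):
            ct = grf_cluster_correct(sm, connectivity=conn, cluster_p=1.0)
            n_by_conn[conn] = int(ct.table.n_voxels.sum())
        assert n_by_conn[6] == n_by_conn[26]

    def test_permutation_agrees_on_planted_effect(self, mask12, rng):
        stack, groups, blob = self._planted_stat(mask12, rng, shift=2.5)
        maps = _fake_maps(mask12, stack)
        sm = two_sample_t_adjusted(maps, groups, None)
        grf = grf_cluster_correct(sm)
        perm = permutation_cluster_correct(maps, groups, None, n_perm=200, seed=4)
        assert len(grf) >= 1 and len(perm) >= 1
        # every GRF-surviving cluster peak lies inside some permutation cluster
        for _, row in grf.table.iterrows():
            idx = np.round(np.linalg.solve(
                mask12.geometry.affine[:3, :3],
                np.array([row.x, row.y, row.z]) - mask12.geometry.affine[:3, 3],
            )).astype(int)
            assert perm.label_grid[tuple(idx)] > 0


class TestClusterMeans:
    def test_constant_and_single_voxel_clusters(self, mask12):
        eligible = (mask12.label == 1) | (mask12.label == 2)
        eligible_n = int(eligible.sum())
        stack = np.full((4, eligible_n), 3.25)
        label_grid = np.zeros(mask12.geometry.shape, dtype=np.int32)
        coords = np.argwhere(eligible)
        label_grid[tuple(coords[0])] = 1
        for c in coords[1:5]:
            label_grid[tuple(c)] = 2
        table = pd.DataFrame({
            "location_label": ["one_voxel", "four_voxels"],
            "x": [0.0, 0.0], "y": [0.0, 0.0], "z": [0.0, 0.0],
            "n_voxels": [1, 4], "peak_t": [5.0, 4.0], "cluster_p": [0.01, 0.01],
        })
        ct = ClusterTable(table=table, label_grid=label_grid, mask=mask12,
                          voxel_p=0.001, cluster_p=0.05)
        means = extract_cluster_means(_fake_maps(mask12, stack), ct)
        assert np.allclose(means["one_voxel"], 3.25)
        assert np.allclose(means["four_voxels"], 3.25)

    def test_checkerboard_averages_to_zero(self, mask12):
        eligible = (mask12.label == 1) | (mask12.label == 2)
        eligible_n = int(eligible.sum())
        stack = np.zeros((2, eligible_n))
        stack[:, 0], stack[:, 1] = 1.0, -1.0
        label_grid = np.zeros(mask12.geometry.shape, dtype=np.int32)
        coords = np.argwhere(eligible)
        label_grid[tuple(coords[0])] = 1
        label_grid[tuple(coords[1])] = 1
        table = pd.DataFrame({
            "location_label": ["pair"], "x": [0.0], "y": [0.0], "z": [0.0],
            "n_voxels": [2], "peak_t": [4.0], "cluster_p": [0.02],
        })
        ct = ClusterTable(table=table, label_grid=label_grid, mask=mask12,
                          voxel_p=0.001, cluster_p=0.05)
        means = extract_cluster_means(_fake_maps(mask12, stack), ct)
        assert np.allclose(means["pair"], 0.0)

    def test_empty_cluster_table_rejected(self, mask12):
        ct = ClusterTable(
            table=pd.DataFrame(columns=["location_label", "x", "y", "z",
                                        "n_voxels", "peak_t", "cluster_p"]),
            label_grid=np.zeros(mask12.geometry.shape, dtype=np.int32),
            mask=mask12, voxel_p=0.001, cluster_p=0.05,
        )
        eligible_n = int(((mask12.label == 1) | (mask12.label == 2)).sum())
        with pytest.raises(ValueError, match="empty"):
            extract_cluster_means(_fake_maps(mask12, np.zeros((3, eligible_n))), ct)
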