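"""PAS statistic: brute-force oracle, symmetry null, thresholds, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pasmap.pas import fisher_z, pas_map, pas_map_bruteforce, voxel_fc_profile
from pasmap.synthetic import default_grid, generate_subject
from pasmap.volumes import (
    LABEL_LEFT,
    LABEL_RIGHT,
    HemisphereMask,
    TimeSeriesVolume,
    build_hemisphere_mask,
)
from tests.conftest import make_volume


class TestFisherZ:
    @pytest.mark.parametrize(
        "r,expected",
        [(0.0, 0.0), (0.5, 0.5493061443340549), (-0.5, -0.5493061443340549),
         (0.3, 0.30951960420311175)],
    )
    def test_closed_form(self, r, expected):
        assert fisher_z(r) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(-0.999, 0.999))
    @settings(max_examples=50, deadline=None)
    def test_odd_symmetry(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    @pytest.mark.parametrize("r", [1.0, -1.0, 1.5])
    def test_out_of_domain_rejected(self, r):
        with pytest.raises(ValueError):
            fisher_z(r)


def _two_voxel_rows(grid):
    """Mask with a handful of eligible voxels on a small grid."""
    label = np.zeros(grid.shape, dtype=np.int8)
    return label


class TestVoxelFCProfile:
    def test_identical_contralateral_pair(self, rng):
        # seed matches exactly one contralateral voxel; everything else is
        # uncorrelated noise below the threshold
        grid = default_grid((4, 2, 2), 3.0)
        label = np.zeros(grid.shape, dtype=np.int8)
        label[1, 0, 0] = LABEL_LEFT
        label[2, 0, 0] = LABEL_RIGHT
        label[0, 0, 0] = LABEL_LEFT
        mask = HemisphereMask(geometry=grid, label=label)
        n_t = 500
        data = np.zeros((*grid.shape, n_t))
        shared = rng.standard_normal(n_t)
        data[1, 0, 0] = shared
        data[2, 0, 0] = shared  # mirror twin
        data[0, 0, 0] = rng.standard_normal(n_t)  # independent
        vol = make_volume(grid, data)
        inter, intra, counts = voxel_fc_profile(vol, mask, (1, 0, 0))
        assert inter == pytest.approx(1.0)
        assert counts["n_inter_used"] == 1
        assert counts["n_intra_used"] == 0 or intra < 1.0

    def test_uniform_correlation_case(self):
        # shared latent + per-voxel-scaled copies: all pairwise r identical
        grid = default_grid((4, 2, 2), 3.0)
        label = np.zeros(grid.shape, dtype=np.int8)
        label[:2] = LABEL_LEFT
        label[2:] = LABEL_RIGHT
        mask = HemisphereMask(geometry=grid, label=label)
        n_t = 400
        rng = np.random.default_rng(0)
        shared = rng.standard_normal(n_t)
        data = np.empty((*grid.shape, n_t))
        it = np.nditer(np.zeros(grid.shape), flags=["multi_index"])
        k = 0
        for _ in it:
            noise = rng.standard_normal(n_t)
            data[it.multi_index] = shared + noise
            k += 1
        vol = make_volume(grid, data)
        inter, intra, _ = voxel_fc_profile(vol, mask, (0, 0, 0))
        # same construction either side, so the two means must be close
        assert inter == pytest.approx(intra, abs=0.05)

    def test_constant_seed_rejected(self):
        grid = default_grid((4, 2, 2), 3.0)
        label = np.zeros(grid.shape, dtype=np.int8)
        label[:2] = LABEL_LEFT
        label[2:] = LABEL_RIGHT
        mask = HemisphereMask(geometry=grid, label=label)
        data = np.random.default_rng(0).standard_normal((*grid.shape, 50))
        data[0, 0, 0] = 1.0  # constant series
        with pytest.raises(ValueError, match="constant"):
            voxel_fc_profile(make_volume(grid, data), mask, (0, 0, 0))


class TestPASMapOracle:
    @pytest.mark.parametrize("combine", ["z_of_mean", "mean_of_z"])
    def test_matches_bruteforce_on_random_volume(self, combine, small_mask, rng):
        data = rng.standard_normal((*small_mask.geometry.shape, 40))
        vol = make_volume(small_mask.geometry, data)
        fast = pas_map(vol, small_mask, combine=combine)
        slow = pas_map_bruteforce(vol, small_mask, combine=combine)
        np.testing.assert_array_equal(fast.n_inter_used, slow.n_inter_used)
        np.testing.assert_array_equal(fast.n_intra_used, slow.n_intra_used)
        np.testing.assert_allclose(fast.pas, slow.pas, atol=1e-10)

    def test_matches_bruteforce_on_structured_volume(self, small_cohort_spec, small_mask):
        vol, _, _ = generate_subject(small_cohort_spec, "patients", 3)
        fast = pas_map(vol, small_mask)
        slow = pas_map_bruteforce(vol, small_mask)
        np.testing.assert_allclose(fast.pas, slow.pas, atol=1e-10)

    def test_chunking_bit_identical(self, small_mask, rng):
        data = rng.standard_normal((*small_mask.geometry.shape, 30))
        vol = make_volume(small_mask.geometry, data)
        ref = pas_map(vol, small_mask)
        for cs in (1, 7, 10_000):
            out = pas_map(vol, small_mask, chunk_size=cs)
            np.testing.assert_array_equal(
                np.nan_to_num(out.pas), np.nan_to_num(ref.pas)
            )
            np.testing.assert_array_equal(out.n_inter_used, ref.n_inter_used)


class TestPASProperties:
    def test_exchange_symmetric_volume_null_pas(self):
        # exactly equicorrelated volume: the correlation structure is
        # invariant under swapping hemispheres, so every seed's surviving
        # inter and intra means coincide and PAS vanishes identically
        from tests.conftest import exchange_symmetric_volume

        grid = default_grid((6, 4, 4), 3.0)
        label = np.zeros(grid.shape, dtype=np.int8)
        label[:3] = LABEL_LEFT
        label[3:] = LABEL_RIGHT
        mask = HemisphereMask(geometry=grid, label=label)
        vol = exchange_symmetric_volume(grid, label, c=0.5, n_t=120, seed=3)
        pm = pas_map(vol, mask)
        assert np.nanmax(np.abs(pm.pas)) < 1e-10

    def test_literal_mirror_twin_raises_inter_side(self, rng):
        # with literally mirrored series each seed keeps an r = 1 partner on
        # the inter side while the intra side excludes the seed itself, so
        # PAS is strictly positive wherever defined — the reason the null
        # test above uses the exchange-invariant construction instead
        grid = default_grid((6, 4, 4), 3.0)
        label = np.zeros(grid.shape, dtype=np.int8)
        label[:3] = LABEL_LEFT
        label[3:] = LABEL_RIGHT
        mask = HemisphereMask(geometry=grid, label=label)
        half = rng.standard_normal((3, 4, 4, 60))
        data = np.concatenate([half, half[::-1]], axis=0)
        pm = pas_map(make_volume(grid, data), mask)
        assert np.nanmin(pm.pas[~np.isnan(pm.pas)]) > 0

    def test_threshold_monotonicity(self, small_mask, rng):
        data = rng.standard_normal((*small_mask.geometry.shape, 40))
        vol = make_volume(small_mask.geometry, data)
        lo = pas_map(vol, small_mask, r_threshold=0.1)
        hi = pas_map(vol, small_mask, r_threshold=0.3)
        assert np.all(hi.n_inter_used <= lo.n_inter_used)
        assert np.all(hi.n_intra_used <= lo.n_intra_used)

    def test_invariant_under_linear_rescaling(self, small_mask, rng):
        data = rng.standard_normal((*small_mask.geometry.shape, 40))
        vol = make_volume(small_mask.geometry, data)
        scale = rng.uniform(0.5, 3.0, size=small_mask.geometry.shape)[..., None]
        shift = rng.uniform(-10, 10, size=small_mask.geometry.shape)[..., None]
        vol2 = make_volume(small_mask.geometry, data * scale + shift)
        np.testing.assert_allclose(
            pas_map(vol, small_mask).pas, pas_map(vol2, small_mask).pas, atol=1e-9
        )

    def test_threshold_is_strict_greater_than(self):
        # a correlation only survives when it is strictly above the
        # threshold: thresholding at the measured r itself must drop the
        # pair, while a threshold just below must keep it
        grid = default_grid((4, 2, 2), 3.0)
        label = np.zeros(grid.shape, dtype=np.int8)
        label[:2, 0, 0] = LABEL_LEFT
        label[2:, 0, 0] = LABEL_RIGHT
        mask = HemisphereMask(geometry=grid, label=label)
        n_t = 40
        rng = np.random.default_rng(5)
        a = rng.standard_normal(n_t)
        c = 0.4 * a + rng.standard_normal(n_t)
        data = np.zeros((*grid.shape, n_t))
        data[0, 0, 0] = a
        data[2, 0, 0] = c
        data[1, 0, 0] = rng.standard_normal(n_t)
        data[3, 0, 0] = rng.standard_normal(n_t)
        vol = make_volume(grid, data)
        r_ac = float(np.corrcoef(a, c)[0, 1])
        assert r_ac > 0.2
        # bracket the measured r: a threshold just above drops the pair, a
        # threshold just below keeps it (floating point rules out testing
        # exact equality through the engine's arithmetic)
        _, _, above = voxel_fc_profile(vol, mask, (0, 0, 0), r_threshold=r_ac + 1e-6)
        _, _, below = voxel_fc_profile(vol, mask, (0, 0, 0), r_threshold=r_ac - 1e-6)
        assert below["n_inter_used"] == above["n_inter_used"] + 1

    def test_undefined_side_is_flagged_not_zero(self, rng):
        # only-noise volume with a high threshold: many voxels survive nothing
        grid = default_grid((4, 4, 2), 3.0)
        label = np.zeros(grid.shape, dtype=np.int8)
        label[:2] = LABEL_LEFT
        label[2:] = LABEL_RIGHT
        mask = HemisphereMask(geometry=grid, label=label)
        data = rng.standard_normal((*grid.shape, 200))
        pm = pas_map(make_volume(grid, data), mask, r_threshold=0.9)
        assert pm.n_undefined == pm.pas.size
        assert np.isnan(pm.pas).all()
        assert (pm.n_inter_used == 0).all()

    def test_no_eligible_voxels_rejected(self, rng):
        grid = default_grid((4, 2, 2), 3.0)
        label = np.zeros(grid.shape, dtype=np.int8)
        mask = HemisphereMask(geometry=grid, label=label)
        with pytest.raises(ValueError, match="eligible"):
            pas_map(make_volume(grid, rng.standard_normal((*grid.shape, 10))), mask)
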