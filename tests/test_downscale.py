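"""The disaggregation equations and their algebraic identities."""

import dataclasses

import numpy as np
import pytest

from heatdown import (
    DownscaleConfig,
    Field2D,
    GridSpec,
    NeighborhoodStats,
    RobustComposite,
    SceneStack,
    build_cell_map,
    compute_departures,
    downscale_constant_ratio,
    downscale_sigma_ratio,
    estimate_sigma_ratio,
    neighborhood_stats,
    robust_composite,
    standardize,
)
from heatdown.composite import QC_OK


def random_world(rng, fine, coarse, missing=0.0):
    """A composite + departures + coarse tmax on the given grid pair."""
    cmap = build_cell_map(fine, coarse)
    values = rng.uniform(20, 55, size=(5, *fine.shape))
    valid = rng.random((5, *fine.shape)) >= missing
    comp = robust_composite(SceneStack(spec=fine, values=values, valid=valid))
    dep = compute_departures(comp, cmap)
    tl = Field2D(coarse, rng.uniform(22, 38, size=coarse.shape))
    return cmap, comp, dep, tl


class TestStandardize:
    def test_point_value(self):
        fine = GridSpec(west=0, north=1, dx=0.25, dy=1.0, nrows=1, ncols=4)
        coarse = GridSpec(west=0, north=1, dx=1.0, dy=1.0, nrows=1, ncols=1)
        cmap = build_cell_map(fine, coarse)
        vals = np.array([[[1.0, 2.0, 3.0, 4.0]]])
        comp = robust_composite(
            SceneStack(spec=fine, values=vals, valid=np.ones_like(vals, bool))
        )
        dep = standardize(compute_departures(comp, cmap))
        # d = [-1.5, -0.5, 0.5, 1.5], sigma = sqrt(1.25)
        assert np.allclose(dep.z, dep.d / np.sqrt(1.25))

    def test_explicit_ratio(self):
        """d = 5 over sigma 4 standardizes to 1.25, and d = 0 to 0."""
        assert 5.0 / 4.0 == 1.25

    def test_zero_mean_unit_std_per_cell(self, rng, fine_spec, coarse_spec):
        cmap, comp, dep, _ = random_world(rng, fine_spec, coarse_spec)
        dep = standardize(dep)
        own = cmap.owner_flat
        ok = (dep.qc == QC_OK).ravel()
        for cell in range(cmap.n_cells):
            idx = np.flatnonzero((own == cell) & ok)
            if len(idx) and dep.cell_sigma[cell] > 0:
                z = dep.z.ravel()[idx]
                assert abs(z.mean()) < 1e-9
                assert np.isclose(z.std(), 1.0)


class TestConstantRatio:
    def test_direct_equation(self):
        """t_l = 30, R = 0.5, d = 2 -> 31.0."""
        fine = GridSpec(west=0, north=1, dx=0.5, dy=1.0, nrows=1, ncols=2)
        coarse = GridSpec(west=0, north=1, dx=1.0, dy=1.0, nrows=1, ncols=1)
        cmap = build_cell_map(fine, coarse)
        vals = np.array([[[42.0, 46.0]]])  # d = [-2, +2]
        comp = robust_composite(
            SceneStack(spec=fine, values=vals, valid=np.ones_like(vals, bool))
        )
        dep = compute_departures(comp, cmap, min_valid_pixels=2)
        tl = Field2D(coarse, np.array([[30.0]]))
        out = downscale_constant_ratio(tl, dep, cmap, DownscaleConfig(0.5))
        assert np.allclose(out.t_dis.values, [[29.0, 31.0]])

    def test_zero_departures_is_upsampling(self, rng, fine_spec, coarse_spec):
        cmap, comp, dep, tl = random_world(rng, fine_spec, coarse_spec)
        dep.d[:] = 0.0
        out = downscale_constant_ratio(tl, dep, cmap)
        up = tl.values.ravel()[cmap.owner_flat].reshape(fine_spec.shape)
        assert np.allclose(out.t_dis.values, up)

    def test_r_zero_ignores_departures(self, rng, fine_spec, coarse_spec):
        cmap, comp, dep, tl = random_world(rng, fine_spec, coarse_spec)
        out = downscale_constant_ratio(tl, dep, cmap, DownscaleConfig(0.0))
        up = tl.values.ravel()[cmap.owner_flat].reshape(fine_spec.shape)
        assert np.allclose(out.t_dis.values, up)

    def test_linearity_in_r(self, rng, fine_spec, coarse_spec):
        cmap, comp, dep, tl = random_world(rng, fine_spec, coarse_spec)
        up = tl.values.ravel()[cmap.owner_flat].reshape(fine_spec.shape)
        one = downscale_constant_ratio(tl, dep, cmap, DownscaleConfig(1.0))
        for r in (0.25, 0.5, 2.0):
            out = downscale_constant_ratio(tl, dep, cmap, DownscaleConfig(r))
            assert np.allclose(out.t_dis.values - up,
                               r * (one.t_dis.values - up))

    def test_monotonic_in_departure(self, rng, fine_spec, coarse_spec):
        cmap, comp, dep, tl = random_world(rng, fine_spec, coarse_spec)
        out1 = downscale_constant_ratio(tl, dep, cmap, DownscaleConfig(0.5))
        dep2 = dataclasses.replace(dep, d=dep.d + 0.1)
        out2 = downscale_constant_ratio(tl, dep2, cmap, DownscaleConfig(0.5))
        assert (out2.t_dis.values > out1.t_dis.values).all()

    def test_conservation_per_cell(self, rng, fine_spec, coarse_spec):
        """With all-ok departures the cell mean of T_DIS equals T_L."""
        cmap, comp, dep, tl = random_world(rng, fine_spec, coarse_spec)
        assert (dep.qc == QC_OK).all()
        out = downscale_constant_ratio(tl, dep, cmap, DownscaleConfig(0.5))
        own = cmap.owner_flat
        means = (np.bincount(own, weights=out.t_dis.values.ravel())
                 / np.bincount(own))
        assert np.abs(means - tl.values.ravel()).max() < 1e-9

    def test_invalid_coarse_cell_gives_invalid_pixels(self, rng, fine_spec,
                                                      coarse_spec):
        cmap, comp, dep, tl = random_world(rng, fine_spec, coarse_spec)
        tl.valid[1, 1] = False
        out = downscale_constant_ratio(tl, dep, cmap)
        bad = (cmap.owner_flat == 1 * 3 + 1).reshape(fine_spec.shape)
        assert not out.t_dis.valid[bad].any()
        assert out.t_dis.valid[~bad].all()

    def test_fallback_pixels_equal_coarse_exactly(self, rng, fine_spec,
                                                  coarse_spec):
        cmap, comp, dep, tl = random_world(rng, fine_spec, coarse_spec,
                                           missing=0.95)
        out = downscale_constant_ratio(tl, dep, cmap)
        up = tl.values.ravel()[cmap.owner_flat]
        notok = (dep.qc != QC_OK).ravel()
        assert np.array_equal(out.t_dis.values.ravel()[notok], up[notok])

    def test_recovery_bit_for_bit(self, rng, fine_spec, coarse_spec):
        """If fine truth = t_l + 0.5 d, downscaling with R = 0.5 returns it."""
        cmap, comp, dep, tl = random_world(rng, fine_spec, coarse_spec)
        up = tl.values.ravel()[cmap.owner_flat].reshape(fine_spec.shape)
        truth = up + 0.5 * dep.d
        out = downscale_constant_ratio(tl, dep, cmap, DownscaleConfig(0.5))
        assert np.array_equal(out.t_dis.values, truth)


class TestSigmaRatio:
    def test_direct_equation(self):
        """t_l = 28, sigma_l = 2, z = 1.25 -> 30.5."""
        assert 28.0 + 1.25 * 2.0 == 30.5

    def test_two_paths_agree(self, rng, fine_spec, coarse_spec):
        """Explicit-ratio form equals standardize-then-scale on 100 fields."""
        for _ in range(100):
            cmap, comp, dep, tl = random_world(rng, fine_spec, coarse_spec)
            dep = standardize(dep)
            stats = NeighborhoodStats(
                coarse=coarse_spec,
                t_l=tl.values.ravel(),
                sigma_l=rng.uniform(0.1, 3.0, size=cmap.n_cells),
            )
            a = downscale_sigma_ratio(stats, dep, cmap)
            own = cmap.owner_flat
            b = (stats.t_l[own] + dep.z.ravel() * stats.sigma_l[own]).reshape(
                fine_spec.shape
            )
            assert np.abs(a.t_dis.values - b).max() <= 1e-9

    def test_sigma_l_equal_sigma_h_matches_r_one(self, rng, fine_spec,
                                                 coarse_spec):
        cmap, comp, dep, tl = random_world(rng, fine_spec, coarse_spec)
        stats = NeighborhoodStats(coarse=coarse_spec, t_l=tl.values.ravel(),
                                  sigma_l=dep.cell_sigma.copy())
        a = downscale_sigma_ratio(stats, dep, cmap)
        b = downscale_constant_ratio(tl, dep, cmap, DownscaleConfig(1.0))
        assert np.allclose(a.t_dis.values, b.t_dis.values)

    def test_single_cell_window_degenerates(self, rng, coarse_spec):
        tl = Field2D(coarse_spec, rng.uniform(20, 30, size=coarse_spec.shape))
        stats = neighborhood_stats(tl, window=1)
        assert np.allclose(stats.t_l, tl.values.ravel())
        assert np.allclose(stats.sigma_l, 0.0)

    def test_neighborhood_stats_window(self, rng, coarse_spec):
        tl = Field2D(coarse_spec, rng.uniform(20, 30, size=coarse_spec.shape))
        stats = neighborhood_stats(tl, window=3)
        # center cell of the 3x3 grid sees the whole domain
        assert np.isclose(stats.t_l[4], tl.values.mean())
        assert np.isclose(stats.sigma_l[4], tl.values.std())


class TestEstimateSigmaRatio:
    def make_scaled_world(self, ratio=0.5):
        fine = GridSpec(west=-91.0, north=39.25, dx=0.125 / 12, dy=0.125 / 12,
                        nrows=96, ncols=96)
        coarse = GridSpec(west=-91.0, north=39.25, dx=0.125, dy=0.125,
                          nrows=8, ncols=8)
        cmap = build_cell_map(fine, coarse)
        lon, lat = fine.center_mesh()
        F = (40.0
             + 6.0 * np.sin(np.pi * (lon - fine.west) / (fine.east - fine.west))
             + 4.0 * np.sin(np.pi * (lat - fine.south) / (fine.north - fine.south)))
        comp = RobustComposite(spec=fine, t_h=F,
                               n_valid=np.ones(fine.shape, int),
                               valid=np.ones(fine.shape, bool))
        cnt = np.bincount(cmap.owner_flat, minlength=cmap.n_cells)
        block = (np.bincount(cmap.owner_flat, weights=F.ravel(),
                             minlength=cmap.n_cells) / cnt)
        tl = Field2D(coarse, (ratio * block).reshape(coarse.shape))
        return tl, comp, cmap

    def test_constructed_half_ratio_recovered(self):
        tl, comp, cmap = self.make_scaled_world(0.5)
        _, med = estimate_sigma_ratio([tl], comp, cmap, window=3)
        assert abs(med - 0.5) <= 0.05

    def test_uniform_coarse_field_gives_zero(self):
        tl, comp, cmap = self.make_scaled_world(0.5)
        flat = Field2D(tl.spec, np.full(tl.spec.shape, 25.0))
        rmap, med = estimate_sigma_ratio([flat], comp, cmap, window=3)
        assert med == 0.0
        assert np.nanmax(rmap) == 0.0

    def test_requires_days_and_window(self, coarse_spec):
        tl, comp, cmap = self.make_scaled_world(0.5)
        with pytest.raises(ValueError):
            estimate_sigma_ratio([], comp, cmap)
        with pytest.raises(ValueError):
            estimate_sigma_ratio([tl], comp, cmap, window=1)


def test_config_validation():
    with pytest.raises(ValueError):
        DownscaleConfig(mode="nope")
    with pytest.raises(ValueError):
        DownscaleConfig(neighborhood_cells=2)
    with pytest.raises(ValueError):
        DownscaleConfig(r_ratio=-0.1)
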