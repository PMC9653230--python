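"""Coarse-graining: order fields, stress fields, profiles."""

import math

import numpy as np
import pytest

from rodcolony.dynamics import Domain
from rodcolony.fields import (FieldGrid, GridSpec, RegionSpec, delta_sigma,
                              order_field, overlap_area, profile,
                              region_order, region_stress, stress_field,
                              _clip_fraction)
from rodcolony.fixtures import random_gas, snapshot_from_rods, single_rod
from rodcolony.mechanics import Rod
from rodcolony.params import ModelParams


def two_rod_snapshot(delta=0.9, l=4.0, Y=200.0):
    p = ModelParams(lmax=6.0, Y=Y)
    rods = [Rod(0, np.array([-delta / 2, 0.0]), math.pi / 2, l, l, 1.0),
            Rod(1, np.array([delta / 2, 0.0]), math.pi / 2, l, l, 1.0)]
    return snapshot_from_rods(rods, p, Domain("open", 40.0, 40.0)), p


class TestOrderField:
    def test_aligned_rods_fully_ordered(self):
        p = ModelParams(lmax=6.0)
        rods = [Rod(k, np.array([2.0 * k - 3.0, 0.0]), math.pi / 2,
                    4.0, 4.0, 1.0) for k in range(4)]
        snap = snapshot_from_rods(rods, p, Domain("open", 20.0, 20.0))
        f = order_field(snap, GridSpec.cover(20.0, 20.0, 2.0))
        xi = f.xi[f.occupied]
        assert np.nanmin(xi) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(f.phi_mean[f.occupied], math.pi / 2, atol=1e-9)

    def test_crossed_rods_cancel(self):
        p = ModelParams(lmax=6.0)
        rods = [Rod(0, np.zeros(2), 0.0, 4.0, 4.0, 1.0),
                Rod(1, np.zeros(2), math.pi / 2, 4.0, 4.0, 1.0)]
        snap = snapshot_from_rods(rods, p, Domain("open", 20.0, 20.0))
        # one big cell covering both rods entirely
        f = order_field(snap, GridSpec(-10, -10, 20.0, 1, 1))
        assert f.xi[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_nematic_pi_symmetry(self):
        p = ModelParams(lmax=6.0)
        rng = np.random.default_rng(2)
        grid = GridSpec.cover(30.0, 30.0, 2.0)
        rods = [Rod(k, rng.uniform(-8, 8, 2), rng.uniform(0, math.pi),
                    3.0, 3.0, 1.0) for k in range(12)]
        flipped = [Rod(r.id, r.r, r.phi + math.pi, r.l_rest, r.l, r.gamma)
                   for r in rods]
        d = Domain("open", 30.0, 30.0)
        fa = order_field(snapshot_from_rods(rods, p, d), grid)
        fb = order_field(snapshot_from_rods(flipped, p, d), grid)
        np.testing.assert_allclose(fa.Xi[fa.occupied], fb.Xi[fb.occupied],
                                   atol=1e-12)

    def test_xi_bounded(self):
        snap = random_gas(60, 40.0, 40.0, 6.0, seed=3)
        f = order_field(snap, GridSpec.cover(40.0, 40.0, 2.0))
        xi = f.xi[f.occupied]
        assert (xi >= 0.0).all() and (xi <= 1.0 + 1e-12).all()

    def test_empty_cells_flagged_not_zero(self):
        snap = single_rod(0.0, 0.0, 0.0, 4.0)
        f = order_field(snap, GridSpec.cover(40.0, 40.0, 2.0))
        assert np.isnan(f.xi[~f.occupied]).all()
        assert f.occupied.any() and not f.occupied.all()


class TestOverlapArea:
    def test_full_containment_matches_footprint(self):
        rod = Rod(0, np.array([0.3, -0.2]), 0.7, 4.0, 4.0, 1.0)
        a = overlap_area(rod, (-4.0, -4.0, 8.0, 8.0))
        true = 4.0 * 1.0 - (4.0 - math.pi) * 0.25
        assert a == pytest.approx(true, rel=0.02)

    def test_symmetric_straddle_splits_evenly(self):
        rod = Rod(0, np.zeros(2), math.pi / 2, 4.0, 4.0, 1.0)
        left = overlap_area(rod, (-4.0, -4.0, 4.0, 8.0))
        right = overlap_area(rod, (0.0, -4.0, 4.0, 8.0))
        assert left == pytest.approx(right, rel=1e-9)

    def test_partition_over_grid_cells(self):
        """Summed per-cell overlap areas reproduce the analytic
        spherocylinder footprint l*2R - (4-pi)R^2 within 2%."""
        rng = np.random.default_rng(7)
        grid = GridSpec.cover(24.0, 24.0, 2.0)
        for _ in range(10):
            l = rng.uniform(1.0, 6.0)
            snap = single_rod(rng.uniform(-3, 3), rng.uniform(-3, 3),
                              rng.uniform(0, math.pi), l)
            f = order_field(snap, grid)
            true = l - (4.0 - math.pi) * 0.25
            assert f.Z.sum() == pytest.approx(true, rel=0.02)


class TestStressField:
    def test_no_contacts_zero_everywhere(self):
        snap = single_rod(0.0, 0.0, 0.0, 4.0)
        f = stress_field(snap, GridSpec.cover(40.0, 40.0, 2.0))
        assert np.all(f.sigma == 0.0)

    def test_single_bond_hand_value(self):
        """Two parallel vertical rods at spacing Delta in one cell:
        sigma_xx = -fx * Delta / dV, other components zero."""
        delta = 0.9
        snap, p = two_rod_snapshot(delta=delta)
        grid = GridSpec(-2.0, -2.0, 4.0, 1, 1)  # one cell covers both
        f = stress_field(snap, grid)
        fx = p.hertz_prefactor * (1.0 - delta) ** 1.5
        assert f.sigma[0, 0, 0, 0] == pytest.approx(-fx * delta / 16.0,
                                                    rel=1e-12)
        assert f.sigma[0, 0, 1, 1] == pytest.approx(0.0, abs=1e-14)
        assert f.sigma[0, 0, 0, 1] == pytest.approx(0.0, abs=1e-14)

    def test_tensor_symmetry_for_central_forces(self):
        # disc-shaped rods (l = 2R): every contact force is central
        # (along the centre-to-centre line), so F (x) r_kl is symmetric
        # per cell to round-off
        p = ModelParams(lmax=2.0)
        rng = np.random.default_rng(11)
        rods = [Rod(k, rng.uniform(-10, 10, 2), rng.uniform(0, math.pi),
                    1.0, 1.0, 1.0) for k in range(120)]
        snap = snapshot_from_rods(rods, p, Domain("open", 40.0, 40.0))
        assert snap.n_contacts > 10
        f = stress_field(snap, GridSpec.cover(40.0, 40.0, 2.0))
        smax = np.abs(f.sigma).max()
        assert smax > 0
        asym = np.abs(f.sigma[..., 0, 1] - f.sigma[..., 1, 0]).max()
        assert asym <= 1e-10 * smax

    def test_grid_refinement_preserves_integral(self):
        snap = random_gas(80, 40.0, 40.0, 6.0, seed=11)
        tot = {}
        for h in (2.0, 1.0):
            f = stress_field(snap, GridSpec.cover(40.0, 40.0, h))
            tot[h] = (f.sigma * h * h).sum(axis=(0, 1))
        np.testing.assert_allclose(tot[2.0], tot[1.0], rtol=0.01,
                                   atol=1e-12)

    def test_contactless_snapshot_rejected(self):
        snap = single_rod(0.0, 0.0, 0.0, 4.0)
        snap.c_i = None
        with pytest.raises(ValueError):
            stress_field(snap, GridSpec.cover(10.0, 10.0, 2.0))


class TestBondPartition:
    def test_lambda_sums_to_one_for_interior_bonds(self):
        rng = np.random.default_rng(4)
        grid = GridSpec.cover(20.0, 20.0, 2.0)
        for _ in range(200):
            a = rng.uniform(-5, 5, 2)
            b = a + rng.uniform(-4, 4, 2)
            lam = 0.0
            for ix in range(grid.nx):
                for iy in range(grid.ny):
                    xmin = grid.x0 + ix * grid.h
                    ymin = grid.y0 + iy * grid.h
                    lam += _clip_fraction(a[0], a[1], b[0], b[1],
                                          xmin, xmin + grid.h,
                                          ymin, ymin + grid.h)
            assert lam == pytest.approx(1.0, abs=1e-9)


class TestDeltaSigma:
    def test_trivial_values(self):
        assert delta_sigma(np.diag([-2.0, -2.0])) == 0.0
        assert delta_sigma(np.diag([-1.0, 0.0])) == 1.0
        assert delta_sigma(np.diag([0.0, -1.0])) == -1.0
        assert math.isnan(delta_sigma(np.zeros((2, 2))))

    def test_sign_convention_ignores_compression_sign(self):
        assert delta_sigma(np.diag([2.0, -1.0])) == \
            delta_sigma(np.diag([-2.0, -1.0]))


class TestProfileAndRegions:
    def test_constant_field_constant_profile(self):
        grid = GridSpec.cover(20.0, 20.0, 2.0)
        sigma = np.zeros((grid.nx, grid.ny, 2, 2))
        sigma[..., 0, 0] = -1.5
        fgs = [FieldGrid(grid=grid, sigma=sigma)] * 3
        pos, mean, stderr, n = profile(
            fgs, RegionSpec.cut("y", slab=10.0), "sigma_xx")
        assert np.allclose(mean, -1.5)
        assert np.allclose(stderr, 0.0)
        assert n == 3

    def test_slab_outside_grid_rejected(self):
        grid = GridSpec.cover(20.0, 20.0, 2.0)
        fgs = [FieldGrid(grid=grid,
                         sigma=np.zeros((grid.nx, grid.ny, 2, 2)))]
        with pytest.raises(ValueError):
            profile(fgs, RegionSpec.cut("y", coordinate=100.0, slab=2.0),
                    "sigma_xx")

    def test_region_stress_matches_field_average(self):
        snap = random_gas(60, 40.0, 40.0, 6.0, seed=9)
        region = RegionSpec.rect((0.0, 0.0), 16.0, 16.0)
        direct = region_stress(snap, region)
        f = stress_field(snap, GridSpec(-8.0, -8.0, 2.0, 8, 8))
        grid_avg = f.sigma.mean(axis=(0, 1))
        np.testing.assert_allclose(direct, grid_avg, rtol=1e-9, atol=1e-13)

    def test_region_order_of_aligned_state_is_one(self):
        p = ModelParams(lmax=6.0)
        rods = [Rod(k, np.array([1.5 * k - 3.0, 0.0]), math.pi / 2,
                    4.0, 4.0, 1.0) for k in range(5)]
        snap = snapshot_from_rods(rods, p, Domain("open", 20.0, 20.0))
        xi = region_order(snap, RegionSpec.rect((0, 0), 10.0, 6.0))
        assert xi == pytest.approx(1.0, abs=1e-9)
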