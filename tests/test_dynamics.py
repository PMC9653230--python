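"""Time evolution: growth, division, removal, determinism, columns."""

import math

import numpy as np
import pytest
from scipy import stats

from rodcolony.dynamics import (Domain, RunConfig, SimState, divide,
                                initial_rods, remove_exited, run,
                                run_frozen_column, step)
from rodcolony.mechanics import Rod
from rodcolony.params import ModelParams


def make_state(rods, params=None, domain=None, seed=1):
    params = params or ModelParams(lmax=6.0)
    domain = domain or Domain("open", 40.0, 40.0)
    st = SimState(params, domain, seed=seed)
    st.add_rods(rods)
    return st


class TestStep:
    def test_isolated_rod_grows_without_moving(self):
        p = ModelParams(lmax=6.0)
        r0 = Rod(0, np.array([1.0, -2.0]), 0.7, 4.0, 4.0, 1.1)
        st = make_state([r0], params=p)
        step(st)
        assert st.x[0] == pytest.approx(1.0, abs=1e-15)
        assert st.y[0] == pytest.approx(-2.0, abs=1e-15)
        assert st.phi[0] == pytest.approx(0.7, abs=1e-15)
        assert st.l_rest[0] == pytest.approx(
            4.0 + p.dt * 1.1 * p.lmax / 2.0, rel=1e-12)

    def test_overlapping_parallel_rods_separate_monotonically(self):
        p = ModelParams(lmax=6.0)
        rods = [Rod(0, np.array([-0.3, 0.0]), math.pi / 2, 4.0, 4.0, 1.0),
                Rod(1, np.array([0.3, 0.0]), math.pi / 2, 4.0, 4.0, 1.0)]
        st = make_state(rods, params=p)
        gaps = []
        for _ in range(300):
            step(st)
            gaps.append(st.x[1] - st.x[0])
        gaps = np.array(gaps)
        assert (np.diff(gaps) >= -1e-14).all()
        assert gaps[-1] > 0.6  # pushed most of the way to contact loss

    def test_symmetric_three_rod_column_centre_stationary(self):
        p = ModelParams(lmax=6.0)
        rods = [Rod(0, np.array([0.0, -3.8]), math.pi / 2, 4.0, 4.0, 1.0),
                Rod(1, np.array([0.0, 0.0]), math.pi / 2, 4.0, 4.0, 1.0),
                Rod(2, np.array([0.0, 3.8]), math.pi / 2, 4.0, 4.0, 1.0)]
        st = make_state(rods, domain=Domain("column", 10.0, 40.0))
        for _ in range(50):
            step(st)
        centre = list(st.ids[: st.n]).index(1)
        assert st.y[centre] == pytest.approx(0.0, abs=1e-12)


class TestDivide:
    def test_daughter_geometry(self):
        p = ModelParams(lmax=6.0)
        rng = np.random.default_rng(0)
        mother = Rod(7, np.array([0.0, 0.0]), math.pi / 2, 6.0, 6.0, 1.0)
        a, b = divide(mother, p, rng)
        assert a.r == pytest.approx([0.0, -1.5])
        assert b.r == pytest.approx([0.0, 1.5])
        assert a.l_rest == b.l_rest == 3.0
        assert a.phi == b.phi == mother.phi
        # combined rest length conserved
        assert a.l_rest + b.l_rest == pytest.approx(mother.l_rest)

    def test_compression_deficit_split(self):
        p = ModelParams(lmax=6.0)
        rng = np.random.default_rng(0)
        mother = Rod(7, np.zeros(2), 0.0, 6.0, 5.8, 1.0)
        a, b = divide(mother, p, rng)
        assert a.l == pytest.approx(3.0 - 0.1)
        # daughters placed at +- l/4 of the actual length
        assert b.r[0] - a.r[0] == pytest.approx(5.8 / 2.0)

    def test_below_division_length_rejected(self):
        p = ModelParams(lmax=6.0)
        with pytest.raises(ValueError):
            divide(Rod(0, np.zeros(2), 0.0, 5.0, 5.0, 1.0), p,
                   np.random.default_rng(0))

    def test_growth_rates_uniform(self):
        # daughters redraw gamma ~ Uniform[3/4, 5/4] independently
        p = ModelParams(lmax=6.0)
        rng = np.random.default_rng(123)
        mother = Rod(0, np.zeros(2), 0.0, 6.0, 6.0, 1.0)
        gammas = []
        for _ in range(30_000):
            a, b = divide(mother, p, rng)
            gammas.extend((a.gamma, b.gamma))
        res = stats.kstest(gammas, stats.uniform(0.75, 0.5).cdf)
        assert res.pvalue > 0.01


class TestRemoval:
    def test_centre_point_criterion(self):
        d = Domain("channel", 20.0, 20.0)
        eps = 1e-6
        rods = [
            Rod(0, np.array([0.0, 10.0 + eps]), 0.0, 4.0, 4.0, 1.0),  # out
            # centre just inside, cap protruding past the outlet: kept
            Rod(1, np.array([0.0, 10.0 - eps]), math.pi / 2, 4.0, 4.0, 1.0),
            Rod(2, np.array([0.0, 0.0]), 0.0, 4.0, 4.0, 1.0),
        ]
        st = make_state(rods, domain=d)
        remove_exited(st)
        assert sorted(st.ids[: st.n]) == [1, 2]

    def test_open_domain_removes_on_all_sides(self):
        d = Domain("open", 20.0, 20.0)
        st = make_state([Rod(0, np.array([10.1, 0.0]), 0.0, 4.0, 4.0, 1.0),
                         Rod(1, np.array([-10.1, 0.0]), 0.0, 4.0, 4.0, 1.0),
                         Rod(2, np.array([0.0, -10.1]), 0.0, 4.0, 4.0, 1.0),
                         Rod(3, np.zeros(2), 0.0, 4.0, 4.0, 1.0)], domain=d)
        remove_exited(st)
        assert list(st.ids[: st.n]) == [3]

    def test_walls_never_delete(self):
        # a rod pushed beyond a channel wall is pushed back, not removed
        d = Domain("channel", 20.0, 20.0)
        st = make_state([Rod(0, np.array([9.9, 0.0]), math.pi / 2,
                             4.0, 4.0, 1.0)], domain=d)
        remove_exited(st)
        assert st.n == 1


class TestRun:
    def test_zero_generations_returns_initial_condition(self):
        cfg = RunConfig(geometry="channel", width=20.0, height=20.0,
                        lmax=4.0, seed=5, generations=0.0)
        res = run(cfg)
        assert len(res.snapshots) == 1
        assert res.snapshots[0].n == 4
        assert res.snapshots[0].time == 0.0

    def test_determinism_bit_identical(self):
        cfg = RunConfig(geometry="channel", width=20.0, height=20.0,
                        lmax=4.0, seed=9, generations=3.0,
                        snapshot_every=1.0)
        a = run(cfg)
        b = run(cfg)
        for sa, sb in zip(a.snapshots, b.snapshots):
            assert sa.n == sb.n
            np.testing.assert_array_equal(sa.x, sb.x)
            np.testing.assert_array_equal(sa.y, sb.y)
            np.testing.assert_array_equal(sa.phi, sb.phi)
            np.testing.assert_array_equal(sa.gamma, sb.gamma)
            np.testing.assert_array_equal(sa.c_fx, sb.c_fx)

    def test_initial_rods_respect_invariants(self):
        cfg = RunConfig(geometry="channel", width=30.0, height=30.0,
                        lmax=6.0, seed=3)
        rods = initial_rods(cfg, np.random.default_rng(3))
        assert len(rods) == 4
        for r in rods:
            assert 3.0 <= r.l_rest < 6.0
            assert 0.75 <= r.gamma <= 1.25
            assert np.abs(r.r).max() <= 3.0

    def test_rods_stay_inside_channel(self):
        cfg = RunConfig(geometry="channel", width=20.0, height=20.0,
                        lmax=4.0, seed=2, generations=6.0,
                        snapshot_every=2.0)
        res = run(cfg)
        last = res.snapshots[-1]
        assert last.n > 4
        assert np.abs(last.y).max() <= 10.0
        assert np.abs(last.x).max() <= 10.0


class TestFrozenColumn:
    def test_orientations_stay_vertical(self, frozen_column_run):
        for s in frozen_column_run.snapshots[:: 40]:
            assert np.all(s.phi == math.pi / 2)
            # daughter placement along the axis injects only the
            # round-off of cos(pi/2) into x
            assert np.abs(s.x).max() < 1e-12

    def test_expansion_velocity_profile(self, frozen_column_run):
        """Steady-state speed profile is linear in y with slope
        <gamma>/<1+g> (the rate at which column length is produced)."""
        from rodcolony.theory import steady_state_distribution

        snaps = frozen_column_run.snapshots
        dt_snap = snaps[1].time - snaps[0].time
        ys, vs = [], []
        for s0, s1 in zip(snaps[:-1], snaps[1:]):
            common, i0, i1 = np.intersect1d(s0.ids, s1.ids,
                                            return_indices=True)
            ys.append(s0.y[i0])
            vs.append((s1.y[i1] - s0.y[i0]) / dt_snap)
        ys = np.concatenate(ys)
        vs = np.concatenate(vs)
        slope = np.polyfit(ys, vs, 1)[0]
        dist = steady_state_distribution(6.0, (0.75, 1.25))
        assert slope == pytest.approx(dist.alpha, rel=0.05)

    def test_stress_vanishes_at_outlets(self, frozen_column_run):
        from rodcolony.fields import line_stress_profile

        edges = np.linspace(-25, 25, 26)
        prof = np.mean([line_stress_profile(s, edges)
                        for s in frozen_column_run.snapshots], axis=0)
        # outlet bins carry far less stress than the centre
        assert abs(prof[0]) < 0.15 * abs(prof[12])
        assert abs(prof[-1]) < 0.15 * abs(prof[12])


class TestSteadyState:
    def test_population_without_removal_grows_at_chi(self):
        """Before outlets matter, the cell count grows exponentially at
        the Euler-Lotka rate chi."""
        from rodcolony.theory import steady_state_distribution

        cfg = RunConfig(geometry="open", width=60.0, height=60.0, lmax=4.0,
                        seed=4, generations=6.0, snapshot_every=0.25)
        res = run(cfg)
        t = np.array([s.time for s in res.snapshots])
        n = np.array([float(s.n) for s in res.snapshots])
        sel = (t >= 1.0)  # skip the initial-condition transient
        growth = np.polyfit(t[sel], np.log(n[sel]), 1)[0]
        chi = steady_state_distribution(4.0, (0.75, 1.25)).chi
        assert growth == pytest.approx(chi, rel=0.03)
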