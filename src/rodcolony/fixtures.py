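"""Deterministic test configurations: column lattices and rod gases.

These stand-ins emulate emergent states of the simulator (the
quasi-columnar ordered phase, a disordered gas) so the field-extraction
and theory modules can be exercised without long runs.  They are
synthetic constructions, not simulation output.
"""

from __future__ import annotations

import math

import numpy as np

from .dynamics import Domain, Snapshot, SimState
from .mechanics import Rod
from .params import ModelParams
from .theory import steady_state_distribution

__all__ = ["snapshot_from_rods", "make_column_lattice", "random_gas",
           "single_rod"]


def snapshot_from_rods(rods, params: ModelParams, domain: Domain) -> Snapshot:
    """Build a snapshot (with resolved contacts) from a list of rods."""
    state = SimState(params, domain, seed=0,
                     capacity=max(1024, 2 * len(rods)))
    state.add_rods(rods)
    return state.snapshot()


def make_column_lattice(n: int, W: float, H: float, lmax: float,
                        dist=None, seed: int = 0,
                        params: ModelParams | None = None) -> Snapshot:
    """A lattice of n perfectly vertical single-cell columns.

    Columns sit at spacing Delta = W/n (overlapping when n 2R > W);
    each is filled bottom-to-top with rods whose lengths are i.i.d.
    draws from the steady-state length law l = (lmax/2)(1 + g) and whose
    vertical phases are independent across columns.  Within a column,
    rods touch cap-to-cap (zero axial force), so all stress is the
    passive inter-column repulsion.
    """
    params = params or ModelParams(lmax=lmax)
    if dist is None:
        dist = steady_state_distribution(lmax, params.gamma_range)
    rng = np.random.default_rng(seed)
    delta = W / n
    if delta > W:  # pragma: no cover - degenerate
        raise ValueError("infeasible packing")
    rods = []
    rid = 0
    lo, hi = params.gamma_range
    for col in range(n):
        xc = -0.5 * W + (col + 0.5) * delta
        # independent vertical phase per column
        l0 = 0.5 * lmax * (1.0 + dist.sample_g(rng, 1)[0, 0])
        yc = -0.5 * H - rng.uniform(0.0, l0) + 0.5 * l0
        while yc - 0.5 * l0 < 0.5 * H:
            if abs(yc) <= 0.5 * H:
                rods.append(Rod(id=rid, r=np.array([xc, yc]),
                                phi=0.5 * math.pi, l_rest=l0, l=l0,
                                gamma=float(rng.uniform(lo, hi))))
                rid += 1
            l_next = 0.5 * lmax * (1.0 + dist.sample_g(rng, 1)[0, 0])
            yc += 0.5 * l0 + 0.5 * l_next
            l0 = l_next
    domain = Domain("channel", W, H)
    return snapshot_from_rods(rods, params, domain)


def random_gas(n: int, W: float, H: float, lmax: float, seed: int = 0,
               params: ModelParams | None = None) -> Snapshot:
    """n randomly placed, randomly oriented rods in a box (overlaps
    allowed); useful for grid-refinement and partition checks."""
    params = params or ModelParams(lmax=lmax)
    rng = np.random.default_rng(seed)
    lo, hi = params.gamma_range
    rods = []
    for k in range(n):
        l0 = rng.uniform(0.5 * lmax, lmax)
        rods.append(Rod(
            id=k,
            r=np.array([rng.uniform(-0.5 * W + lmax, 0.5 * W - lmax),
                        rng.uniform(-0.5 * H + lmax, 0.5 * H - lmax)]),
            phi=rng.uniform(0, math.pi), l_rest=l0, l=l0,
            gamma=float(rng.uniform(lo, hi))))
    return snapshot_from_rods(rods, params, Domain("open", W, H))


def single_rod(x=0.0, y=0.0, phi=0.0, l=4.0, lmax: float = 6.0,
               params: ModelParams | None = None) -> Snapshot:
    params = params or ModelParams(lmax=lmax)
    rod = Rod(id=0, r=np.array([x, y]), phi=phi, l_rest=l, l=l, gamma=1.0)
    return snapshot_from_rods([rod], params,
                              Domain("open", 10 * l + 2, 10 * l + 2))
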