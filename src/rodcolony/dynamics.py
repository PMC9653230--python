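"""Time evolution of a growing-rod population.

The population lives in one of three geometries:

* ``channel`` -- confining Hertzian walls at x = +-W/2, absorbing
  outlets at y = +-H/2 (cells are removed once their *centre* crosses an
  outlet);
* ``open``    -- absorbing outlets on all four sides, no walls;
* ``column``  -- a single one-dimensional column: the orientational
  degree of freedom is frozen (all rods stay vertical), transverse
  motion is suppressed, outlets at y = +-H/2.

Dynamics are overdamped: v_i = mu_i F_i with the anisotropic Tirado
mobility tensor.  Rest lengths grow linearly, d l_rest/dt = gamma
lmax/2, so a cell with gamma = 1 divides exactly once per time unit.
Each newborn draws an independent growth rate, uniform on
``params.gamma_range``.  Integration uses an explicit Euler step with a
displacement cap of R/10 per step; a step that would exceed the cap is
retried with a halved time step (counted in the diagnostics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .mechanics import Rod
from .params import ModelParams

__all__ = [
    "Domain",
    "RunConfig",
    "Snapshot",
    "RunResult",
    "SimState",
    "divide",
    "step",
    "remove_exited",
    "initial_rods",
    "run",
    "run_frozen_column",
]

_KINDS = {"channel": _kernels.DOMAIN_CHANNEL,
          "open": _kernels.DOMAIN_OPEN,
          "column": _kernels.DOMAIN_COLUMN}


@dataclass(frozen=True)
class Domain:
    """Simulation domain; W and H are the x- and y-extents."""

    kind: str
    W: float
    H: float

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown domain kind {self.kind!r}")
        if self.W <= 0 or self.H <= 0:
            raise ValueError("domain extents must be positive")

    @property
    def kind_code(self) -> int:
        return _KINDS[self.kind]

    @property
    def outlets(self) -> tuple:
        if self.kind == "open":
            return ("x-", "x+", "y-", "y+")
        return ("y-", "y+")

    @property
    def walls(self) -> tuple:
        return ("x-", "x+") if self.kind == "channel" else ()


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one simulation run.

    ``generations`` is the total simulated time (in division times of a
    gamma = 1 cell); snapshots are taken every ``snapshot_every``
    generations starting at ``snapshot_start`` (plus the initial
    condition at t = 0 when ``snapshot_start`` is 0).
    """

    geometry: str = "channel"
    width: float = 50.0
    height: float = 50.0
    lmax: float = 6.0
    Y: float = 200.0
    kc: float = -1.0
    zeta0: float = 1e-4
    dt: float = 1e-4
    seed: int = 1
    generations: float = 15.0
    burn_in_generations: float = 10.0
    snapshot_every: float = 0.5
    snapshot_start: float = 0.0
    gamma_range: tuple = (0.75, 1.25)
    n_initial: int = 4

    def params(self) -> ModelParams:
        return ModelParams(lmax=self.lmax, Y=self.Y, kc=self.kc,
                           zeta0=self.zeta0, dt=self.dt,
                           gamma_range=tuple(self.gamma_range))

    def domain(self) -> Domain:
        return Domain(self.geometry, self.width, self.height)

    def validate(self):
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.snapshot_every <= 0:
            raise ValueError("snapshot_every must be positive")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        d = self.domain()
        p = self.params()
        if min(d.W, d.H) <= p.lmax:
            raise ValueError("domain extents must exceed lmax")
        return self


@dataclass
class Snapshot:
    """Per-rod state plus the resolved contact list at one instant."""

    time: float
    ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    phi: np.ndarray
    l_rest: np.ndarray
    l: np.ndarray
    gamma: np.ndarray
    # contacts: indices into the rod arrays plus d and F_kl components
    c_i: np.ndarray
    c_j: np.ndarray
    c_dx: np.ndarray
    c_dy: np.ndarray
    c_fx: np.ndarray
    c_fy: np.ndarray

    @property
    def n(self) -> int:
        return self.ids.shape[0]

    @property
    def n_contacts(self) -> int:
        return self.c_i.shape[0]

    def g(self, lmax: float) -> np.ndarray:
        return 2.0 * self.l_rest / lmax - 1.0

    def rods(self) -> list:
        return [Rod(int(self.ids[k]), np.array([self.x[k], self.y[k]]),
                    float(self.phi[k]), float(self.l_rest[k]),
                    float(self.l[k]), float(self.gamma[k]))
                for k in range(self.n)]


@dataclass
class RunResult:
    config: RunConfig
    snapshots: list
    n_halvings: int
    max_overlap: float

    def __iter__(self):
        return iter(self.snapshots)


def _splitmix64(seed: int) -> np.uint64:
    mask = (1 << 64) - 1
    z = (int(seed) + 0x9E3779B97F4A7C15) & mask
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
    z = z ^ (z >> 31)
    return np.uint64(z if z != 0 else 0x1234567)


class SimState:
    """Array-backed population state (the fast path used by `run`)."""

    def __init__(self, params: ModelParams, domain: Domain, seed: int = 1,
                 capacity: int | None = None):
        self.params = params
        self.domain = domain
        self.seed = int(seed)
        if capacity is None:
            capacity = max(1024, int(3.0 * domain.W * domain.H
                                     / max(params.lmax, 1.0)) + 64)
        self._alloc(capacity)
        self.n = 0
        self.time = 0.0
        self.rng_state = np.array([_splitmix64(seed)], dtype=np.uint64)
        self.next_id = np.array([0], dtype=np.int64)
        self.n_halvings = 0
        self.max_overlap = 0.0
        # neighbour grid: cell side 2R + lmax/2, 5x5 sweep covers the
        # maximal interaction range lmax + 2R
        self.cell_size = 2.0 * params.R + 0.5 * params.lmax
        self.ncx = max(1, int(math.ceil(domain.W / self.cell_size)))
        self.ncy = max(1, int(math.ceil(domain.H / self.cell_size)))
        self.head = np.empty(self.ncx * self.ncy, dtype=np.int64)

    def _alloc(self, capacity: int):
        self.capacity = capacity
        for name in ("x", "y", "phi", "l_rest", "l", "gamma"):
            setattr(self, name, np.zeros(capacity))
        self.ids = np.zeros(capacity, dtype=np.int64)
        self.nxt = np.empty(capacity, dtype=np.int64)
        for name in ("ux", "uy", "fx", "fy", "tq", "load_p", "load_m"):
            setattr(self, name, np.zeros(capacity))

    def _grow(self):
        old = {name: getattr(self, name)
               for name in ("x", "y", "phi", "l_rest", "l", "gamma", "ids")}
        self._alloc(self.capacity * 2)
        for name, arr in old.items():
            getattr(self, name)[: arr.shape[0]] = arr

    def add_rods(self, rods):
        for rod in rods:
            k = self.n
            if k >= self.capacity:
                self._grow()
            self.x[k] = rod.r[0]
            self.y[k] = rod.r[1]
            self.phi[k] = rod.phi
            self.l_rest[k] = rod.l_rest
            self.l[k] = rod.l
            self.gamma[k] = rod.gamma
            self.ids[k] = rod.id
            self.n += 1
            self.next_id[0] = max(self.next_id[0], rod.id + 1)

    def rods(self) -> list:
        return [Rod(int(self.ids[k]), np.array([self.x[k], self.y[k]]),
                    float(self.phi[k]), float(self.l_rest[k]),
                    float(self.l[k]), float(self.gamma[k]))
                for k in range(self.n)]

    def advance_to(self, t_target: float):
        p, d = self.params, self.domain
        while True:
            n_arr = np.array([self.n], dtype=np.int64)
            t_arr = np.array([self.time])
            diag = np.zeros(2)
            status = _kernels.advance(
                self.x, self.y, self.phi, self.l_rest, self.l, self.gamma,
                self.ids, n_arr, t_arr, float(t_target),
                p.R, p.lmax, p.hertz_prefactor, p.kc, p.dt, p.zeta0,
                d.kind_code, d.W, d.H,
                p.gamma_range[0], p.gamma_range[1],
                self.rng_state, self.next_id,
                self.cell_size, self.ncx, self.ncy, self.head, self.nxt,
                self.ux, self.uy, self.fx, self.fy, self.tq,
                self.load_p, self.load_m, diag)
            self.n = int(n_arr[0])
            self.time = float(t_arr[0])
            self.n_halvings += int(diag[0])
            self.max_overlap = max(self.max_overlap, float(diag[1]))
            if status == 0:
                return
            self._grow()

    def snapshot(self) -> Snapshot:
        """Copy the live state and resolve the current contact list."""
        n = self.n
        p, d = self.params, self.domain
        cap = max(16, 12 * n)
        while True:
            ci = np.empty(cap, dtype=np.int64)
            cj = np.empty(cap, dtype=np.int64)
            cdx = np.empty(cap)
            cdy = np.empty(cap)
            cfx = np.empty(cap)
            cfy = np.empty(cap)
            m = _kernels.resolve_contacts(
                self.x, self.y, self.phi, self.l, n, p.R,
                p.hertz_prefactor, ci, cj, cdx, cdy, cfx, cfy,
                self.cell_size, self.ncx, self.ncy, self.head, self.nxt,
                d.W, d.H)
            if m >= 0:
                break
            cap *= 2
        return Snapshot(
            time=self.time,
            ids=self.ids[:n].copy(), x=self.x[:n].copy(),
            y=self.y[:n].copy(), phi=self.phi[:n].copy(),
            l_rest=self.l_rest[:n].copy(), l=self.l[:n].copy(),
            gamma=self.gamma[:n].copy(),
            c_i=ci[:m].copy(), c_j=cj[:m].copy(),
            c_dx=cdx[:m].copy(), c_dy=cdy[:m].copy(),
            c_fx=cfx[:m].copy(), c_fy=cfy[:m].copy())


def divide(rod: Rod, params: ModelParams, rng: np.random.Generator,
           next_id: int | None = None):
    """Split a rod at division length into two daughters.

    Daughters keep the mother's orientation, are placed at +- l/4 along
    the axis so the combined footprint equals the mother's, start at
    rest length lmax/2, split the mother's compression deficit equally,
    draw independent growth rates uniform on ``gamma_range`` and carry
    fresh ids (``next_id`` and ``next_id + 1``; defaults to continuing
    from the mother's id).
    """
    if rod.l_rest < params.lmax:
        raise ValueError("cannot divide below the division length lmax")
    if next_id is None:
        next_id = rod.id + 1
    deficit = rod.l_rest - rod.l
    u = rod.axis
    off = 0.25 * rod.l
    child_l = max(0.5 * params.lmax - 0.5 * deficit, 2.0 * params.R)
    lo, hi = params.gamma_range
    daughters = []
    for sgn, new_id in ((-1.0, next_id), (+1.0, next_id + 1)):
        daughters.append(Rod(
            id=new_id, r=rod.r + sgn * off * u, phi=rod.phi,
            l_rest=0.5 * params.lmax, l=child_l,
            gamma=float(rng.uniform(lo, hi))))
    return tuple(daughters)


def step(state: SimState) -> SimState:
    """Advance the state by one time step dt (in place)."""
    state.advance_to(state.time + state.params.dt)
    return state


def remove_exited(state: SimState) -> SimState:
    """Delete rods whose centre lies beyond an outlet (in place)."""
    d = state.domain
    keep = np.abs(state.y[: state.n]) <= 0.5 * d.H
    if d.kind == "open":
        keep &= np.abs(state.x[: state.n]) <= 0.5 * d.W
    idx = np.nonzero(keep)[0]
    m = idx.shape[0]
    for name in ("x", "y", "phi", "l_rest", "l", "gamma", "ids"):
        arr = getattr(state, name)
        arr[:m] = arr[idx]
    state.n = m
    return state


def _sample_rest_lengths(lmax, gamma_range, rng, size):
    """Rest lengths from the steady-state length law l = (lmax/2)(1+g)."""
    from .theory import steady_state_distribution

    dist = steady_state_distribution(lmax, gamma_range)
    g = dist.sample_g(rng, size)[:, 0]
    return 0.5 * lmax * (1.0 + g)


def initial_rods(config: RunConfig, rng: np.random.Generator) -> list:
    """Random few-rod initial condition at the domain centre.

    Orientations are uniform on [0, pi); centres are i.i.d. in a
    central box of side lmax, resampled until no pair of rods overlaps.
    Rest lengths are drawn from the steady-state length law to shorten
    transients.
    """
    from .mechanics import segment_closest_points

    def overlapping(a, b):
        _, _, d = segment_closest_points(a.spine(R=p.R), b.spine(R=p.R))
        return math.hypot(d[0], d[1]) <= 2.0 * p.R

    p = config.params()
    lrs = _sample_rest_lengths(config.lmax, p.gamma_range, rng,
                               config.n_initial)
    # an lmax-sized box cannot always hold n_initial non-overlapping
    # rods (short rods still need a rod width of clearance), so the box
    # is enlarged geometrically until placement succeeds
    half = 0.5 * config.lmax
    half_cap = 0.25 * min(config.width, config.height)
    while True:
        rods = []
        ok = True
        for k in range(config.n_initial):
            for _attempt in range(200):
                r = rng.uniform(-half, half, size=2)
                phi = rng.uniform(0.0, math.pi)
                cand = Rod(id=k, r=r, phi=phi, l_rest=lrs[k], l=lrs[k],
                           gamma=float(rng.uniform(*p.gamma_range)))
                if not any(overlapping(cand, other) for other in rods):
                    rods.append(cand)
                    break
            else:
                ok = False
                break
        if ok:
            return rods
        if half >= half_cap:
            raise RuntimeError("could not place non-overlapping seed rods")
        half = min(1.3 * half, half_cap)


def _initial_column(config: RunConfig, rng: np.random.Generator) -> list:
    """Seed rods for the frozen column: vertical, stacked at x = 0."""
    p = config.params()
    lrs = _sample_rest_lengths(config.lmax, p.gamma_range, rng,
                               config.n_initial)
    rods, yc = [], 0.0
    for k in range(config.n_initial):
        rods.append(Rod(id=k, r=np.array([0.0, yc + 0.5 * lrs[k]]),
                        phi=0.5 * math.pi, l_rest=lrs[k], l=lrs[k],
                        gamma=float(rng.uniform(*p.gamma_range))))
        yc += lrs[k] + 1e-3
    mid = 0.5 * (yc - 1e-3)
    for rod in rods:
        rod.r[1] -= mid
    return rods


def _snapshot_times(config: RunConfig) -> np.ndarray:
    t0 = max(config.snapshot_start, 0.0)
    times = np.arange(t0, config.generations + 1e-9, config.snapshot_every)
    if times.size == 0 or config.generations == 0:
        times = np.array([0.0]) if t0 == 0 else np.array([config.generations])
    return times


def run(config: RunConfig, initial=None) -> RunResult:
    """Run a channel / open-domain experiment; returns snapshot series.

    The initial condition is a small set of randomly oriented rods at
    the domain centre (see :func:`initial_rods`); the series is
    bit-reproducible for a given config and seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    state = SimState(config.params(), config.domain(), seed=config.seed)
    state.add_rods(initial if initial is not None else
                   initial_rods(config, rng))
    snaps = []
    for t in _snapshot_times(config):
        if t > state.time:
            state.advance_to(t)
        snaps.append(state.snapshot())
    return RunResult(config=config, snapshots=snaps,
                     n_halvings=state.n_halvings,
                     max_overlap=state.max_overlap)


def run_frozen_column(config: RunConfig, initial=None) -> RunResult:
    """Run a one-dimensional column with frozen orientations.

    All rods stay exactly vertical; transverse displacements and
    torques are suppressed, while growth, division, axial pushing and
    outlet removal proceed as usual.
    """
    if config.geometry != "column":
        config = RunConfig(**{**config.__dict__, "geometry": "column"})
    config.validate()
    rng = np.random.default_rng(config.seed)
    state = SimState(config.params(), config.domain(), seed=config.seed)
    state.add_rods(initial if initial is not None else
                   _initial_column(config, rng))
    snaps = []
    for t in _snapshot_times(config):
        if t > state.time:
            state.advance_to(t)
        snaps.append(state.snapshot())
    return RunResult(config=config, snapshots=snaps,
                     n_halvings=state.n_halvings,
                     max_overlap=state.max_overlap)
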