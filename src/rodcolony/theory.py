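"""Asymptotic predictions for perfectly aligned growing-rod colonies.

Three closed-form/asymptotic results are collected here:

* the steady-state joint law ``p(g, gamma)`` of normalised cell age
  ``g in [0, 1)`` and growth rate ``gamma`` for a binary-splitting
  population in which every newborn draws an independent growth rate and
  divides at age ``1 / gamma`` (an Euler-Lotka renewal calculation);

* the active stress parabola ``|sigma_yy|(y) = alpha (ymax^2 - y^2) /
  (2 mu_eff)`` of a one-dimensional growing column with outlet boundary
  conditions, where ``alpha = <gamma> / <1 + g>`` is the rate of line
  expansion and ``mu_eff`` an effective mobility;

* the passive inter-column stress ``sigma_xx`` of a compressed lattice
  of ``n`` vertical columns in a channel of width ``W``, from a counting
  argument for the Hertzian contacts between neighbouring columns.

All results depend only on model parameters, never on simulation
output, so they serve as independent oracles for the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import brentq

from .params import ModelParams
from .mechanics import mu_parallel

__all__ = [
    "AgeGrowthDistribution",
    "ActiveStressProfile",
    "ColumnState",
    "steady_state_distribution",
    "effective_mobility",
    "active_stress_profile",
    "passive_stress",
    "stress_unit_S0",
]

_NODES = 96  # Gauss-Legendre order; integrands are smooth, error << 1e-10


def _gauss(a: float, b: float, n: int = _NODES):
    x, w = leggauss(n)
    return 0.5 * (b - a) * x + 0.5 * (a + b), 0.5 * (b - a) * w


@dataclass(frozen=True)
class AgeGrowthDistribution:
    """Steady-state joint law of normalised age g and growth rate gamma."""

    chi: float
    gamma_range: tuple
    lmax: float
    mean_gamma: float
    mean_g: float

    @property
    def delta_l(self) -> float:
        """Length grown between birth and division, lmax / 2."""
        return self.lmax / 2.0

    @property
    def mean_one_plus_g(self) -> float:
        return 1.0 + self.mean_g

    @property
    def mean_length(self) -> float:
        """<l> = delta_l * <1 + g>, the mean space occupied per cell."""
        return self.delta_l * self.mean_one_plus_g

    @property
    def alpha(self) -> float:
        """Steady-state expansion rate <gamma> / <1 + g>."""
        return self.mean_gamma / self.mean_one_plus_g

    def p_g_gamma(self, g, gamma):
        """Joint density p(g, gamma), vectorised; zero outside support."""
        g = np.asarray(g, dtype=float)
        gamma = np.asarray(gamma, dtype=float)
        lo, hi = self.gamma_range
        dens = self._norm / gamma * np.exp(-self.chi * g / gamma)
        support = (g >= 0) & (g < 1) & (gamma >= lo) & (gamma <= hi)
        return np.where(support, dens, 0.0)

    @property
    def _norm(self) -> float:
        lo, hi = self.gamma_range
        if hi == lo:
            # degenerate point mass in gamma: density over g only
            c = self.chi / lo
            return c / (1.0 - np.exp(-c))
        ga, wa = _gauss(lo, hi)
        g, wg = _gauss(0.0, 1.0)
        G, GA = np.meshgrid(g, ga, indexing="ij")
        Z = np.einsum("i,j,ij->", wg, wa, np.exp(-self.chi * G / GA) / GA)
        return 1.0 / Z

    def expectation(self, func) -> float:
        """E[func(g, gamma)] by Gauss-Legendre quadrature."""
        lo, hi = self.gamma_range
        if hi == lo:
            g, wg = _gauss(0.0, 1.0)
            p = self._norm * np.exp(-self.chi * g / lo)
            return float(np.sum(wg * p * func(g, np.full_like(g, lo))))
        ga, wa = _gauss(lo, hi)
        g, wg = _gauss(0.0, 1.0)
        G, GA = np.meshgrid(g, ga, indexing="ij")
        P = self._norm / GA * np.exp(-self.chi * G / GA)
        W = np.outer(wg, wa)
        return float(np.sum(W * P * func(G, GA)))

    def sample_g(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw (g, gamma) pairs from the joint law by inverse transform.

        gamma is drawn from its marginal (by rejection against the
        uniform proposal), then g from the conditional truncated
        exponential.
        """
        lo, hi = self.gamma_range
        if hi == lo:
            gamma = np.full(size, lo)
        else:
            # marginal over gamma is prop. to (1 - exp(-chi/gamma))/chi
            out = np.empty(0)
            while out.size < size:
                cand = rng.uniform(lo, hi, size=2 * size)
                acc = (1.0 - np.exp(-self.chi / cand))
                keep = rng.uniform(0, 1, size=cand.size) < acc / acc.max()
                out = np.concatenate([out, cand[keep]])
            gamma = out[:size]
        c = self.chi / gamma
        u = rng.uniform(0, 1, size=size)
        g = -np.log(1.0 - u * (1.0 - np.exp(-c))) / c
        return np.column_stack([g, gamma])


def steady_state_distribution(
    lmax: float = 6.0, gamma_range: tuple = (0.75, 1.25)
) -> AgeGrowthDistribution:
    """Solve the renewal closure and build the steady-state (g, gamma) law.

    Each newborn draws gamma uniformly on ``gamma_range`` and divides in
    two at age ``1/gamma``.  The population then grows exponentially at
    the Malthusian rate chi fixed by the Euler-Lotka condition
    ``2 * E_gamma[exp(-chi/gamma)] = 1``, and the standing density over
    (g = gamma * age, gamma) is proportional to
    ``u(gamma) * exp(-chi g / gamma) / gamma``.
    """
    lo, hi = map(float, gamma_range)
    if not (0 < lo <= hi):
        raise ValueError("gamma_range must lie within (0, inf)")

    if hi == lo:
        chi = lo * np.log(2.0)
    else:
        ga, wa = _gauss(lo, hi)
        u = 1.0 / (hi - lo)

        def closure(chi):
            return 2.0 * np.sum(wa * u * np.exp(-chi / ga)) - 1.0

        lo_b, hi_b = 0.05, 4.0
        if closure(lo_b) * closure(hi_b) > 0:
            raise ValueError("renewal-equation root not bracketed")
        chi = brentq(closure, lo_b, hi_b, xtol=1e-13)

    dist = AgeGrowthDistribution(
        chi=float(chi), gamma_range=(lo, hi), lmax=float(lmax),
        mean_gamma=np.nan, mean_g=np.nan,
    )
    mg = dist.expectation(lambda g, ga: ga)
    mgg = dist.expectation(lambda g, ga: g)
    return AgeGrowthDistribution(
        chi=float(chi), gamma_range=(lo, hi), lmax=float(lmax),
        mean_gamma=mg, mean_g=mgg,
    )


def effective_mobility(dist: AgeGrowthDistribution, params: ModelParams) -> float:
    """Effective column mobility mu_eff = <l> / <1/mu_par(l)>.

    The drag of a column per unit length is the number density of cells
    ``1/<l>`` times the mean single-cell drag ``<1/mu_par>``, with cell
    length following the steady-state law ``l = (lmax/2)(1 + g)``.
    """
    dl = dist.delta_l

    def inv_mu(g, gamma):
        return 1.0 / mu_parallel(dl * (1.0 + g), params)

    return dist.mean_length / dist.expectation(inv_mu)


@dataclass(frozen=True)
class ActiveStressProfile:
    """Parabolic axial stress of a growing column with open ends."""

    ymax: float
    alpha: float
    mu_eff: float

    def sigma_yy(self, y):
        """Signed (compressive, negative) axial stress at height y."""
        y = np.asarray(y, dtype=float)
        return -self.alpha * (self.ymax**2 - y**2) / (2.0 * self.mu_eff)

    def abs_sigma_yy(self, y):
        return np.abs(self.sigma_yy(y))

    def v_y(self, y):
        """Expansion velocity profile v_y = alpha * y."""
        return self.alpha * np.asarray(y, dtype=float)

    @property
    def central_stress(self) -> float:
        """|sigma_yy(0)| = alpha * ymax^2 / (2 mu_eff)."""
        return self.alpha * self.ymax**2 / (2.0 * self.mu_eff)


def active_stress_profile(
    dist: AgeGrowthDistribution, mu_eff: float, ymax: float
) -> ActiveStressProfile:
    """Build the active stress parabola for a column of half-height ymax."""
    if ymax <= 0:
        raise ValueError("ymax must be positive")
    return ActiveStressProfile(ymax=float(ymax), alpha=dist.alpha, mu_eff=float(mu_eff))


@dataclass(frozen=True)
class ColumnState:
    """Passive-stress prediction for an n-column lattice in a channel."""

    n: int
    W: float
    Delta: float
    overlap: float
    fx: float
    sigma_xx_passive: float
    p_loss: float
    in_contact: bool


def passive_stress(
    n: int,
    W: float,
    dist: AgeGrowthDistribution,
    params: ModelParams,
    spacing: str = "W/n",
) -> ColumnState:
    """Predict the passive inter-column stress |sigma_xx| of a column lattice.

    Columns at spacing Delta overlap by ``2R - Delta`` and repel with the
    per-pair Hertzian force ``fx = Y sqrt(R/8) (2R - Delta)^{3/2}``.  Two
    neighbouring columns gain one touching pair per new cell in either
    column, i.e. ``2 / <l>`` pairs per unit column length, except when two
    cap regions coincide (probability ``p = 4R/<l>``), which voids one of
    the two:

        sigma_xx = (2/<l>) * fx * (1 - 0.5 * 4R/<l>)

    ``spacing`` selects the lattice convention: "W/n" (uniform
    compression, wall contacts sharing the column overlap) or
    "(W-2R)/(n-1)" (walls touching without overlap).
    """
    if n < 2:
        raise ValueError("need at least two columns")
    if spacing == "W/n":
        Delta = W / n
    elif spacing == "(W-2R)/(n-1)":
        Delta = (W - 2 * params.R) / (n - 1)
    else:
        raise ValueError(f"unknown spacing convention {spacing!r}")
    two_R = 2.0 * params.R
    overlap = two_R - Delta
    mean_l = dist.mean_length
    p_loss = 4.0 * params.R / mean_l
    if overlap <= 0:
        return ColumnState(n, W, Delta, max(overlap, 0.0) * 0.0, 0.0, 0.0,
                           p_loss, in_contact=False)
    fx = params.hertz_prefactor * overlap**1.5
    sigma = (2.0 / mean_l) * fx * (1.0 - 0.5 * p_loss)
    return ColumnState(n, W, Delta, overlap, fx, sigma, p_loss, in_contact=True)


def stress_unit_S0(params: ModelParams | None = None) -> float:
    """Stress unit S0: the predicted central |sigma_yy| for lmax = 6 cells
    in a domain of the standard height 200 (ymax = 100).

    Computed from the asymptotic theory so that S0 is available without
    running a full-height simulation.
    """
    if params is None:
        params = ModelParams(lmax=6.0)
    else:
        params = params.replace(lmax=6.0)
    dist = steady_state_distribution(6.0, params.gamma_range)
    mu = effective_mobility(dist, params)
    return active_stress_profile(dist, mu, ymax=100.0).central_stress
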