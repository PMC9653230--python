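"""Model parameters and unit conventions.

Lengths are measured in rod widths (2R = 1), so the default radius is
R = 0.5.  Time is measured in generations: a cell with growth rate
gamma = 1 doubles its rest length, and hence divides, in one time unit.
Stress carries one free overall scale set by the elastic prefactor Y and
the background drag zeta0; reported stresses are usually normalised by
the S0 unit defined in :mod:`rodcolony.theory`.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ModelParams:
    """Physical parameters of the growing-rod model.

    Attributes
    ----------
    R : float
        Rod radius.  Default 0.5 so the rod width 2R is the length unit.
    lmax : float
        Division length including the caps; newborns have rest length
        ``lmax / 2``.
    Y : float
        Elastic prefactor of the Hertzian contact law
        ``F = Y * sqrt(R/8) * (2R - |d|)**1.5``.
    kc : float
        Stiffness of the internal axial Hertzian spring,
        ``F = kc * (l_rest - l)**1.5``.  Defaults to ``Y * sqrt(R/8)`` so
        axial and lateral compliances are comparable.
    gamma_range : tuple
        Closed interval from which each newborn draws its growth rate.
    dt : float
        Integration time step in generations.
    zeta0 : float
        Background drag scale entering all mobilities as ``1 / zeta0``.
        The default keeps steady-state contact overlaps around 10% of
        the rod width in a 200-unit-tall domain with the default Y.
    """

    R: float = 0.5
    lmax: float = 6.0
    Y: float = 200.0
    kc: float = field(default=-1.0)
    gamma_range: tuple = (0.75, 1.25)
    dt: float = 1e-4
    zeta0: float = 1e-4

    def __post_init__(self):
        if self.kc < 0:
            object.__setattr__(self, "kc", self.Y * (self.R / 8.0) ** 0.5)
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.lmax < 4 * self.R:
            raise ValueError(
                "lmax must be at least twice the rod width so a newborn "
                "of length lmax/2 is at least as long as wide"
            )
        lo, hi = self.gamma_range
        if not (0 < lo <= hi):
            raise ValueError("gamma_range must lie within (0, inf)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.zeta0 <= 0:
            raise ValueError("zeta0 must be positive")

    @property
    def width(self) -> float:
        """Rod width 2R."""
        return 2.0 * self.R

    @property
    def hertz_prefactor(self) -> float:
        """Y * sqrt(R/8), the contact-force prefactor."""
        return self.Y * (self.R / 8.0) ** 0.5

    def replace(self, **kw) -> "ModelParams":
        from dataclasses import replace

        return replace(self, **kw)
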