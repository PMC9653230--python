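# Methods

## Model

Cells are 2D spherocylinders: a rectangle of fixed width 2R with
half-disc caps, described by centre **r**, orientation φ, rest length
`l_rest` and actual length `l` (both including caps). Lengths are in
rod widths (R = 0.5), time in generations: `l_rest` grows at rate
γ·lmax/2, so a γ = 1 cell goes from lmax/2 to lmax and divides in one
time unit. At division the two daughters keep φ, are placed at
±l/4 along the axis (their combined footprint is exactly the
mother's), start at rest length lmax/2, split the mother's compression
deficit equally, and draw independent growth rates γ ~ U[3/4, 5/4].

Pair interactions are Hertzian: with **d** the shortest connection
between the two centre-line segments,
`F = Y √(R/8) (2R − |d|)^{3/2} d̂` for |d| ≤ 2R, zero otherwise. For
exactly parallel overlapping centre lines the contact point is the
midpoint of the overlap interval — symmetric, torque-free for
mirror-symmetric configurations, and equal to the per-pair force the
passive column theory assumes. Exactly coincident centre lines have no
defined direction; the library raises a degenerate-contact error while
the integrator falls back to the centre-to-centre direction. Channel
walls exert the same law with **d** the connection from the centre
line to the wall, applied at the closest spine point (midpoint when
parallel). Torques are levers of the contact forces about the rod
centre.

Compressibility: each rod carries an internal Hertzian spring
`kc (l_rest − l)^{3/2}`. Every step, the compressive axial components
of the contact forces on the two rod halves are averaged into a tip
load P and the actual length relaxes quasi-statically to
`l = l_rest − (P/kc)^{2/3}` (clamped at one rod width). This is the
simplest scheme that transmits measurable stress through geometry
without virtual forces.

Motion is overdamped, **v** = μ**F**, with the Tirado–García de la
Torre short-cylinder mobilities in the aspect ratio p = l/2R:

    μ∥   = (ln p − 0.207 + 0.980/p − 0.133/p²) / (2π ζ0 l)
    μ⊥   = (ln p + 0.839 + 0.185/p + 0.233/p²) / (4π ζ0 l)
    μrot = 3 (ln p − 0.662 + 0.917/p − 0.050/p²) / (π ζ0 l³)

These satisfy μ∥ ≥ μ⊥ > 0 and are non-increasing in l over the whole
range p ≥ 1 used here.

## Parameters

| parameter | default | role |
|---|---|---|
| R | 0.5 | rod radius; 2R = 1 defines the length unit |
| lmax | 2–6 | division length; the control parameter of the study |
| Y | 200 | Hertz prefactor (stress scale) |
| kc | Y√(R/8) = 50 | axial spring stiffness |
| γ range | [3/4, 5/4] | per-cell growth-rate spread |
| ζ0 | 1e-4 | background drag; sets the mobility scale |
| dt | 1e-4 | integration step (generations) |

Only the ratio of elastic to drag forces matters for the emergent
state; ζ0 = 1e-4 puts the steady-state contact overlaps near 10% of a
rod width at the standard 200-unit domain height with Y = 200, keeping
contacts stiff but resolvable. Absolute stresses therefore carry one
free scale, which is why reported stresses are normalised by
S0 = |σyy(0)| predicted for lmax = 6 at domain height 200.

## Integration

Explicit Euler with a displacement cap: each step the maximum
per-rod displacement (|**v**|dt plus tip swing |ω|·l/2·dt) is checked
against R/10; a step that would exceed the cap is retried with dt
halved (for growth as well, so time stays consistent), and the event is
counted in the run diagnostics. Neighbour search is a uniform cell
grid of side 2R + lmax/2 rebuilt every step; a half-neighbourhood
(13-cell) sweep visits every unordered pair once and is exact for the
maximal interaction range lmax + 2R. Cells are removed when their
centre crosses an outlet. The whole loop is Numba-compiled and
bit-reproducible for a given configuration and seed (an internal
xorshift64* stream seeded via splitmix64 from the run seed).

The frozen-column geometry suppresses transverse displacements and
torques (orientations stay exactly vertical) while growth, division,
axial pushing and outlet removal proceed as usual; it isolates the
active stress channel.

Initial conditions: four rods with orientations uniform on [0, π),
centres i.i.d. in a central box of side lmax (enlarged geometrically by
30% when four non-overlapping rods do not fit, as happens for short
rods), rest lengths drawn from the steady-state length law to shorten
transients. Default burn-in before measurements is 10 generations.

## Field extraction

Order: Ξ(r) = Σk exp(2iφk) a(k,ΔV) / Z(r) on a square grid (default
h = 2), with a(k,ΔV) the overlap area of the rod footprint with the
cell, computed by supersampled rasterisation — at least 8×8 points per
cell and enough that the sample spacing stays below R/3, with linear
anti-aliasing at the footprint boundary; summed per-rod areas match the
analytic footprint to well under 2%. Empty cells (Z = 0) are flagged,
never counted as zero order; region aggregates weight by Z.

Stress: σ = −1/(2ΔV) Σk Σl≠k λkl **F**kl ⊗ **r**kl with λkl the exact
clipped fraction of the centre-to-centre segment inside the cell
(Liang–Barsky). Only cell–cell forces enter; wall forces and the
internal spring do not, so cells within lmax of a wall should be read
as boundary cells. **r**kl is the centre-to-centre vector as written
(the difference to the contact-point convention is second order in the
overlap). Compression is negative in σ; ΔΣ uses absolute values.
Region averages are computed directly from the contact list with exact
clipping; 1D column line stress uses the same bond partition in y
alone.

## Theory

The renewal construction: newborns draw γ ~ u(γ) and divide at age
1/γ, so the population grows at rate χ with 2⟨e^{−χ/γ}⟩u = 1 and the
standing density over (g = γ·age, γ) is ∝ u(γ)(1/γ)e^{−χg/γ}. All
moments use Gauss–Legendre quadrature (96 nodes per axis; the
integrands are analytic, so this is far below 1e-8 error). The
printed-form ambiguity of the density was resolved by this derivation;
it reproduces the reference averages ⟨γ⟩ ≈ 0.985, ⟨g⟩ ≈ 0.441.

Active stress: incompressible steady state gives ∂y vy = α =
⟨γ⟩/⟨1+g⟩ and force balance vy = μ ∂y σyy with μ_eff = ⟨l⟩/⟨μ∥⁻¹⟩
(drag per unit column length is ⟨μ∥⁻¹⟩/⟨l⟩). Integrating with
σyy(±ymax) = 0 yields the *symmetric* parabola |σyy| =
α (ymax² − y²)/(2μ_eff) — the form that both satisfies the outlet
boundary conditions and integrates the linear velocity profile; its
centre-to-half-height ratio is 4/3. We read μ = ⟨l⟩/⟨μ∥⁻¹⟩ rather
than ⟨l⟩·⟨μ∥⁻¹⟩⁻¹-with-other-weights and validate against the frozen
column, which matches within ~1% centrally; the factorised α =
⟨γ⟩/⟨1+g⟩ differs from ⟨γ/(1+g)⟩ by under 1% for this γ interval.

Passive stress: columns at spacing Δ = W/n (uniform compression; the
convention (W−2R)/(n−1) is exposed as an option and differs at
O(1/n)) repel with fx = Y√(R/8)(2R−Δ)^{3/2}. Each new cell in either
column opens one touching pair (2/⟨l⟩ per unit length), except when two
cap regions coincide (probability 4R/⟨l⟩), which voids one of the two:
σxx = (2/⟨l⟩) fx (1 − 2R/⟨l⟩). The synthetic lattice fixture measures
a few per cent *above* this because near-coincident caps still touch
diagonally with a weakened force — the counting argument treats them as
fully lost. The same sign of deviation is expected in emergent states.

## Synthetic data and what the tests show

The lattice fixture (perfect columns, i.i.d. steady-state lengths,
independent phases) emulates the emergent ordered state but has no
axial compression, no orientation fluctuations and no wall-driven
rearrangement; agreement there validates the stress extraction and the
counting argument, not the self-organisation. The emergent behaviour
itself is tested by the reduced-scale (50 × 50) channel runs: global
order ξ ≈ 1 and median ΔΣ < 0 for lmax = 6, partial order and ΔΣ > 0
for lmax = 2, and the transition of both quantities around lmax ≈ 4.
Reduced domains shift absolute values relative to full-scale (200 ×
200) colonies — order is enhanced and the column count is small enough
that ΔΣ fluctuates between seeds (occasional positive-ΔΣ seeds at
lmax = 6 are genuine minority states, which is why medians over seeds
are used). The shift matters most for short rods: at 50 × 50 the
lmax = 2 state is more ordered (ξ ≈ 0.6) than at full scale (ξ ≈ 0.5)
and sits almost exactly at the anisotropy crossing, so its central ΔΣ
is statistically zero (0.00 ± 0.03 across seeds and long time windows);
a 100 × 100 control recovers ξ = 0.52 and a positive ΔΣ, showing the
sign approaches the full-scale behaviour from below as the domain
grows. Problem sizes in the test-suite and acceptance protocols
(50 × 50 domains, 5 measured generations, 3–5 seeds, a 30-generation
frozen column, 100-unit-tall lattices) were chosen as the smallest
configurations at which these statements are stable.

## Numerical choices and edge cases

* Parallel-contact tie-break at the overlap midpoint (above).
* Segment distances validated against hierarchical brute-force grid
  minimisation to 1e-3 on random pairs, including exactly parallel and
  degenerate zero-length cases.
* Bond clipping uses half-open cell intervals so axis-aligned bonds
  lying on a cell edge are counted once; Σcells λ = 1 to 1e-9.
* Quadrature: Gauss–Legendre 96² for moments; χ by Brent on a bracket
  checked for sign change (raises if the interval does not bracket).
* Divisions of compressed rods clamp the daughter length at one rod
  width (relevant only for lmax = 2 under strong compression).
* The displacement cap makes dt self-correcting; runs report the
  number of halvings and the maximum overlap seen as diagnostics.

## Known limitations

2D only; no friction/adhesion/hydrodynamics; no noise except the
growth-rate draws; no nutrient or motility coupling; stress has no
kinetic contribution (overdamped); wall bonds are excluded from σ so
near-wall cells are boundary cells; full-scale (200-unit) sweeps and
the open-domain buckling statistics are runnable through
`rodcolony.experiments` but are outside the default test protocol.
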