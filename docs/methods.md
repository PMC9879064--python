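# Methods

## Physical model

The exposure rig is modelled as a 1D vertical stack: a well-mixed gas
chamber, a PDMS membrane (165 μm by default), the scaffold (hydrogel or
tissue slice, 300–800 μm), and optionally a media column.  Coordinates:
`z = 0` at the membrane–scaffold interface, positive into the sample.

Within each layer the dissolved oxygen concentration `C(z,t)` obeys

    ∂C/∂t = D ∂²C/∂z² − ρ_cell · sOCR · C/(K_m + C)

with Michaelis–Menten consumption.  The state variable of the solver is the
partial pressure `p` (mmHg), related to concentration by Henry's law
`C = α·p/760` with a per-layer solubility α.  Partial pressure — not
concentration — is continuous across material interfaces; this is the
standard Henry-law matching condition and avoids needing a PDMS solubility,
which is poorly constrained: only the product D·α of the membrane enters the
transmitted flux.  PDMS α therefore defaults to the water value
(1.1×10⁻⁶ mol/(cm³·atm)) and is overridable; the configuration loader warns
when the default is used.

Boundary conditions:

* bottom — Dirichlet in partial pressure, following the gas schedule.  The
  chamber is treated as ideally mixed; an optional first-order lag
  (`gas_chamber_lag_tau`) models finite washout.
* top — sealed (`no_flux`) by default.  The experimental top condition (a
  millilitre of media over a hydrogel, carbogen-bubbled bath around a slice)
  is not characterized well enough to pick anything sharper; a fixed-fraction
  Dirichlet top and an explicit media layer are provided for sensitivity
  analysis.  Among these options the sealed top gives the *largest*
  top-of-scaffold cycling amplitude, so suitability verdicts made with it are
  optimistic, not conservative.

The driving schedule is a square wave defined by events/h (60/h ⇒ 60 s
period), high/low O₂ fractions and duty 0.5 by default: each cycle starts
with the normoxic phase, phases are half-open intervals.  Gas fractions are
converted at the boundary via p = fraction × 760 mmHg.

## Units

Internally: cm, s, mol/cm³, mmHg, fractions in [0, 1].  User-facing %O₂ is
`100 × p/760`.  Built-in constants (cm²/s unless noted): O₂ in PDMS 3.5e-5,
in water 2.5e-5, in ECM-type hydrogel 1.87e-5; CO₂ in PDMS 2.2e-5, in water
2.1e-5; α(water) = 1.1e-6 mol/(cm³·atm).  The hydrogel value is stored as
the conventional rounded figure 1.87e-5 rather than recomputed as
0.75 × 2.5e-5 = 1.875e-5, so the worked diffusion-time examples (22 s at
500 μm, 57 s at 800 μm) reproduce exactly; the 75 %-of-water rule remains
available as a constructor for other gases.

The diffusion-time estimate is implemented verbatim as Δt = L²/6D.  The 1/6
factor is the 3D mean-square-displacement convention; the planar relaxation
time for these slabs is L²/2D, three times longer.  The formula is kept as
the field's conventional quick estimate and documented as optimistic — the
package's envelope analysis, not Δt, is the quantitative tool.

## Numerics

Vertex-centred finite volume.  Nodes are placed exactly on material
interfaces (≥ 21 nodes per layer, spacing ≤ `target_dz`, default 10 μm), so
every inter-node segment lies in one material and the interfacial
permeability D·α is exact — the harmonic-mean formula for cell-centred
schemes degenerates to the segment value here, and flux across the
membrane–scaffold junction is conserved to machine precision (the sealed
mass-conservation test holds to ~1e-12 relative).

Time stepping is θ-weighted implicit, backward Euler (θ = 1) by default:
unconditionally stable and robust for the square-wave boundary, at the cost
of first-order damping.  The trapezoidal option (θ = 0.5) is used where
amplitude fidelity against closed-form oracles matters.  Default
dt = period/600 (0.1 s at 60 events/h); the time grid inserts the square
wave's phase-change instants exactly so the drive is never smeared across a
step.  The Michaelis–Menten sink is solved by Newton iteration each step
(tolerance 1e-10, ≤ 25 iterations, error on non-convergence naming the time
step); solving the full nonlinearity rather than lagging the coefficient
keeps the sink below its saturation bound and the solution non-negative
(values below −1e-9 mmHg raise; smaller negatives are clipped to 0).
Linear (acellular) steps reduce to one banded solve.

Periodic steady state: whole cycles are iterated until every node's cycle
max and min (in %O₂) move < `psss_tol` (default 1e-3 %O₂) between
consecutive cycles; 500 μm stacks converge in ~14 cycles, 800 μm in ~26.

Validation oracles (all in the test suite): the exact slab frequency
response |cosh(γ(W−z))/cosh(γW)|, γ = √(iω/D) (agreement to 3.8e-5 in gain
at Δz = W/100, Δt = period/200); Fourier synthesis of the square-wave
envelope over 51 odd harmonics (< 1 % on amplitudes); the half-space erfc
step response at early times (< 5e-4); second-order spatial convergence
(error ratio ≈ 3.9 on grid halving); parabolic and cosh/cosh steady profiles
in the saturated (C ≫ K_m) and dilute (C ≪ K_m) consumption limits.  At
physiological pressures C = α·p sits one to two orders below the hepatocyte
K_m = 4.1e-6 mol/cm³, so the sink operates in its effectively-first-order
regime; the full Michaelis–Menten form is implemented regardless.

## Envelope analysis and design verdicts

The primary readout is the per-depth envelope over one converged cycle:
max, min, peak-to-peak amplitude, cycle mean (%O₂).  Homogeneity across
depths is quantified as the *range* (max-across-depths minus
min-across-depths) of the envelope maxima and of the minima, each compared
to a 2 %O₂ threshold; a range is used deliberately — a variance would carry
units of %² and could not be compared against a %O₂ criterion.

`design_report` runs to periodic steady state and declares a configuration
suitable iff the amplitude at the scaffold top is at least
`fidelity_threshold` × the driving amplitude and (optionally) homogeneity
passes.  Physics caps the achievable fidelity: for a 500 μm gel at
D = 1.87e-5 cm²/s under 60 events/h with a sealed top, the exact frequency
response limits the top-of-scaffold peak-to-peak swing to ≈ 19 % of the
drive (≈ 11 % with the membrane included), and 800 μm to ≈ 2 %.  Published
measurements in comparable rigs show larger high-z amplitudes than any 1D
sealed-column model permits, plausibly because the gas-permeable well walls
admit lateral oxygen exchange; lateral transport is outside this model's
scope, so measured envelope values are treated as qualitative context, not
validation targets.  Default thresholds should be chosen with the ~0.1–0.2
fidelity scale of the 1D model in mind.

## Flux-ratio estimate

`flux_ratio` compares consumption and diffusive resupply per unit area:
V'_con = ρ·sOCR·C̄·W/(K_m + C̄), V'_dif = D·α·ΔP/W.  C̄, the mean dissolved
concentration, is by convention taken at the arithmetic mean of the driving
fractions (10 %O₂ for a 20/0 schedule), converted via α; the choice is
documented and overridable, and the ratio is insensitive to it in the
C̄ ≪ K_m regime.  For the hepatocyte reference set (ρ = 5e5 cells/cm³,
sOCR = 1.22e-16 mol/(cell·s), K_m = 4.1e-6 mol/cm³, D = 1.2e-5 cm²/s,
W = 500 μm, ΔP = 152 mmHg) the package computes 1.5e-3 — comfortably below
the 0.015 negligibility bound quoted for this scenario, and still below it
at tenfold cell density.  We note that 0.015 is not recoverable from these
parameters under any physical C̄ (the saturated limit gives 7.6e-3); the
package reports what the formula yields and treats the bound, which carries
the scientific claim, as the criterion.

## Synthetic sensor benchmark

The generator emulates the verification measurement: an optical microprobe
at a fixed depth, modelled as a point sensor with first-order lag
(τ = t90/ln 10, t90 = 2 s per the probe class's quoted response time),
sampled at 1 Hz with additive i.i.d. Gaussian read noise of 0.2 %O₂.  The
noise level and rate are synthetic defaults (instrument values are not
published); the lag is applied on the solver's fine time grid, the trace is
then resampled to the sensor clock and noise is added per retained sample —
for i.i.d. noise this is distributionally identical to noising before
decimation and avoids correlating noise through interpolation.  Not
emulated: probe drift, photobleaching, and the ~40 μm tip's volume
averaging (≤ 8 % of a 500 μm scaffold; treated as a point).

Benchmark scenarios mirror the canonical measurement situations: 500/800 μm
hydrogels at 20/0 % and 15/5 %, and 300/500 μm tissue slices at 95/50 %,
all at 60 events/h, 3 cycles from normoxic equilibration, depths on a
100 μm ladder.  Slice kinetic parameters are synthetic stand-ins chosen once
from qualitative literature statements (D = 1.4e-5 cm²/s, below hydrogel
values, as reported for native tissue; ρ_cell = 8e7 cells/cm³ with
hepatocyte-like sOCR to represent high-metabolism tissue).  Every trace's
noise seed derives deterministically from the master seed, and the manifest
records ground truth, so regeneration is bit-identical.  Passing tests on
this benchmark demonstrate internal consistency of the forward and inverse
machinery — not agreement with any particular real rig, whose top boundary
and lateral transport the 1D model does not capture.

## Diffusivity fitting

The fit minimizes the summed squared difference between observed traces and
lag-applied forward-model traces over all depths, in log-parameter space
with bounds (default: one decade either side of the nominal value), using
bounded least squares with three log-spaced starts; the best converged start
wins.  Unknowns are the scaffold D and optionally the lumped consumption
capacity ρ_cell·sOCR (K_m fixed): in the C ≪ K_m regime the three sink
parameters enter only through ρ·sOCR/K_m, so fitting them separately is
hopeless by construction.  The sensor τ is treated as known — it is quoted
by the manufacturer and nearly collinear with D at 60 s periods.  Standard
errors come from the Gauss–Newton curvature at the optimum.  Constant
schedules and flat traces raise an identifiability error before any
optimization.  The forward model assumes the exposure starts from uniform
normoxic equilibration, matching the generator and the usual protocol; an
initial-condition nuisance offset for traces of unknown phase is a known
limitation, not implemented.

Performance of the default study (4 depths at 100–400 μm, 3 cycles,
t90 = 2 s, 0.2 %O₂ noise): noiseless recovery is exact to optimizer
tolerance (≪ 0.5 %), and across 20 noise seeds the median |D̂ − D|/D is
well under 1 % — the acceptance test asserts the much looser 10 % bound.

## Problem sizes

Default resolutions — 10 μm cells, 0.1 s steps, ~70–100 nodes, tens of
cycles to periodic steady state — were chosen so that every simulation in
the test suite and every fit completes in seconds on a single core while
staying an order of magnitude inside the validated accuracy envelope.
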