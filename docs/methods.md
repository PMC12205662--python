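# Methods

This note records the scientific model behind `luminachip`, the defaults
that matter, the numerical choices, and what the synthetic-data tests do
and do not demonstrate.

## Device model

The chip cross-section is modelled in the (x, z) plane: a rectangular
hydrogel channel (width 800 μm, height 300 μm — two bonded 150 μm mould
halves) centred at the origin, flanked by two circular lumens (Ø 300 μm)
whose centres sit 550 μm off-axis, tangent to the channel walls.  Each
lumen communicates with the gel only through a slit of height 30 μm
centred on the tangent plane; everywhere else the compartments are
walled off.  The exposed fraction of the lumen perimeter is
`f = gap / (π · diameter) ≈ 0.0318`.

Discretization is a cell-centred lattice of pitch `p` (default 5 μm).
Slit interface pairs — one lumen cell, one matrix cell per lattice row
with `|z| < gap/2` — are marked during mask construction, which keeps
the slit arc length exact to one pitch.  A pitch coarser than the gap
cannot represent the slit at all and is refused; a pitch coarser than
gap/3 is accepted with a warning (the arc is then 1–3 cells).

## Transport model

The solute obeys the dilute-species transport equation
`∂C/∂t + u·∇C = ∇·(D ∇C) + R` with `R ≡ 0`.  Concentrations are
normalized to the initial lumen value 1.  The axial direction is not
resolved; reservoir replenishment by slow creeping axial flow is
emulated per lumen as either a Dirichlet hold (`held_constant`, the
default — a well-mixed reservoir) or a first-order relaxation toward the
reservoir concentration (`replenished_flow`, rate `u/L` when an axial
velocity is given).  `closed` runs have no exchange and conserve mass.

**Partition interface.**  The endothelialized slit carries a membrane
flux per unit arc length

    q = T · (k · C_lumen − C_matrix),

which vanishes at the equilibrium jump `C_matrix = k · C_lumen` and is
continuous across the interface.  `k ∈ (0, 1]` is the partition
coefficient: k = 1 is no barrier, smaller k a tighter barrier (the
70 kDa tracer, which permeates less, carries the smaller fitted
coefficient).  The transmission `T` (μm/s) defaults to `D_matrix / p` —
a membrane one cell thick — and is exposed separately because the
synthetic-assay generator uses it as the dial for a target permeability.

**Defaults.**  Tracer diffusivities are configuration values, not
measurements: 100 μm²/s (10 kDa) and 35 μm²/s (70 kDa), order-of-
magnitude typical for dextran in dilute collagen.  Fitted partition
coefficients: 0.85 (10 kDa), 0.05 (70 kDa).

**Discretization.**  Cell-centred finite volumes with harmonic-mean face
diffusivities; backward Euler (sparse LU factored once per run) by
default, an explicit scheme for cross-checks guarded by the stability
bound `dt ≤ p²/(4 D_max)`.  The interface coupling is assembled so that
its column sums vanish, making closed-system mass conservation exact up
to linear-solver round-off (measured drift ~1e−12 over 1000 steps).
Backward Euler on this M-matrix also preserves the maximum principle.
Against the semi-infinite-slab closed form `C = erfc(x/2√(Dt))` the
solver is second-order in pitch once the time step is subordinated
(dt ∝ p²); the L∞ error at 2 μm pitch is ~3 × 10⁻⁴.

Negative concentrations below −1e−12 are clamped to zero with a logged
warning; anything below −1e−6 aborts the run as a solver failure.

**Scenarios.**  `high_concentration_gel` halves and
`low_concentration_gel` doubles the matrix diffusivity;
`extra_right_source` holds the right lumen at concentration 0.5 while
the left stays at 1, which moves the steady matrix profile's minimum
toward the weaker source.

## Permeability assay

The estimator mirrors the Fiji-style workflow: a measurement line starts
at the matrix-side cell of the central interface pair (the outer vessel
edge at the slit) and runs perpendicular into the matrix, 200 μm by
default; intensities are sampled bilinearly at 1-pixel spacing and
integrated trapezoidally (`TI`, intensity·μm).  `ΔI₀` is the mean lumen
intensity at t₀ over a lumen disk eroded 2 px from the wall (the
step-across-the-wall assumption).  Profiles are recorded over 30 min;
the permeability uses the 15 min read-out:

    P = (1/ΔI₀) · ((TI_f − TI_0)/(t_f − t_0)) · (f·D/4)   [μm/s].

The estimate is invariant to global intensity rescaling and strictly
increasing in both k and T.

**Assay ceiling.**  Because `TI` of a 200 μm line is bounded by
200 × the lumen intensity, the formula cannot report more than
≈ 0.5 μm/s at t_f = 15 min regardless of the wall; in practice the
readout saturates near 0.35 μm/s once the interface is transparent and
matrix diffusion (D = 100 μm²/s) becomes limiting.  Recovery tests
therefore use ground-truth permeabilities in the reachable decade
0.1–0.3 μm/s.  The generator's ground-truth permeability is defined
operationally: the same formula applied to the exact noiseless simulated
fields; what the recovery tests then verify is the imaging path —
rendering, noise, interpolation, ROI statistics — not a tautology.

**Calibration.**  `fit_partition_coefficient` minimizes the mean squared
mismatch between simulated and observed intensity profiles (or between
simulated and target permeability) over `k ∈ (0.01, 1]` with bounded
Brent search (xatol 1e−4, ≤ 60 iterations; each evaluation is one
forward run with a cached factorization).  Near-wall profile values are
≈ k at this transmission, so the objective is steep and recovery from
noiseless profiles is essentially exact.  A fit landing within 2×xatol
of a bound triggers an "unbracketed optimum" warning.

## Hydraulics

Closed forms only: `ΔP = ρ g h_M` (defaults ρ = 1000 kg/m³,
g = 9.81 m/s²) and the fully developed laminar wall-shear magnitude
`τ_max = ΔP·R/(2L)`; the sign in the shear expression is a direction
convention and magnitudes are reported.  A convenience
`reservoir_head(volume, well_diameter)` converts a pipetted volume to a
head.  The channel length L is device-specific and never defaulted to a
manufacturer value; for example a 1 cm head over a 1 cm channel of
radius 150 μm gives τ ≈ 0.74 Pa, a plausible refreshment transient.

## Invasion and roughness quantification

Invasion distances are measured per cell from the matrix-side edge of
the slit along the invasion direction, negatives clipped to zero;
`d_max` is the per-ROI maximum and `n_invaded` counts cells deeper than
a threshold defaulting to 20 μm (≈ one cell diameter — a choice, logged,
since no standard threshold exists).  Images use 0-based pixel-centre
coordinates.

Protrusion lengths are geodesic distances through each 8-connected
component that crosses the interface, from its interface-crossing pixels
to the farthest matrix-side pixel (Dijkstra on the pixel graph, 1/√2
step weights).  A geodesic through the shape is used instead of a
skeleton path because thinning trims each end of a protrusion by about
half its width, biasing lengths low by more than a pixel; the geodesic
is accurate to one pitch on rectangular test bars.

Roughness follows ISO 4287 amplitude definitions on a mean-detrended
profile: `Ra` mean absolute deviation, `Rq` RMS deviation, `Rz` mean of
the five highest strict local maxima minus mean of the five lowest
strict local minima (ties broken by first occurrence; fewer than five
extrema → all available with a warning; monotone/flat profiles fall back
to global extremes).

## Statistics

`compare_groups` wraps the classical tests: equal-variance two-sample
t-test (Welch by flag), one-way ANOVA (with Tukey HSD pairwise
adjustment in the `one_way_anova_tukey` design; the plain
`one_way_anova` design is the cheap variant used in simulation loops),
and two-way ANOVA with type-II sums of squares on an OLS fit — type II
is stated explicitly because balanced synthetic designs make the choice
invisible.  Degenerate data (all values identical) report p = 1 with a
warning.  Null calibration: the one-way ANOVA's type-I error over 10⁴
three-group null draws sits at the nominal 0.05 within ±0.01.

## Synthetic data: what it does and does not show

Generators emulate the statistical structure of the real inputs — not
their optics or biology.  Assay stacks are the forward model rendered at
the simulation pitch (no resampling, keeping round trips exact) with
detector gain, additive Gaussian read noise (default sd 2 % of the lumen
intensity) and optional Poisson shot noise; there is no point-spread
function, photobleaching, background gradient or cell texture.  Invasion
scenes place disk nuclei at controlled depths on separated rows so that
the label-image and centroid-table paths are exactly comparable; real
nuclei overlap and deform.  Consequently the passing tests certify the
estimators and solvers against known truth under idealized imaging; they
do not certify robustness to real-microscopy artefacts.

All randomness flows through seeded `numpy.random.Generator` instances;
regeneration with the same seed is bit-identical, and every generator
serializes its parameters and derived ground truth alongside its output.

## Problem sizes

Default analyses run the cross-section at 5 μm pitch (~15 k active
cells; a 30 min simulated assay in ~1 s, a partition-coefficient fit in
2–3 s).  Property and ordering tests use a 10 μm lattice, which
preserves every qualitative behaviour at a quarter of the cell count.

## Known limitations

- The simulator is 2-D; axial transport appears only through the lumen
  replenishment modes, and no Navier–Stokes flow is solved.
- The interface treatment is first-order at the slit corners; the
  membrane has no finite thickness.
- The permeability formula is used as the field uses it — as an
  operational assay readout; its saturation ceiling (above) means very
  leaky barriers are not distinguishable by this assay at 15 min.
- Tukey HSD p-values come from statsmodels' studentized-range
  evaluation, which is slow (~0.3 s per call); use the plain
  `one_way_anova` design inside large simulation loops.
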