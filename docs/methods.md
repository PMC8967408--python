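# Methods

This package quantifies how the *Drosophila* dorsal abdominal epidermis
is built by its progenitor cells (histoblasts): lineage statistics of
tracked cells, a stochastic model of the population's growth, mechanics
of laser-ablated tissue discs, and the fluorescence bookkeeping used to
stage cells in the cell cycle.  Everything runs on synthetic data that
the package itself generates, so each estimator can be scored against a
known ground truth.

## Lineage statistics (`histogrowth.stats`)

A tracked movie is a *forest*: every cell has a birth time (its
mother's division, or the movie start for founders), an end time, and a
fate — divided, extruded, or censored at the end of observation.  Times
are hours after puparium formation (hAPF).

**Cycle times.** The cycle time of a divided cell is `end - birth`.
Summaries use the sample (n-1) standard deviation — per-movie counts
are small — and CV = sd/mean.  Sensory-organ precursors (SOPs, which
never divide again) and extruded cells are excluded.

**Division rate.** The per-capita rate on a grid is
`events in [t-w/2, t+w/2) / (w * Nbar(t))` with a top-hat window
w = 0.875 h.  `Nbar` is the *time-averaged* alive count over the same
window (exact integral of the piecewise-constant count); the
instantaneous count is available via `denominator="instantaneous"`.
The window average is the default because the event count in the
numerator is itself a window aggregate; for the narrow default window
the two differ by well under a percent.  The Fourier spectrum of the
rate before a cutoff (default 28.5 hAPF) is reported as |FFT|
normalized to its zero-frequency value; with a 12.5 h observation
window the frequency resolution is 0.08 h⁻¹, so single-run peak
positions are quantized and spectra should be averaged over runs
before locating the oscillation peak (~0.25 h⁻¹, the inverse mean
cycle time).  Oscillation peaks are counted with a prominence floor
(default 10% of the window maximum) computed on the full series, so a
maximum near the window edge keeps its true prominence.

**Growth decomposition.** Writing the tracked tissue area as
`A = N * abar` (cell count x mean cell area), each frame interval's
`dln A` splits identically into a division part `ln((N0+d)/N0)`, an
extrusion part `ln(N1/(N0+d))` (negative), and the mean-cell-area part
`dln abar`.  This is the isotropic part of a shear decomposition —
closure (`total = division + area + extrusion`) is an algebraic
identity and is enforced to 1e-9 by a property test.  A censored cell
counts as present on its final frame; a divided or extruded cell does
not (its daughters do).

**Correlations.** Mother-daughter pairs use both daughters when both
divided.  Sister pairs are unordered, and Pearson on unordered pairs
depends on the ordering convention, so within-pair order is randomized
with a seeded generator.

**Arrest analysis.** A cell is *arrested* iff it is censored at the
movie end, not an SOP, and not extruded — the operational definition
used on the tracked movies.  This labels as arrested any cell born too
close to the movie end to have divided; the closer the movie end is to
the division transition, the more the empirical arrest probability is
inflated there.  A `min_followup` option excludes such cells (default
off, matching the operational definition).  Per division-time bin
(width 1 h, edges anchored at integer hAPF):
`p = P(>=1 arrested daughter)`, `alpha = P(2 arrested | >=1)`.  Both
are fitted with the Hill form `plateau * t^n / (t_half^n + t^n)` by
least squares weighted by the bin counts; the bin abscissa is the
*mean* division time in the bin, because under exponential growth
events crowd the late side of a bin and midpoints bias `t_half` low.
Multistart over the Hill exponent guards against the fit's mild
nonconvexity.

## Growth simulator (`histogrowth.sim`)

Event-driven, one division event at a time:

1. **Cycle-time law.** Sisters draw their cycle times at birth from a
   bivariate normal with identical marginals N(m(t), (cv*m(t))^2) and
   correlation rho = 0.55.  The mean m(t) is indexed by birth time:
   2.7 h before 3.3 hAPF (cleavage), the expansion starting value for
   births between 3.3 and 14.7 hAPF, and a cubic in birth time
   afterwards.  The cleavage CV is 0.10 (cleavage divisions are nearly
   synchronous; no measured value is available), the expansion CV 0.22.
   Pairs with a component below `min_cycle` = 0.5 h are redrawn whole,
   preserving the correlation rather than clipping marginals.
2. **Expansion cubic.** The default coefficients were calibrated once
   and frozen: value 4.30 h at the pause end (the "expansion starting
   value", which also sets the 3.3-14.7 hAPF span, and places the third
   cleavage-phase division near 9.7 hAPF so the population completes
   ~3 doublings by 10 hAPF), a 15-28 hAPF average of 4.50 h, and a
   shallow dip near 22 hAPF.  These are the package's own defaults,
   chosen to reproduce the measured summary statistics; they are not
   published coefficients.
3. **Pause.** Divisions scheduled inside [12.5, 14.7) hAPF are deferred
   to 14.7 hAPF: cells keep ageing during the pause, so all overdue
   cells divide together just after release — the division burst that
   seeds the subsequent rate oscillations.  The alternative (freezing
   the cell's clock) would spread the released divisions and was
   rejected because it removes the observed synchrony.
4. **Arrest.** At a division at time t, with probability p(t) the pair
   contains arrested daughter(s); with conditional probability
   alpha(t) both are arrested, otherwise one side chosen uniformly.
   Defaults: Hill curves with t_half 26 hAPF (p) / 26.5 hAPF (alpha),
   exponent 40, plateau 1 — a transition from ~0.04 at 24 hAPF to
   ~0.95 at 28 hAPF.  The exponent is steep because the measured
   transition runs from about zero to about one over those 4 hours; no
   published exponent exists.
5. **SOPs.** Non-arrested newborns inside a window (default 20-26
   hAPF) become SOPs with probability 0.02, never divide, and end a
   few percent of the final population.  Window and probability are
   package defaults, exposed in the config.
6. **Determinism.** One `numpy` Generator seeded from the config
   drives every draw in event order; identical (config, seed) gives a
   bitwise-identical forest.

Founders are mutually independent (no shared mother inside the
simulated window).  The closed loop — simulate, then re-estimate with
`histogrowth.stats` — recovers the input mean, CV, sister correlation
and arrest schedule within Monte-Carlo error, and is the backbone of
the test suite.

## Ablation analytics (`histogrowth.ablation`)

The excised-disc outline is fitted with a direct least-squares conic
constrained to an ellipse (the numerically stable Halir-Flusser
formulation, via `skimage.measure.EllipseModel`).  "Bounding ellipse"
is read as this least-squares fit — robust to outline noise — rather
than the minimum-area enclosing ellipse.  The fit is summarized as a
shape tensor `M = R diag(a^2, b^2) R^T`; its diagonal in the lab frame
gives the axis extents along AP (x) and DV (y), the normalized
off-diagonal the shear (near zero in practice).  Axis lengths are full
diameters, matching the annulus geometry (45.54 um inner / 57.96 um
outer diameter).

Hencky (true) strain is `eps = ln(L/Lr)` with L the non-ablated and Lr
the relaxed axis length; it is antisymmetric and additive along a
deformation path.  Recoil velocity is the frame-to-frame length
difference over dt (signed; magnitudes via a flag).  The relaxation
time comes from an OLS line of velocity against the mid-interval
length: for Kelvin-Voigt relaxation `L(t) = Linf + (L0-Linf)e^(-t/tau)`
the slope is -1/tau.  The mid-interval regressor makes the
discretization bias second order, `tau_est = (dt/2) coth(dt/2tau)`
(+0.2% at dt/tau = 1/6); tests assert recovery at 0.5%.  Single-junction
recoil offers both a first-interval finite difference (default) and an
exponential-fit initial slope, since the upstream methodology is not
reproduced in the available text.

## Continuum model (`histogrowth.continuum`)

The excised disc is 2D linear elastic — area modulus K̄, shear modulus
μ̄ — carrying a uniform anisotropic active pre-tension diag(ζx, ζy)
and tethered to the substrate by elastic links of stiffness-per-area k:

    div(sigma_el) = k u  in the disc,   sigma_el·n = -zeta·n  on the rim,

with `sigma_el = K̄ tr(eps) I + 2 μ̄ dev(eps)`.  Lengths are normalized
by the disc radius R and stresses by K̄, giving the fitted parameters
k̂ = kR²/K̄, ζ̂x = ζx/K̄, ζ̂y = ζy/K̄; μ̂ defaults to 1 and is held
fixed during fitting (fitting it is an option).  This constitutive
reading and the normalization are the package's own — they are
self-consistent, but a published nondimensionalization could differ by
a fixed factor, so *ratios and orderings* of fitted parameters are the
comparable quantities.

Uniform diagonal tension excites only the angular harmonics m=0
(isotropic, driven by ζ_iso = (ζx+ζy)/2) and m=2 (deviatoric, driven
by ζ_dev = (ζx-ζy)/2).  Each reduces to a radial two-point BVP solved
by collocation (`scipy.integrate.solve_bvp`) on a mesh refined toward
the rim when the decay length ℓ = sqrt((1+μ̂)/k̂) is short.  The
isotropic problem has a closed form — u_r = A I₁(r/ℓ), modified Bessel
functions, A set by the rim traction — implemented independently as
`axisym_reference`; solver and oracle agree to <0.5% relative L2
(measured: ~1e-6).  Limits: k̂=0 gives uniform contraction
-ζ_iso/K̄ (free disc) and uniform elongation -ζ_dev/μ̄; k̂→∞ pins the
interior and confines deformation to a rim boundary layer, which is
what the edge-localization index (mean |area change| outer 25% annulus
/ inner 50% disc) quantifies, monotone in k̂.

**Fitting.**  The observables are the pointwise area change, both
traceless-strain components, and the rim displacement along AP and DV,
each block weighted by the inverse of its empirical spread.  The PDE is
linear in (ζ_iso, ζ_dev), so for any k̂ the tensions are profiled out
by weighted linear least squares and only k̂ is searched (coarse log
grid, then bounded scalar refinement).  This variable-projection
scheme is equivalent to a multistart nonlinear fit of all three
parameters at a fraction of the cost.  Bootstrap CIs resample sample
points and refit on the cached k̂ grid (so the k̂ CI is quantized to
that grid); a flat profile in k̂ — uniform observed deformation — is
reported as a wide CI, not an error.  Noiseless round trips recover
parameters to <0.1%; at 10% multiplicative noise and 200 points,
within 15%.

## Intensity bookkeeping (`histogrowth.intensity`)

Junction Myo II intensities are binned every 5° of junction angle from
the DV axis (folded into [0, 90]; a junction is axial), reporting
median and IQR with linear-interpolation quantiles.  Pre-pupal ECM
series are normalized to their value at 13 hAPF (first still frame
after head eversion).  The pupal ECM normalization sentence in the
source protocol is ambiguous; it is resolved as: background B = mean of
the five lowest LEC-frame intensities, both series shifted by -B, then
scaled by one common factor so the first LEC value is 1 (the LEC series
then decays from 1 to ~0).  The alternative — dividing the shifted
series by B — is behind a flag.  FUCCI totals per channel are
normalized to the first frame.

Phase calling normalizes each nucleus to the per-channel population
mean, takes r = RFP/GFP of the normalized values, and thresholds:
r < 0.5 → G1, r > 2 → S, else G2/M.  The published threshold values
are not recoverable from the available text; the defaults were
calibrated on synthetic mixtures and are config-exposed.  Because of
the population-mean normalization the call is relative to the frame:
it is scale-free and per-channel-gain invariant, but degenerates on a
perfectly homogeneous population (every ratio ≈ 1 → mid band).  Real
frames mix states; the recovery tests therefore use mixed populations.

## Synthetic data (`histogrowth.synth`)

The generators emulate the *statistical structure* the estimators
assume, not images: they share the exact file schemas with the readers
and always retain ground truth.

- **Forests with geometry** wrap the simulator and add per-frame areas
  and centroids on one shared frame grid.  Daughters take exactly half
  the mother's final area and relax exponentially toward a set point
  (15 um², 0.4/h) — deliberately a bookkeeping fixture that conserves
  area at divisions, not tissue mechanics.  Centroids sit on jittered
  hexagonal packing, enough for nearest-neighbor statistics.
- **Deformation fields** are forward continuum solutions on a
  quasi-uniform sunflower layout plus additive or multiplicative
  Gaussian noise.
- **FUCCI populations** draw log-normal channel intensities with
  class-conditional medians separated 8-fold ("on" 8, "off" 1 a.u.)
  and sigma_log = 0.12.  Class counts are *stratified* by default
  (largest-remainder rounding, shuffled order) so the composition
  equals the stated fractions exactly and recovery error reads out the
  classifier alone; independent multinomial labels are an option.
- **Recoil series** are exact Kelvin-Voigt exponentials plus noise;
  **junction tables** draw angles uniform on [0, 90]° with intensities
  from a supplied angular profile.

What passing tests show — and do not.  The generators realize the
model assumptions exactly (normal cycle times, ideal exponential
recoil, log-normal intensities, the forward continuum model itself),
so recovery tests validate the estimators' correctness and calibration
under those assumptions.  They do not probe segmentation or tracking
errors, non-normal cycle-time tails, spatially correlated mechanics,
or bleaching — all absent from real-data preprocessing upstream of
this package's scope.

## Problem sizes and numerical choices

Default simulations run 16 founders to 33 hAPF (~5,500 cells, ~50 ms);
statistics that need more data pool 10-20 seeded runs.  Continuum
solves use BVP tolerance 1e-8 (1e-6 inside fitting loops) on ~400-node
meshes; fits use 200 sample points and a 24-point k̂ grid spanning
1e-3 to 300.  Division-rate grids use 0.125 h steps.  Bin edges are
left-closed right-open anchored at integer hAPF; nearest-neighbor ties
break to the lowest cell id; zero-variance correlation inputs raise
rather than return NaN.

## Known limitations

- The continuum constitutive law and nondimensionalization are frozen
  package choices; absolute fitted values are comparable only within
  this package.
- The arrest label is operational (censoring-based); near the movie
  end it overestimates arrest, mitigated but not removed by the
  `min_followup` option and by simulating past the transition.
- The simulator is non-spatial: no mechanics, no neighbor coupling
  (measured cycle times showed no geometry dependence, which this
  mirrors but cannot test).
- Single-run division-rate spectra are quantized to 0.08 h⁻¹; peak
  locations should be read from seed-averaged spectra.
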