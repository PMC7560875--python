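# Methods

## Reaction-cycle model

The cycle is modelled as a closed, well-mixed compartment with mass-action
kinetics over five species (fuel F, precursor P, O-acylisourea intermediate
I, anhydride product A, urea waste W). The wiring is the standard
carbodiimide activation scheme: direct fuel hydrolysis (k0, 1/min),
bimolecular activation of the precursor's aspartate by fuel (k1, 1/mM/min),
partitioning of the intermediate between productive anhydride formation
(k2, 1/min) and futile hydrolysis back to the precursor (k3, 1/min), and
anhydride hydrolysis closing the cycle (k4, 1/min). This is the only wiring
consistent with the five species and with activation and deactivation
running simultaneously throughout the cycle.

Assumptions worth stating explicitly:

* **One compartment, one rate set.** No separate in-droplet rate constants:
  a single parameter set describes the whole sample, consistent with the
  observation that one set of constants predicts fuel, precursor and
  product profiles irrespective of droplet load. The droplet phase occupies
  ≲0.2% of the sample volume, so its contribution to bulk kinetics is
  below the data's resolution anyway.
* **Units.** mM and minutes everywhere; every I/O schema names its units.
* **Solver.** LSODA (stiff-capable) with rtol 1e-8, atol 1e-9 mM, output on
  a regular grid (default 0.1 min). The two linear conservation laws
  (P+I+A, F+I+W) are validated to 1e-6 relative on every integration and a
  violation raises rather than warns.

## Rate-constant provenance

The five default constants packaged in `data/defaults.json`
(k0 = 0.3228, k1 = 0.03342, k2 = 5.755, k3 = 19.82, k4 = 0.08575) were
calibrated with the package's own least-squares machinery against the
macroscopic observables of the standard system (23 mM precursor, 200 mM MES
pH 5.3, 25 °C): the 7.5 mM fuel threshold corresponding to a 0.9 mM peak
anhydride, the ~3 min anhydride peak and ~18 min clearance of the 0.9 mM
coacervation threshold at 25 mM fuel, and the ~3 mM total product at 2 min
implied by the filtrate partitioning data. They are configuration, not code:
every operation takes a `RateConstants` argument and nothing numeric is
hard-coded in stage logic.

One scenario-level observable is **not** reproduced by this (or any)
parameterization of the five-rate scheme: simultaneous depletion of fuel
and product below 0.1 mM at ~30 min with 60 mM fuel. Because more fuel
always activates more peptide, A(t; 60 mM) ≥ A(t; 25 mM) pointwise, and the
anhydride tail decays at k4; holding the 18-min threshold clearance at
25 mM then forces the 60 mM depletion time past ~50 min. The corresponding
acceptance test is kept and fails by design; a faster measured depletion
would indicate kinetics outside this scheme (e.g. composition-dependent
deactivation) that the single-compartment model deliberately omits.

## Kinetic fitting

`KineticModel` minimizes least squares between unfiltered HPLC
concentrations and model predictions evaluated exactly at the sample times
(no interpolation error enters the residual). The loss is relative
(proportional-error) by default because fuel (tens of mM) and anhydride
(sub-mM) spans differ by orders of magnitude; each residual is scaled by
|obs| plus a 2%-of-species-max floor so zero-concentration points stay
finite. Absolute weighting is a constructor switch, since the original
analysis does not state its weighting. Parameters are fitted in log space,
which enforces positivity without active bounds; covariance comes from the
Gauss-Newton approximation at the optimum mapped back by the delta method.
Structural non-identifiability (e.g. everything but k0 in a fuel-only
experiment) is detected from near-zero Jacobian columns and flagged on the
result rather than raised.

## Quench correction

Filtrate anhydride is quantified after a benzylamine quench; during the
15–25 s between filtration and quench (default 20 s when unrecorded, the
midpoint of that range), fuel and precursor continue producing anhydride in
the filtrate. The correction integrates the cycle over the delay from the
filtrate composition and subtracts the net anhydride change. The filtrate
composition is taken as the model state at filtration time with A replaced
by the measurement when no better estimate exists; the intermediate I is
carried from the model because the quench assay cannot see it. The
mono-amide is treated as a 1:1 proxy for anhydride at quench time. The
round trip (simulate → sample later → correct) is exact to <1% for delays
up to 60 s anywhere in the cycle.

## ITC one-site fit

Heats follow the single-site (Wiseman) isotherm with the perfusion dilution
model (cell contents diluted by exp(−ΣdV/V0), syringe material accumulating
as its complement) and the standard displaced-volume heat increment. Units
are chosen so mM · µL · kJ/mol = µJ. The first injection is excluded by
default (partial delivery during equilibration). Kd, dH and n are all free,
fitted as (log Kd, dH, log n). At the study design (1.1 mM RNA monomer
sites, Kd ≈ 2.9 mM) the Wiseman c-value is ~0.4; the fit flags this low-c
regime as weakly identified rather than failing, and the reported
confidence intervals widen accordingly. An all-zero isotherm (dH = 0)
returns a flagged degenerate result.

## Phase analysis

* **Critical concentration** is defined operationally: the peak anhydride
  reached at the turbidity-onset fuel level (0.9 mM at 7.5 mM fuel).
* **Fuel-threshold scan** brackets geometrically, bisects to the requested
  resolution and snaps up to the grid, so the returned value is the
  smallest grid fuel whose peak reaches the target.
* **Regime classification** is intentionally empirical: no droplets at or
  below 7.5 mM fuel (RNA-independent), metastable at or above a boundary
  linearly interpolated between the anchors (1.4 mM RNA, 25 mM fuel) and
  (4.1 mM RNA, 40 mM fuel), clamped outside; dynamic in between. The
  mechanism of metastability (kinetic arrest) is not modelled.
* **Mass balance**: droplet amount (sample basis) = total − filtrate·(1−φ),
  in-droplet molarity = amount/φ/1000. The droplet-phase volume fraction φ
  is an *input* (a centrifugation measurement, not software-reproducible).
  Packaged values — φ = 0.0014 (dynamic) and 0.0015 (metastable), the
  3.9 mM metastable filtrate, and the 90%/100% RNA droplet fractions — are
  chosen so the packaged scenarios reproduce the observed ~0.9 M / ~1.8 M
  in-droplet product and the 1.1 / 2.0 charge ratios; they are recorded
  observables of the scenario configuration, not model predictions.
* **Charge ratio** counts only the +3 product against −1 per RNA monomer.
  The precursor's +1 is excluded by default — it is the choice that
  reproduces the observed ratios, and the precursor partitions weakly —
  but `ChargeModel(include_precursor=True)` switches it on.
* **Turbidity lifetime** is the last crossing below 0.01 a.u. (blank
  subtracted) after the trace maximum; both this cutoff and the 0.1 mM HPLC
  detection limit are configurable, since "clear" and "absent" are
  instrument conventions.

## Imaging

Segmentation: global Otsu threshold, connected components, rejection of
components under 4 px². Otsu always splits a histogram, so on a
droplet-free noisy frame the threshold must clear the background median by
4 robust sigma (MAD-based) before any object is accepted — this is what
keeps the false-positive rate at zero on blank frames. A fixed-threshold
mode is provided for deterministic pipelines. Volumes assume perfect
spheres on the 2-D equivalent diameter; no z-information is used.
Touching-droplet splitting is deliberately absent: fused droplets are
physically merged objects here. Time-lapse statistics use right-closed
5-minute bins (minutes 1–5 form the first bin); empty bins are absent, not
zero. Vacuole annotation (interior pixels under 50% of the rim intensity
after hole-filling) is optional metadata, never a headline count.

Partition coefficients are median interior intensity over median background
intensity; the interior mask is eroded by 2 px to drop blurred rims and the
background excludes a 2 px dilation halo. Medians make the estimate robust
to Poisson noise and residual halo pixels, and the estimator is exactly
invariant under global intensity scaling.

## Synthetic data

Generators are pure functions of (truth, design, seed) — identical inputs
give identical outputs — and always emit the ground truth needed to score
the estimator they feed. Noise models: multiplicative Gaussian for HPLC and
ITC (instrument-proportional), additive Gaussian for turbidity,
Poisson-Gaussian for images. Defaults: 5% HPLC noise, 2% ITC noise,
background 200 counts with 5-count read noise (SNR ≈ 13 on the background,
well above the SNR 5 regime the segmentation guarantees are stated for).

The synthetic micrograph link between chemistry and image content — droplet
count proportional to the anhydride excess above the critical concentration
(12 droplets per mM by default), radii uniform on 6–14 px at 0.1 µm/px,
interior intensity K_true × background, Gaussian PSF σ = 2 px — is an
artifact construction. It reproduces the qualitative product↔droplet-load
correlation so the estimators can be exercised end to end; it is not a
nucleation model. Likewise the metastable turbidity generator simply holds
the running maximum until the persistence time (default 76 min) and then
drops, reproducing the hysteresis signature without modelling arrest.
Consequently, passing recovery tests demonstrates correctness of the
estimators under the assumed noise/optics, not fidelity of real micrograph
or plate-reader data: absolute droplet counts, volumes and turbidity
magnitudes of the original experiments are covered only as recovery
properties, never as exact targets.

## Numerical choices and degenerate inputs

* Threshold crossings and depletion times are linearly interpolated between
  output grid points; peak location is the earliest grid maximum.
* Depletion requires *both* fuel and anhydride to stay below the limit to
  the end of the trace; a trace that never clears returns an absent result,
  as does turbidity that never exceeds its cutoff.
* `mass_balance` clamps negative droplet amounts (filtrate > total, a noise
  artifact) to zero with a warning instead of failing.
* Fits are deterministic given the same starting point; the kinetic fit's
  default start is the packaged constants.
* The Euler cross-check oracle in the tests uses a step small enough that
  its own first-order truncation error stays below the 0.1% comparison
  band (1e-3 min for O(1)/min rates, 1e-4 min for the packaged constants,
  whose intermediate turnover k2+k3 ≈ 26/min is the fastest timescale).

## Problem sizes

Recovery studies use 20 replicates throughout (kinetic Monte-Carlo, ITC
seeds, micrograph frames); frames are 512×512 with ≥ 20 droplets. These
sizes put the medians' sampling error well below the stated tolerances
while keeping the whole suite around a quarter of a minute.

## Known limitations

* No spatial or stochastic kinetics; no temperature or salt dependence of
  rates or boundaries (robustness conditions enter only as configuration).
* The metastable regime is classified, not explained; droplet tracking,
  fusion/fragmentation event detection and 3-D reconstruction are out of
  scope.
* The 60 mM depletion-time discrepancy described above is the clearest
  signature that a single well-mixed rate set cannot capture every
  observable at once.
* Low-c ITC fits genuinely cannot pin n and Kd independently; the package
  reports this rather than hiding it.
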