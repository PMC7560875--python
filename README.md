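# dropcycle

Analysis pipeline for **chemically fueled peptide–RNA coacervate droplets**:
membraneless-organelle model systems in which a carbodiimide fuel (EDC)
transiently switches a peptide into a state that phase-separates with RNA.

The package is aimed at experimentalists and modellers working on
dissipative self-assembly and active liquid–liquid phase separation who need
to (i) simulate and calibrate the fuel-driven reaction cycle against HPLC
time courses, (ii) map droplet phase regimes and two-phase compositions, and
(iii) extract droplet statistics and partition coefficients from confocal
micrographs — with seeded synthetic-data generators providing ground truth
for every estimator.

## The model

A well-mixed five-species reaction cycle (concentrations in mM, time in
minutes): fuel F (EDC), precursor P (Ac-FRGRGRGD-OH, net charge +1),
O-acylisourea intermediate I, anhydride product A (net charge +3) and waste
W (EDU):

```
dF/dt = −k0·F − k1·F·P
dP/dt = −k1·F·P + k3·I + k4·A
dI/dt =  k1·F·P − (k2+k3)·I
dA/dt =  k2·I − k4·A
dW/dt =  k0·F + (k2+k3)·I
```

Fuel is lost to direct hydrolysis (k0) or activates the precursor (k1); the
intermediate partitions between anhydride formation (k2) and futile
hydrolysis (k3); the anhydride deactivates back to the precursor (k4). Two
conservation laws (P+I+A and F+I+W) are enforced on every integration.
Droplets form while A exceeds a critical coacervation concentration
(~0.9 mM with 4.1 mM poly-U); the (fuel, RNA) plane splits empirically into
no-droplet, dynamic and metastable regimes.

Around the cycle the package provides:

* `KineticModel` / `fit_rate_constants` — weighted least-squares calibration
  of (k0…k4) to HPLC data, with identifiability diagnostics and a
  benzylamine-quench delay correction for filtrate samples;
* `ITCModel` / `fit_binding_isotherm` — one-site (Wiseman) fit of
  precursor–RNA titration heats with dilution accounting;
* phase analysis — critical concentration, fuel-threshold scan, regime
  classification, two-phase mass balance, charge ratios, turbidity
  lifetimes;
* imaging — particle-analysis segmentation, 5-minute binned time-lapse
  statistics, median-ratio partition coefficients;
* `dropcycle` CLI — `simulate`, `fit-kinetics`, `fit-itc`, `phase-map`,
  `analyze-images`, `synth …`, `report`.

## Worked example

```python
import numpy as np
import dropcycle as dc

k = dc.RateConstants.default()                 # packaged calibrated constants
cfg = dc.ExperimentConfig(F0=25.0)             # 25 mM fuel, standard conditions
tc = dc.integrate(cfg, k, 90.0)

t_peak, A_peak = dc.peak_anhydride(tc)
t_on, t_off = dc.threshold_times(tc, 0.9)
print(f"peak anhydride: {A_peak:.2f} mM at {t_peak:.1f} min")
print(f"droplet window (A >= 0.9 mM): {t_on:.2f} -> {t_off:.2f} min")
print(f"fuel threshold: {dc.fuel_threshold_scan(cfg, k, A_crit=0.9, resolution=0.5)} mM")

total_A = float(np.interp(2.0, tc.t, tc.A))
mb = dc.mass_balance(total=total_A, filtrate=1.7, droplet_volume_fraction=0.0014)
print(f"A at 2 min: {total_A:.2f} mM total; {mb.outer_mM:.2f} mM outside; "
      f"{mb.in_droplet_M:.2f} M inside droplets")
print(f"charge ratio (cations:anions): {dc.charge_ratio(mb.droplet_mM, 0.9 * 4.1):.2f}")
print(f"regime at (25 mM fuel, 4.1 mM RNA): {dc.classify_regime(25.0, 4.1).value}")
```

prints

```
peak anhydride: 3.06 mM at 2.7 min
droplet window (A >= 0.9 mM): 0.29 -> 18.00 min
fuel threshold: 7.5 mM
A at 2 min: 2.98 mM total; 1.70 mM outside; 0.92 M inside droplets
charge ratio (cations:anions): 1.04
regime at (25 mM fuel, 4.1 mM RNA): dynamic
```

Read: at 25 mM fuel the anhydride peaks at ~3 mM within three minutes and
stays above the 0.9 mM coacervation threshold for ~18 minutes — the droplet
lifetime. At least 7.5 mM fuel is needed to cross the threshold at all. Two
minutes in, 1.7 mM of the ~3 mM product sits outside the droplets; the rest
is packed into ~0.14% of the sample volume at ~0.9 M, giving a near-neutral
+1.04 cation:anion ratio characteristic of dynamic (rapidly dissolving)
droplets.

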