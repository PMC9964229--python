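# climflav

Climate-to-flavonoid chemometrics for field studies of medicinal
plants.

Secondary metabolites such as flavonoids vary strongly between
collection sites, and a recurring question in pharmacognosy is which
climate factors drive that variation. `climflav` implements the full
computational chain for one such study design: per-site monthly climate
records over eight factors (average/maximum/minimum temperature,
average/daytime/overnight precipitation, sunshine duration, relative
humidity) are linked to total flavonoid content, radical-scavenging
activity and individual flavonoid abundances of a subtropical fern.
It is aimed at analysts who have bench assay read-outs, accurate-mass
peak lists and a climate table, and want a reproducible, testable
pipeline from raw numbers to factor rankings.

## What it computes

**Assay arithmetic** (`climflav.assay`) — rutin-equivalent total
flavonoid content from OD triplicates at 510 nm,

    TFC(%) = ((mean OD − A)/B) · (10/2) · (V/1000) · dilution · 100,

with (A, B) the standard-curve intercept and slope and V the extract
volume in mL (mg/g = TFC% · 10); DPPH/ABTS/superoxide scavenging
percentages (1 − A_sample/A_control) · 100; IC50 by log-linear
interpolation of the first 50% crossing; blank-corrected Fe(III)
reducing force at 700 nm.

**Accurate-mass annotation** (`climflav.msannotate`) — monoisotopic
masses from pinned atomic constants (¹²C = 12 exactly), theoretical m/z
of [M−H]⁻, [M+H]⁺ and [2M−H]⁻ ions via the proton mass 1.00727646688 Da,
ppm/mDa errors, exhaustive CHNOS formula enumeration inside a ppm
window with an integer-RDBE plausibility filter, and tentative
identification against a bundled flavonoid library keyed on formula and
UV λmax pattern.

**GA-BP modelling** (`climflav.gabp`) — inputs and outputs min-max
scaled to [0.10, 0.90]; a feed-forward network with logistic-sigmoid
activations and default topology 8-50-30-1; a real-coded genetic
algorithm pre-optimizes the weight chromosome (fitness 1/(1+SSE)),
batch backpropagation with momentum and a multiplicative learning-rate
schedule fine-tunes it; training stops when the summed squared error
falls below Δ²·N (Δ = 0.02) and the mean absolute error below 0.02.
Factor importance is a one-at-a-time central-difference perturbation of
the trained net, normalized to sum to one.

**Verification statistics** (`climflav.stats`) — Pearson correlation
matrices with qualitative strength bands (|r| ≥ 0.7 high, ≥ 0.4 medium,
≥ 0.1 low), correlation-matrix PCA with a fixed sign convention, and
agglomerative hierarchical clustering with heatmap-ready exports.

**Synthetic study generator** (`climflav.synthetic`) — seeded
generators for all of the above with known ground truth: climate tables
obeying MIT ≤ AT ≤ MAT, planted effect functions with analytic
sensitivity vectors, invertible OD/dose-response/peak-list simulators.
Every generator/estimator pair round-trips exactly at zero noise.

## Worked example

```python
import numpy as np
from climflav import (CalibrationCurve, ExtractionSpec, OdTriplicate, compute_tfc,
                      adduct_mz, estimate_ic50, gen_dose_response,
                      gen_climate, gen_response, EffectSpec, NetworkConfig,
                      fit_gabp, sensitivity, CLIMATE_FACTORS)

curve = CalibrationCurve(slope=10.655, intercept=-0.0076)   # rutin standard
spec = ExtractionSpec(extract_volume_ml=50, aliquot_factor=5, dilution_factor=10)
res = compute_tfc(OdTriplicate(1.21, 1.19, 1.20), curve, spec)
print(f"TFC: {res.tfc_mg_per_g:.1f} mg/g ({res.tfc_percent:.2f}% w/w)")

series = gen_dose_response(true_ic50=0.8, hill=2.0,
                           concentrations=tuple(np.geomspace(0.1, 5, 12)))
print(f"IC50: {estimate_ic50(series):.3f} mg/mL")

print(f"[M-H]- of rutin (C27H30O16): {adduct_mz('C27H30O16', '[M-H]-'):.4f}")

climate = gen_climate(n_sites=100, seed=1)
draw = gen_response(climate, EffectSpec(coefficients={"MIT": 1.5, "SD": -0.4, "DP": 0.3},
                                        noise_sd=0.05), seed=2)
net = fit_gabp(climate[list(CLIMATE_FACTORS)].to_numpy(), draw.values.to_numpy(),
               NetworkConfig(seed=3))
prof = sensitivity(net, net.x_scaler.transform(climate[list(CLIMATE_FACTORS)].to_numpy()),
                   factors=list(CLIMATE_FACTORS))
print("factor ranking:", ", ".join(f"{f}={v:.2f}" for f, v in
      sorted(zip(prof.factors, prof.values), key=lambda t: -t[1])[:4]))
```

prints

```
TFC: 283.3 mg/g (28.33% w/w)
IC50: 0.799 mg/mL
[M-H]- of rutin (C27H30O16): 609.1461
factor ranking: MIT=0.52, AT=0.17, SD=0.17, DP=0.10
```

The triplicate with mean OD 1.20 corresponds to 283.3 mg rutin
equivalents per gram of dry mass; the simulated dose-response recovers
its planted IC50 of 0.8 mg/mL to interpolation accuracy; the
deprotonated rutin ion lands on the reference value at four decimals;
and the trained network ranks the planted dominant factor (minimum
temperature) first, with the residual weight spread over the factors
correlated with it.

The same chain is available from the shell:

```sh
climflav run --seed 1 --out my_run        # simulate -> ... -> report
climflav annotate --out my_run            # single stage, reads my_run/peaks.csv
```

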