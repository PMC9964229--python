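# Methods

This note records the models, parameter choices and numerical
conventions behind `climflav`, and what the synthetic-data tests do and
do not establish about real field data.

## Assay arithmetic

Total flavonoid content is computed from the colorimetric formula

    TFC(%) = ((OD₁ + OD₂ + OD₃)/3 − A)/B · f_aliquot · (V/1000) · f_dilution · 100

with the rutin standard curve OD = B·c + A (defaults B = 10.655,
A = −0.0076, R² = 0.99869, read at 510 nm), aliquot factor 5 (a 2 mL
aliquot of a notional 10 mL reaction basis), extract volume V = 50 mL,
and mg/g = TFC% · 10. As printed, the formula cannot reach the
hundreds-of-mg/g range reported for fern extracts from plausible ODs
(0–4) without an additional dilution step, so a configurable
`dilution_factor` (default 1) is part of `ExtractionSpec`; the pipeline
default is 10, which puts implied ODs near 1.2 for TFC ≈ 280 mg/g. A
mean OD below the intercept returns 0 with a `below_blank` flag rather
than a negative concentration, and a triplicate coefficient of
variation above 10% warns but does not fail.

IC50 estimation is deliberately the simplest defensible estimator:
linear interpolation of scavenging percentage against log₁₀
concentration between the first pair of points bracketing 50%. No
four-parameter logistic fit is imposed, because the upstream assays are
routinely reported from interpolation and a parametric fit would add
assumptions the data cannot check at 9 sites. Consequences: the
estimate is exact when 50% lies on a grid point, biased by curvature
between grid points (the dose-response is logistic in log c, the
interpolant is linear), and undefined when the series never crosses
50% — that case raises `NoCrossingError` naming the achieved range.

## Accurate-mass annotation

Monoisotopic masses use pinned constants (¹²C = 12 exactly,
H = 1.00782503207, O = 15.9949146196, N = 14.0030740048,
S = 31.97207100 Da); adduct m/z is (k·M ± m_p)/|z| with the
electron-corrected proton mass m_p = 1.00727646688 Da. This
combination reproduces reference deprotonated-ion values at four
decimal places. The ppm sign convention is
(measured − theoretical)/theoretical.

Formula matching enumerates every CHNOS composition inside
configurable element bounds (defaults C ≤ 60, H ≤ 100, N ≤ 5, O ≤ 20,
S ≤ 2; search spaces above 10⁷ combinations are refused), keeps
candidates within the ppm tolerance whose ring-double-bond equivalents
RDBE = C − H/2 + N/2 + 1 lie in [0, 40] **and are integers** — the
nitrogen rule: a half-integer RDBE describes an open-shell species
that cannot be a neutral molecule. Without the integer filter,
odd-electron CHNOS near-isobars (e.g. C23H16NOS at nominal 354)
occasionally outrank genuine formulas by fractions of a ppm on
experimental masses; with it, candidate ranking by |ppm| is stable.

A peak observed as several adducts is assigned the formula common to
all adducts' candidate lists with the smallest summed |ppm|; disjoint
candidate sets (e.g. a printed dimer ion that is not arithmetically
2M−H of its monomer) set an `ambiguous` flag, report every per-adduct
top candidate, and carry the deprotonated-ion candidate forward.
Identity assignment requires the consensus formula plus a UV match:
every library λmax reproduced within ±5 nm by an observed maximum.
Among multiple matching entries the most specific pattern (most
reference maxima, then smallest total deviation) wins — this is what
separates isomeric flavonol glycosides sharing a formula. Isotope
patterns and MS/MS spectra are out of scope; identifications are
tentative by construction.

## GA-BP network

Inputs and outputs are min-max scaled to [0.10, 0.90]
feature-by-feature (outputs must live strictly inside the logistic
range; sharing the input bounds keeps one convention). Constant
features map to the midpoint and are flagged. The network is fully
connected with logistic-sigmoid activations on every non-input layer,
default topology 8-50-30-1; the topology is configurable because the
hidden-layer sizing in this design family is conventional, not
principled, at n ≈ 9–100 samples.

The genetic algorithm operates on the flat weight/bias chromosome:
population 40, 100 generations, tournament selection of size 2,
per-gene arithmetic crossover with probability 0.8, additive Gaussian
mutation (rate 0.05, sd 0.1), elitism of one, chromosomes initialized
uniform(−0.5, 0.5), fitness 1/(1+SSE). These hyperparameters are
fixed, documented defaults — the method's value is the global
initialization, not any particular setting — and all are configurable
with a mandatory seed.

Backpropagation is full-batch gradient descent with momentum 0.9 on
the mean squared error (the MSE gradient makes the learning rate
comparable across sample sizes; traces record SSE). The learning rate
(initial 0.05) is multiplied by 1.05 after an epoch that reduces the
SSE and by 0.7 otherwise; a step inflating the SSE by more than 4% is
rejected outright with the momentum reset. Two numerical choices
matter here: (1) a learning-rate floor of 10⁻³ (inactive when the
initial rate is zero) — on error plateaus the multiplicative schedule
otherwise decays the rate geometrically to zero and training stalls
permanently; (2) convergence is declared when the summed squared
per-sample error is strictly below Δ²·N (Δ = 0.02) *and* the mean
absolute error on the scaled outputs is below 0.02. The ε in the stop
rule is read as the SSE and the "average output error" as the MAE;
both interpretations are tested exactly as stated and no stronger
claim is made.

Sensitivity analysis is one-at-a-time central differencing on the
trained net: s_j = mean over training inputs of
|f(x + δe_j) − f(x − δe_j)|/(2δ), δ = 0.10 of the scaled span,
normalized to sum to one. This is the most common reading of ANN
sensitivity analysis; it estimates the normalized mean absolute
partial derivative, which is precisely how the generator defines its
planted ground truth — so recovery tests compare like with like.
Caveat: when input factors are collinear (the generated temperature
triple MIT ≤ AT ≤ MAT shares one underlying draw), the network may
express a planted effect partly through correlated inputs and the
one-at-a-time profile smears across them; rankings of a dominant
factor survive this, exact attribution does not.

With nine sites no train/test split is meaningful; fits on fewer than
20 samples warn explicitly that they are training-set fits only.

## Verification statistics

Pearson correlations use the standard estimator with two-sided
p-values from the t transform (n − 2 df); constant columns yield an
"undefined" flag for their pairs instead of failing the report, and no
multiple-testing correction is applied — p-values are raw and labelled
as such. Qualitative bands use |r| cut points 0.1/0.4/0.7
(negligible/low/medium/high), a common convention chosen because the
upstream qualitative language never defines its thresholds; the cut
points are configurable and recorded in the report.

PCA is performed on the correlation matrix (variables z-scored,
ddof = 1) via symmetric eigendecomposition; each loading vector is
oriented so its largest-magnitude entry is positive, which fixes the
sign indeterminacy reproducibly across BLAS implementations. HCA
defaults to average linkage on Euclidean distances over z-scored
features (Ward available); merge heights under average linkage are
non-inverting, which the tests check property-style.

## Synthetic-data generator

The generator emulates subtropical August station records: AT ~
N(27, 2) °C, MAT/MIT offset by |N(5, 1)| °C above/below, day and night
precipitation log-normal around 90 mm (AP is their sum, by
convention — whether a real "average precipitation" series is a total
or an independent record is left open, and nothing downstream depends
on it), sunshine ~ N(170, 30) h clipped at 0, humidity ~ N(78, 6) %
clipped to [0, 100]. Planted responses are linear-plus-Gaussian-bump
functions of z-scored factors with additive Gaussian noise; compound
abundances exponentiate a small response so they stay positive; TFC is
mapped into [100, 400] mg/g, bracketing published fern ranges. The
default site count is 9 to mirror the field design, but recovery tests
use 30–200 sites because 9 is statistically fragile.

What passing tests show: the estimators invert their generators
exactly at zero noise; the full scale → GA → BP → sensitivity chain
recovers a planted dominant factor in ≥ 90% of seeded runs at n = 100;
the statistics agree with closed-form and brute-force oracles. What
they do not show: anything about unmodelled features of real data —
spatial autocorrelation between stations, measurement drift,
non-Gaussian assay noise, matrix effects in ESI ionization, or
flavonoid responses outside the planted function class.

## Problem sizes and determinism

The training benchmark uses n = 30 samples with observation noise sd
0.01 and three seeded repeats; the ranking benchmark uses n = 100 and
20 repeats — sizes chosen so the statistical claims are stable while a
full run of the suite stays in the minutes range on one CPU. All
randomness flows through `numpy.random.default_rng` seeds; child
streams derive from the master seed via `SeedSequence`, so a fixed
configuration reproduces byte-identical pipeline outputs.
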