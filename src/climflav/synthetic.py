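"""Synthetic study generator with known ground truth.

Emulates a nine-site field study of a subtropical fern in August:
per-site monthly climate tables over eight factors (AT/MAT/MIT
temperatures in degrees C, AP/DP/OP precipitation in mm, SD sunshine
hours, ARH relative humidity in %), compound abundances responding to
those factors through planted effect functions, raw assay data (OD
triplicates for total flavonoid content, dose-response absorbance
series for the radical-scavenging assays), and accurate-mass peak lists
with ppm-scale noise.  Every generator is seeded and paired with a
downstream estimator that recovers its ground truth exactly at zero
noise, which is what makes the full pipeline testable without any field
data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import msannotate
from .assay import CalibrationCurve, DoseResponseSeries, ExtractionSpec, OdTriplicate, compute_tfc

__all__ = [
    "CLIMATE_FACTORS",
    "ClimateGenParams",
    "GaussianBump",
    "EffectSpec",
    "ResponseDraw",
    "gen_climate",
    "gen_response",
    "gen_dose_response",
    "gen_tfc_od",
    "gen_peak_list",
]

#: Canonical climate factor codes and column order.
CLIMATE_FACTORS: tuple[str, ...] = ("AT", "MAT", "MIT", "AP", "DP", "OP", "SD", "ARH")


def smooth_benchmark_effect(noise_sd: float = 0.01) -> "EffectSpec":
    """Smooth response over all eight factors used to benchmark training.

    A fixed linear combination plus one Gaussian bump on humidity; the
    default observation noise (sd 0.01) is small relative to the unit
    response scale so the network's fitting error, not the noise floor,
    dominates the training criterion.
    """
    return EffectSpec(
        coefficients={"AT": 0.3, "MAT": -0.2, "MIT": 0.8, "AP": 0.1,
                      "DP": -0.3, "OP": 0.2, "SD": -0.4, "ARH": 0.25},
        bumps={"ARH": GaussianBump(center=0.0, width=1.0, amplitude=0.5)},
        noise_sd=noise_sd,
    )


@dataclass(frozen=True)
class ClimateGenParams:
    """Distributional constants for the climate generator.

    Defaults emulate subtropical August monthly records: mean monthly
    temperature about 27 degrees C with maxima/minima offset by about 5
    degrees, day/night precipitation around 90 mm each (log-normal),
    about 170 sunshine hours, and relative humidity near 78%.  AP is
    the total monthly precipitation, DP + OP, by generator convention.
    """

    at_mean: float = 27.0
    at_sd: float = 2.0
    mat_offset_mean: float = 5.0
    mat_offset_sd: float = 1.0
    mit_offset_mean: float = 5.0
    mit_offset_sd: float = 1.0
    precip_log_mean: float = math.log(90.0)
    precip_log_sd: float = 0.4
    sd_mean: float = 170.0
    sd_sd: float = 30.0
    arh_mean: float = 78.0
    arh_sd: float = 6.0


def gen_climate(
    n_sites: int = 9,
    seed: int = 0,
    params: ClimateGenParams | None = None,
) -> pd.DataFrame:
    """Generate a per-site climate table (sites as rows, factors as columns).

    Invariants hold by construction: MIT <= AT <= MAT, ARH in [0, 100],
    non-negative precipitation and sunshine, and AP = DP + OP.
    Deterministic for a fixed seed.  Requires ``n_sites >= 2`` (a single
    site supports no downstream correlation analysis).
    """
    if n_sites < 2:
        raise ValueError("n_sites must be at least 2")
    p = params or ClimateGenParams()
    rng = np.random.default_rng(seed)

    at = rng.normal(p.at_mean, p.at_sd, n_sites)
    mat = at + np.abs(rng.normal(p.mat_offset_mean, p.mat_offset_sd, n_sites))
    mit = at - np.abs(rng.normal(p.mit_offset_mean, p.mit_offset_sd, n_sites))
    dp = rng.lognormal(p.precip_log_mean, p.precip_log_sd, n_sites)
    op = rng.lognormal(p.precip_log_mean, p.precip_log_sd, n_sites)
    ap = dp + op
    sd = np.clip(rng.normal(p.sd_mean, p.sd_sd, n_sites), 0.0, None)
    arh = np.clip(rng.normal(p.arh_mean, p.arh_sd, n_sites), 0.0, 100.0)

    df = pd.DataFrame(
        {"AT": at, "MAT": mat, "MIT": mit, "AP": ap, "DP": dp, "OP": op, "SD": sd, "ARH": arh},
        index=pd.Index([f"S{i + 1:02d}" for i in range(n_sites)], name="site_id"),
    )
    return df


# ---------------------------------------------------------------------------
# Planted effect functions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaussianBump:
    """Localized nonlinearity on a z-scored factor."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("bump width must be positive")


@dataclass(frozen=True)
class EffectSpec:
    """Planted response: linear coefficients plus optional Gaussian bumps
    on z-scored climate factors, with additive Gaussian observation noise.

    The derived ground-truth sensitivity vector is the normalized mean
    absolute partial derivative of the noiseless response over sites —
    the quantity a one-at-a-time perturbation analysis estimates.
    """

    coefficients: Mapping[str, float] = field(default_factory=dict)
    bumps: Mapping[str, GaussianBump] = field(default_factory=dict)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.coefficients and not self.bumps:
            raise ValueError("effect spec must involve at least one factor")

    @property
    def factor_codes(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys([*self.coefficients, *self.bumps]))

    def evaluate(self, Z: pd.DataFrame) -> np.ndarray:
        """Noiseless response on a table of z-scored factors."""
        f = np.zeros(len(Z))
        for code, c in self.coefficients.items():
            f = f + c * Z[code].to_numpy()
        for code, b in self.bumps.items():
            z = Z[code].to_numpy()
            f = f + b.amplitude * np.exp(-((z - b.center) ** 2) / (2.0 * b.width**2))
        return f

    def gradient(self, Z: pd.DataFrame) -> pd.DataFrame:
        """Analytic partial derivatives w.r.t. each involved z-scored factor."""
        g = {}
        for code in self.factor_codes:
            z = Z[code].to_numpy() if code in Z else None
            grad = np.full(len(Z), self.coefficients.get(code, 0.0))
            if code in self.bumps and z is not None:
                b = self.bumps[code]
                grad = grad + b.amplitude * np.exp(
                    -((z - b.center) ** 2) / (2.0 * b.width**2)
                ) * (-(z - b.center) / b.width**2)
            g[code] = grad
        return pd.DataFrame(g, index=Z.index)


@dataclass
class ResponseDraw:
    """Generated response values with their planted sensitivity truth."""

    values: pd.Series
    sensitivity: pd.Series  # over all climate columns, non-negative, sums to 1
    spec: EffectSpec


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=0)
    sd = sd.where(sd > 0, 1.0)
    return (df - df.mean()) / sd


def gen_response(
    climate: pd.DataFrame, spec: EffectSpec, seed: int = 0
) -> ResponseDraw:
    """Evaluate a planted effect on a climate table and add noise.

    Factors are z-scored over sites before the effect function is
    applied, so coefficients are in comparable (per-standard-deviation)
    units.  Unknown factor codes raise ``ValueError``.
    """
    unknown = [c for c in spec.factor_codes if c not in climate.columns]
    if unknown:
        raise ValueError(f"unknown climate factor code(s): {unknown}")
    rng = np.random.default_rng(seed)
    Z = _zscore(climate)
    f = spec.evaluate(Z)
    noise = rng.normal(0.0, spec.noise_sd, len(f)) if spec.noise_sd > 0 else 0.0
    values = pd.Series(f + noise, index=climate.index, name="response")

    grad = spec.gradient(Z)
    sens = pd.Series(0.0, index=climate.columns)
    for code in grad.columns:
        sens[code] = np.mean(np.abs(grad[code].to_numpy()))
    total = sens.sum()
    if total <= 0:
        raise ValueError("effect spec has zero sensitivity everywhere")
    return ResponseDraw(values=values, sensitivity=sens / total, spec=spec)


# ---------------------------------------------------------------------------
# Assay raw data
# ---------------------------------------------------------------------------


def gen_dose_response(
    true_ic50: float,
    hill: float = 2.0,
    concentrations: Sequence[float] = (),
    control_abs: float = 0.7,
    noise_sd: float = 0.0,
    seed: int = 0,
    assay: str = "DPPH",
) -> DoseResponseSeries:
    """Simulate a radical-scavenging absorbance series.

    Fractional scavenging follows a logistic in log concentration,
    1 / (1 + (IC50/c)^hill), so that scavenging is exactly 50% at
    c = IC50 when noiseless; sample absorbance is
    control * (1 - scavenging) + Gaussian noise.
    """
    if true_ic50 <= 0:
        raise ValueError("true_ic50 must be positive")
    c = np.asarray(list(concentrations), float)
    if c.size == 0:
        c = np.geomspace(true_ic50 / 8.0, true_ic50 * 8.0, 9)
    if np.any(c <= 0) or np.any(np.diff(c) <= 0):
        raise ValueError("concentrations must be positive and strictly increasing")
    rng = np.random.default_rng(seed)
    frac = 1.0 / (1.0 + (true_ic50 / c) ** hill)
    absorb = control_abs * (1.0 - frac)
    if noise_sd > 0:
        absorb = absorb + rng.normal(0.0, noise_sd, c.size)
    return DoseResponseSeries(
        assay=assay,
        concentrations=tuple(float(x) for x in c),
        sample_absorbances=tuple(float(a) for a in absorb),
        control_absorbance=float(control_abs),
    )


def gen_tfc_od(
    true_tfc: float,
    curve: CalibrationCurve,
    extraction: ExtractionSpec | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> OdTriplicate:
    """Invert the TFC formula: OD triplicate whose noiseless readout
    recovers ``true_tfc`` (mg/g) exactly through :func:`compute_tfc`.

    Raises ``ValueError`` when the implied mean OD falls outside [0, 4]
    (physically implausible photometry; adjust the dilution factor).
    """
    if true_tfc <= 0:
        raise ValueError("true_tfc must be positive")
    spec = extraction or ExtractionSpec()
    tfc_pct = true_tfc / 10.0
    denom = spec.aliquot_factor * (spec.extract_volume_ml / 1000.0) * spec.dilution_factor * 100.0
    mean_od = curve.intercept + curve.slope * tfc_pct / denom
    if not 0.0 <= mean_od <= 4.0:
        raise ValueError(
            f"implied mean OD {mean_od:.3f} outside [0, 4]; adjust dilution_factor"
        )
    rng = np.random.default_rng(seed)
    ods = mean_od + (rng.normal(0.0, noise_sd, 3) if noise_sd > 0 else np.zeros(3))
    ods = np.clip(ods, 0.0, None)
    return OdTriplicate(*map(float, ods))


def gen_peak_list(
    formulas: Sequence[msannotate.MolecularFormula | str],
    adducts: Sequence[msannotate.AdductSpec | str] = ("[M-H]-",),
    ppm_noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate measured m/z values for a list of formulas.

    measured = theoretical * (1 + eps/1e6) with eps ~ Normal(0, ppm_noise).
    Returns a long-format table (peak, formula, adduct, mz_theoretical,
    mz); an empty formula list is an error.
    """
    if ppm_noise < 0:
        raise ValueError("ppm_noise must be non-negative")
    if not formulas:
        raise ValueError("formula list must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for i, f in enumerate(formulas, start=1):
        for a in adducts:
            t = msannotate.adduct_mz(f, a)
            eps = rng.normal(0.0, ppm_noise) if ppm_noise > 0 else 0.0
            name = a if isinstance(a, str) else a.name
            rows.append(
                {
                    "peak": i,
                    "formula": str(f),
                    "adduct": name,
                    "mz_theoretical": t,
                    "mz": t * (1.0 + eps / 1e6),
                }
            )
    return pd.DataFrame(rows)
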