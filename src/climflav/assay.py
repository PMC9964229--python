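"""Colorimetric and radical-scavenging assay arithmetic.

Covers the bench calculations for total flavonoid content (TFC, rutin
equivalents by the aluminium-nitrate colorimetric method read at 510 nm),
the DPPH/ABTS/superoxide radical-scavenging percentages, log-linear IC50
interpolation, and the blank-corrected Fe(III) reducing-force readout at
700 nm.

Units: extract concentrations in mg/mL, TFC in % (w/w) and mg/g dry
mass, absorbances dimensionless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "CalibrationCurve",
    "ExtractionSpec",
    "OdTriplicate",
    "DoseResponseSeries",
    "ReducingForceReading",
    "TfcResult",
    "NoCrossingError",
    "ASSAY_WAVELENGTH_NM",
    "fit_calibration",
    "compute_tfc",
    "scavenging_pct",
    "estimate_ic50",
    "reducing_force",
]

#: Detection wavelength per radical-scavenging assay.
ASSAY_WAVELENGTH_NM = {"DPPH": 517, "ABTS": 734, "superoxide": 560}


@dataclass(frozen=True)
class CalibrationCurve:
    """Standard curve ``OD = slope * conc + intercept`` (conc in mg/mL)."""

    slope: float
    intercept: float
    r_squared: float = 1.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")

    def concentration(self, od: float) -> float:
        """Invert the curve: concentration (mg/mL) for an absorbance."""
        return (od - self.intercept) / self.slope


@dataclass(frozen=True)
class ExtractionSpec:
    """Extraction constants entering the TFC formula.

    ``aliquot_factor`` is the ratio of the reaction basis to the aliquot
    taken (default 5, i.e. a 2 mL aliquot of a notional 10 mL basis);
    ``extract_volume`` is the constant volume of the crude extract in mL.
    """

    sample_mass_g: float = 1.0
    extract_volume_ml: float = 50.0
    aliquot_factor: float = 5.0
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sample_mass_g", "extract_volume_ml", "aliquot_factor", "dilution_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class OdTriplicate:
    """Triplicate optical densities at 510 nm."""

    od1: float
    od2: float
    od3: float

    def __post_init__(self) -> None:
        if min(self.od1, self.od2, self.od3) < 0:
            raise ValueError("optical densities must be non-negative")

    @property
    def mean(self) -> float:
        return (self.od1 + self.od2 + self.od3) / 3.0

    @property
    def cv(self) -> float:
        vals = np.array([self.od1, self.od2, self.od3])
        m = vals.mean()
        return float(vals.std(ddof=1) / m) if m > 0 else 0.0


@dataclass(frozen=True)
class DoseResponseSeries:
    """Absorbance series across extract concentrations for one assay."""

    assay: str
    concentrations: tuple[float, ...]
    sample_absorbances: tuple[float, ...]
    control_absorbance: float
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        if self.assay not in ASSAY_WAVELENGTH_NM:
            raise ValueError(f"assay must be one of {sorted(ASSAY_WAVELENGTH_NM)}")
        c = np.asarray(self.concentrations, float)
        if len(c) != len(self.sample_absorbances):
            raise ValueError("concentrations and absorbances differ in length")
        if len(c) and (np.any(c <= 0) or np.any(np.diff(c) <= 0)):
            raise ValueError("concentrations must be positive and strictly increasing")
        if self.control_absorbance <= 0:
            raise ValueError("control absorbance must be positive")
        if self.wavelength_nm is None:
            object.__setattr__(self, "wavelength_nm", ASSAY_WAVELENGTH_NM[self.assay])

    def scavenging(self) -> np.ndarray:
        """Scavenging percentage at each concentration."""
        return np.array(
            [scavenging_pct(a, self.control_absorbance) for a in self.sample_absorbances]
        )


@dataclass(frozen=True)
class ReducingForceReading:
    """Paired 700 nm absorbances: reaction (part A) and blank (part B)."""

    a700_sample: float
    a700_blank: float

    def __post_init__(self) -> None:
        if self.a700_sample < 0 or self.a700_blank < 0:
            raise ValueError("absorbances must be non-negative")


@dataclass
class TfcResult:
    tfc_percent: float
    tfc_mg_per_g: float
    below_blank: bool = False
    flags: list[str] = field(default_factory=list)


class NoCrossingError(ValueError):
    """Dose-response never crosses 50% scavenging."""


def fit_calibration(
    concentrations: Sequence[float], ods: Sequence[float]
) -> CalibrationCurve:
    """Ordinary least squares fit of a standard curve OD ~ concentration."""
    c = np.asarray(concentrations, float)
    y = np.asarray(ods, float)
    if c.size != y.size:
        raise ValueError("concentrations and ODs differ in length")
    if c.size < 3:
        raise ValueError("calibration needs at least 3 points")
    if np.ptp(c) == 0:
        raise ValueError("concentrations must not be constant")
    fit = _sps.linregress(c, y)
    r2 = float(fit.rvalue**2)
    return CalibrationCurve(slope=float(fit.slope), intercept=float(fit.intercept),
                            r_squared=min(max(r2, 0.0), 1.0))


def compute_tfc(
    od: OdTriplicate, curve: CalibrationCurve, spec: ExtractionSpec | None = None
) -> TfcResult:
    """Total flavonoid content from an OD triplicate.

    TFC% = ((mean OD - A) / B) * aliquot_factor * (volume/1000)
           * dilution_factor * 100, with A/B the calibration intercept
    and slope; the mg/g value is TFC% * 10.  A mean OD below the
    intercept (blank-level signal) yields 0 with ``below_blank`` set
    rather than a negative content.
    """
    spec = spec or ExtractionSpec()
    flags: list[str] = []
    if od.cv > 0.10:
        flags.append("triplicate CV > 10%")
        warnings.warn("OD triplicate coefficient of variation exceeds 10%", stacklevel=2)
    conc = curve.concentration(od.mean)  # mg/mL in the reaction aliquot
    pct = conc * spec.aliquot_factor * (spec.extract_volume_ml / 1000.0) \
        * spec.dilution_factor * 100.0
    below = pct < 0
    if below:
        warnings.warn("mean OD below calibration intercept; reporting TFC = 0", stacklevel=2)
        pct = 0.0
    return TfcResult(tfc_percent=pct, tfc_mg_per_g=pct * 10.0,
                     below_blank=below, flags=flags)


def scavenging_pct(a_sample: float, a_control: float) -> float:
    """Radical scavenging percentage, (1 - A_sample/A_control) * 100.

    Negative values (sample absorbance above control) are returned
    as-is with a warning, never clipped.
    """
    if a_control <= 0:
        raise ValueError("control absorbance must be positive")
    pct = (1.0 - a_sample / a_control) * 100.0
    if pct < 0:
        warnings.warn("sample absorbance exceeds control; negative scavenging", stacklevel=2)
    return pct


def estimate_ic50(series: DoseResponseSeries) -> float:
    """IC50 (mg/mL) by linear interpolation on the log10 concentration axis.

    The first adjacent concentration pair whose scavenging percentages
    bracket 50% is interpolated; an exact 50% grid point is returned
    directly.  Raises :class:`NoCrossingError` when the series never
    reaches 50%, reporting the achieved range.  A non-monotone series
    with several crossings uses the first and warns.
    """
    s = series.scavenging()
    c = np.asarray(series.concentrations, float)
    if s.size < 2:
        raise ValueError("need at least 2 dose-response points")

    exact = np.flatnonzero(s == 50.0)
    if exact.size:
        return float(c[exact[0]])

    crossings = np.flatnonzero((s[:-1] - 50.0) * (s[1:] - 50.0) < 0)
    if crossings.size == 0:
        raise NoCrossingError(
            f"scavenging never crosses 50% (achieved {s.min():.1f}%..{s.max():.1f}%)"
        )
    if crossings.size > 1:
        warnings.warn(
            "multiple 50% crossings (non-monotone series); using the first", stacklevel=2
        )
    i = int(crossings[0])
    lc = np.log10(c)
    frac = (50.0 - s[i]) / (s[i + 1] - s[i])
    return float(10 ** (lc[i] + frac * (lc[i + 1] - lc[i])))


def reducing_force(reading: ReducingForceReading) -> float:
    """Blank-corrected 700 nm absorbance; floored at 0 with a warning."""
    diff = reading.a700_sample - reading.a700_blank
    if diff < 0:
        warnings.warn("blank absorbance exceeds sample; reporting 0", stacklevel=2)
        return 0.0
    return diff
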