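"""Accurate-mass annotation of ESI-TOF flavonoid peak lists.

This module reproduces the identification arithmetic behind qualitative
HPLC-ESI-TOF-MS screening of plant flavonoids: monoisotopic masses from
pinned atomic constants, theoretical m/z of the deprotonated ([M-H]-),
protonated ([M+H]+) and deprotonated-dimer ([2M-H]-) ions, ppm and mDa
mass errors, exhaustive CHNOS formula matching under a ppm tolerance
with a ring-double-bond-equivalents (RDBE) plausibility filter, and
tentative identification against a small bundled flavonoid reference
library keyed on molecular formula and UV absorption maxima.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "MolecularFormula",
    "AdductSpec",
    "ADDUCTS",
    "MassError",
    "FormulaCandidate",
    "RawPeak",
    "LibraryEntry",
    "AnnotatedPeak",
    "monoisotopic_mass",
    "adduct_mz",
    "mass_error",
    "match_formula",
    "neutral_loss_mz",
    "annotate_peak",
    "load_reference_library",
    "read_peak_table",
    "annotate_table",
]

#: Monoisotopic atomic masses (Da).  12C is exactly 12 by definition; the
#: remaining values are the CODATA/AME recommendations at the precision
#: needed to reproduce 4-decimal TOF m/z values.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

#: Mass of the charge carrier (proton), electron-corrected.
PROTON_MASS: float = 1.00727646688

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnsupportedElementError(ValueError):
    """Raised for element symbols without a pinned monoisotopic mass."""


@dataclass(frozen=True)
class MolecularFormula:
    """Element composition, e.g. ``MolecularFormula.parse("C27H30O16")``.

    Counts are non-negative integers over the supported element set
    (C, H, N, O, S); at least one atom is required.
    """

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        total = 0
        for element, n in self.counts:
            if element not in MONOISOTOPIC_MASS:
                raise UnsupportedElementError(
                    f"element {element!r} has no pinned monoisotopic mass"
                )
            if n < 0 or int(n) != n:
                raise ValueError(f"count for {element} must be a non-negative integer")
            total += n
        if total == 0:
            raise ValueError("formula must contain at least one atom")

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        """Parse a plain Hill-style formula string such as ``C21H20O12``."""
        s = text.replace("_", "").strip()
        pos = 0
        counts: dict[str, int] = {}
        for m in _FORMULA_TOKEN.finditer(s):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            element = m.group(1)
            n = int(m.group(2)) if m.group(2) else 1
            counts[element] = counts.get(element, 0) + n
            pos = m.end()
        if pos != len(s) or not counts:
            raise ValueError(f"cannot parse formula {text!r}")
        return cls.from_counts(counts)

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "MolecularFormula":
        # Hill order: C, H, then alphabetical.
        order = {"C": 0, "H": 1}
        items = tuple(
            sorted(
                ((e, int(n)) for e, n in counts.items() if n),
                key=lambda it: (order.get(it[0], 2), it[0]),
            )
        )
        return cls(items)

    def count(self, element: str) -> int:
        for e, n in self.counts:
            if e == element:
                return n
        return 0

    def __str__(self) -> str:
        return "".join(f"{e}{n if n != 1 else ''}" for e, n in self.counts)

    @property
    def rdbe(self) -> float:
        """Ring-double-bond equivalents, C - H/2 + N/2 + 1."""
        return self.count("C") - self.count("H") / 2 + self.count("N") / 2 + 1


@dataclass(frozen=True)
class AdductSpec:
    """ESI adduct: ``(multimer * M + proton_delta * m_p) / |charge|``."""

    name: str
    multimer: int
    proton_delta: int
    charge: int


#: The three adduct species used for flavonoid screening.
ADDUCTS: Mapping[str, AdductSpec] = {
    "[M-H]-": AdductSpec("[M-H]-", multimer=1, proton_delta=-1, charge=-1),
    "[M+H]+": AdductSpec("[M+H]+", multimer=1, proton_delta=+1, charge=+1),
    "[2M-H]-": AdductSpec("[2M-H]-", multimer=2, proton_delta=-1, charge=-1),
}


def get_adduct(name: str) -> AdductSpec:
    try:
        return ADDUCTS[name]
    except KeyError:
        raise ValueError(
            f"unknown adduct {name!r}; supported: {sorted(ADDUCTS)}"
        ) from None


def monoisotopic_mass(formula: MolecularFormula | str) -> float:
    """Neutral monoisotopic mass in Da from the pinned atomic constants."""
    if isinstance(formula, str):
        formula = MolecularFormula.parse(formula)
    return sum(n * MONOISOTOPIC_MASS[e] for e, n in formula.counts)


def adduct_mz(formula: MolecularFormula | str, adduct: AdductSpec | str) -> float:
    """Theoretical m/z of an adduct ion of ``formula`` (full precision).

    Round to 4 decimal places to compare with TOF instrument printouts.
    """
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    m = monoisotopic_mass(formula)
    return (adduct.multimer * m + adduct.proton_delta * PROTON_MASS) / abs(adduct.charge)


@dataclass(frozen=True)
class MassError:
    """Relative (ppm) and absolute (mDa) deviation of a measured m/z."""

    ppm: float
    mda: float


def mass_error(measured: float, theoretical: float) -> MassError:
    """Mass error of ``measured`` against ``theoretical`` m/z.

    Sign convention: positive when the measured value is high,
    ppm = (measured - theoretical) / theoretical * 1e6.
    """
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    delta = measured - theoretical
    return MassError(ppm=delta / theoretical * 1e6, mda=delta * 1000.0)


def neutral_loss_mz(parent_mz: float, loss: MolecularFormula | str) -> float:
    """m/z of a fragment after loss of a neutral with the given formula."""
    return parent_mz - monoisotopic_mass(loss)


# ---------------------------------------------------------------------------
# Formula matching
# ---------------------------------------------------------------------------

#: Default element-count search space for formula enumeration.
DEFAULT_BOUNDS: Mapping[str, tuple[int, int]] = {
    "C": (0, 60),
    "H": (0, 100),
    "N": (0, 5),
    "O": (0, 20),
    "S": (0, 2),
}

_MAX_COMBINATIONS = 10_000_000
_RDBE_RANGE = (0.0, 40.0)


@dataclass(frozen=True)
class FormulaCandidate:
    formula: MolecularFormula
    theoretical_mz: float
    error: MassError
    rdbe: float


def match_formula(
    measured_mz: float,
    adduct: AdductSpec | str,
    bounds: Mapping[str, tuple[int, int]] | None = None,
    tol_ppm: float = 5.0,
) -> list[FormulaCandidate]:
    """Exhaustively enumerate CHNOS formulas matching a measured m/z.

    All element-count combinations within ``bounds`` are generated, the
    theoretical adduct m/z computed, and candidates kept when the
    absolute ppm error is within ``tol_ppm`` and the RDBE is an integer
    in [0, 40] (half-integer RDBE means an open-shell species that
    cannot be a neutral molecule — the nitrogen rule).  Candidates are
    ranked by absolute ppm error.

    Returns an empty list when nothing matches.  Raises ``ValueError``
    when the search space exceeds 1e7 combinations.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    bounds = dict(DEFAULT_BOUNDS) | dict(bounds or {})
    for e in bounds:
        if e not in MONOISOTOPIC_MASS:
            raise UnsupportedElementError(f"no pinned mass for element {e!r}")

    elements = sorted(bounds, key=lambda e: ({"C": 0, "H": 1}.get(e, 2), e))
    axes = [np.arange(bounds[e][0], bounds[e][1] + 1) for e in elements]
    n_combos = int(np.prod([a.size for a in axes]))
    if n_combos > _MAX_COMBINATIONS:
        raise ValueError(
            f"bounds yield {n_combos} combinations (> {_MAX_COMBINATIONS}); tighten them"
        )

    ndim = len(axes)

    def grid(i: int) -> np.ndarray:
        shape = [1] * ndim
        shape[i] = axes[i].size
        return axes[i].reshape(shape)

    mass = np.zeros([a.size for a in axes])
    for i, e in enumerate(elements):
        mass = mass + grid(i) * MONOISOTOPIC_MASS[e]

    mz = (adduct.multimer * mass + adduct.proton_delta * PROTON_MASS) / abs(
        adduct.charge
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ppm = (measured_mz - mz) / mz * 1e6
    ok = np.isfinite(ppm) & (np.abs(ppm) <= tol_ppm) & (mass > 0)

    rdbe = np.zeros([a.size for a in axes])
    for i, e in enumerate(elements):
        coeff = {"C": 1.0, "H": -0.5, "N": 0.5}.get(e)
        if coeff is not None:
            rdbe = rdbe + grid(i) * coeff
    rdbe = rdbe + 1.0
    ok &= (rdbe >= _RDBE_RANGE[0]) & (rdbe <= _RDBE_RANGE[1])
    ok &= rdbe == np.round(rdbe)  # nitrogen rule: neutral molecules only

    out: list[FormulaCandidate] = []
    for idx in np.argwhere(ok):
        counts = {e: int(axes[i][idx[i]]) for i, e in enumerate(elements)}
        f = MolecularFormula.from_counts(counts)
        t = adduct_mz(f, adduct)
        out.append(FormulaCandidate(f, t, mass_error(measured_mz, t), f.rdbe))
    out.sort(key=lambda c: abs(c.error.ppm))
    return out


# ---------------------------------------------------------------------------
# Tentative identification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LibraryEntry:
    """Reference compound: formula string, identity, class, UV maxima (nm)."""

    formula: str
    identity: str
    flavonoid_class: str
    lambda_max: tuple[float, ...]


@dataclass
class RawPeak:
    """One chromatographic peak with measured m/z per observed adduct."""

    number: int
    rt_min: float
    mz_by_adduct: dict[str, float]
    lambda_max: tuple[float, ...] = ()


FLAVONOID_CLASSES = ("flavonol", "flavone", "isoflavone", "other", "unknown")


@dataclass
class AnnotatedPeak:
    number: int
    rt_min: float
    mz_by_adduct: dict[str, float]
    lambda_max: tuple[float, ...]
    formula: str | None
    neutral_mass: float | None
    error: MassError | None
    identity: str | None
    flavonoid_class: str
    ambiguous: bool = False
    candidates_by_adduct: dict[str, str | None] = field(default_factory=dict)


def load_reference_library() -> list[LibraryEntry]:
    """Load the bundled flavonoid/phenolic reference library."""
    path = resources.files("climflav.data").joinpath("flavonoid_library.csv")
    entries: list[LibraryEntry] = []
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            lam = tuple(float(x) for x in row["lambda_max"].split(";") if x)
            entries.append(
                LibraryEntry(
                    formula=row["formula"],
                    identity=row["identity"],
                    flavonoid_class=row["flavonoid_class"],
                    lambda_max=lam,
                )
            )
    return entries


def _lambda_match(
    reference: Sequence[float], observed: Sequence[float], tol_nm: float
) -> bool:
    """Every reference maximum must be matched by some observed one."""
    return all(any(abs(r - o) <= tol_nm for o in observed) for r in reference)


def annotate_peak(
    peak: RawPeak,
    library: Sequence[LibraryEntry],
    tol_ppm: float = 5.0,
    bounds: Mapping[str, tuple[int, int]] | None = None,
    lambda_tol_nm: float = 5.0,
) -> AnnotatedPeak:
    """Assign a formula and tentative identity to a raw peak.

    Each observed adduct m/z is formula-matched independently.  The
    consensus formula is the candidate appearing in every adduct's
    match list with the smallest summed |ppm| error; when the candidate
    sets are disjoint (a genuine conflict, e.g. a dimer ion that is not
    arithmetically 2M-H of the monomer) the peak is flagged
    ``ambiguous``, the per-adduct top candidates are all reported, and
    the deprotonated-ion candidate is carried forward.  Identity is
    assigned when the consensus formula and the UV pattern (every
    library maximum within ``lambda_tol_nm``) agree with a library
    entry; otherwise the class is "unknown".
    """
    if not peak.mz_by_adduct:
        raise ValueError("peak has no measured adduct m/z")

    cands_by_adduct: dict[str, list[FormulaCandidate]] = {}
    per_adduct: dict[str, str | None] = {}
    for name, mz in peak.mz_by_adduct.items():
        cands = match_formula(mz, name, bounds=bounds, tol_ppm=tol_ppm)
        cands_by_adduct[name] = cands
        per_adduct[name] = str(cands[0].formula) if cands else None

    # Intersection of candidate formulas over adducts with any match.
    matched = {n: {str(c.formula) for c in cs} for n, cs in cands_by_adduct.items() if cs}
    common: set[str] = set.intersection(*matched.values()) if matched else set()

    primary = "[M-H]-" if "[M-H]-" in peak.mz_by_adduct else next(iter(peak.mz_by_adduct))
    ambiguous = bool(matched) and not common
    formula: str | None = None
    if common:
        total_ppm = {
            f: sum(
                min(abs(c.error.ppm) for c in cs if str(c.formula) == f)
                for cs in cands_by_adduct.values()
                if cs
            )
            for f in common
        }
        formula = min(total_ppm, key=total_ppm.get)
    elif matched:
        warnings.warn(
            f"peak {peak.number}: conflicting formula matches across adducts: "
            f"{per_adduct}",
            stacklevel=2,
        )
        formula = per_adduct.get(primary) or sorted(
            f for f in per_adduct.values() if f
        )[0]

    neutral = err = None
    if formula is not None:
        neutral = monoisotopic_mass(formula)
        if per_adduct.get(primary) == formula:
            err = mass_error(peak.mz_by_adduct[primary], adduct_mz(formula, primary))

    identity = None
    klass = "unknown"
    if formula is not None:
        # Among formula-consistent entries whose UV pattern is reproduced,
        # prefer the most specific pattern (most reference maxima), then
        # the smallest total wavelength deviation.
        best_key = None
        for entry in library:
            if entry.formula != formula or not _lambda_match(
                entry.lambda_max, peak.lambda_max, lambda_tol_nm
            ):
                continue
            dev = sum(
                min(abs(r - o) for o in peak.lambda_max) if peak.lambda_max else 0.0
                for r in entry.lambda_max
            )
            key = (-len(entry.lambda_max), dev)
            if best_key is None or key < best_key:
                best_key = key
                identity = entry.identity
                klass = entry.flavonoid_class

    return AnnotatedPeak(
        number=peak.number,
        rt_min=peak.rt_min,
        mz_by_adduct=dict(peak.mz_by_adduct),
        lambda_max=tuple(peak.lambda_max),
        formula=formula,
        neutral_mass=neutral,
        error=err,
        identity=identity,
        flavonoid_class=klass,
        ambiguous=ambiguous,
        candidates_by_adduct=per_adduct,
    )


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def read_peak_table(path) -> list[RawPeak]:
    """Read a long-format peak list CSV (peak, rt_min, adduct, mz, uv_lambda_max)."""
    import pandas as pd

    df = pd.read_csv(path)
    peaks: list[RawPeak] = []
    for number, grp in df.groupby("peak", sort=True):
        lam: tuple[float, ...] = ()
        raw = grp["uv_lambda_max"].dropna()
        if len(raw):
            lam = tuple(float(x) for x in str(raw.iloc[0]).split(";") if x)
        peaks.append(
            RawPeak(
                number=int(number),
                rt_min=float(grp["rt_min"].iloc[0]),
                mz_by_adduct={
                    str(r.adduct): float(r.mz) for r in grp.itertuples()
                },
                lambda_max=lam,
            )
        )
    return peaks


def annotate_table(
    peaks: Iterable[RawPeak],
    library: Sequence[LibraryEntry] | None = None,
    tol_ppm: float = 5.0,
    bounds: Mapping[str, tuple[int, int]] | None = None,
):
    """Annotate peaks and return a flat DataFrame mirroring a screening table."""
    import pandas as pd

    if library is None:
        library = load_reference_library()
    rows = []
    for p in peaks:
        a = annotate_peak(p, library, tol_ppm=tol_ppm, bounds=bounds)
        rows.append(
            {
                "peak": a.number,
                "rt_min": a.rt_min,
                "formula": a.formula,
                "neutral_mass": None if a.neutral_mass is None else round(a.neutral_mass, 4),
                "experimental_mz": "; ".join(
                    f"{k}{v}" for k, v in a.mz_by_adduct.items()
                ),
                "error_ppm": None if a.error is None else round(a.error.ppm, 2),
                "error_mda": None if a.error is None else round(a.error.mda, 2),
                "uv_lambda_max": ";".join(f"{x:g}" for x in a.lambda_max),
                "identity": a.identity,
                "flavonoid_class": a.flavonoid_class,
                "ambiguous": a.ambiguous,
            }
        )
    return pd.DataFrame(rows)
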