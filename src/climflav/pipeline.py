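"""End-to-end reproducible pipeline: simulate -> assay -> annotate ->
train -> sensitivity -> stats -> report.

All tabular interchange is CSV, models and reports are JSON, and the
configuration is YAML.  Every stochastic stage draws its seed
deterministically from the single master seed in the configuration, so
a fixed config reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assay import (
    CalibrationCurve,
    DoseResponseSeries,
    ExtractionSpec,
    OdTriplicate,
    ReducingForceReading,
    compute_tfc,
    estimate_ic50,
    reducing_force,
)
from .gabp import NetworkConfig, ScalingParams, TrainedNetwork, fit_gabp, sensitivity as gabp_sensitivity, unflatten_weights, flatten_weights
from .msannotate import annotate_table, load_reference_library, read_peak_table
from .stats import hca, pca_scores, pearson_matrix
from .synthetic import (
    CLIMATE_FACTORS,
    EffectSpec,
    gen_climate,
    gen_dose_response,
    gen_response,
    gen_tfc_od,
    gen_peak_list,
)

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "StageError",
    "RunReport",
    "STAGES",
    "run_pipeline",
    "run_stage",
]


class ConfigError(ValueError):
    """Invalid pipeline configuration (raised before any stage runs)."""


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


# ---------------------------------------------------------------------------
# Planted study structure
# ---------------------------------------------------------------------------

#: Default planted effect of climate on the eight monitored flavonoids.
#: Coefficients act on z-scored factors; signs and dominant factors follow
#: the qualitative pattern expected for subtropical ferns (sunshine driving
#: flavonols/isoflavone, temperature driving flavones).
COMPOUND_EFFECTS: dict[str, dict[str, float]] = {
    "isotrifolin": {"MIT": 0.9, "OP": 0.7, "SD": -0.5},
    "rutin": {"SD": 0.9, "MIT": -0.4},
    "myricetin_deoxyhexoside": {"OP": 0.7, "ARH": 0.5, "SD": 0.6},
    "quercetin_3_rutinoside": {"MIT": -0.9, "AP": -0.5},
    "luteolin_6_C_glucoside": {"MIT": -0.8, "AT": 0.4},
    "quercitrin": {"MAT": 0.8, "SD": -0.5},
    "genestein_G2": {"SD": 0.8, "ARH": 0.6, "AP": 0.4},
    "luteolin_caffeoyl_glucoside": {"SD": 0.6, "ARH": 0.5, "OP": -0.5},
}

TFC_EFFECT = {"MIT": -0.7, "DP": 0.4, "MAT": 0.3, "SD": -0.3}
IC50_EFFECTS = {
    "DPPH": {"DP": 0.6, "MIT": 0.4},
    "ABTS": {"MAT": -0.5, "DP": 0.5},
    "superoxide": {"ARH": 0.6, "MAT": -0.3},
}
REDUCING_EFFECT = {"MIT": -0.5, "AP": -0.4}
IC50_MEDIAN = {"DPPH": 0.8, "ABTS": 1.2, "superoxide": 2.0}  # mg/mL


@dataclass
class PipelineConfig:
    """Everything needed for a reproducible run.

    ``seed`` is the master seed; each stochastic stage derives its own
    stream from it.  TFC ground truth is drawn to span
    ``tfc_range`` mg/g.
    """

    seed: int = 1
    n_sites: int = 9
    ppm_noise: float = 2.0
    od_noise_sd: float = 0.005
    dose_noise_sd: float = 0.005
    response_noise_sd: float = 0.05
    tfc_range: tuple[float, float] = (100.0, 400.0)
    calibration_slope: float = 10.655
    calibration_intercept: float = -0.0076
    extraction: dict = field(
        default_factory=lambda: {
            "sample_mass_g": 1.0,
            "extract_volume_ml": 50.0,
            "aliquot_factor": 5.0,
            "dilution_factor": 10.0,
        }
    )
    annotation_tol_ppm: float = 5.0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    band_thresholds: tuple[float, float, float] = (0.1, 0.4, 0.7)
    hca_linkage: str = "average"
    hca_metric: str = "euclidean"

    def validate(self) -> None:
        if self.n_sites < 2:
            raise ConfigError("n_sites must be at least 2")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        for name in ("ppm_noise", "od_noise_sd", "dose_noise_sd", "response_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        lo, hi = self.tfc_range
        if not 0 < lo < hi:
            raise ConfigError("tfc_range must be increasing and positive")
        try:
            ExtractionSpec(**self.extraction)
            self.network.validate()
        except (ValueError, TypeError) as exc:
            raise ConfigError(str(exc)) from exc

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["network"] = self.network.to_dict()
        d["tfc_range"] = list(self.tfc_range)
        d["band_thresholds"] = list(self.band_thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "network" in d:
            d["network"] = NetworkConfig.from_dict(d["network"])
        if "tfc_range" in d:
            d["tfc_range"] = tuple(d["tfc_range"])
        if "band_thresholds" in d:
            d["band_thresholds"] = tuple(d["band_thresholds"])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def _derive_seed(base: int, *key: int) -> int:
    """Deterministic child seed below 2**31."""
    ss = np.random.SeedSequence([int(base), *map(int, key)])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig, outdir: Path) -> list[str]:
    """Generate climate, responses, assay raw data and peak lists."""
    outdir.mkdir(parents=True, exist_ok=True)
    curve = CalibrationCurve(config.calibration_slope, config.calibration_intercept)
    extraction = ExtractionSpec(**config.extraction)

    climate = gen_climate(config.n_sites, seed=_derive_seed(config.seed, 0))
    climate.to_csv(outdir / "climate.csv")

    truth: dict = {"seed": config.seed, "n_sites": config.n_sites,
                   "sensitivity": {}, "tfc_mg_g": {}, "ic50_mg_ml": {},
                   "abundances": {}}

    responses = {}
    for k, (name, coeffs) in enumerate(COMPOUND_EFFECTS.items()):
        spec = EffectSpec(coefficients=coeffs, noise_sd=config.response_noise_sd)
        draw = gen_response(climate, spec, seed=_derive_seed(config.seed, 1, k))
        # abundances are positive: log-linear response around exp(2)
        responses[name] = np.exp(2.0 + 0.5 * draw.values.to_numpy())
        truth["sensitivity"][name] = draw.sensitivity.round(6).to_dict()
    resp_df = pd.DataFrame(responses, index=climate.index)
    resp_df.to_csv(outdir / "responses.csv")
    truth["abundances"] = {c: resp_df[c].round(6).to_dict() for c in resp_df}

    # --- TFC ground truth and OD triplicates
    tfc_spec = EffectSpec(coefficients=TFC_EFFECT, noise_sd=config.response_noise_sd)
    tfc_draw = gen_response(climate, tfc_spec, seed=_derive_seed(config.seed, 2))
    lo, hi = config.tfc_range
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    tfc = np.clip(mid + half * 0.55 * tfc_draw.values.to_numpy(), lo, hi)
    truth["sensitivity"]["TFC"] = tfc_draw.sensitivity.round(6).to_dict()
    od_rows = []
    for i, site in enumerate(climate.index):
        od = gen_tfc_od(tfc[i], curve, extraction,
                        noise_sd=config.od_noise_sd,
                        seed=_derive_seed(config.seed, 3, i))
        od_rows.append({"site_id": site, "od1": od.od1, "od2": od.od2, "od3": od.od3})
        truth["tfc_mg_g"][site] = round(float(tfc[i]), 6)
    pd.DataFrame(od_rows).to_csv(outdir / "od.csv", index=False)

    # --- dose-response series per assay per site
    dr_rows = []
    for a, (assay_name, coeffs) in enumerate(IC50_EFFECTS.items()):
        spec = EffectSpec(coefficients=coeffs, noise_sd=config.response_noise_sd)
        draw = gen_response(climate, spec, seed=_derive_seed(config.seed, 4, a))
        ic50 = IC50_MEDIAN[assay_name] * np.exp(0.35 * draw.values.to_numpy())
        truth["sensitivity"][f"IC50_{assay_name}"] = draw.sensitivity.round(6).to_dict()
        truth["ic50_mg_ml"][assay_name] = {}
        grid = tuple(np.geomspace(0.05, 10.0, 10))
        for i, site in enumerate(climate.index):
            series = gen_dose_response(
                float(ic50[i]), hill=2.0, concentrations=grid, control_abs=0.7,
                noise_sd=config.dose_noise_sd,
                seed=_derive_seed(config.seed, 5, a, i), assay=assay_name,
            )
            truth["ic50_mg_ml"][assay_name][site] = round(float(ic50[i]), 6)
            for c, ab in zip(series.concentrations, series.sample_absorbances):
                dr_rows.append(
                    {"assay": assay_name, "site_id": site, "concentration": c,
                     "absorbance": ab, "control": series.control_absorbance}
                )
    pd.DataFrame(dr_rows).to_csv(outdir / "dose_response.csv", index=False)

    # --- reducing force readings
    red_spec = EffectSpec(coefficients=REDUCING_EFFECT, noise_sd=config.response_noise_sd)
    red_draw = gen_response(climate, red_spec, seed=_derive_seed(config.seed, 6))
    red = np.clip(0.5 + 0.1 * red_draw.values.to_numpy(), 0.05, None)
    truth["sensitivity"]["reducing_force"] = red_draw.sensitivity.round(6).to_dict()
    rng = np.random.default_rng(_derive_seed(config.seed, 7))
    blank = np.abs(rng.normal(0.08, 0.01, config.n_sites))
    pd.DataFrame(
        {"site_id": climate.index, "a700_sample": red + blank, "a700_blank": blank}
    ).to_csv(outdir / "reducing.csv", index=False)

    # --- accurate-mass peak list over the bundled library
    library = load_reference_library()
    peaks = gen_peak_list(
        [e.formula for e in library], adducts=("[M-H]-", "[M+H]+"),
        ppm_noise=config.ppm_noise, seed=_derive_seed(config.seed, 8),
    )
    peaks["rt_min"] = peaks["peak"] * 3.0
    peaks["uv_lambda_max"] = peaks["peak"].map(
        {i + 1: ";".join(f"{x:g}" for x in e.lambda_max) for i, e in enumerate(library)}
    )
    peaks[["peak", "rt_min", "adduct", "mz", "uv_lambda_max"]].to_csv(
        outdir / "peaks.csv", index=False
    )

    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return ["climate.csv", "responses.csv", "od.csv", "dose_response.csv",
            "reducing.csv", "peaks.csv", "truth.json"]


def stage_assay(config: PipelineConfig, outdir: Path) -> list[str]:
    """Compute per-site TFC, IC50s and reducing force from raw assay CSVs."""
    curve = CalibrationCurve(config.calibration_slope, config.calibration_intercept)
    extraction = ExtractionSpec(**config.extraction)
    od = pd.read_csv(_require(outdir, "od.csv", "assay"))
    dose = pd.read_csv(_require(outdir, "dose_response.csv", "assay"))
    red = pd.read_csv(_require(outdir, "reducing.csv", "assay"))

    rows = {}
    for r in od.itertuples():
        res = compute_tfc(OdTriplicate(r.od1, r.od2, r.od3), curve, extraction)
        rows[r.site_id] = {"tfc_mg_g": res.tfc_mg_per_g}
    for (assay_name, site), grp in dose.groupby(["assay", "site_id"]):
        grp = grp.sort_values("concentration")
        series = DoseResponseSeries(
            assay=assay_name,
            concentrations=tuple(grp["concentration"]),
            sample_absorbances=tuple(grp["absorbance"]),
            control_absorbance=float(grp["control"].iloc[0]),
        )
        rows.setdefault(site, {})[f"ic50_{assay_name}"] = estimate_ic50(series)
    for r in red.itertuples():
        rows.setdefault(r.site_id, {})["reducing_force"] = reducing_force(
            ReducingForceReading(r.a700_sample, r.a700_blank)
        )
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "site_id"
    out.to_csv(outdir / "assay_results.csv")
    return ["assay_results.csv"]


def stage_annotate(config: PipelineConfig, outdir: Path) -> list[str]:
    """Formula-match and tentatively identify the peak list."""
    peaks = read_peak_table(_require(outdir, "peaks.csv", "annotate"))
    table = annotate_table(peaks, tol_ppm=config.annotation_tol_ppm)
    table.to_csv(outdir / "annotations.csv", index=False)
    return ["annotations.csv"]


def _net_to_json(name: str, net: TrainedNetwork) -> dict:
    return {
        "response": name,
        "layer_sizes": list(net.config.layer_sizes),
        "input_range": list(net.config.input_range),
        "seed": net.config.seed,
        "converged": net.converged,
        "epochs": net.epochs,
        "final_sse": net.error_trace[-1] if net.error_trace else None,
        "weights": flatten_weights(net.weights).tolist(),
        "x_scaler": {"mins": net.x_scaler.mins.tolist(),
                     "maxs": net.x_scaler.maxs.tolist(),
                     "lo": net.x_scaler.lo, "hi": net.x_scaler.hi},
        "y_scaler": {"mins": net.y_scaler.mins.tolist(),
                     "maxs": net.y_scaler.maxs.tolist(),
                     "lo": net.y_scaler.lo, "hi": net.y_scaler.hi},
        "error_trace_summary": {
            "first": net.error_trace[0], "last": net.error_trace[-1],
            "epochs": len(net.error_trace) - 1,
        },
    }


def stage_train(config: PipelineConfig, outdir: Path) -> list[str]:
    """Fit one GA-BP network per response column against the climate table."""
    climate = pd.read_csv(_require(outdir, "climate.csv", "train"), index_col="site_id")
    responses = pd.read_csv(
        _require(outdir, "responses.csv", "train"), index_col="site_id"
    )
    X = climate[list(CLIMATE_FACTORS)].to_numpy(float)
    models = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-sample warning surfaces once per run
        if X.shape[0] < 20:
            warnings.simplefilter("default")
            warnings.warn(
                "fewer than 20 sites: models report training-set fit only",
                stacklevel=2,
            )
            warnings.simplefilter("ignore")
        for k, name in enumerate(responses.columns):
            cfg = NetworkConfig.from_dict(config.network.to_dict())
            cfg.seed = _derive_seed(config.seed, 9, k)
            net = fit_gabp(X, responses[name].to_numpy(float), cfg)
            models.append(_net_to_json(name, net))
    (outdir / "model.json").write_text(json.dumps(
        {"version": __version__, "factors": list(CLIMATE_FACTORS), "models": models},
        indent=1))
    return ["model.json"]


def stage_sensitivity(config: PipelineConfig, outdir: Path) -> list[str]:
    """One-at-a-time factor sensitivities from the trained models."""
    blob = json.loads(_require(outdir, "model.json", "sensitivity").read_text())
    climate = pd.read_csv(
        _require(outdir, "climate.csv", "sensitivity"), index_col="site_id"
    )
    X = climate[list(CLIMATE_FACTORS)].to_numpy(float)
    rows = []
    for m in blob["models"]:
        cfg = NetworkConfig(layer_sizes=list(m["layer_sizes"]),
                            input_range=tuple(m["input_range"]), seed=m["seed"])
        xs = ScalingParams(mins=np.array(m["x_scaler"]["mins"]),
                           maxs=np.array(m["x_scaler"]["maxs"]),
                           lo=m["x_scaler"]["lo"], hi=m["x_scaler"]["hi"])
        net = TrainedNetwork(
            weights=unflatten_weights(np.array(m["weights"]), cfg.layer_sizes),
            config=cfg, x_scaler=xs,
        )
        prof = gabp_sensitivity(
            net, xs.transform(X), factors=blob["factors"], response=m["response"]
        )
        rows.append({"response": m["response"],
                     **dict(zip(prof.factors, np.round(prof.values, 6)))})
    pd.DataFrame(rows).set_index("response").to_csv(outdir / "sensitivity.csv")
    return ["sensitivity.csv"]


def stage_stats(config: PipelineConfig, outdir: Path) -> list[str]:
    """Pearson banding, PCA and HCA on the run's tables."""
    climate = pd.read_csv(_require(outdir, "climate.csv", "stats"), index_col="site_id")
    responses = pd.read_csv(
        _require(outdir, "responses.csv", "stats"), index_col="site_id"
    )
    pieces = [responses]
    assay_path = outdir / "assay_results.csv"
    if assay_path.exists():
        pieces.append(pd.read_csv(assay_path, index_col="site_id"))
    obs = pd.concat(pieces, axis=1)

    report = pearson_matrix(obs, climate, thresholds=config.band_thresholds)
    report.to_long().to_csv(outdir / "correlations.csv", index=False)

    pca = pca_scores(climate)
    pca.scores.to_csv(outdir / "pca_scores.csv")
    pca.loadings.to_csv(outdir / "pca_loadings.csv")

    combined = pd.concat([climate, obs], axis=1)
    h = hca(combined, linkage=config.hca_linkage, metric=config.hca_metric)
    pd.DataFrame(
        {"merge": range(len(h.heights)), "left": h.merges[:, 0],
         "right": h.merges[:, 1], "height": h.heights}
    ).to_csv(outdir / "hca_merges.csv", index=False)
    ordered = h.zscored.iloc[h.leaf_order]
    ordered.to_csv(outdir / "heatmap_matrix.csv")
    return ["correlations.csv", "pca_scores.csv", "pca_loadings.csv",
            "hca_merges.csv", "heatmap_matrix.csv"]


@dataclass
class RunReport:
    stages: list[dict]
    config_hash: str
    version: str
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def stage_report(config: PipelineConfig, outdir: Path) -> list[str]:
    """Assemble the machine-readable run report."""
    stages = []
    for name, outputs in _EXPECTED_OUTPUTS.items():
        present = [f for f in outputs if (outdir / f).exists()]
        stages.append({
            "stage": name,
            "status": "ok" if len(present) == len(outputs) else "incomplete",
            "outputs": present,
        })
    report = RunReport(
        stages=stages, config_hash=config.content_hash(),
        version=__version__, seed=config.seed,
    )
    (outdir / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
    return ["report.json"]


_EXPECTED_OUTPUTS = {
    "simulate": ["climate.csv", "responses.csv", "od.csv", "dose_response.csv",
                 "reducing.csv", "peaks.csv", "truth.json"],
    "assay": ["assay_results.csv"],
    "annotate": ["annotations.csv"],
    "train": ["model.json"],
    "sensitivity": ["sensitivity.csv"],
    "stats": ["correlations.csv", "pca_scores.csv", "pca_loadings.csv",
              "hca_merges.csv", "heatmap_matrix.csv"],
}

STAGES = {
    "simulate": stage_simulate,
    "assay": stage_assay,
    "annotate": stage_annotate,
    "train": stage_train,
    "sensitivity": stage_sensitivity,
    "stats": stage_stats,
    "report": stage_report,
}


def _require(outdir: Path, filename: str, stage: str) -> Path:
    path = outdir / filename
    if not path.exists():
        raise StageError(f"stage {stage!r}: required input {filename!r} not found in {outdir}")
    return path


def run_stage(name: str, config: PipelineConfig, outdir: Path) -> list[str]:
    config.validate()
    try:
        fn = STAGES[name]
    except KeyError:
        raise ValueError(f"unknown stage {name!r}") from None
    try:
        return fn(config, Path(outdir))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(config: PipelineConfig, outdir: Path | str) -> RunReport:
    """Run every stage in order; halts on the first failure.

    The configuration is validated (schema errors surface before any
    stage executes) and echoed to ``config.yaml`` in the output
    directory.  Idempotent for fixed seeds.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    for name in ("simulate", "assay", "annotate", "train", "sensitivity", "stats", "report"):
        run_stage(name, config, outdir)
    return RunReport(
        stages=json.loads((outdir / "report.json").read_text())["stages"],
        config_hash=config.content_hash(),
        version=__version__,
        seed=config.seed,
    )
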