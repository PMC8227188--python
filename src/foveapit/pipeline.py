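"""Study workflows: center-location comparison and model comparison.

Two orchestrated analyses mirror how paired raster/star acquisitions of
the same eyes are compared:

``run_center_comparison``
    For every eye and each of the four center-location strategies, center
    each acquisition's TRT map with its own estimated center, resample
    both onto the common 3 x 3 mm / 0.02 mm grid, and measure the
    alignment dissimilarity (Dalign).  Method distributions are compared
    with Kruskal-Wallis and pairwise Mann-Whitney tests.

``run_model_comparison``
    Center every map with the smooth+min strategy (the best aligner),
    build the 24-direction radial profile sets, compute raw geometric
    parameters, fit every configured model/smoother, and report fitting
    RMSE (raster and star separately), per-parameter ICC(2,1) between
    raster and star with bootstrap CIs, per-parameter estimation bias,
    and the LOESS span-sweep ICC-vs-bias curve.

Both workflows are fully deterministic under a fixed seed and treat eyes
as independent work units.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import agreement, morphometry
from .center_location import CENTER_METHODS, FoveaCenter, locate_center
from .oct_io import OCTScan, TRTPointCloud
from .pit_models import fit_model, get_model_spec
from .preprocessing import (
    GRID_EXTENT_MM,
    GRID_SPACING_MM,
    RADIAL_N_DIRECTIONS,
    RADIAL_RADIUS_MM,
    RADIAL_STEP_MM,
    compute_trt,
    resample_radial,
    resample_regular,
    standardize_orientation,
)
from .synthetic import EyeRecord

log = logging.getLogger("foveapit")

PARAM_KEYS = ("cft_um", "rim_height_um", "rim_radius_mm", "max_slope_um_per_mm")

DEFAULT_MODELS = ("dubis", "ding", "scheibe", "liu", "yadav", "breher")
DEFAULT_LOESS_SPANS = (0.20, 0.50)
DEFAULT_SWEEP_SPANS = tuple(np.round(np.arange(0.05, 0.51, 0.05), 2))


@dataclass
class StudyConfig:
    """Declarative configuration of a comparison study."""

    seed: int = 0
    center_method: str = "smooth_min"
    models: tuple = DEFAULT_MODELS
    loess_spans: tuple = DEFAULT_LOESS_SPANS
    loess_sweep_spans: tuple = DEFAULT_SWEEP_SPANS
    grid_extent_mm: float = GRID_EXTENT_MM
    grid_spacing_mm: float = GRID_SPACING_MM
    radial_radius_mm: float = RADIAL_RADIUS_MM
    radial_n_directions: int = RADIAL_N_DIRECTIONS
    radial_step_mm: float = RADIAL_STEP_MM
    n_bootstrap: int = 10_000
    bootstrap_level: float = 0.95

    def __post_init__(self) -> None:
        for m in self.models:
            get_model_spec(m)  # raises on unknown ids
        if self.center_method not in CENTER_METHODS:
            raise ValueError(f"unknown center method {self.center_method!r}")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("models", "loess_spans", "loess_sweep_spans"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def approach_ids(self) -> list[str]:
        """Model/smoother row labels in report order."""
        return list(self.models) + [f"loess{int(round(s * 100))}" for s in self.loess_spans]


def scan_to_cloud(scan: OCTScan) -> TRTPointCloud:
    """TRT cloud in the orientation-standardized (right-eye) frame."""
    return standardize_orientation(compute_trt(scan), scan.meta.eye)


# ---------------------------------------------------------------------------
# center-location comparison


@dataclass
class CenterComparisonReport:
    dalign_um: pd.DataFrame          # rows = eyes, columns = methods
    centers: dict                    # eye -> {method -> (raster FC, star FC)}
    summary: pd.DataFrame            # median / IQR per method
    tests: agreement.DistributionComparison
    localization_error_mm: pd.DataFrame | None = None
    seed: int = 0

    def to_json_dict(self) -> dict:
        out = {
            "seed": self.seed,
            "dalign_um": self.dalign_um.to_dict(orient="index"),
            "summary": self.summary.to_dict(orient="index"),
            "kruskal": {"h": self.tests.kruskal_h, "p": self.tests.kruskal_p},
            "pairwise": self.tests.pairwise,
            "shapiro_p": self.tests.shapiro_p,
        }
        if self.localization_error_mm is not None:
            out["localization_error_mm"] = self.localization_error_mm.to_dict(
                orient="index"
            )
        return out


def run_center_comparison(
    cohort: list[EyeRecord], config: StudyConfig | None = None
) -> CenterComparisonReport:
    """Dalign of paired raster/star maps under each centering strategy."""
    config = config or StudyConfig()
    rows = {}
    centers = {}
    loc_rows = {}
    for rec in cohort:
        clouds = {"raster": scan_to_cloud(rec.raster), "star": scan_to_cloud(rec.star)}
        eye_row = {}
        eye_centers = {}
        loc_row = {}
        for method in CENTER_METHODS:
            fcs = {}
            grids = {}
            for pattern, cloud in clouds.items():
                fc = locate_center(cloud, method)
                fcs[pattern] = fc
                grids[pattern] = resample_regular(
                    cloud,
                    config.grid_extent_mm,
                    config.grid_spacing_mm,
                    center=fc,
                )
            eye_row[method] = agreement.dalign(grids["raster"], grids["star"])
            eye_centers[method] = (fcs["raster"], fcs["star"])
            if rec.raster_cfg is not None:
                for pattern, cfg in (("raster", rec.raster_cfg), ("star", rec.star_cfg)):
                    true_c = cfg.decenter_mm
                    est = fcs[pattern]
                    loc_row[f"{method}_{pattern}"] = float(
                        np.hypot(est.x_mm - true_c[0], est.y_mm - true_c[1])
                    )
        rows[rec.subject_id] = eye_row
        centers[rec.subject_id] = eye_centers
        if loc_row:
            loc_rows[rec.subject_id] = loc_row
        log.info("center comparison: %s done", rec.subject_id)

    dal = pd.DataFrame.from_dict(rows, orient="index")[list(CENTER_METHODS)]
    summary = pd.DataFrame(
        {
            "median_um": dal.median(),
            "q1_um": dal.quantile(0.25),
            "q3_um": dal.quantile(0.75),
        }
    )
    tests = agreement.compare_distributions(
        [dal[m].to_numpy() for m in CENTER_METHODS], names=list(CENTER_METHODS)
    )
    loc = pd.DataFrame.from_dict(loc_rows, orient="index") if loc_rows else None
    return CenterComparisonReport(
        dalign_um=dal,
        centers=centers,
        summary=summary,
        tests=tests,
        localization_error_mm=loc,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# model comparison


@dataclass
class ModelComparisonReport:
    rmse_um: pd.DataFrame        # rows = approach, cols = raster/star mean & sd
    icc: pd.DataFrame            # rows = approach (incl. raw), cols per parameter
    icc_ci: dict                 # (approach, param) -> (low, high)
    bias_pct: pd.DataFrame       # rows = approach, multi-cols param x pattern
    raw_params: dict             # pattern -> DataFrame rows=eyes cols=params
    fitted_params: dict          # approach -> pattern -> DataFrame
    loess_sweep: pd.DataFrame | None
    excluded: dict               # reason -> list of (eye, approach)
    seed: int = 0

    def table_fit_agreement(self) -> pd.DataFrame:
        """Model x {RMSE raster/star, ICC per parameter} with dash cells."""
        rows = {}
        for approach in ["none"] + list(self.icc.index.drop("raw", errors="ignore")):
            key = "raw" if approach == "none" else approach
            row = {}
            if approach == "none":
                row["rmse_raster"] = row["rmse_star"] = "-"
            else:
                row["rmse_raster"] = (
                    f"{self.rmse_um.loc[key, 'raster_mean']:.1f} ± "
                    f"{self.rmse_um.loc[key, 'raster_sd']:.1f}"
                )
                row["rmse_star"] = (
                    f"{self.rmse_um.loc[key, 'star_mean']:.1f} ± "
                    f"{self.rmse_um.loc[key, 'star_sd']:.1f}"
                )
            for param in PARAM_KEYS:
                fixed = key != "raw" and param in morphometry.fixed_parameters(
                    key if key in ("scheibe", "yadav") else ""
                )
                if fixed:
                    row[param] = "-"
                else:
                    icc = self.icc.loc[key, param]
                    lo, hi = self.icc_ci.get((key, param), (np.nan, np.nan))
                    row[param] = f"{icc:.3f} [{lo:.3f}, {hi:.3f}]"
            rows[approach] = row
        return pd.DataFrame.from_dict(rows, orient="index")

    def table_bias(self) -> pd.DataFrame:
        """Model x parameter estimation-bias table with dash cells."""
        rows = {}
        for approach in self.bias_pct.index:
            row = {}
            for param in PARAM_KEYS:
                for pattern in ("raster", "star"):
                    col = f"{param}_{pattern}"
                    fixed = param in morphometry.fixed_parameters(approach)
                    if fixed:
                        row[col] = "-"
                    else:
                        m = self.bias_pct.loc[approach, f"{col}_mean"]
                        s = self.bias_pct.loc[approach, f"{col}_sd"]
                        row[col] = f"{m:.1f} ± {s:.1f}"
            rows[approach] = row
        return pd.DataFrame.from_dict(rows, orient="index")

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "rmse_um": self.rmse_um.to_dict(orient="index"),
            "icc": self.icc.to_dict(orient="index"),
            "icc_ci": {f"{a}|{p}": list(ci) for (a, p), ci in self.icc_ci.items()},
            "bias_pct": self.bias_pct.to_dict(orient="index"),
            "loess_sweep": (
                None if self.loess_sweep is None
                else self.loess_sweep.to_dict(orient="index")
            ),
            "excluded": self.excluded,
        }


def _radial_for_scan(scan: OCTScan, config: StudyConfig):
    cloud = scan_to_cloud(scan)
    fc = locate_center(cloud, config.center_method)
    return resample_radial(
        cloud,
        config.radial_radius_mm,
        config.radial_n_directions,
        config.radial_step_mm,
        center=fc,
    )


def _approach_seed(base: int, approach: str, eye_idx: int) -> int:
    return (base * 1_000_003 + zlib.crc32(approach.encode()) + eye_idx * 131) % (2**31)


def run_model_comparison(
    cohort: list[EyeRecord], config: StudyConfig | None = None
) -> ModelComparisonReport:
    """Fit every configured approach on every eye and compare estimates."""
    config = config or StudyConfig()
    approaches = config.approach_ids()
    sweep_spans = [
        s for s in config.loess_sweep_spans or () if s not in config.loess_spans
    ]
    excluded: dict[str, list] = {"incomplete_radial": [], "non_converged": []}

    raw_means: dict[str, dict[str, dict[str, float]]] = {"raster": {}, "star": {}}
    fit_means: dict[str, dict[str, dict[str, dict[str, float]]]] = {
        a: {"raster": {}, "star": {}} for a in approaches
    }
    sweep_means = {
        f"sweep{int(round(s * 100))}": {"raster": {}, "star": {}} for s in sweep_spans
    }
    rmse_records: dict[str, dict[str, list[float]]] = {
        a: {"raster": [], "star": []} for a in approaches
    }

    for eye_idx, rec in enumerate(cohort):
        radial = {}
        try:
            # small out-of-hull tails are tolerated downstream; resampling
            # itself rejects scans with more than 5% undefined samples
            for pattern, scan in (("raster", rec.raster), ("star", rec.star)):
                radial[pattern] = _radial_for_scan(scan, config)
        except ValueError as exc:
            excluded["incomplete_radial"].append([rec.subject_id, str(exc)])
            log.warning("excluding %s: %s", rec.subject_id, exc)
            continue

        for pattern, rp in radial.items():
            raw = morphometry.compute_parameters(rp)
            raw_means[pattern][rec.subject_id] = raw.means()
            for approach in approaches:
                model_id, span = _parse_approach(approach)
                fit = fit_model(
                    rp,
                    model_id,
                    seed=_approach_seed(config.seed, approach, eye_idx),
                    span=span if span is not None else 0.2,
                )
                if not fit.converged:
                    excluded["non_converged"].append(
                        [rec.subject_id, pattern, approach]
                    )
                    log.warning(
                        "fit %s on %s/%s did not converge; excluded",
                        approach, rec.subject_id, pattern,
                    )
                    continue
                rmse_records[approach][pattern].append(fit.rmse_um)
                params = morphometry.parameters_from_fit(fit, rp)
                fit_means[approach][pattern][rec.subject_id] = params.means()
            for span in sweep_spans:
                fit = fit_model(rp, "loess", span=span)
                params = morphometry.parameters_from_fit(fit, rp)
                key = f"sweep{int(round(span * 100))}"
                sweep_means[key][pattern][rec.subject_id] = params.means()
        log.info("model comparison: %s done", rec.subject_id)

    if not raw_means["raster"]:
        raise ValueError("no eye produced complete radial data")

    rng = np.random.default_rng(config.seed)
    icc_rows, icc_ci = {}, {}
    icc_rows["raw"] = _icc_row(raw_means, raw_means, None, icc_ci, "raw", config, rng)
    bias_rows = {}
    for approach in approaches:
        icc_rows[approach] = _icc_row(
            fit_means[approach], raw_means, approach, icc_ci, approach, config, rng
        )
        bias_rows[approach] = _bias_row(fit_means[approach], raw_means, approach)

    rmse_df = pd.DataFrame.from_dict(
        {
            a: {
                "raster_mean": float(np.mean(v["raster"])) if v["raster"] else np.nan,
                "raster_sd": float(np.std(v["raster"], ddof=1)) if len(v["raster"]) > 1 else np.nan,
                "star_mean": float(np.mean(v["star"])) if v["star"] else np.nan,
                "star_sd": float(np.std(v["star"], ddof=1)) if len(v["star"]) > 1 else np.nan,
            }
            for a, v in rmse_records.items()
        },
        orient="index",
    )

    sweep_df = None
    if sweep_spans:
        sweep_rows = {}
        for span in sweep_spans:
            key = f"sweep{int(round(span * 100))}"
            row = {"span": span}
            means = sweep_means[key]
            for param in PARAM_KEYS:
                pairs = _param_pairs(means, param)
                row[f"icc_{param}"] = agreement.icc_2_1(pairs) if len(pairs) >= 3 else np.nan
                for pattern in ("raster", "star"):
                    biases = _biases(means, raw_means, pattern, param)
                    row[f"bias_{param}_{pattern}"] = float(np.mean(biases))
            sweep_rows[key] = row
        # include the configured spans so the curve covers them too
        for approach in approaches:
            model_id, span = _parse_approach(approach)
            if model_id != "loess":
                continue
            row = {"span": span}
            for param in PARAM_KEYS:
                row[f"icc_{param}"] = icc_rows[approach][param]
                for pattern in ("raster", "star"):
                    biases = _biases(fit_means[approach], raw_means, pattern, param)
                    row[f"bias_{param}_{pattern}"] = float(np.mean(biases))
            sweep_rows[approach] = row
        sweep_df = pd.DataFrame.from_dict(sweep_rows, orient="index").sort_values("span")

    return ModelComparisonReport(
        rmse_um=rmse_df,
        icc=pd.DataFrame.from_dict(icc_rows, orient="index"),
        icc_ci=icc_ci,
        bias_pct=pd.DataFrame.from_dict(bias_rows, orient="index"),
        raw_params={
            p: pd.DataFrame.from_dict(raw_means[p], orient="index") for p in raw_means
        },
        fitted_params={
            a: {p: pd.DataFrame.from_dict(m[p], orient="index") for p in m}
            for a, m in fit_means.items()
        },
        loess_sweep=sweep_df,
        excluded=excluded,
        seed=config.seed,
    )


def _parse_approach(approach: str) -> tuple[str, float | None]:
    if approach.startswith("loess") and approach != "loess":
        return "loess", int(approach[5:]) / 100.0
    return approach, None


def _param_pairs(means: dict, param: str) -> np.ndarray:
    common = sorted(set(means["raster"]) & set(means["star"]))
    return np.array(
        [[means["raster"][s][param], means["star"][s][param]] for s in common]
    )


def _biases(fit: dict, raw: dict, pattern: str, param: str) -> list[float]:
    out = []
    for subj, vals in fit[pattern].items():
        if subj in raw[pattern]:
            out.append(agreement.relative_bias(vals[param], raw[pattern][subj][param]))
    return out


def _bias_row(means: dict, raw_means: dict, approach: str) -> dict:
    """Mean ± sd of per-eye relative bias for each parameter and pattern."""
    model_id = _parse_approach(approach)[0]
    fixed = morphometry.fixed_parameters(model_id)
    row = {}
    for param in PARAM_KEYS:
        for pattern in ("raster", "star"):
            key = f"{param}_{pattern}"
            if param in fixed:
                row[f"{key}_mean"] = 0.0
                row[f"{key}_sd"] = 0.0
                continue
            biases = _biases(means, raw_means, pattern, param)
            row[f"{key}_mean"] = float(np.mean(biases)) if biases else np.nan
            row[f"{key}_sd"] = (
                float(np.std(biases, ddof=1)) if len(biases) > 1 else np.nan
            )
    return row


def _icc_row(means, raw_means, approach, icc_ci, label, config, rng) -> dict:
    row = {}
    for param in PARAM_KEYS:
        fixed = approach is not None and param in morphometry.fixed_parameters(
            _parse_approach(approach)[0]
        )
        source = raw_means if fixed else means
        pairs = _param_pairs(source, param)
        if len(pairs) < 3:
            row[param] = np.nan
            continue
        row[param] = agreement.icc_2_1(pairs)
        if config.n_bootstrap > 0:
            icc_ci[(label, param)] = agreement.bootstrap_ci(
                pairs,
                agreement.icc_2_1,
                n_resamples=config.n_bootstrap,
                seed=rng,
                level=config.bootstrap_level,
            )
    return row
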