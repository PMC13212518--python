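"""End-to-end stage orchestration over CSV artifacts.

Stages (``simulate -> [extract] -> series -> fit -> kinetics -> classify ->
cohort -> export``) communicate only through files in the output directory,
so each stage is rerunnable and idempotent for a fixed config and seed.  A
run log records the package version, seed and every threshold used.

``simulate`` writes a synthetic cohort; ``extract`` instead consumes label
masks or an instance CSV through the calibration profiles — the two entry
points produce the same long-format series schema
(plant_id, germplasm_id, replicate, day, trait, value).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import CalibrationSet, calibrate_from_ruler, pixels_to_area
from .cohort import (aggregate_germplasm, cluster_germplasms,
                     correlation_matrix, derive_plant_traits)
from .kinetics import (KineticsError, classify_curd, curd_rate_stats,
                       inflection_vs_tca_regression, rapid_growth_window)
from .masks import bbox_to_dimensions, extract_instances, parse_filename
from .models import FitOptions, ModelFit, evaluate_model, fit_model, get_model
from .series import GrowthSeries, detect_curd_appearance, growth_rate
from .synthetic import AcquisitionSchedule, DEFAULT_ARCHETYPES, simulate_cohort

__all__ = ["PipelineConfig", "run_stage", "export_summary", "STAGES"]

log = logging.getLogger("caulipheno.pipeline")

STAGES = ("simulate", "extract", "series", "fit", "kinetics", "classify",
          "cohort", "export", "all")


class MissingUpstreamError(FileNotFoundError):
    """An artifact from an earlier stage is missing."""


@dataclass
class PipelineConfig:
    """Plain-text pipeline configuration (YAML on disk)."""

    out_dir: str = "caulipheno_out"
    seed: int = 0
    # synthetic-cohort entry point
    replicates: int = 3
    germplasms_per_archetype: list | None = None  # default: the full 47
    # mask/CSV entry point
    masks_dir: str | None = None
    instance_csv: str | None = None
    transplant_date: str = "2024-10-01"
    calibration: dict = field(default_factory=lambda: {
        # camera height (m) -> ruler measurement
        1.5: {"ruler_length_cm": 30.0, "ruler_pixel_span": 600.0},
        2.2: {"ruler_length_cm": 30.0, "ruler_pixel_span": 409.0},
    })
    # schedule
    base_interval: int = 3
    height_switch_day: float = 70.0
    # series stage
    min_consecutive: int = 2
    # fit stage
    n_starts: int = 8
    jitter_scale: float = 0.2
    leaf_model: str = "richards"
    curd_model: str = "sine"
    # kinetics / classification
    plateau_threshold: float = 0.95
    # cohort stage
    cluster_k: int = 4

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "calibration" in raw:
            raw["calibration"] = {float(k): v for k, v in raw["calibration"].items()}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    def __post_init__(self):
        if self.cluster_k < 2:
            raise ValueError("cluster_k must be >= 2")
        if not 0 < self.plateau_threshold <= 1:
            raise ValueError("plateau_threshold must be in (0, 1]")

    @property
    def out(self) -> Path:
        return Path(self.out_dir)

    def fit_options(self) -> FitOptions:
        return FitOptions(n_starts=self.n_starts, jitter_scale=self.jitter_scale,
                          seed=self.seed)

    def calibration_set(self) -> CalibrationSet:
        profiles = {}
        for height, spec in self.calibration.items():
            if "pixel_to_length" in spec:
                from .calibration import CalibrationProfile
                profiles[height] = CalibrationProfile(height, spec["pixel_to_length"])
            else:
                profiles[height] = calibrate_from_ruler(
                    spec["ruler_length_cm"], spec["ruler_pixel_span"], height
                )
        return CalibrationSet(profiles, height_switch_day=self.height_switch_day)


def _require(config: PipelineConfig, filename: str, producer: str) -> Path:
    path = config.out / filename
    if not path.exists():
        raise MissingUpstreamError(
            f"missing {path}; run the {producer!r} stage first"
        )
    return path


def _log_run(config: PipelineConfig, stage: str) -> None:
    config.out.mkdir(parents=True, exist_ok=True)
    msg = (f"stage={stage} version={__version__} seed={config.seed} "
           f"plateau_threshold={config.plateau_threshold} "
           f"min_consecutive={config.min_consecutive} n_starts={config.n_starts} "
           f"cluster_k={config.cluster_k}")
    log.info(msg)
    with open(config.out / "run.log", "a") as fh:
        fh.write(f"{_dt.datetime.now().isoformat(timespec='seconds')} {msg}\n")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig) -> None:
    schedule = AcquisitionSchedule(
        transplant_date=_dt.date.fromisoformat(config.transplant_date),
        base_interval=config.base_interval,
        height_switch_day=config.height_switch_day,
    )
    archetypes = DEFAULT_ARCHETYPES
    if config.germplasms_per_archetype is not None:
        counts = list(config.germplasms_per_archetype)
        if len(counts) != len(archetypes):
            raise ValueError(
                f"germplasms_per_archetype needs {len(archetypes)} counts"
            )
        archetypes = tuple(
            dataclasses.replace(a, n_germplasms=int(n))
            for a, n in zip(archetypes, counts) if int(n) > 0
        )
    cohort = simulate_cohort(archetypes, replicates=config.replicates,
                             schedule=schedule, seed=config.seed)
    _write_csv(cohort.series_frame(), config.out / "series.csv")
    _write_csv(cohort.truth, config.out / "truth.csv")


def stage_extract(config: PipelineConfig) -> None:
    """Masks or instance CSV -> long-format trait series."""
    calib = config.calibration_set()
    transplant = _dt.date.fromisoformat(config.transplant_date)
    rows = []
    if config.masks_dir:
        from PIL import Image

        for path in sorted(Path(config.masks_dir).glob("*.png")):
            parsed = parse_filename(path.name)
            day = (parsed.date - transplant).days
            profile = calib.for_record(day=day)
            mask = np.asarray(Image.open(path))
            for rec in extract_instances(mask, plant_id=parsed.plant_id,
                                         date=parsed.date, day=day):
                area = pixels_to_area(rec.pixel_area, profile)
                trait = "LA" if rec.class_label == "plant" else "CA"
                rows.append((parsed.plant_id, parsed.plant_id, 1, day, trait, area))
                dims = bbox_to_dimensions(rec, profile)
                wtrait = "PCW" if rec.class_label == "plant" else "FCD"
                rows.append((parsed.plant_id, parsed.plant_id, 1, day, wtrait,
                             dims["value"]))
    elif config.instance_csv:
        df = pd.read_csv(config.instance_csv)
        for _, r in df.iterrows():
            parsed = parse_filename(str(r["filename"]))
            day = (parsed.date - transplant).days
            height = r.get("camera_height")
            profile = calib.for_record(
                camera_height=None if pd.isna(height) else float(height), day=day
            )
            area = pixels_to_area(float(r["pixel_area"]), profile)
            trait = "LA" if r["class"] == "plant" else "CA"
            rows.append((parsed.plant_id, parsed.plant_id, 1, day, trait, area))
    else:
        raise ValueError("extract stage needs masks_dir or instance_csv")
    frame = pd.DataFrame(rows, columns=["plant_id", "germplasm_id", "replicate",
                                        "day", "trait", "value"])
    frame = frame.sort_values(["plant_id", "trait", "day"], kind="stable")
    _write_csv(frame, config.out / "series.csv")


def _load_series(config: PipelineConfig) -> pd.DataFrame:
    return pd.read_csv(_require(config, "series.csv", "simulate"))


def _plant_series(df: pd.DataFrame, plant_id: str, trait: str) -> GrowthSeries | None:
    sub = df[(df["plant_id"] == plant_id) & (df["trait"] == trait)]
    if sub.empty:
        return None
    sub = sub.sort_values("day")
    return GrowthSeries(plant_id, trait, sub["day"].to_numpy(),
                        sub["value"].to_numpy())


def stage_series(config: PipelineConfig) -> None:
    """Curd-appearance detection, harvest days and growth rates."""
    df = _load_series(config)
    plants = sorted(df["plant_id"].unique())
    tca_rows, rate_rows = [], []
    for pid in plants:
        leaf = _plant_series(df, pid, "LA")
        curd = _plant_series(df, pid, "CA")
        harvest = leaf.final_day if leaf is not None else curd.final_day
        if curd is not None and leaf is not None:
            all_days = leaf.days
            detected = np.isin(all_days, curd.days)
            tca = detect_curd_appearance(all_days, detected,
                                         min_consecutive=config.min_consecutive)
        elif curd is not None:
            tca = detect_curd_appearance(curd.days,
                                         min_consecutive=config.min_consecutive)
        else:
            tca = None
        tca_rows.append((pid, tca if tca is not None else np.nan, harvest))
        for s in (leaf, curd):
            if s is not None and len(s) >= 2:
                r = growth_rate(s)
                rate_rows.extend(
                    (pid, s.trait, float(d), float(v)) for d, v in zip(r.days, r.rates)
                )
    _write_csv(pd.DataFrame(tca_rows, columns=["plant_id", "tca", "harvest_day"]),
               config.out / "tca.csv")
    _write_csv(pd.DataFrame(rate_rows, columns=["plant_id", "trait", "day", "rate"]),
               config.out / "rates.csv")


def stage_fit(config: PipelineConfig) -> None:
    df = _load_series(config)
    _require(config, "tca.csv", "series")
    options = config.fit_options()
    rows = []
    for pid in sorted(df["plant_id"].unique()):
        for trait, model in (("LA", config.leaf_model), ("CA", config.curd_model)):
            s = _plant_series(df, pid, trait)
            if s is None or len(s) <= get_model(model).n_params:
                continue
            fit = fit_model(s, model, options)
            rows.append({
                "plant_id": pid, "trait": trait, "model": fit.model,
                "params": json.dumps(fit.params), "n": fit.n, "k": fit.k,
                "r2": fit.r2, "rmse": fit.rmse, "mae": fit.mae,
                "reduced_chi_sq": fit.reduced_chi_sq,
                "converged": fit.converged,
            })
    _write_csv(pd.DataFrame(rows), config.out / "fits.csv")


def _fits_as_objects(config: PipelineConfig, df_series: pd.DataFrame) -> dict:
    fits = pd.read_csv(_require(config, "fits.csv", "fit"))
    out = {}
    for _, row in fits.iterrows():
        s = _plant_series(df_series, row["plant_id"], row["trait"])
        params = json.loads(row["params"])
        pred = evaluate_model(row["model"], params, s.days)
        out[(row["plant_id"], row["trait"])] = ModelFit(
            model=row["model"], params=params, n=int(row["n"]), k=int(row["k"]),
            days=s.days, predictions=pred, r2=float(row["r2"]),
            rmse=float(row["rmse"]), mae=float(row["mae"]),
            reduced_chi_sq=float(row["reduced_chi_sq"]),
            converged=bool(row["converged"]), cost=float("nan"),
        )
    return out


def stage_kinetics(config: PipelineConfig) -> None:
    df = _load_series(config)
    tca = pd.read_csv(_require(config, "tca.csv", "series")).set_index("plant_id")
    fits = _fits_as_objects(config, df)
    rows = []
    for (pid, trait), fit in fits.items():
        if trait != "LA" or not fit.spec.sigmoid:
            continue
        try:
            kin = rapid_growth_window(fit)
        except KineticsError:
            continue
        rows.append((pid, kin.t_infl1, kin.t_infl2, kin.t_max_rate,
                     kin.max_rate, kin.rapid_duration))
    kdf = pd.DataFrame(rows, columns=["plant_id", "t_infl1", "t_infl2",
                                      "t_max_rate", "max_rate", "rapid_duration"])
    _write_csv(kdf, config.out / "kinetics.csv")
    merged = kdf.merge(tca.reset_index()[["plant_id", "tca"]], on="plant_id")
    merged = merged.dropna(subset=["tca"])
    if len(merged) >= 3:
        reg = inflection_vs_tca_regression(merged[["tca", "t_infl2"]].to_numpy())
        (config.out / "inflection_regression.json").write_text(json.dumps(reg, indent=1))


def stage_classify(config: PipelineConfig) -> None:
    df = _load_series(config)
    tca = pd.read_csv(_require(config, "tca.csv", "series")).set_index("plant_id")
    fits = _fits_as_objects(config, df)
    rows = []
    for (pid, trait), fit in fits.items():
        if trait != "CA" or fit.model != "sine":
            continue
        harvest = float(tca.loc[pid, "harvest_day"])
        t = tca.loc[pid, "tca"]
        try:
            stats = curd_rate_stats(fit, harvest, tca=None if pd.isna(t) else float(t))
        except (KineticsError, ValueError):
            continue
        rows.append({
            "plant_id": pid, "t_peak_rate": stats.t_peak_rate,
            "max_rate": stats.max_rate, "harvest_rate": stats.harvest_rate,
            "rate_ratio": stats.rate_ratio, "trend": stats.trend_at_harvest,
            "growth_duration": stats.growth_duration,
            "classification": classify_curd(stats, config.plateau_threshold),
        })
    _write_csv(pd.DataFrame(rows), config.out / "classification.csv")


def stage_cohort(config: PipelineConfig) -> None:
    df = _load_series(config)
    tca = pd.read_csv(_require(config, "tca.csv", "series")).set_index("plant_id")
    kin = pd.read_csv(_require(config, "kinetics.csv", "kinetics")).set_index("plant_id")
    cls = pd.read_csv(_require(config, "classification.csv", "classify"))
    cls = cls.set_index("plant_id") if not cls.empty else cls
    fits = _fits_as_objects(config, df)
    meta = df[["plant_id", "germplasm_id"]].drop_duplicates().set_index("plant_id")

    records = []
    for pid in sorted(df["plant_id"].unique()):
        leaf = _plant_series(df, pid, "LA")
        curd = _plant_series(df, pid, "CA")
        if leaf is None:
            continue
        leaf_kin = None
        if pid in kin.index:
            row = kin.loc[pid]
            from .kinetics import KineticsSummary
            leaf_kin = KineticsSummary(row["t_infl1"], row["t_infl2"],
                                       row["t_max_rate"], row["max_rate"])
        t = tca.loc[pid, "tca"] if pid in tca.index else np.nan
        harvest = float(tca.loc[pid, "harvest_day"]) if pid in tca.index else leaf.final_day
        curd_stats = None
        if (pid, "CA") in fits and not pd.isna(t):
            try:
                curd_stats = curd_rate_stats(fits[(pid, "CA")], harvest, tca=float(t))
            except (KineticsError, ValueError):
                curd_stats = None
        pcw = _final_value(df, pid, "PCW")
        fcd = _final_value(df, pid, "FCD")
        rec = derive_plant_traits(leaf, curd, leaf_kin, curd_stats,
                                  None if pd.isna(t) else float(t),
                                  pcw_final=pcw, fcd_final=fcd)
        rec["germplasm_id"] = meta.loc[pid, "germplasm_id"]
        records.append(rec)
    plant_traits = pd.DataFrame(records)
    _write_csv(plant_traits, config.out / "plant_traits.csv")

    table = aggregate_germplasm(plant_traits)
    _write_csv(table, config.out / "germplasm_traits.csv")
    r, p = correlation_matrix(table)
    r.to_csv(config.out / "correlation_r.csv", float_format="%.10g")
    p.to_csv(config.out / "correlation_p.csv", float_format="%.10g")
    if len(table) >= config.cluster_k:
        res = cluster_germplasms(table, k=config.cluster_k)
        res.labels.reset_index().to_csv(config.out / "clusters.csv", index=False)
        pd.DataFrame(res.linkage,
                     columns=["left", "right", "height", "size"]).to_csv(
            config.out / "linkage.csv", index=False, float_format="%.10g")


def _final_value(df: pd.DataFrame, pid: str, trait: str) -> float | None:
    sub = df[(df["plant_id"] == pid) & (df["trait"] == trait)]
    if sub.empty:
        return None
    return float(sub.sort_values("day")["value"].iloc[-1])


def export_summary(config: PipelineConfig) -> pd.DataFrame:
    """One row per plant joining traits, fit quality, kinetics and label."""
    traits = pd.read_csv(_require(config, "plant_traits.csv", "cohort"))
    fits = pd.read_csv(_require(config, "fits.csv", "fit"))
    cls = pd.read_csv(_require(config, "classification.csv", "classify"))
    leaf_fit = fits[fits["trait"] == "LA"][["plant_id", "model", "r2", "rmse"]]
    leaf_fit = leaf_fit.rename(columns={"model": "leaf_model", "r2": "leaf_r2",
                                        "rmse": "leaf_rmse"})
    curd_fit = fits[fits["trait"] == "CA"][["plant_id", "model", "r2", "rmse"]]
    curd_fit = curd_fit.rename(columns={"model": "curd_model", "r2": "curd_r2",
                                        "rmse": "curd_rmse"})
    out = traits.merge(leaf_fit, on="plant_id", how="left")
    out = out.merge(curd_fit, on="plant_id", how="left")
    if not cls.empty:
        out = out.merge(cls[["plant_id", "classification", "rate_ratio"]],
                        on="plant_id", how="left")
    out = out.sort_values("plant_id", kind="stable")
    _write_csv(out, config.out / "summary.csv")
    return out


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "extract": stage_extract,
    "series": stage_series,
    "fit": stage_fit,
    "kinetics": stage_kinetics,
    "classify": stage_classify,
    "cohort": stage_cohort,
    "export": export_summary,
}


def run_stage(name: str, config: PipelineConfig):
    """Run one pipeline stage (or ``all`` to chain them) with logging."""
    if name == "all":
        chain = ["extract" if (config.masks_dir or config.instance_csv)
                 else "simulate",
                 "series", "fit", "kinetics", "classify", "cohort", "export"]
        for stage in chain:
            run_stage(stage, config)
        return None
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; valid: {STAGES}")
    _log_run(config, name)
    return _STAGE_FUNCS[name](config)
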