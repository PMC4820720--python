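"""Pipeline orchestration: simulate → reduce → normalize → chronology → stats.

Each stage consumes and emits plain CSV tables (UTF-8, comma-separated,
header row mandatory; missing values are empty fields and record-level
problems live in a separate ``status`` column so that "fallen out" and
"failed separation" survive round trips).  Per-row failures are recorded
and skipped, never abort a run; schema and configuration errors do.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from datetime import date, datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import composition as comp_mod
from . import stats as stats_mod
from .chronology import ExposureStep, post_step_fraction, recover_step, stage_at_date
from .composition import ToothComposition, normalize_activity, triplicate_summary
from .radiometrics import (
    ActivityResult,
    AssayCalibration,
    CountSeries,
    NuclideConstants,
    detection_limit,
    fit_ingrowth_series,
)
from .synthetic import ScenarioConfig, simulate_study

logger = logging.getLogger("toothsr")

__all__ = [
    "run_reduce",
    "run_compose",
    "run_normalize",
    "run_chronology",
    "run_stats",
    "run_report",
    "run_study",
    "RunManifest",
]

#: GOF p below which a series is flagged as departing from the ingrowth curve
GOF_FLAG_P = 0.05

#: fallback ash Ca mass fraction when no per-sample ICP value is available
DEFAULT_CA_FRACTION = 0.37


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name}: missing required columns {missing}")


def run_reduce(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    calib: AssayCalibration,
    constants: NuclideConstants = NuclideConstants(),
    composition: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Reduce β-count series to decay-corrected ⁹⁰Sr activities (mBq).

    One output row per usable sample: fitted activity at separation and at
    the reference date, standard error, ingrowth goodness-of-fit p (flagged
    below GOF_FLAG_P, not dropped), the per-sample detection limit, and a
    below-detection flag.  The detection limit uses the per-sample ICP Ca
    fraction when a composition table is supplied, else a configuration
    default with a warning.
    """
    _require_columns(counts, ["sample_id", "t_hours", "duration_min", "gross_counts"], "counts")
    _require_columns(
        samples,
        ["sample_id", "status", "ash_mass_g", "chemical_yield", "thickness_mg_cm2", "separation_date"],
        "samples",
    )
    if counts.empty:
        warnings.warn("empty counts table; producing empty reduction", stacklevel=2)
    ca_by_sample: dict[str, float] = {}
    if composition is not None:
        ca_by_sample = dict(
            zip(composition["sample_id"], composition["ca_frac_mean"])
        )
    rows = []
    grouped = counts.groupby("sample_id", sort=False)
    for srow in samples.itertuples(index=False):
        sid = srow.sample_id
        rec = {
            "sample_id": sid,
            "status": srow.status,
            "activity_mBq_at_separation": np.nan,
            "se_mBq": np.nan,
            "gof_p": np.nan,
            "gof_flagged": False,
            "activity_mBq_ref": np.nan,
            "below_detection": False,
            "detection_limit_mBq": np.nan,
            "error": "",
        }
        if srow.status != "ok":
            rows.append(rec)
            continue
        try:
            if not 0.0 < srow.chemical_yield <= 1.0:
                raise ValueError(f"chemical yield {srow.chemical_yield} outside (0, 1]")
            sub = grouped.get_group(sid).sort_values("t_hours")
            series = CountSeries(
                sample_id=sid,
                observations=tuple(
                    (float(t), float(d), float(c))
                    for t, d, c in zip(
                        sub["t_hours"], sub["duration_min"], sub["gross_counts"]
                    )
                ),
            )
            sep_date = date.fromisoformat(str(srow.separation_date))
            res: ActivityResult = fit_ingrowth_series(
                series,
                thickness=float(srow.thickness_mg_cm2),
                calib=calib,
                constants=constants,
                chemical_yield=float(srow.chemical_yield),
                measurement_date=sep_date,
            )
            ca_frac = ca_by_sample.get(sid)
            if ca_frac is None or not np.isfinite(ca_frac):
                ca_frac = DEFAULT_CA_FRACTION
                logger.warning(
                    "sample %s: no ICP Ca fraction; using default %.2f", sid, ca_frac
                )
            mean_dur = float(sub["duration_min"].mean())
            dl = detection_limit(
                calib,
                count_duration=mean_dur,
                chemical_yield=float(srow.chemical_yield),
                ash_mass=float(srow.ash_mass_g),
                ca_fraction=float(ca_frac),
            )  # mBq per g Ca
            dl_mBq = dl * float(srow.ash_mass_g) * float(ca_frac)  # per sample
            act_mBq = res.activity_at_separation * 1000.0
            rec.update(
                activity_mBq_at_separation=act_mBq,
                se_mBq=res.standard_error * 1000.0,
                gof_p=res.goodness_of_fit_p,
                gof_flagged=bool(res.goodness_of_fit_p < GOF_FLAG_P),
                activity_mBq_ref=res.activity_at_reference * 1000.0,
                below_detection=bool(res.below_detection or act_mBq < dl_mBq),
                detection_limit_mBq=dl_mBq,
            )
        except KeyError:
            rec["error"] = "no count series"
        except Exception as exc:  # per-row robustness contract
            rec["error"] = str(exc)
            logger.error("sample %s: %s", sid, exc)
        rows.append(rec)
    return pd.DataFrame(rows)


def run_compose(assays: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Turn ICP assay records into per-sample composition (Sr µg/g, Ca fraction).

    Each replicate is fitted separately (standard addition for Sr, external
    calibration for Ca) and replicates are summarized as mean ± sample SD.
    """
    _require_columns(
        assays,
        ["sample_id", "element", "method", "replicate", "role", "conc_ug_L", "intensity"],
        "assays",
    )
    rows = []
    assay_groups = dict(iter(assays.groupby("sample_id", sort=False))) if len(assays) else {}
    for srow in samples.itertuples(index=False):
        sid = srow.sample_id
        rec = {
            "sample_id": sid,
            "sr_ug_g_mean": np.nan,
            "sr_ug_g_sd": np.nan,
            "ca_frac_mean": np.nan,
            "ca_frac_sd": np.nan,
            "status": srow.status,
            "error": "",
        }
        if srow.status != "ok" or sid not in assay_groups:
            rows.append(rec)
            continue
        sub = assay_groups[sid]
        try:
            sr_vals, ca_vals = [], []
            for rep, rep_df in sub[sub["element"] == "Sr"].groupby("replicate"):
                assay = comp_mod.ElementAssay(
                    sample_id=sid,
                    element="Sr",
                    method="standard_addition",
                    points=tuple(
                        (float(c), float(i))
                        for c, i in zip(rep_df["conc_ug_L"], rep_df["intensity"])
                    ),
                    ash_mass_g=float(srow.ash_mass_g),
                )
                sr_vals.append(comp_mod.standard_addition_concentration(assay))
            for rep, rep_df in sub[sub["element"] == "Ca"].groupby("replicate"):
                std = rep_df[rep_df["role"] == "standard"]
                samp = rep_df[rep_df["role"] == "sample"]
                if samp.empty:
                    raise comp_mod.AssayFitError("no Ca sample intensity")
                assay = comp_mod.ElementAssay(
                    sample_id=sid,
                    element="Ca",
                    method="calibration_curve",
                    points=tuple(
                        (float(c), float(i))
                        for c, i in zip(std["conc_ug_L"], std["intensity"])
                    ),
                    ash_mass_g=float(srow.ash_mass_g),
                )
                ca_ug_g = comp_mod.calibration_curve_concentration(
                    assay, float(samp["intensity"].iloc[0])
                )
                ca_vals.append(ca_ug_g / 1e6)  # µg/g -> mass fraction
            sr_mean, sr_sd = triplicate_summary(sr_vals)
            ca_mean, ca_sd = triplicate_summary(ca_vals)
            rec.update(
                sr_ug_g_mean=sr_mean,
                sr_ug_g_sd=sr_sd,
                ca_frac_mean=ca_mean,
                ca_frac_sd=ca_sd,
            )
        except Exception as exc:
            rec["error"] = str(exc)
            logger.error("sample %s: %s", sid, exc)
        rows.append(rec)
    return pd.DataFrame(rows)


def run_normalize(
    reduced: pd.DataFrame,
    composition: pd.DataFrame,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Join reduction and composition; emit normalized activities per tooth."""
    merged = samples.merge(
        reduced.drop(columns=["status", "error"], errors="ignore"),
        on="sample_id",
        how="left",
    ).merge(
        composition.drop(columns=["status", "error"], errors="ignore"),
        on="sample_id",
        how="left",
    )
    act_conc, spec_act = [], []
    for row in merged.itertuples(index=False):
        if (
            row.status != "ok"
            or not np.isfinite(row.activity_mBq_ref)
            or not np.isfinite(row.sr_ug_g_mean)
            or not np.isfinite(row.ca_frac_mean)
        ):
            act_conc.append(np.nan)
            spec_act.append(np.nan)
            continue
        comp = ToothComposition(
            sample_id=row.sample_id,
            sr_ug_g_mean=float(row.sr_ug_g_mean),
            sr_ug_g_sd=float(row.sr_ug_g_sd),
            ca_frac_mean=float(row.ca_frac_mean),
            ca_frac_sd=float(row.ca_frac_sd),
        )
        na = normalize_activity(float(row.activity_mBq_ref), float(row.ash_mass_g), comp)
        act_conc.append(na.activity_conc)
        spec_act.append(na.specific_activity)
    merged["activity_conc"] = act_conc  # mBq per g Ca
    merged["specific_activity"] = spec_act  # Bq per g Sr
    return merged


def run_chronology(
    normalized: pd.DataFrame,
    herd: pd.DataFrame,
    accident_date: date,
    windows=None,
) -> tuple[pd.DataFrame, dict]:
    """Annotate teeth with developmental stage and post-step fraction φ, and
    recover the exposure step per area from observed specific activities."""
    from .chronology import DEFAULT_WINDOWS

    if windows is None:
        windows = DEFAULT_WINDOWS
    birth = {
        r.animal_id: date.fromisoformat(str(r.birth_date))
        for r in herd.itertuples(index=False)
    }
    phis, stages = [], []
    for row in normalized.itertuples(index=False):
        w = windows[row.tooth_class]
        b = birth[row.animal_id]
        phis.append(post_step_fraction(w, b, accident_date))
        stages.append(stage_at_date(w, b, accident_date))
    out = normalized.copy()
    out["phi"] = phis
    out["stage_at_accident"] = stages

    steps: dict[str, dict] = {}
    usable = out[(out["status"] == "ok") & out["specific_activity"].notna()]
    for area, sub in usable.groupby("area"):
        obs = [
            (r.tooth_class, birth[r.animal_id], float(r.specific_activity))
            for r in sub.itertuples(index=False)
        ]
        try:
            step, se = recover_step(obs, accident_date, windows)
            steps[area] = {
                "pre_level": step.pre_level,
                "post_level": step.post_level,
                "se_pre": se[0],
                "se_post": se[1],
                "n": len(obs),
            }
        except ValueError as exc:
            steps[area] = {"error": str(exc), "n": len(obs)}
    return out, steps


def run_stats(
    teeth: pd.DataFrame,
    factor: str,
    response: str,
    method: str = "asymptotic",
) -> pd.DataFrame:
    """Kruskal-Wallis over a grouping factor for one response column."""
    grouped = stats_mod.group_teeth(teeth, factor=factor, response=response)
    res = stats_mod.kruskal_wallis(grouped, method=method)
    return pd.DataFrame(
        [
            {
                "factor": factor,
                "response": response,
                "groups": "/".join(grouped.labels),
                "group_sizes": "/".join(str(n) for n in grouped.sizes),
                "N": grouped.n_total,
                "statistic": res.statistic,
                "df": res.df,
                "p": round(res.p, 4),
            }
        ]
    )


def run_report(normalized: pd.DataFrame) -> dict:
    """Summaries of a completed run: per-area and per-tooth-group means ± SD
    of both normalized activities, all Kruskal-Wallis tests, and the soil
    correlation.  Every number is taken from stage output columns."""
    ok = normalized[(normalized["status"] == "ok") & normalized["activity_conc"].notna()]
    report: dict = {"n_teeth": int(len(ok))}
    if ok.empty:
        report["stats"] = "not applicable: no usable teeth"
        return report
    per_area = (
        ok.groupby("area")[["activity_conc", "specific_activity"]]
        .agg(["mean", "std", "count"])
        .round(4)
    )
    ok = ok.assign(tooth_group=ok["tooth_class"].map(stats_mod.TOOTH_GROUP_MAP))
    per_group = (
        ok.groupby("tooth_group")[["activity_conc", "specific_activity"]]
        .agg(["mean", "std", "count"])
        .round(4)
    )
    report["per_area"] = per_area
    report["per_tooth_group"] = per_group

    tests = []
    for factor in ("area", "tooth_group"):
        for response in ("activity_conc", "specific_activity"):
            try:
                tests.append(run_stats(ok, factor, response))
            except ValueError as exc:
                tests.append(
                    pd.DataFrame(
                        [{"factor": factor, "response": response, "error": str(exc)}]
                    )
                )
    report["tests"] = pd.concat(tests, ignore_index=True)

    if "soil_sr90" in ok.columns and ok["soil_sr90"].nunique() > 1:
        report["spearman_soil_activity_conc"] = stats_mod.spearman(
            ok["soil_sr90"], ok["activity_conc"]
        )
        report["spearman_soil_specific"] = stats_mod.spearman(
            ok["soil_sr90"], ok["specific_activity"]
        )
    else:
        report["spearman_soil_activity_conc"] = None
        report["spearman_soil_specific"] = None
    return report


def run_study(
    config: ScenarioConfig,
    seed: int,
    noise: bool = True,
) -> dict:
    """End-to-end run on a simulated study; returns all stage outputs."""
    logger.info("simulate: seed=%d noise=%s", seed, noise)
    tables = simulate_study(config, seed, noise=noise)
    calib = config.lab.calibration()
    composition = run_compose(tables["assays"], tables["samples"])
    reduced = run_reduce(
        tables["counts"], tables["samples"], calib, config.constants, composition
    )
    normalized = run_normalize(reduced, composition, tables["samples"])
    herd = pd.DataFrame(
        [
            {
                "animal_id": a.animal_id,
                "area": a.area,
                "birth_date": a.birth_date.isoformat(),
                "age_accident_months": a.age_accident_months,
                "age_sampling_months": a.age_sampling_months,
            }
            for a in config.herd
        ]
    )
    annotated, steps = run_chronology(
        normalized, herd, config.accident_date, config.windows
    )
    report = run_report(annotated)
    return {
        **tables,
        "composition": composition,
        "reduced": reduced,
        "normalized": annotated,
        "recovered_steps": steps,
        "report": report,
        "herd": herd,
    }


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    seed: int
    config_hash: str
    stage: str
    file_digests: dict[str, str] = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    @staticmethod
    def hash_config(config) -> str:
        blob = json.dumps(str(config), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @staticmethod
    def digest_file(path: str | Path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]

    def add_file(self, path: str | Path) -> None:
        self.file_digests[str(path)] = self.digest_file(path)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")
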