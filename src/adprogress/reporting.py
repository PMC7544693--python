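"""Tabular I/O, descriptive summaries, configuration and the pipeline runner.

The pipeline runner ties the stages together deterministically: load (or
simulate) visit records, optionally exclude non-decliners, run the
education-stratified analysis, and write a report bundle of JSON model
files, transition/milestone CSV tables, a descriptive summary and a plain
log of every decision taken (quadratic term kept or dropped, outliers
removed, overlap scores), all reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import continuum as _continuum
from . import synthetic as _synthetic
from .continuum import DEFAULT_MILESTONES, StratumResult, stratified_pipeline
from .synthetic import apply_decliner_filter, default_study
from .trajectory import QuadraticLogModel

__all__ = [
    "read_visits",
    "write_visits",
    "summarize_study",
    "PipelineConfig",
    "run_pipeline",
]

_BASE_COLUMNS = ["patient_id", "cohort", "time_months", "cdrsb", "education_years"]


def read_visits(path) -> pd.DataFrame:
    """Read and validate a visit-record CSV.

    Required columns: patient_id, cohort, time_months, cdrsb,
    education_years (latent_time is carried through when present).
    Validation failures name the offending 1-based data row.
    """
    df = pd.read_csv(path)
    missing = [c for c in _BASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    def _bad(mask, msg):
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0]) + 1
            raise ValueError(f"{path}: row {row}: {msg}")

    cdrsb = pd.to_numeric(df["cdrsb"], errors="coerce")
    _bad(cdrsb.isna(), "cdrsb is not numeric")
    _bad((cdrsb < 0) | (cdrsb > 18), "cdrsb outside [0, 18]")
    _bad((cdrsb * 2) % 1 != 0, "cdrsb not a multiple of 0.5")
    t = pd.to_numeric(df["time_months"], errors="coerce")
    _bad(t.isna() | ~np.isfinite(t), "time_months is not a finite number")
    _bad(t < 0, "time_months is negative")
    edu = pd.to_numeric(df["education_years"], errors="coerce")
    _bad(edu.isna() | (edu < 0), "education_years must be a non-negative number")

    df["cdrsb"] = cdrsb.astype(float)
    df["time_months"] = t.astype(float)
    df["education_years"] = edu.astype(int)

    grouped = df.groupby("patient_id")["time_months"]
    first = grouped.transform("min")
    _bad(pd.Series(first != 0.0), "patient's first visit must be at time 0")
    sizes = df.groupby("patient_id").size()
    small = sizes[sizes < 3]
    if len(small):
        raise ValueError(f"{path}: patient(s) with fewer than 3 visits: "
                         f"{small.index.tolist()[:5]}")
    for pid, g in df.groupby("patient_id"):
        tt = g["time_months"].to_numpy()
        if np.any(np.diff(np.sort(tt)) <= 0):
            raise ValueError(f"{path}: patient {pid}: visit times not strictly increasing")
    return df


def write_visits(records: pd.DataFrame, path) -> None:
    """Write records as UTF-8 CSV with '.' decimals; lossless round-trip."""
    cols = _BASE_COLUMNS + (["latent_time"] if "latent_time" in records.columns else [])
    records[cols].to_csv(path, index=False, encoding="utf-8")


def _median_iqr(x: pd.Series) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(np.asarray(x, dtype=float), [25, 50, 75])
    return float(med), float(q1), float(q3)


def summarize_study(records: pd.DataFrame, education_cutoff_years: int = 12
                    ) -> pd.DataFrame:
    """Descriptive summary per cohort x education stratum.

    Medians and IQRs (linear-interpolation percentiles) of visit counts,
    follow-up months and baseline CDR-SB, plus patient counts — the
    demographics table of a typical longitudinal dementia cohort study.
    """
    if len(records) == 0:
        raise ValueError("no records to summarize")
    rec = records.copy()
    rec["stratum"] = np.where(rec["education_years"] <= education_cutoff_years,
                              "lower", "higher")
    rows = []
    for stratum in ("lower", "higher", "total"):
        sub = rec if stratum == "total" else rec[rec["stratum"] == stratum]
        for cohort in sorted(sub["cohort"].unique(),
                             key=lambda c: (_synthetic.COHORT_ORDER + (c,)).index(c)):
            g = sub[sub["cohort"] == cohort]
            per = g.groupby("patient_id").agg(
                n_visits=("time_months", "size"),
                followup=("time_months", "max"),
            )
            baseline = g.sort_values("time_months").groupby("patient_id")["cdrsb"].first()
            row = {"stratum": stratum, "cohort": cohort, "n_patients": len(per)}
            for name, series in [("visits", per["n_visits"]),
                                 ("followup_months", per["followup"]),
                                 ("baseline_cdrsb", baseline)]:
                med, q1, q3 = _median_iqr(series)
                row.update({f"{name}_median": med, f"{name}_q1": q1, f"{name}_q3": q3})
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# configuration and pipeline
# ---------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    input_path: str | None = None      # CSV of visits; None -> simulate
    simulate_scale: float = 1.0        # shrink factor for simulated n
    sigma_b: float = 0.30
    sigma_e: float = 0.20
    nondecliner_fraction: float = 0.0
    include_nondecliners: bool = False
    education_cutoff_years: int = 12
    level: float = 0.95
    threshold: float = 3.0
    bootstrap_draws: int = 10_000
    seed: int = 0
    milestones: tuple = DEFAULT_MILESTONES
    outdir: str = "results/pipeline"

    def __post_init__(self):
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.bootstrap_draws < 100:
            raise ValueError("bootstrap_draws must be >= 100")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "milestones" in data:
            data["milestones"] = tuple(float(m) for m in data["milestones"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["milestones"] = list(self.milestones)
        return d

    def digest(self) -> str:
        """Hash of the analysis-relevant settings (outdir excluded)."""
        d = self.to_dict()
        d.pop("outdir")
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


def _model_dict(m: QuadraticLogModel) -> dict:
    return {
        "beta0": m.beta0, "beta1": m.beta1, "beta2": m.beta2,
        "fixed_cov": np.asarray(m.fixed_cov).tolist(),
        "sigma_b": m.sigma_b, "sigma_e": m.sigma_e,
        "n_obs": m.n_obs, "n_patients": m.n_patients,
        "loglik": m.loglik, "aic": m.aic, "bic": m.bic, "aicc": m.aicc,
        "time_domain": list(m.time_domain),
        "equation": m.equation(),
    }


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: PipelineConfig) -> dict[str, StratumResult]:
    """Run the full analysis and write the report bundle to config.outdir.

    Outputs: visits.csv (when simulated), summary.csv, models.json
    (per-stratum per-cohort fits with outlier reports), stitching.json
    (overlap scores and shifts), continuum.json (per-stratum equations),
    transitions.csv / milestones.csv / segment_durations.csv (tables),
    and pipeline.log (seed, config hash, decisions).  Deterministic given
    (config, seed).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed={config.seed}", f"config_hash={config.digest()}"]

    if config.input_path:
        records = read_visits(config.input_path)
        log.append(f"loaded {records['patient_id'].nunique()} patients "
                   f"from {config.input_path}")
    else:
        design = default_study(
            sigma_b=config.sigma_b, sigma_e=config.sigma_e,
            nondecliner_fraction=config.nondecliner_fraction,
            scale=config.simulate_scale)
        records = design.generate(seed=config.seed)
        write_visits(records, out / "visits.csv")
        log.append(f"simulated {records['patient_id'].nunique()} patients "
                   f"(scale={config.simulate_scale})")

    if not config.include_nondecliners:
        records, excluded = apply_decliner_filter(records)
        log.append(f"excluded {len(excluded)} non-decliner patients")
    else:
        log.append("non-decliners included (sensitivity mode)")

    results = stratified_pipeline(
        records,
        education_cutoff_years=config.education_cutoff_years,
        milestones=config.milestones,
        level=config.level,
        threshold=config.threshold,
        B=config.bootstrap_draws,
        seed=config.seed,
    )

    summarize_study(records, config.education_cutoff_years).to_csv(
        out / "summary.csv", index=False)

    models_json, stitching_json, continuum_json = {}, {}, {}
    trans_rows, mile_rows, dur_rows = [], [], []
    for stratum, res in results.items():
        models_json[stratum] = {
            lab: {
                **_model_dict(m),
                "quadratic_p": res.stitch.quad_pvalues[lab],
                "outliers_removed": list(res.stitch.reports[lab].removed_obs_ids),
                "ic_before": list(res.stitch.reports[lab].ic_before),
                "ic_after": list(res.stitch.reports[lab].ic_after),
            }
            for lab, m in res.stitch.models.items()
        }
        stitching_json[stratum] = {
            "offsets": res.stitch.offsets,
            "overlaps": [dataclasses.asdict(ov) for ov in res.stitch.overlaps],
        }
        continuum_json[stratum] = {
            **_model_dict(res.continuum.model),
            "offsets": res.continuum.offsets,
            "transition_scores": {k: list(v) for k, v in
                                  res.continuum.transition_scores.items()},
            "n_patients": res.n_patients,
        }
        trans_rows.append(res.transitions.assign(stratum=stratum))
        mile_rows.append(res.milestones.table.assign(stratum=stratum))
        dur_rows.append(res.milestones.durations.assign(stratum=stratum))
        for lab in res.stitch.models:
            p = res.stitch.quad_pvalues[lab]
            kept = "kept" if res.stitch.models[lab].has_quadratic else "dropped"
            nrem = len(res.stitch.reports[lab].removed_obs_ids)
            log.append(f"[{stratum}/{lab}] quadratic term {kept} (p={p:.4g}); "
                       f"{nrem} outlier observation(s) removed")
        for ov in res.stitch.overlaps:
            log.append(f"[{stratum}] {ov.earlier_cohort}->{ov.later_cohort}: "
                       f"overlap score {ov.overlap_cdrsb:.3f}, "
                       f"shift {ov.shift_months:.1f} months")

    for name, payload in [("models.json", models_json),
                          ("stitching.json", stitching_json),
                          ("continuum.json", continuum_json)]:
        (out / name).write_text(
            json.dumps(payload, indent=2, sort_keys=True, default=_json_default))
    pd.concat(trans_rows, ignore_index=True).to_csv(out / "transitions.csv", index=False)
    pd.concat(mile_rows, ignore_index=True).to_csv(out / "milestones.csv", index=False)
    pd.concat(dur_rows, ignore_index=True).to_csv(
        out / "segment_durations.csv", index=False)
    (out / "pipeline.log").write_text("\n".join(log) + "\n")
    return results
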