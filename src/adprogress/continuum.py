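"""Continuum model over stitched cohorts: milestones, transitions, strata.

After stitching, one mixed-effect quadratic log-trajectory is fitted to
the combined data; milestone times (months at which the mean curve first
reaches a given CDR-SB value) follow by inverting the quadratic, and
their confidence intervals by a parametric bootstrap of the fixed-effect
vector from its asymptotic normal distribution (percentile intervals; a
delta-method alternative is available).  Transition analyses re-evaluate
the cohort-overlap rule per bootstrap draw.  The education-stratified
pipeline runs the whole chain (per-cohort fits -> stitch -> continuum ->
tables) independently for the lower (<= cutoff years) and higher strata
and for the pooled total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stitching import (
    StitchResult,
    find_overlap,
    invert_trajectory,
    prediction_band,
    stitch,
)
from .synthetic import COHORT_ORDER
from .trajectory import QuadraticLogModel, fit_cohort, log_transform

__all__ = [
    "ContinuumModel",
    "MilestoneTable",
    "GroupComparison",
    "StratumResult",
    "DEFAULT_MILESTONES",
    "fit_continuum",
    "milestone_times",
    "transition_times",
    "compare_groups_at_milestone",
    "stratified_pipeline",
]

#: milestone grid: instrument endpoints plus the staging breakpoints
#: conventionally tabulated for CDR-SB progression (2.5, 4.5, 9.5, 16)
DEFAULT_MILESTONES = (0.0, 2.5, 4.5, 9.5, 16.0, 18.0)


@dataclass(frozen=True)
class ContinuumModel:
    """Single trajectory model over the stitched multi-cohort data."""

    model: QuadraticLogModel
    offsets: dict
    transition_scores: dict
    stratum_label: str = "total"

    def __post_init__(self):
        if self.offsets:
            first = next(iter(self.offsets))
            if self.offsets[first] != 0.0:
                raise ValueError("first cohort's offset must be 0")


@dataclass(frozen=True)
class MilestoneTable:
    """Milestone times plus derived segment durations, each with CIs.

    ``table`` has columns (milestone, time_months, ci_lo, ci_hi, note);
    ``durations`` has (from_milestone, to_milestone, duration, ci_lo,
    ci_hi).  Milestones at or below the fitted score at t = 0 are clamped
    to time 0 and flagged in ``note`` rather than dropped.
    """

    table: pd.DataFrame
    durations: pd.DataFrame
    level: float
    method: str


@dataclass(frozen=True)
class GroupComparison:
    """Milestone-time comparison between two fitted strata."""

    milestone: float
    time_a: float
    ci_a: tuple[float, float]
    time_b: float
    ci_b: tuple[float, float]
    difference: float
    ci_overlap: bool


@dataclass(frozen=True)
class StratumResult:
    """Everything the pipeline produces for one education stratum."""

    stitch: StitchResult
    continuum: ContinuumModel
    milestones: MilestoneTable
    transitions: pd.DataFrame
    n_patients: int


# ---------------------------------------------------------------------
# root solving over bootstrap draws
# ---------------------------------------------------------------------

def _roots_for_draws(draws: np.ndarray, target: float) -> np.ndarray:
    """Non-negative crossing time per coefficient draw; NaN when the drawn
    curve never reaches the target, 0 when the target is at/below the
    drawn curve's origin."""
    b0, b1 = draws[:, 0], draws[:, 1]
    b2 = draws[:, 2] if draws.shape[1] == 3 else np.zeros_like(b0)
    c = b0 - log_transform(target)
    out = np.full(len(draws), np.nan)
    lin = np.abs(b2) < 1e-300
    with np.errstate(invalid="ignore", divide="ignore"):
        out[lin] = -c[lin] / b1[lin]
        disc = b1**2 - 4.0 * b2 * c
        ok = ~lin & (disc >= 0)
        out[ok] = (-b1[ok] + np.sqrt(disc[ok])) / (2.0 * b2[ok])
    out[c >= 0] = 0.0  # target at/below the drawn origin
    out[out < 0] = np.nan
    return out


def _draw_coefficients(model: QuadraticLogModel, B: int,
                       rng: np.random.Generator) -> np.ndarray:
    beta = model.coefficients[: model.fixed_cov.shape[0]]
    if not np.any(model.fixed_cov):
        return np.tile(beta, (B, 1))
    return rng.multivariate_normal(beta, model.fixed_cov, size=B,
                                   method="svd")


def _milestone_time_point(model: QuadraticLogModel, m: float) -> tuple[float, str]:
    if m <= model.origin_score:
        return 0.0, "at/below model origin; clamped to t = 0"
    return invert_trajectory(model, m), ""


def milestone_times(
    model: QuadraticLogModel,
    milestones=DEFAULT_MILESTONES,
    B: int = 10_000,
    seed: int | None = None,
    method: str = "bootstrap",
    level: float = 0.95,
) -> MilestoneTable:
    """Times at which the mean curve reaches each milestone, with CIs.

    ``method='bootstrap'`` draws the fixed-effect vector B times from
    N(beta_hat, Cov) and takes percentile bounds of the inverted times
    (and of the successive differences, for segment-duration CIs);
    ``method='delta'`` uses the implicit-function gradient
    dt/dbeta = -(1, t, t^2) / (beta1 + 2 beta2 t) with a normal interval.
    """
    milestones = [float(m) for m in milestones]
    alpha = 1.0 - level
    rng = np.random.default_rng(seed)

    rows, time_draws = [], {}
    if method == "bootstrap":
        draws = _draw_coefficients(model, B, rng)
    elif method != "delta":
        raise ValueError(f"unknown ci method: {method}")

    for m in milestones:
        time, note = _milestone_time_point(model, m)
        if method == "bootstrap":
            td = _roots_for_draws(draws, m)
            lo, hi = np.nanpercentile(td, [100 * alpha / 2, 100 * (1 - alpha / 2)])
            time_draws[m] = td
        else:
            x = np.array([1.0, time, time**2][: model.fixed_cov.shape[0]])
            grad = -x / (model.beta1 + 2.0 * model.beta2 * time)
            se = float(np.sqrt(grad @ model.fixed_cov @ grad))
            z = stats.norm.ppf(0.5 + level / 2.0)
            lo, hi = time - z * se, time + z * se
            if note:  # clamped milestone has no meaningful interval
                lo = hi = time
        rows.append({"milestone": m, "time_months": time,
                     "ci_lo": float(lo), "ci_hi": float(hi), "note": note})
    table = pd.DataFrame(rows)

    dur_rows = []
    for (_, a), (_, b) in zip(table.iterrows(), table.iloc[1:].iterrows()):
        dur = b["time_months"] - a["time_months"]
        if method == "bootstrap":
            dd = time_draws[b["milestone"]] - time_draws[a["milestone"]]
            lo, hi = np.nanpercentile(dd, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        else:
            spread = (b["ci_hi"] - b["ci_lo"]) / 2 + (a["ci_hi"] - a["ci_lo"]) / 2
            lo, hi = dur - spread, dur + spread
        dur_rows.append({"from_milestone": a["milestone"], "to_milestone": b["milestone"],
                         "duration": dur, "ci_lo": float(lo), "ci_hi": float(hi)})
    durations = pd.DataFrame(
        dur_rows, columns=["from_milestone", "to_milestone", "duration", "ci_lo", "ci_hi"])
    return MilestoneTable(table=table, durations=durations, level=level, method=method)


# ---------------------------------------------------------------------
# continuum fit and transitions
# ---------------------------------------------------------------------

def fit_continuum(
    combined_records: pd.DataFrame,
    offsets: dict | None = None,
    stratum_label: str = "total",
    threshold: float = 3.0,
    transition_scores: dict | None = None,
) -> ContinuumModel:
    """Fit the single continuum trajectory on stitched (shifted) records.

    Uses the same machinery as the per-cohort fits: quadratic-term test
    followed by the single outlier pass.
    """
    model, _report, _p = fit_cohort(combined_records, threshold=threshold)
    return ContinuumModel(
        model=model,
        offsets=dict(offsets or {}),
        transition_scores=dict(transition_scores or {}),
        stratum_label=stratum_label,
    )


def _union_segments(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge per-time CIs into disjoint envelope segments (sorted by lo)."""
    order = np.argsort(lo)
    lo, hi = lo[order], hi[order]
    run_hi = np.maximum.accumulate(hi)
    new_seg = np.empty(len(lo), dtype=bool)
    new_seg[0] = True
    new_seg[1:] = lo[1:] > run_hi[:-1]
    starts = np.flatnonzero(new_seg)
    ends = np.append(starts[1:], len(lo)) - 1
    return lo[starts], run_hi[ends]


def _overlap_for_draw(
    est_later_sorted: np.ndarray,
    lo_earlier: np.ndarray,
    hi_earlier: np.ndarray,
) -> float:
    """Smallest later estimate inside the earlier envelope, or NaN."""
    seg_lo, seg_hi = _union_segments(lo_earlier, hi_earlier)
    idx = np.searchsorted(est_later_sorted, seg_lo)
    ok = (idx < len(est_later_sorted))
    cand = np.where(ok, est_later_sorted[np.minimum(idx, len(est_later_sorted) - 1)], np.inf)
    cand = np.where(cand <= seg_hi, cand, np.inf)
    best = cand.min()
    return float(best) if np.isfinite(best) else np.nan


def transition_times(
    stitch_result: StitchResult,
    cohort_times: dict | None = None,
    B: int = 10_000,
    seed: int | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Transition scores and times between consecutive cohorts, with CIs.

    The point estimates are the stitch's overlap scores and pairwise
    shifts; CIs re-evaluate the overlap rule per parametric-bootstrap draw
    of both cohorts' fixed effects (the per-time CI half-widths stay at
    their fitted values).  Returns one row per consecutive pair with the
    cumulative time along the severity path; empty for a single cohort.
    """
    cols = ["pair", "score", "score_lo", "score_hi",
            "months", "months_lo", "months_hi", "cumulative_months", "n_draws_used"]
    if len(stitch_result.overlaps) == 0:
        return pd.DataFrame(columns=cols)
    if cohort_times is None:
        cohort_times = {
            lab: stitch_result.combined_records.loc[
                stitch_result.combined_records["cohort"] == lab, "time_months"
            ].to_numpy() - stitch_result.offsets[lab]
            for lab in stitch_result.offsets
        }
    alpha = 1.0 - level
    rng = np.random.default_rng(seed)
    z = stats.norm.ppf(0.5 + level / 2.0)

    rows, cumulative = [], 0.0
    for ov in stitch_result.overlaps:
        m_e = stitch_result.models[ov.earlier_cohort]
        m_l = stitch_result.models[ov.later_cohort]
        t_e = np.unique(np.round(np.asarray(cohort_times[ov.earlier_cohort], float), 3))
        t_l = np.unique(np.round(np.asarray(cohort_times[ov.later_cohort], float), 3))
        X_e, X_l = m_e.design(t_e), m_l.design(t_l)
        se_e = np.sqrt(np.maximum(
            np.einsum("ij,jk,ik->i", X_e, m_e.fixed_cov, X_e), 0.0))
        draws_e = _draw_coefficients(m_e, B, rng)
        draws_l = _draw_coefficients(m_l, B, rng)
        y_e = draws_e @ X_e.T                       # (B, n_e) log-scale means
        est_l = np.exp(draws_l @ X_l.T) - 0.5       # (B, n_l) natural scale
        lo_e = np.exp(y_e - z * se_e) - 0.5
        hi_e = np.exp(y_e + z * se_e) - 0.5

        score_draws = np.full(B, np.nan)
        for b in range(B):
            score_draws[b] = _overlap_for_draw(np.sort(est_l[b]), lo_e[b], hi_e[b])
        valid = np.isfinite(score_draws)
        time_draws = np.full(B, np.nan)
        if valid.any():
            # invert each drawn earlier model at its own drawn overlap score
            b0, b1 = draws_e[valid, 0], draws_e[valid, 1]
            b2 = draws_e[valid, 2] if draws_e.shape[1] == 3 else np.zeros_like(b0)
            c = b0 - np.log(score_draws[valid] + 0.5)
            with np.errstate(invalid="ignore", divide="ignore"):
                disc = b1**2 - 4.0 * b2 * c
                t = np.where(np.abs(b2) < 1e-300, -c / b1,
                             (-b1 + np.sqrt(np.where(disc >= 0, disc, np.nan)))
                             / (2.0 * b2))
            t = np.where((c < 0) & np.isfinite(t) & (t >= 0), t, np.nan)
            time_draws[valid] = t

        def _ci(d):
            if np.isfinite(d).sum() == 0:
                return (np.nan, np.nan)
            return tuple(np.nanpercentile(d, [100 * alpha / 2, 100 * (1 - alpha / 2)]))

        s_lo, s_hi = _ci(score_draws)
        t_lo, t_hi = _ci(time_draws)
        cumulative += ov.shift_months
        rows.append({
            "pair": f"{ov.earlier_cohort}->{ov.later_cohort}",
            "score": ov.overlap_cdrsb, "score_lo": s_lo, "score_hi": s_hi,
            "months": ov.shift_months, "months_lo": t_lo, "months_hi": t_hi,
            "cumulative_months": cumulative,
            "n_draws_used": int(np.isfinite(time_draws).sum()),
        })
    return pd.DataFrame(rows, columns=cols)


def compare_groups_at_milestone(
    model_a: QuadraticLogModel,
    model_b: QuadraticLogModel,
    milestone: float,
    B: int = 10_000,
    seed: int | None = None,
    level: float = 0.95,
) -> GroupComparison:
    """Milestone-time comparison between two fitted curves.

    ``difference`` is time_b - time_a; ``ci_overlap`` is True iff the two
    percentile intervals intersect.
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    ta = milestone_times(model_a, [milestone], B=B,
                         seed=int(ss[0].generate_state(1)[0] % 2**31), level=level)
    tb = milestone_times(model_b, [milestone], B=B,
                         seed=int(ss[1].generate_state(1)[0] % 2**31), level=level)
    ra, rb = ta.table.iloc[0], tb.table.iloc[0]
    ci_a = (float(ra["ci_lo"]), float(ra["ci_hi"]))
    ci_b = (float(rb["ci_lo"]), float(rb["ci_hi"]))
    overlap = (ci_a[0] <= ci_b[1]) and (ci_b[0] <= ci_a[1])
    return GroupComparison(
        milestone=float(milestone),
        time_a=float(ra["time_months"]), ci_a=ci_a,
        time_b=float(rb["time_months"]), ci_b=ci_b,
        difference=float(rb["time_months"] - ra["time_months"]),
        ci_overlap=bool(overlap),
    )


# ---------------------------------------------------------------------
# stratified pipeline
# ---------------------------------------------------------------------

def _severity_sorted(records: pd.DataFrame) -> list:
    present = [c for c in COHORT_ORDER if c in set(records["cohort"])]
    extra = sorted(set(records["cohort"]) - set(COHORT_ORDER))
    return present + extra


def _run_stratum(records: pd.DataFrame, label: str, milestones, level: float,
                 threshold: float, B: int, seed: int) -> StratumResult:
    datasets = [(c, records[records["cohort"] == c].copy())
                for c in _severity_sorted(records)]
    st = stitch(datasets, level=level, threshold=threshold)
    ss = np.random.SeedSequence(seed).spawn(2)
    trans = transition_times(st, B=B, level=level,
                             seed=int(ss[0].generate_state(1)[0] % 2**31))
    scores = {row["pair"]: (row["score"], row["score_lo"], row["score_hi"])
              for _, row in trans.iterrows()}
    cont = fit_continuum(st.combined_records, offsets=st.offsets,
                         stratum_label=label, threshold=threshold,
                         transition_scores=scores)
    miles = milestone_times(cont.model, milestones, B=B, level=level,
                            seed=int(ss[1].generate_state(1)[0] % 2**31))
    return StratumResult(stitch=st, continuum=cont, milestones=miles,
                         transitions=trans,
                         n_patients=records["patient_id"].nunique())


def stratified_pipeline(
    records: pd.DataFrame,
    education_cutoff_years: int = 12,
    milestones=DEFAULT_MILESTONES,
    level: float = 0.95,
    threshold: float = 3.0,
    B: int = 10_000,
    seed: int | None = None,
) -> dict[str, StratumResult]:
    """Full pipeline per education stratum and for the pooled total.

    Lower stratum: education <= cutoff; higher: > cutoff.  Each stratum is
    fitted fully independently (per-cohort fits, stitching, continuum,
    milestone and transition tables).
    """
    if "education_years" not in records.columns:
        raise ValueError("records must carry education_years")
    edu = records["education_years"].to_numpy()
    subsets = {
        "total": records,
        "lower": records[edu <= education_cutoff_years],
        "higher": records[edu > education_cutoff_years],
    }
    for name, sub in subsets.items():
        if len(sub) == 0:
            raise ValueError(f"education stratum '{name}' is empty")
    seeds = np.random.SeedSequence(seed).spawn(len(subsets))
    return {
        name: _run_stratum(sub, name, milestones, level, threshold, B,
                           int(s.generate_state(1)[0] % 2**31))
        for (name, sub), s in zip(subsets.items(), seeds)
    }
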