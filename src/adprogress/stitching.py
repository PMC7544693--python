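"""Temporal alignment of severity-ordered cohorts onto one disease clock.

Each cohort is fitted on its own follow-up clock.  Two consecutive
cohorts are aligned by the confidence-envelope overlap rule: a later
cohort's point estimates (evaluated at its patients' measurement times)
are tested for containment in the earlier cohort's union-of-CIs envelope;
the smallest contained estimate is the overlap score, and the time at
which the earlier cohort's mean curve attains that score — obtained by
inverting its quadratic — is the pairwise shift.  Shifts accumulate
additively along the severity order, and shifted records are pooled into
one combined dataset for the continuum fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trajectory import (
    QuadraticLogModel,
    back_transform,
    fit_cohort,
    log_transform,
)

__all__ = [
    "PredictionBand",
    "OverlapResult",
    "StitchResult",
    "prediction_band",
    "invert_trajectory",
    "find_overlap",
    "shift_records",
    "stitch",
]


@dataclass(frozen=True)
class PredictionBand:
    """Pointwise estimate and CI of the cohort mean CDR-SB curve.

    ``est/lo/hi`` are on the natural CDR-SB scale; the log-scale
    counterparts are kept alongside since the model is linear there.
    """

    times: np.ndarray
    est: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    level: float
    est_log: np.ndarray
    lo_log: np.ndarray
    hi_log: np.ndarray


@dataclass(frozen=True)
class OverlapResult:
    """Overlap score and implied time shift between two cohorts."""

    earlier_cohort: str
    later_cohort: str
    overlap_cdrsb: float
    shift_months: float
    n_overlapped: int
    extrapolated: bool


@dataclass(frozen=True)
class StitchResult:
    """Combined stitched dataset plus everything used to build it."""

    combined_records: pd.DataFrame
    offsets: dict
    overlaps: tuple
    models: dict
    reports: dict
    quad_pvalues: dict

    @property
    def cohort_order(self) -> tuple:
        return tuple(self.offsets)


def prediction_band(model: QuadraticLogModel, times, level: float = 0.95
                    ) -> PredictionBand:
    """95% (by default) CI band of the fixed-effect mean curve.

    Computed on the log scale as x(t)'beta +- z * sqrt(x(t)' Cov x(t))
    and mapped through the monotone back-transform, so the ordering
    lo <= est <= hi is preserved on the natural scale.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if times.size == 0:
        empty = np.array([])
        return PredictionBand(times, empty, empty, empty, level, empty, empty, empty)
    X = model.design(times)
    est_log = X @ np.array([model.beta0, model.beta1, model.beta2][: X.shape[1]])
    var = np.einsum("ij,jk,ik->i", X, model.fixed_cov, X)
    if np.any(var < -1e-12):
        raise ValueError("negative prediction variance: broken covariance matrix")
    se = np.sqrt(np.maximum(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo_log, hi_log = est_log - z * se, est_log + z * se
    return PredictionBand(
        times=times,
        est=back_transform(est_log),
        lo=back_transform(lo_log),
        hi=back_transform(hi_log),
        level=level,
        est_log=est_log,
        lo_log=lo_log,
        hi_log=hi_log,
    )


def invert_trajectory(model: QuadraticLogModel, target_cdrsb: float) -> float:
    """Months at which the fitted mean curve reaches ``target_cdrsb``.

    Solves beta2 t^2 + beta1 t + (beta0 - ln(target + 0.5)) = 0 for its
    unique non-negative root (linear solution when beta2 = 0).
    """
    if model.beta1 <= 0:
        raise ValueError("inversion requires beta1 > 0")
    if target_cdrsb > 18.0:
        raise ValueError("target exceeds the CDR-SB ceiling of 18")
    c = model.beta0 - log_transform(target_cdrsb)
    if c > 0:
        raise ValueError(
            f"target {target_cdrsb} precedes model origin "
            f"(fitted score {model.origin_score:.3f} at t = 0)")
    if model.beta2 == 0.0:
        return float(-c / model.beta1)
    disc = model.beta1**2 - 4.0 * model.beta2 * c
    if disc < 0:
        raise ValueError("negative discriminant: curve never reaches target")
    return float((-model.beta1 + np.sqrt(disc)) / (2.0 * model.beta2))


def find_overlap(
    earlier_model: QuadraticLogModel,
    earlier_times,
    later_model: QuadraticLogModel,
    later_times,
    level: float = 0.95,
    earlier_label: str = "earlier",
    later_label: str = "later",
) -> OverlapResult:
    """Overlap score between two consecutive cohorts and the time shift.

    A later-cohort point estimate is "overlapped" when it falls inside
    the earlier cohort's CI envelope (the union over the earlier cohort's
    measurement times of the per-time CIs, natural scale).  The smallest
    overlapped estimate is substituted into the earlier model to obtain
    the shift on the earlier cohort's clock.
    """
    band = prediction_band(earlier_model, earlier_times, level=level)
    later_times = np.atleast_1d(np.asarray(later_times, dtype=float))
    est = later_model.predict(later_times)
    contained = np.any(
        (band.lo[None, :] <= est[:, None]) & (est[:, None] <= band.hi[None, :]),
        axis=1,
    )
    n_overlap = int(contained.sum())
    if n_overlap == 0:
        raise ValueError(
            f"cohorts {earlier_label} and {later_label} do not overlap; "
            "widen the confidence level or check the severity ordering")
    overlap_cdrsb = float(est[contained].min())
    shift = invert_trajectory(earlier_model, overlap_cdrsb)
    lo_dom, hi_dom = earlier_model.time_domain
    return OverlapResult(
        earlier_cohort=earlier_label,
        later_cohort=later_label,
        overlap_cdrsb=overlap_cdrsb,
        shift_months=shift,
        n_overlapped=n_overlap,
        extrapolated=not (lo_dom <= shift <= hi_dom),
    )


def shift_records(records: pd.DataFrame, offset_months: float) -> pd.DataFrame:
    """Add a constant offset to every visit time; nothing else changes."""
    if offset_months < 0:
        raise ValueError("offset must be non-negative")
    out = records.copy()
    out["time_months"] = out["time_months"] + offset_months
    return out


def stitch(cohort_datasets, level: float = 0.95, threshold: float = 3.0
           ) -> StitchResult:
    """Align severity-ordered cohorts onto one disease clock.

    ``cohort_datasets`` is an ordered sequence of (label, records) pairs,
    mildest cohort first.  Each cohort is fitted by the full per-cohort
    procedure (quadratic-term test plus outlier pass); pairwise shifts are
    computed on the unshifted within-cohort clocks and accumulated, so the
    first cohort's offset is 0 and offsets are non-decreasing in severity.
    """
    cohort_datasets = list(cohort_datasets)
    if len(cohort_datasets) < 1:
        raise ValueError("need at least one cohort")
    models, reports, pvals = {}, {}, {}
    for label, records in cohort_datasets:
        try:
            models[label], reports[label], pvals[label] = fit_cohort(
                records, threshold=threshold)
        except Exception as err:
            raise RuntimeError(f"per-cohort fit failed for {label}: {err}") from err

    offsets = {cohort_datasets[0][0]: 0.0}
    overlaps = []
    for (lab_a, rec_a), (lab_b, rec_b) in zip(cohort_datasets, cohort_datasets[1:]):
        try:
            ov = find_overlap(
                models[lab_a], rec_a["time_months"].to_numpy(),
                models[lab_b], rec_b["time_months"].to_numpy(),
                level=level, earlier_label=lab_a, later_label=lab_b,
            )
        except ValueError as err:
            raise RuntimeError(f"stitching failed for pair {lab_a}->{lab_b}: {err}") from err
        overlaps.append(ov)
        # the later cohort is translated to START at the overlap time, so
        # any constant already added to its clock is absorbed; with visit
        # times starting at 0 (the normal case) the offset is the plain
        # cumulative sum of pairwise shifts
        t_min_b = float(rec_b["time_months"].min())
        offsets[lab_b] = offsets[lab_a] + ov.shift_months - t_min_b

    combined = pd.concat(
        [shift_records(rec, offsets[lab]) for lab, rec in cohort_datasets],
        ignore_index=True,
    )
    return StitchResult(
        combined_records=combined,
        offsets=offsets,
        overlaps=tuple(overlaps),
        models=models,
        reports=reports,
        quad_pvalues=pvals,
    )
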