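"""Mixed-effect trajectory model for CDR-SB on the log scale.

The Clinical Dementia Rating Sum of Boxes (CDR-SB, 0-18 in half-point
steps) is right-skewed and contains zeros, so each cohort is modelled on
the transformed scale y = ln(CDR-SB + 0.5) as

    y_ij = beta0 + beta1 * t_ij + beta2 * t_ij**2 + u_i + e_ij ,

where t_ij is months since the patient's first visit, u_i ~ N(0, sigma_b^2)
is a per-patient random intercept and e_ij ~ N(0, sigma_e^2) is residual
noise.  The quadratic time term is kept only when a Wald test rejects
beta2 = 0 at the 5% level.  Estimation is by full maximum likelihood so
that AIC/BIC/AICC are comparable across fixed-effect specifications and
across the before/after stages of the outlier pass.

Outliers are single observations whose conditional studentized residual
(observed minus fixed part minus predicted random intercept, scaled by
the residual SD) exceeds a threshold (default 3) in absolute value; they
are removed in one pass and the model is refitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "QuadraticLogModel",
    "OutlierReport",
    "log_transform",
    "back_transform",
    "information_criteria",
    "fit_lmm",
    "test_quadratic_term",
    "studentized_residuals",
    "remove_outliers_and_refit",
    "fit_cohort",
]

#: columns every visit-record table must carry
REQUIRED_COLUMNS = ("patient_id", "cohort", "time_months", "cdrsb")

_QUAD_FORMULA = "log_cdrsb ~ time_months + I(time_months ** 2)"
_LIN_FORMULA = "log_cdrsb ~ time_months"


def log_transform(cdrsb):
    """ln(CDR-SB + 0.5); the 0.5 offset admits the zero score."""
    x = np.asarray(cdrsb, dtype=float)
    if np.any(x < 0):
        raise ValueError("CDR-SB scores must be non-negative")
    out = np.log(x + 0.5)
    return float(out) if np.isscalar(cdrsb) else out


def back_transform(y):
    """Inverse of :func:`log_transform`: exp(y) - 0.5."""
    out = np.exp(np.asarray(y, dtype=float)) - 0.5
    return float(out) if np.isscalar(y) else out


def information_criteria(loglik: float, k: int, n: int) -> tuple[float, float, float]:
    """AIC, BIC and small-sample-corrected AICC for a model with
    ``k`` estimated parameters fitted by ML to ``n`` observations.

    AICC = AIC + 2k(k+1)/(n-k-1) requires n > k + 1.
    """
    if n <= k + 1:
        raise ValueError(f"AICC undefined for n={n} <= k+1={k + 1}")
    aic = -2.0 * loglik + 2.0 * k
    bic = -2.0 * loglik + k * np.log(n)
    aicc = aic + 2.0 * k * (k + 1) / (n - k - 1)
    return aic, bic, aicc


@dataclass(frozen=True)
class QuadraticLogModel:
    """Fitted trajectory ln(CDR-SB + 0.5) = beta0 + beta1*t + beta2*t^2.

    ``beta2`` is 0.0 when the quadratic term was dropped, in which case
    ``fixed_cov`` is 2x2 (intercept, linear).  ``time_domain`` records
    the span of observation times the model was fitted on.
    """

    beta0: float
    beta1: float
    beta2: float
    fixed_cov: np.ndarray
    sigma_b: float
    sigma_e: float
    n_obs: int
    n_patients: int
    loglik: float
    aic: float
    bic: float
    aicc: float
    time_domain: tuple[float, float] = (0.0, np.inf)

    def __post_init__(self):
        cov = np.asarray(self.fixed_cov, dtype=float)
        if cov.shape not in ((2, 2), (3, 3)):
            raise ValueError("fixed_cov must be 2x2 or 3x3")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("fixed_cov must be symmetric")
        if np.linalg.eigvalsh(cov).min() < -1e-8 * max(1.0, np.abs(cov).max()):
            raise ValueError("fixed_cov must be positive semi-definite")
        if self.sigma_b < 0 or self.sigma_e < 0:
            raise ValueError("variance components must be non-negative")
        object.__setattr__(self, "fixed_cov", cov)

    # -- construction -------------------------------------------------
    @classmethod
    def from_coefficients(
        cls,
        beta0: float,
        beta1: float,
        beta2: float = 0.0,
        fixed_cov: np.ndarray | None = None,
        sigma_b: float = 0.0,
        sigma_e: float = 0.0,
        time_domain: tuple[float, float] = (0.0, np.inf),
    ) -> "QuadraticLogModel":
        """Wrap published or externally supplied coefficients as a model.

        With no covariance given the fixed effects are treated as known
        exactly (degenerate zero covariance), so all interval estimates
        collapse onto the point estimate.
        """
        p = 3 if beta2 != 0.0 else 2
        cov = np.zeros((p, p)) if fixed_cov is None else np.asarray(fixed_cov, float)
        return cls(
            beta0=beta0, beta1=beta1, beta2=beta2, fixed_cov=cov,
            sigma_b=sigma_b, sigma_e=sigma_e, n_obs=0, n_patients=0,
            loglik=np.nan, aic=np.nan, bic=np.nan, aicc=np.nan,
            time_domain=time_domain,
        )

    # -- evaluation ---------------------------------------------------
    @property
    def has_quadratic(self) -> bool:
        return self.fixed_cov.shape[0] == 3

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2])

    @property
    def origin_score(self) -> float:
        """Fitted CDR-SB at t = 0 (exp(beta0) - 0.5; not necessarily 0)."""
        return back_transform(self.beta0)

    def design(self, times) -> np.ndarray:
        t = np.atleast_1d(np.asarray(times, dtype=float))
        cols = [np.ones_like(t), t] + ([t**2] if self.has_quadratic else [])
        return np.column_stack(cols)

    def predict_log(self, times):
        t = np.asarray(times, dtype=float)
        out = self.beta0 + self.beta1 * t + self.beta2 * t**2
        return float(out) if np.isscalar(times) else out

    def predict(self, times):
        """Mean CDR-SB (natural scale) at the given times."""
        return back_transform(self.predict_log(times))

    def equation(self) -> str:
        s = f"ln(CDR-SB + 0.5) = {self.beta0:.6g} + {self.beta1:.6g}*t"
        if self.beta2:
            s += f" + {self.beta2:.6g}*t^2"
        return s


@dataclass(frozen=True)
class OutlierReport:
    """Bookkeeping for the single-pass outlier removal."""

    removed_obs_ids: tuple
    threshold: float
    ic_before: tuple[float, float, float]
    ic_after: tuple[float, float, float]
    n_removed_patients: int = 0


# ---------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------

def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns: {missing}")
    if records["patient_id"].nunique() < 2:
        raise ValueError("need at least 2 patients to fit a mixed model")
    t = records["time_months"].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise ValueError("time_months must be finite and non-negative")
    counts = records.groupby("patient_id").size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"patients with fewer than 2 visits: {bad[:5]}")
    return records


def fit_lmm(records: pd.DataFrame, include_quadratic: bool = True) -> QuadraticLogModel:
    """ML fit of the random-intercept trajectory model.

    Parameters are counted as k = (number of fixed effects) + 2 variance
    components in the information criteria.  The fit is invariant to the
    ordering of rows and to patient-id relabeling.
    """
    records = _validate_records(records)
    df = records[list(REQUIRED_COLUMNS)].copy()
    t = df["time_months"].to_numpy(dtype=float)
    if np.ptp(t) == 0:
        cohorts = ", ".join(sorted(df["cohort"].astype(str).unique()))
        raise ValueError(f"singular design (all times equal) in cohort(s): {cohorts}")
    df["log_cdrsb"] = log_transform(df["cdrsb"].to_numpy(dtype=float))
    # deterministic row order regardless of how the caller sorted the input
    df = df.sort_values(["patient_id", "time_months"], kind="mergesort").reset_index(drop=True)

    n_obs = len(df)
    n_patients = df["patient_id"].nunique()
    n_fe = 3 if include_quadratic else 2
    k = n_fe + 2
    tdom = (float(t.min()), float(t.max()))

    # Degenerate noiseless input (e.g. data lying exactly on the mean
    # curve): the mixed-model likelihood is unbounded, so return the
    # exact interpolating polynomial from least squares.
    X = np.column_stack([np.ones(n_obs), df["time_months"]] +
                        ([df["time_months"] ** 2] if include_quadratic else []))
    y = df["log_cdrsb"].to_numpy()
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta_ols) ** 2))
    if rss / n_obs < 1e-20:
        sigma_e = max(np.sqrt(rss / n_obs), 1e-12)
        ll = -0.5 * n_obs * (np.log(2 * np.pi * sigma_e**2) + rss / (n_obs * sigma_e**2))
        aic, bic, aicc = information_criteria(ll, k, n_obs)
        b2 = float(beta_ols[2]) if include_quadratic else 0.0
        return QuadraticLogModel(
            beta0=float(beta_ols[0]), beta1=float(beta_ols[1]), beta2=b2,
            fixed_cov=np.zeros((n_fe, n_fe)), sigma_b=0.0, sigma_e=sigma_e,
            n_obs=n_obs, n_patients=n_patients, loglik=ll,
            aic=aic, bic=bic, aicc=aicc, time_domain=tdom,
        )

    formula = _QUAD_FORMULA if include_quadratic else _LIN_FORMULA
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["patient_id"])
        try:
            res = model.fit(reml=False)
            if not res.converged:
                res = model.fit(reml=False, method="powell")
        except np.linalg.LinAlgError as err:  # pragma: no cover
            raise RuntimeError(f"mixed-model fit failed: {err}") from err
    if not res.converged:
        raise RuntimeError("mixed-model optimizer did not converge "
                           f"(n_obs={n_obs}, n_patients={n_patients})")

    fe = res.fe_params.to_numpy()
    cov = res.cov_params().to_numpy()[:n_fe, :n_fe]
    cov = 0.5 * (cov + cov.T)
    sigma_b = float(np.sqrt(max(res.cov_re.to_numpy()[0, 0], 0.0)))
    sigma_e = float(np.sqrt(res.scale))
    ll = float(res.llf)
    aic, bic, aicc = information_criteria(ll, k, n_obs)
    return QuadraticLogModel(
        beta0=float(fe[0]), beta1=float(fe[1]),
        beta2=float(fe[2]) if include_quadratic else 0.0,
        fixed_cov=cov, sigma_b=sigma_b, sigma_e=sigma_e,
        n_obs=n_obs, n_patients=n_patients, loglik=ll,
        aic=aic, bic=bic, aicc=aicc, time_domain=tdom,
    )


def test_quadratic_term(records: pd.DataFrame, alpha: float = 0.05
                        ) -> tuple[float, QuadraticLogModel]:
    """Wald z-test of beta2 = 0; keep the quadratic only if p < alpha."""
    quad = fit_lmm(records, include_quadratic=True)
    se2 = np.sqrt(quad.fixed_cov[2, 2])
    if se2 == 0.0:
        p_value = 0.0 if quad.beta2 != 0.0 else 1.0
    else:
        z = quad.beta2 / se2
        p_value = float(2.0 * stats.norm.sf(abs(z)))
    if p_value < alpha:
        return p_value, quad
    return p_value, fit_lmm(records, include_quadratic=False)


def studentized_residuals(model: QuadraticLogModel, records: pd.DataFrame) -> pd.Series:
    """Conditional studentized residuals, indexed like ``records``.

    The per-patient random intercept is predicted by its BLUP
    u_i = sigma_b^2 / (sigma_b^2 + sigma_e^2 / n_i) * mean(marginal residual),
    and the conditional residual (observed - fixed part - u_i) is scaled
    by the estimated residual SD.
    """
    _ = _validate_records(records)
    y = log_transform(records["cdrsb"].to_numpy(dtype=float))
    marg = y - model.predict_log(records["time_months"].to_numpy(dtype=float))
    marg = pd.Series(marg, index=records.index)
    sb2, se2 = model.sigma_b**2, model.sigma_e**2
    if se2 == 0.0:
        se2 = 1e-24  # degenerate noiseless model: residuals are ~0 anyway
    grp = marg.groupby(records["patient_id"])
    shrink = sb2 / (sb2 + se2 / grp.transform("size"))
    blup = shrink * grp.transform("mean")
    return (marg - blup) / np.sqrt(se2)


def remove_outliers_and_refit(
    records: pd.DataFrame,
    threshold: float = 3.0,
    include_quadratic: bool = True,
) -> tuple[QuadraticLogModel, OutlierReport]:
    """Single outlier pass: fit, flag |studentized residual| > threshold,
    drop the flagged observations (whole patients only when fewer than
    two visits remain), refit, and report both IC triples.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    before = fit_lmm(records, include_quadratic=include_quadratic)
    resid = studentized_residuals(before, records)
    flagged = resid.index[np.abs(resid.to_numpy()) > threshold]
    if len(flagged) == len(records):
        raise ValueError("all observations flagged as outliers")
    kept = records.drop(index=flagged)
    counts = kept.groupby("patient_id").size()
    dropped_patients = counts[counts < 2].index
    kept = kept[~kept["patient_id"].isin(dropped_patients)]
    if len(flagged) == 0:
        after = before
    else:
        after = fit_lmm(kept, include_quadratic=include_quadratic)
    report = OutlierReport(
        removed_obs_ids=tuple(flagged.tolist()),
        threshold=threshold,
        ic_before=(before.aic, before.bic, before.aicc),
        ic_after=(after.aic, after.bic, after.aicc),
        n_removed_patients=len(dropped_patients),
    )
    return after, report


def fit_cohort(records: pd.DataFrame, threshold: float = 3.0, alpha: float = 0.05
               ) -> tuple[QuadraticLogModel, OutlierReport, float]:
    """Full per-cohort procedure: choose linear vs quadratic time by the
    Wald test, then run the single outlier pass with that specification.

    Returns (final model, outlier report, quadratic-term p-value).
    """
    p_quad, chosen = test_quadratic_term(records, alpha=alpha)
    model, report = remove_outliers_and_refit(
        records, threshold=threshold, include_quadratic=chosen.has_quadratic
    )
    return model, report, p_quad
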