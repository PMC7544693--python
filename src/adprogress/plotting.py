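"""Optional figures (spaghetti plot, fitted continuum with CI band).

Convenience only — nothing downstream depends on these.  Requires
matplotlib, imported lazily so the core package works without it.
"""

from __future__ import annotations

import numpy as np

from .stitching import prediction_band
from .trajectory import QuadraticLogModel

_COHORT_COLORS = {"SCI": "tab:blue", "AMCI": "tab:green", "ADD": "tab:red"}


def plot_continuum(model: QuadraticLogModel, records=None, offsets=None,
                   level: float = 0.95, ax=None):
    """Fitted mean CDR-SB curve with its CI band, plus (optionally) the
    stitched observations colored by cohort."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    t_hi = model.time_domain[1]
    if not np.isfinite(t_hi):
        from .stitching import invert_trajectory
        t_hi = invert_trajectory(model, 18.0)
    grid = np.linspace(0, t_hi, 300)
    band = prediction_band(model, grid, level=level)
    ax.plot(grid, band.est, color="k", lw=2, label="fitted mean")
    ax.fill_between(grid, band.lo, band.hi, color="k", alpha=0.15,
                    label=f"{int(level * 100)}% CI")
    if records is not None:
        for cohort, g in records.groupby("cohort"):
            ax.scatter(g["time_months"], g["cdrsb"], s=6, alpha=0.3,
                       color=_COHORT_COLORS.get(cohort, "gray"), label=cohort)
    if offsets:
        for lab, off in offsets.items():
            ax.axvline(off, ls=":", color=_COHORT_COLORS.get(lab, "gray"), lw=1)
    ax.set_xlabel("months on the disease clock")
    ax.set_ylabel("CDR-SB")
    ax.set_ylim(-0.5, 18.5)
    ax.legend(fontsize=8)
    return ax


def plot_spaghetti(records, ax=None):
    """Per-patient CDR-SB trajectories on each cohort's own clock."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for (_, _), g in records.groupby(["cohort", "patient_id"]):
        ax.plot(g["time_months"], g["cdrsb"], lw=0.5, alpha=0.4,
                color=_COHORT_COLORS.get(g["cohort"].iloc[0], "gray"))
    ax.set_xlabel("months since baseline")
    ax.set_ylabel("CDR-SB")
    return ax
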