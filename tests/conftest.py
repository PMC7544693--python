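"""Shared fixtures: small synthetic cohorts built from the package's own
generator, sized so the whole suite stays quick."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from adprogress import TOTAL_EQUATION, TrueProcess, generate_patient


def simulate_cohort(
    process: TrueProcess,
    n_patients: int,
    rng: np.random.Generator,
    entry_low: float = 0.0,
    entry_high: float = 0.0,
    n_visits_range: tuple[int, int] = (4, 6),
    interval_mean: float = 18.0,
    interval_sd: float = 5.0,
    label: str = "SCI",
    round_to_grid: bool = True,
    education_years: int = 12,
) -> pd.DataFrame:
    """Simulate one cohort whose patients enter at latent times drawn
    uniformly in [entry_low, entry_high] months."""
    frames = []
    for i in range(n_patients):
        n_vis = int(rng.integers(n_visits_range[0], n_visits_range[1] + 1))
        intervals = np.maximum(rng.normal(interval_mean, interval_sd, n_vis - 1), 1.0)
        frames.append(generate_patient(
            process=process,
            entry_latent_time=float(rng.uniform(entry_low, entry_high)),
            n_visits=n_vis,
            intervals=intervals,
            education_years=education_years,
            rng=rng,
            patient_id=f"{label}-{i:04d}",
            cohort=label,
            round_to_grid=round_to_grid,
        ))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def fig_process() -> TrueProcess:
    """Generating process with the published combined-curve coefficients."""
    return TrueProcess(TOTAL_EQUATION.beta0, TOTAL_EQUATION.beta1,
                       TOTAL_EQUATION.beta2, sigma_b=0.20, sigma_e=0.15)


@pytest.fixture(scope="session")
def noisy_cohort(fig_process) -> pd.DataFrame:
    """60 patients, unrounded scores, entries spread over the latent curve."""
    rng = np.random.default_rng(2024)
    return simulate_cohort(fig_process, 60, rng, entry_low=0.0, entry_high=140.0,
                           round_to_grid=False)


@pytest.fixture(scope="session")
def three_latent_cohorts(fig_process):
    """SCI/AMCI/ADD cut from one latent curve at entries 0/110/170 months."""
    rng = np.random.default_rng(77)
    out = []
    for label, entry in (("SCI", 0.0), ("AMCI", 110.0), ("ADD", 170.0)):
        out.append((label, simulate_cohort(
            fig_process, 120, rng, entry_low=entry, entry_high=entry,
            n_visits_range=(4, 6), interval_mean=22.0, interval_sd=5.0,
            label=label)))
    return out
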