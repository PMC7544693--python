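"""Published reference equations for the CDR-SB disease continuum.

The single-center clinic study that motivates this package reports one
combined predictive equation for the whole SCI -> AMCI -> ADD continuum
and one per education stratum (12 years of schooling, the duration that
precedes college in South Korea, is the cut-off).  All are quadratic in
months on the stitched disease clock, on the ln(CDR-SB + 0.5) scale:

    total            ln(CDR-SB + 0.5) = -0.06008 + 0.004275 t + 0.000024 t^2
    lower education  ln(CDR-SB + 0.5) = -0.01585 + 0.005247 t + 0.000021 t^2
    higher education ln(CDR-SB + 0.5) = -0.1377  + 0.00323  t + 0.000022 t^2

These coefficients are shipped so that milestone and transition-time
analyses can be run directly on the published fits (the ``milestones
--equation`` CLI path), and they double as the default generating truths
of the synthetic-cohort simulator.  No covariance matrices were
published, so the wrapped models carry a degenerate (zero) fixed-effect
covariance: interval estimates collapse onto the point estimate.
"""

from __future__ import annotations

from .trajectory import QuadraticLogModel

__all__ = [
    "TOTAL_EQUATION",
    "LOWER_EDUCATION_EQUATION",
    "HIGHER_EDUCATION_EQUATION",
    "PUBLISHED_EQUATIONS",
]

TOTAL_EQUATION = QuadraticLogModel.from_coefficients(-0.06008, 0.004275, 0.000024)
LOWER_EDUCATION_EQUATION = QuadraticLogModel.from_coefficients(-0.01585, 0.005247, 0.000021)
HIGHER_EDUCATION_EQUATION = QuadraticLogModel.from_coefficients(-0.1377, 0.00323, 0.000022)

PUBLISHED_EQUATIONS = {
    "total": TOTAL_EQUATION,
    "lower": LOWER_EDUCATION_EQUATION,
    "higher": HIGHER_EDUCATION_EQUATION,
}
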