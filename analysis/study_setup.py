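"""Shared study conditions for the numbered analysis scripts.

One synthetic clinic study, regenerated deterministically by every script
so they can be run independently: half-scale patient counts (283
patients) with the default severity windows, education split and noise
levels, seed 20200.
"""

from adprogress import apply_decliner_filter, default_study

SEED = 20200
SCALE = 0.5
BOOTSTRAP_DRAWS = 2000


def make_study(nondecliner_fraction: float = 0.0):
    design = default_study(
        nondecliner_fraction=nondecliner_fraction, scale=SCALE)
    return design.generate(seed=SEED)


def make_filtered_study():
    records = make_study()
    kept, excluded = apply_decliner_filter(records)
    return kept, excluded
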