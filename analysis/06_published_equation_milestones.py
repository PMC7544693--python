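"""Milestone times implied by the published predictive equations.

No fitting involved: the three published quadratic log-trajectories
(combined, lower-education, higher-education) are inverted at the
standard CDR-SB breakpoints.  Writes results/published_milestones.csv.
"""

import pathlib

import pandas as pd

from adprogress import PUBLISHED_EQUATIONS, milestone_times

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main():
    rows = []
    for name, model in PUBLISHED_EQUATIONS.items():
        mt = milestone_times(model, [0, 2.5, 4.5, 9.5, 16, 18], B=100, seed=0)
        tab = mt.table.assign(equation=name)
        rows.append(tab)
        times = tab.set_index("milestone")["time_months"]
        print(f"{name:>6}: to 2.5 = {times[2.5]:.1f} months, "
              f"to 18 = {times[18.0]:.1f} months "
              f"({times[18.0] / 12:.1f} years)")
        segs = mt.durations
        seg_str = ", ".join(
            f"{r.from_milestone:g}->{r.to_milestone:g}: {r.duration:.1f}"
            for r in segs.itertuples())
        print(f"        segments (months): {seg_str}")
    (ROOT / "results").mkdir(exist_ok=True)
    pd.concat(rows, ignore_index=True).round(2).to_csv(
        ROOT / "results" / "published_milestones.csv", index=False)


if __name__ == "__main__":
    main()
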