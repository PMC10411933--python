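"""Practice effects across the 20 aim-trainer rounds.

Per-round medians of acquire time and its four phases, plus the spatial
measures, averaged over the cohort; reports the first-to-last-round
improvement in each and writes the group learning table to results/.
"""

import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).parent))
from _cohort import exp2_sessions

from aimkin.metrics import round_summary, trials_table

RESULTS = pathlib.Path(__file__).parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    per = []
    for pid, sess in exp2_sessions():
        rs = round_summary(trials_table(sess))
        rs.insert(0, "participant", pid)
        per.append(rs)
    per = pd.concat(per, ignore_index=True)
    group = per.drop(columns="participant").groupby("round_index").mean()
    group.to_csv(RESULTS / "exp2_learning.tsv", sep="\t")

    first, last = group.iloc[0], group.iloc[-1]
    print(f"cohort acquire-time improvement over 20 rounds: "
          f"{first['median_acquire'] - last['median_acquire']:.0f} ms "
          f"({first['median_acquire']:.0f} -> {last['median_acquire']:.0f})")
    for col, label in [
        ("median_reaction", "reaction"),
        ("median_primary_mt", "primary movement"),
        ("mean_correction", "corrections (mean)"),
        ("median_dwell", "click dwell"),
        ("mean_peak_speed", "peak speed (au/s)"),
        ("sd_angle", "angle variability (deg)"),
    ]:
        print(f"  {label}: {first[col]:.1f} -> {last[col]:.1f}")
    print("table: results/exp2_learning.tsv")


if __name__ == "__main__":
    main()
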