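"""Simulate example sessions and exercise the session file round trip.

Writes one staircased two-context session (640 trials) and one aim-trainer
session (20 x 48 movements) for the first synthetic participant to
scratch/sessions/ (raw traces are bulky, so they stay out of results/),
reads them back with full validation, and reports basic counts.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).parent))
from _cohort import exp1_sessions, exp2_sessions

from aimkin.sessions import read_session, write_session

OUT = pathlib.Path(__file__).parent.parent / "scratch" / "sessions"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    pid, sess1 = next(exp1_sessions(n=1))
    path1 = OUT / f"exp1_p{pid}.tsv"
    write_session(sess1, path1)
    back = read_session(path1)
    assert len(back) == len(sess1) == 640
    print(f"exp1 participant {pid}: {len(sess1)} trials "
          f"({sum(t.success for t in sess1.trials)} successful) -> {path1}")

    pid, sess2 = next(exp2_sessions(n=1))
    path2 = OUT / f"exp2_p{pid}.tsv"
    write_session(sess2, path2)
    back = read_session(path2)
    assert len(back) == len(sess2) == 960
    print(f"exp2 participant {pid}: {len(sess2)} movements in 20 rounds -> {path2}")
    print("round trip validated: timestamps sorted, deltas consistent, clicks inside targets")


if __name__ == "__main__":
    main()
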