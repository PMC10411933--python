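"""Shared synthetic cohort for the analysis scripts.

Each synthetic participant is the default performer with mild between-
subject jitter on latencies, movement-time slope and noise scales, and a
device label (trackpad users are a little slower, as in the human cohorts).
Simulation is deterministic given the cohort seed, so every script can
regenerate the same cohort without shuttling multi-megabyte raw files.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from aimkin.performer import PerformerParams, simulate_experiment1, simulate_experiment2

COHORT_SEED = 2023
COHORT_SIZE = 8


def cohort_params(seed: int = COHORT_SEED, n: int = COHORT_SIZE):
    """(participant_id, device, PerformerParams) per synthetic participant."""
    rng = np.random.default_rng(seed)
    out = []
    for pid in range(n):
        device = "mouse" if pid % 2 == 0 else "trackpad"
        slow = device == "trackpad"
        params = replace(
            PerformerParams(),
            rt_location=float(rng.normal(180.0, 20.0)) + (30.0 if slow else 0.0),
            mt_slope=float(rng.normal(280.0, 25.0)),
            corr_latency=float(rng.normal(150.0, 15.0)) + (40.0 if slow else 0.0),
            dwell_scale=float(np.clip(rng.normal(70.0, 15.0), 30.0, None)),
            extent_cv=float(np.clip(rng.normal(0.12, 0.012), 0.08, 0.18)),
            angle_sd=float(np.clip(rng.normal(3.0, 0.35), 2.0, 4.0)),
        )
        out.append((pid, device, params))
    return out


def exp1_sessions(seed: int = COHORT_SEED, n: int = COHORT_SIZE):
    for pid, device, params in cohort_params(seed, n):
        sess = simulate_experiment1(params, np.random.default_rng(seed * 1000 + pid), seed=pid)
        sess.device = device
        yield pid, sess


def exp2_sessions(seed: int = COHORT_SEED, n: int = COHORT_SIZE):
    for pid, device, params in cohort_params(seed, n):
        sess = simulate_experiment2(params, np.random.default_rng(seed * 2000 + pid), seed=pid)
        sess.device = device
        yield pid, sess
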