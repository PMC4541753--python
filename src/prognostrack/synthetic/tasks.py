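"""Simulated trunk force tests: MVC trial sequences and endurance holds.

The MVC protocol shows the participant a target 10 % above the previous
trial from the second trial on; the sequence ends when a trial misses that
target or after three trials.  The endurance task is an isometric hold at
30 % +/- 5 % of the just-measured MVC until voluntary failure.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps


def simulate_endurance_and_mvc(
    capacity: float,
    seed: int = 0,
    trace_fs: float = 64.0,
    endurance_mean_s: float = 57.46,
    endurance_sd_s: float = 27.10,
) -> tuple[list[float], float, np.ndarray]:
    """Simulate one participant's MVC trial sequence and endurance hold.

    ``capacity`` is the true maximal force (N).  Returns (mvc_trials,
    endurance_time_s, force_trace): at most three MVC trials, each later
    trial either exceeding 1.1x the previous or ending the sequence, and a
    force trace sampled at ``trace_fs`` held strictly within the
    30 % +/- 5 % band of the recorded MVC for the whole hold.
    """
    if not capacity > 0:
        raise ValueError("capacity must be positive")
    rng = np.random.default_rng(seed)
    # first trial without visual feedback recruits below true capacity;
    # later trials chase the 10 %-above target until capacity caps them
    trials = [capacity * rng.uniform(0.78, 0.88)]
    for _ in range(2):
        attempt = min(capacity, trials[-1] * rng.uniform(1.04, 1.22))
        trials.append(attempt)
        if attempt < 1.1 * trials[-2]:
            break
    mvc = max(trials)
    # weak positive coupling between strength and endurance, floored at 5 s
    endurance_time = float(
        np.clip(
            rng.normal(endurance_mean_s + 0.1 * (capacity - 147.9), endurance_sd_s),
            5.0,
            300.0,
        )
    )
    n = max(int(round(endurance_time * trace_fs)), 8)
    target = 0.30 * mvc
    # smooth wander, normalized so the trace never leaves the +/-5 % band
    raw = rng.standard_normal(n + 64)
    b, a = sps.butter(2, 0.5 / (trace_fs / 2.0))
    wander = sps.filtfilt(b, a, raw)[32 : 32 + n]
    peak = np.max(np.abs(wander))
    if peak > 0:
        wander = wander / peak
    trace = target + 0.045 * mvc * wander
    return [float(f) for f in trials], endurance_time, trace
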