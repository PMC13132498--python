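"""Shared fixtures: simulated eyes and cohorts at desk-scale sizes.

Simulations run at 256 Hz (15 Hz stays exactly on the 1/3 Hz bin grid for
3-s epochs regardless of sampling rate), which keeps the full suite fast
while exercising the identical code paths as the 2048 Hz default.
"""

from __future__ import annotations

import numpy as np
import pytest

from ssvepkit.pipeline import analyze_recording
from ssvepkit.synth import (
    DEFAULT_SF_GRID,
    EyeGroundTruth,
    make_stim_schedule,
    simulate_recording,
)

FS = 256.0


def make_eye_truth(
    g_max: float = 16.0,
    f_max: float = 4.20,
    beta: float = 0.80,
    flicker_snr: float = 12.0,
    pid: str = "P01",
    eye: str = "OS",
    group: str = "Control",
) -> EyeGroundTruth:
    return EyeGroundTruth(
        participant_id=pid,
        eye=eye,
        group=group,
        f_max=f_max,
        g_max=g_max,
        beta=beta,
        flicker_snr=flicker_snr,
        noise_psd_1hz=30.0,
        noise_alpha=1.0,
        common_noise_psd_1hz=60.0,
    )


def simulate_eye(
    eye_truth: EyeGroundTruth,
    seed: int,
    sf_list=DEFAULT_SF_GRID,
    n_cycles: int = 20,
    fs: float = FS,
):
    """Simulate and fully analyze one eye; returns (EpochSet, SSVEPCurve)."""
    schedule = make_stim_schedule(
        sf_list, n_cycles=n_cycles, eye=eye_truth.eye, seed=seed, sampling_rate=fs
    )
    recording = simulate_recording(schedule, eye_truth, seed=seed + 1_000_003)
    return analyze_recording(recording)


def simulate_cohort_epochs(
    n_participants: int,
    seed: int,
    *,
    gains: tuple[tuple[float, float, float, float], ...] = (
        (4.20, 16.0, 0.80, 12.0),  # control-like
        (0.68, 8.67, 1.71, 10.0),  # macular dystrophy-like
        (0.08, 3.26, 4.43, 8.0),  # generalized degeneration-like
    ),
    sf_list=DEFAULT_SF_GRID,
    n_cycles: int = 20,
):
    """Two eyes per participant, tuning cycled over the given group profiles."""
    rng = np.random.default_rng(seed)
    epoch_sets = {}
    for p in range(n_participants):
        f_max, g_max, beta, flick = gains[p % len(gains)]
        u = rng.normal(0.0, 1.5)
        for eye in ("OS", "OD"):
            et = make_eye_truth(
                g_max=g_max + u + rng.normal(0.0, 1.0),
                f_max=f_max,
                beta=beta,
                flicker_snr=flick,
                pid=f"P{p:02d}",
                eye=eye,
            )
            es, _ = simulate_eye(et, seed=seed + 17 * p + (eye == "OD"), sf_list=sf_list, n_cycles=n_cycles)
            epoch_sets[(et.participant_id, eye)] = es
    return epoch_sets


@pytest.fixture(scope="session")
def signal_cohort_epochs():
    """15 participants / 30 eyes spanning the three tuning profiles."""
    return simulate_cohort_epochs(15, seed=11)


@pytest.fixture(scope="session")
def noise_cohort_factory():
    """Factory for cohorts with zero response amplitude everywhere."""

    def build(seed: int, n_participants: int = 15):
        silent = ((4.20, -99.0, 0.80, -99.0),)
        return simulate_cohort_epochs(n_participants, seed=seed, gains=silent)

    return build
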