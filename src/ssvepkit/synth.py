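"""Synthetic ssVEP study generator.

Produces the three ingredients of a steady-state visual evoked potential
(ssVEP) spatial-frequency experiment with known ground truth:

* stimulus schedules — cycles of contrast-reversing gratings presented in
  ascending spatial frequency with a full-screen flicker (0 cpd) closing each
  cycle, 20 cycles per eye split into two runs;
* cohort tables — two correlated eyes per participant, three groups
  (sighted controls, macular dystrophy, generalized retinal degeneration)
  whose group-level tuning follows a log parabola, with visual acuity linked
  to each eye's response gain;
* continuous 3-channel occipital EEG (Oz, O1, O2) in which every stimulation
  segment carries a phase-locked sinusoid at the reversal rate embedded in
  1/f background noise, calibrated through a closed-form SNR oracle so the
  downstream spectral pipeline recovers a chosen target SNR.

Every function is a pure function of its arguments and an explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_SF_GRID",
    "DEFAULT_GROUP_TUNING",
    "StimCondition",
    "StimEvent",
    "StimSchedule",
    "GroundTruth",
    "EyeGroundTruth",
    "AcuityLink",
    "ContinuousRecording",
    "make_stim_schedule",
    "sample_cohort",
    "simulate_recording",
    "expected_snr_oracle",
    "amplitude_for_snr",
    "one_over_f_noise",
]

#: Seven log-spaced grating spatial frequencies, 0.5–13.33 cycles/degree.
DEFAULT_SF_GRID: tuple[float, ...] = (0.50, 0.86, 1.49, 2.58, 4.47, 7.72, 13.33)

#: Group-level log-parabola tuning (f_max cpd, g_max dB, beta octaves).
DEFAULT_GROUP_TUNING: dict[str, tuple[float, float, float]] = {
    "Control": (4.20, 16.0, 0.80),
    "MD": (0.68, 8.67, 1.71),
    "GRD": (0.08, 3.26, 4.43),
}

#: Target SNR (dB) of the full-screen flicker response per group.  Flicker
#: stays measurable even with generalized degeneration, unlike gratings.
DEFAULT_FLICKER_SNR: dict[str, float] = {"Control": 12.0, "MD": 10.0, "GRD": 8.0}


@dataclass(frozen=True)
class StimCondition:
    """One stimulus type: a grating spatial frequency or full-screen flicker.

    ``spatial_frequency`` is in cycles per degree; 0 denotes spatially
    uniform flicker.  ``duration * reversal_rate`` must be an integer so the
    response frequency falls exactly on a PSD bin centre.
    """

    spatial_frequency: float
    reversal_rate: float = 15.0
    duration: float = 3.0

    def __post_init__(self) -> None:
        if self.spatial_frequency < 0:
            raise ValueError("spatial_frequency must be >= 0")
        if self.reversal_rate <= 0 or self.reversal_rate >= 40.0:
            raise ValueError("reversal_rate must lie inside the 4-40 Hz analysis band")
        n_rev = self.duration * self.reversal_rate
        if abs(n_rev - round(n_rev)) > 1e-9:
            raise ValueError(
                "duration x reversal_rate must be an integer "
                f"(got {self.duration} s x {self.reversal_rate} Hz = {n_rev})"
            )

    @property
    def is_flicker(self) -> bool:
        return self.spatial_frequency == 0.0


@dataclass(frozen=True)
class StimEvent:
    onset_sample: int
    condition: StimCondition
    cycle: int
    run: int
    eye: str


@dataclass(frozen=True)
class StimSchedule:
    """Ordered, non-overlapping stimulation events for one tested eye."""

    events: tuple[StimEvent, ...]
    sampling_rate: float = 2048.0

    def __post_init__(self) -> None:
        last_end = -1
        for ev in self.events:
            if ev.onset_sample <= last_end:
                raise ValueError("schedule events must be sorted and non-overlapping")
            last_end = ev.onset_sample + int(round(ev.condition.duration * self.sampling_rate)) - 1

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def conditions(self) -> tuple[StimCondition, ...]:
        """Distinct conditions in presentation order within a cycle."""
        seen: dict[StimCondition, None] = {}
        for ev in self.events:
            seen.setdefault(ev.condition, None)
        return tuple(seen)

    def n_epochs_per_condition(self, condition: StimCondition) -> int:
        return sum(ev.condition == condition for ev in self.events)

    @property
    def end_sample(self) -> int:
        ev = self.events[-1]
        return ev.onset_sample + int(round(ev.condition.duration * self.sampling_rate))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_sample": [ev.onset_sample for ev in self.events],
                "cpd": [ev.condition.spatial_frequency for ev in self.events],
                "reversal_rate": [ev.condition.reversal_rate for ev in self.events],
                "duration": [ev.condition.duration for ev in self.events],
                "cycle": [ev.cycle for ev in self.events],
                "run": [ev.run for ev in self.events],
                "eye": [ev.eye for ev in self.events],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sampling_rate: float) -> "StimSchedule":
        events = tuple(
            StimEvent(
                onset_sample=int(r.onset_sample),
                condition=StimCondition(float(r.cpd), float(r.reversal_rate), float(r.duration)),
                cycle=int(r.cycle),
                run=int(r.run),
                eye=str(r.eye),
            )
            for r in df.itertuples()
        )
        return cls(events=events, sampling_rate=float(sampling_rate))


def make_stim_schedule(
    sf_list: Sequence[float] = DEFAULT_SF_GRID,
    n_cycles: int = 20,
    jitter_range: tuple[float, float] = (3.0, 5.0),
    eye: str = "OS",
    seed: int = 0,
    *,
    sampling_rate: float = 2048.0,
    reversal_rate: float = 15.0,
    duration: float = 3.0,
    include_flicker: bool = True,
    lead_in: float = 1.0,
) -> StimSchedule:
    """Build a jittered stimulation schedule for one eye.

    Each cycle presents ``sf_list`` in ascending order followed by the
    full-screen flicker, with inter-stimulus gaps drawn uniformly from
    ``jitter_range`` seconds.  Cycles 1..n/2 are labelled run 1, the rest
    run 2.
    """
    sf = [float(s) for s in sf_list]
    if not sf:
        raise ValueError("sf_list must be non-empty")
    if any(s <= 0 for s in sf):
        raise ValueError("sf_list must contain positive spatial frequencies; flicker is appended automatically")
    if any(b <= a for a, b in zip(sf, sf[1:])):
        raise ValueError("sf_list must be strictly ascending")
    lo, hi = jitter_range
    if not (3.0 <= lo <= hi <= 5.0):
        raise ValueError("jitter_range must lie within [3, 5] seconds")
    if n_cycles < 1 or n_cycles % 2:
        raise ValueError("n_cycles must be a positive even number (two equal runs)")

    conds = [StimCondition(s, reversal_rate, duration) for s in sf]
    if include_flicker:
        conds.append(StimCondition(0.0, reversal_rate, duration))

    rng = np.random.default_rng(seed)
    events: list[StimEvent] = []
    t = lead_in
    half = n_cycles // 2
    for cycle in range(1, n_cycles + 1):
        run = 1 if cycle <= half else 2
        for cond in conds:
            events.append(
                StimEvent(
                    onset_sample=int(round(t * sampling_rate)),
                    condition=cond,
                    cycle=cycle,
                    run=run,
                    eye=eye,
                )
            )
            t += cond.duration + rng.uniform(lo, hi)
    return StimSchedule(events=tuple(events), sampling_rate=sampling_rate)


@dataclass(frozen=True)
class GroundTruth:
    """Group-level generative parameters of the synthetic study.

    Tuning is a log parabola per group (dB SNR vs cpd); eye-level gains add
    participant and eye random effects (dB) to the group ``g_max``.  Noise is
    1/f^alpha with one-sided spectral density ``noise_psd_1hz / f**alpha``
    (uV^2/Hz) per channel, plus a common component cancelled by the
    O1/O2 Laplacian reference.  ``harmonics`` are relative amplitudes of
    response components at multiples of the reversal rate beyond the first.
    """

    group_tuning: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_TUNING)
    )
    flicker_snr: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FLICKER_SNR))
    participant_gain_sd: float = 1.5
    eye_gain_sd: float = 1.0
    noise_psd_1hz: float = 30.0
    noise_alpha: float = 1.0
    common_noise_psd_1hz: float = 60.0
    harmonics: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        for g, (f_max, _g_max, beta) in self.group_tuning.items():
            if f_max <= 0 or beta <= 0:
                raise ValueError(f"group {g!r}: f_max and beta must be positive")
        if self.noise_psd_1hz <= 0:
            raise ValueError("noise_psd_1hz must be positive")
        if self.participant_gain_sd < 0 or self.eye_gain_sd < 0:
            raise ValueError("random-effect SDs must be non-negative")


@dataclass(frozen=True)
class EyeGroundTruth:
    """Generative parameters for a single tested eye."""

    participant_id: str
    eye: str
    group: str
    f_max: float
    g_max: float
    beta: float
    flicker_snr: float
    noise_psd_1hz: float
    noise_alpha: float
    common_noise_psd_1hz: float
    harmonics: tuple[float, ...] = ()

    def tuning_snr(self, cpd: float) -> float:
        """Target SNR (dB) at ``cpd``; the flicker target for 0 cpd."""
        if cpd == 0.0:
            return self.flicker_snr
        # log parabola in log2-frequency, half maximum (-10*log10 2 dB) at
        # f_max * 2**(+-beta/2)
        half_db = 10.0 * math.log10(2.0)
        x = 2.0 * (math.log2(cpd) - math.log2(self.f_max)) / self.beta
        return self.g_max - half_db * x * x


@dataclass(frozen=True)
class AcuityLink:
    """Monotone map from an eye's linear response gain to logMAR acuity.

    ``logmar = intercept - slope * log10(gain)`` plus Gaussian noise, where
    ``gain = 10**(g_max_dB / 20)``.  Values above ``hm_threshold`` /
    ``pl_threshold`` become the categorical entries "HM" / "PL" when
    ``categorical`` is set, mirroring clinical charts that bottom out below
    measurable letter acuity.
    """

    intercept: float = 1.73
    slope: float = 2.15
    noise_sd: float = 0.15
    categorical: bool = True
    hm_threshold: float = 2.1
    pl_threshold: float = 2.5

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("acuity noise SD must be non-negative")


_PHENOTYPES = {"Control": ["Control"], "MD": ["MD"], "GRD": ["LCA/EOSRD", "LCA/EOSRD", "CRD"]}


def sample_cohort(
    n_per_group: int,
    ground_truth: GroundTruth | None = None,
    acuity_link: AcuityLink | None = None,
    seed: int = 0,
    *,
    groups: Sequence[str] = ("Control", "MD", "GRD"),
) -> tuple[pd.DataFrame, dict[tuple[str, str], EyeGroundTruth]]:
    """Draw a balanced cohort with two correlated eyes per participant.

    Returns the eye-level cohort table (participant_id, group, eye,
    acuity_raw, age, disease_duration, phenotype) and a dict mapping
    ``(participant_id, eye)`` to that eye's generative parameters.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    gt = ground_truth if ground_truth is not None else GroundTruth()
    link = acuity_link if acuity_link is not None else AcuityLink()
    rng = np.random.default_rng(seed)

    rows = []
    eye_truth: dict[tuple[str, str], EyeGroundTruth] = {}
    for group in groups:
        f_max, g_max, beta = gt.group_tuning[group]
        phenotypes = _PHENOTYPES.get(group, [group])
        for i in range(n_per_group):
            pid = f"{group[0]}{i + 1:02d}"
            phenotype = phenotypes[i % len(phenotypes)]
            if group == "Control":
                age = rng.uniform(21.0, 54.0)
                duration = np.nan
            else:
                age = rng.uniform(15.0, 58.0)
                duration = min(rng.uniform(3.0, 49.0), age - 0.1)
            u_p = rng.normal(0.0, gt.participant_gain_sd)
            for eye in ("OS", "OD"):
                g_eye = g_max + u_p + rng.normal(0.0, gt.eye_gain_sd)
                logmar = link.intercept - link.slope * (g_eye / 20.0)
                if link.noise_sd > 0:
                    logmar += rng.normal(0.0, link.noise_sd)
                logmar = float(np.clip(logmar, -0.3, 2.7))
                acuity_raw: object = logmar
                if link.categorical and logmar >= link.pl_threshold:
                    acuity_raw = "PL"
                elif link.categorical and logmar >= link.hm_threshold:
                    acuity_raw = "HM"
                rows.append(
                    {
                        "participant_id": pid,
                        "group": group,
                        "eye": eye,
                        "acuity_raw": acuity_raw,
                        "age": round(age, 1),
                        "disease_duration": round(duration, 1) if np.isfinite(duration) else np.nan,
                        "phenotype": phenotype,
                    }
                )
                eye_truth[(pid, eye)] = EyeGroundTruth(
                    participant_id=pid,
                    eye=eye,
                    group=group,
                    f_max=f_max,
                    g_max=g_eye,
                    beta=beta,
                    flicker_snr=gt.flicker_snr.get(group, 10.0),
                    noise_psd_1hz=gt.noise_psd_1hz,
                    noise_alpha=gt.noise_alpha,
                    common_noise_psd_1hz=gt.common_noise_psd_1hz,
                    harmonics=gt.harmonics,
                )
    return pd.DataFrame(rows), eye_truth


@dataclass
class ContinuousRecording:
    """Multi-channel continuous EEG (uV) with its stimulation schedule."""

    channels: dict[str, np.ndarray]
    sampling_rate: float
    events: StimSchedule

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError("all channels must have equal length")
        if self.events.sampling_rate != self.sampling_rate:
            raise ValueError("schedule sampling rate differs from recording sampling rate")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))


def one_over_f_noise(
    n_samples: int,
    sampling_rate: float,
    psd_1hz: float,
    alpha: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Gaussian noise with one-sided spectral density ``psd_1hz / f**alpha``.

    Synthesized in the frequency domain so the expected one-sided periodogram
    power in a bin at frequency f is ``psd_1hz / f**alpha * df``.
    """
    if psd_1hz <= 0:
        raise ValueError("psd_1hz must be positive")
    rng = np.random.default_rng() if rng is None else rng
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sampling_rate)
    density = np.zeros_like(freqs)
    density[1:] = psd_1hz / freqs[1:] ** alpha
    df = sampling_rate / n_samples
    scale = n_samples * np.sqrt(density * df / 2.0)
    z = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    return np.fft.irfft(scale * z / np.sqrt(2.0), n_samples)


def expected_snr_oracle(
    signal_amplitude: float,
    noise_psd_at_band: float,
    n_averaged_epochs: int,
) -> float:
    """Closed-form expected SNR (dB) of the neighbour-bin statistic.

    For a coherent sinusoid of amplitude A (uV) sitting exactly on a bin
    centre, coherent averaging of n epochs leaves the signal power A^2/2
    untouched while dividing the per-bin noise power by n, so the expected
    bin-power ratio is ``1 + (A^2/2) / (noise/n)``.
    """
    if noise_psd_at_band <= 0:
        raise ValueError("noise_psd_at_band must be positive (zero noise leaves the ratio undefined)")
    if n_averaged_epochs < 1:
        raise ValueError("n_averaged_epochs must be >= 1")
    if signal_amplitude < 0:
        raise ValueError("signal_amplitude must be non-negative")
    signal_power = signal_amplitude**2 / 2.0
    noise_power = noise_psd_at_band / n_averaged_epochs
    return 10.0 * math.log10(1.0 + signal_power / noise_power)


def amplitude_for_snr(
    target_snr_db: float,
    noise_psd_at_band: float,
    n_averaged_epochs: int,
) -> float:
    """Invert :func:`expected_snr_oracle`; targets at/below 0 dB map to 0 uV."""
    if noise_psd_at_band <= 0:
        raise ValueError("noise_psd_at_band must be positive")
    ratio = 10.0 ** (target_snr_db / 10.0) - 1.0
    if ratio <= 0:
        return 0.0
    return math.sqrt(2.0 * ratio * noise_psd_at_band / n_averaged_epochs)


def laplacian_noise_bin_power(eye_truth: EyeGroundTruth, condition: StimCondition) -> float:
    """Expected noise power (uV^2) in one PSD bin of the Laplacian signal.

    Independent per-channel noise contributes 1.5x the single-channel power
    after Oz - (O1 + O2)/2; the common component cancels exactly.
    """
    band = condition.reversal_rate
    density = eye_truth.noise_psd_1hz / band**eye_truth.noise_alpha
    bin_width = 1.0 / condition.duration
    return 1.5 * density * bin_width


def simulate_recording(
    schedule: StimSchedule,
    eye_truth: EyeGroundTruth,
    seed: int = 0,
    *,
    n_samples: int | None = None,
    margin: float = 2.0,
) -> ContinuousRecording:
    """Forward-model a continuous 3-channel recording for one eye.

    During each scheduled segment a sinusoid at the reversal rate is added to
    Oz, with amplitude chosen (via :func:`amplitude_for_snr`) so that the
    full pipeline — Laplacian reference, epoching, coherent averaging over
    the schedule's epochs per condition, periodogram, neighbour-bin SNR —
    recovers the eye's target tuning curve in expectation.  Background is
    independent 1/f noise per channel plus a common component shared by all
    three channels (removed by the Laplacian reference).
    """
    fs = schedule.sampling_rate
    needed = schedule.end_sample + int(round(margin * fs))
    needed = int(math.ceil(needed / fs) * fs)  # whole seconds, eases EDF export
    if n_samples is None:
        n_samples = needed
    if schedule.end_sample > n_samples:
        bad = [ev for ev in schedule.events if ev.onset_sample + int(round(ev.condition.duration * fs)) > n_samples]
        raise ValueError(
            f"{len(bad)} event(s) extend past the recording end "
            f"(first at sample {bad[0].onset_sample})"
        )

    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4)]
    channels: dict[str, np.ndarray] = {}
    for name, rng in zip(("Oz", "O1", "O2"), rngs):
        channels[name] = one_over_f_noise(n_samples, fs, eye_truth.noise_psd_1hz, eye_truth.noise_alpha, rng)
    common = one_over_f_noise(n_samples, fs, eye_truth.common_noise_psd_1hz, eye_truth.noise_alpha, rngs[3])
    for name in channels:
        channels[name] = channels[name] + common

    n_avg = {c: schedule.n_epochs_per_condition(c) for c in schedule.conditions}
    for ev in schedule.events:
        cond = ev.condition
        n_seg = int(round(cond.duration * fs))
        target = eye_truth.tuning_snr(cond.spatial_frequency)
        amp = amplitude_for_snr(target, laplacian_noise_bin_power(eye_truth, cond), n_avg[cond])
        if amp == 0.0:
            continue
        t = np.arange(n_seg) / fs
        wave = amp * np.sin(2.0 * np.pi * cond.reversal_rate * t)
        for k, rel in enumerate(eye_truth.harmonics, start=2):
            if k * cond.reversal_rate < fs / 2:
                wave += amp * rel * np.sin(2.0 * np.pi * k * cond.reversal_rate * t)
        channels["Oz"][ev.onset_sample : ev.onset_sample + n_seg] += wave

    return ContinuousRecording(channels=channels, sampling_rate=fs, events=schedule)
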