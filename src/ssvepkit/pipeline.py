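"""End-to-end orchestration: recordings -> curves -> group inference.

`run_pipeline` drives the whole analysis from a single `PipelineConfig`:
either on a simulated cohort (the default, fully self-contained) or on a
manifest of recorded EDF/BDF files.  Each stage reuses the public module
functions, every random draw derives from the config seed, and the results
bundle echoes the full configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .preprocess import (
    EpochSet,
    average_epochs,
    bandpass_filter,
    extract_epochs,
    laplacian_reference,
    power_spectrum,
)
from .reliability import icc2_single, resample_segments_auc, split_half_reliability
from .spectrum import SSVEPCurve, build_ssvep_curve, snr_db
from .stats import (
    acuity_to_logmar,
    cohort_descriptives,
    fit_association_lmm,
    fit_group_lmm,
    monte_carlo_perm_test,
    pairwise_emmeans,
)
from .synth import (
    DEFAULT_GROUP_TUNING,
    DEFAULT_SF_GRID,
    AcuityLink,
    ContinuousRecording,
    GroundTruth,
    make_stim_schedule,
    sample_cohort,
    simulate_recording,
)
from .tuning import bootstrap_tuning_se, fit_tuning, permute_tuning_difference

__all__ = ["PipelineConfig", "analyze_recording", "run_pipeline", "save_results"]


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; unknown keys are rejected on load."""

    # simulated-cohort inputs (ignored when a manifest is given)
    n_per_group: int = 6
    sampling_rate: float = 2048.0
    sf_list: tuple[float, ...] = DEFAULT_SF_GRID
    n_cycles: int = 20
    jitter_range: tuple[float, float] = (3.0, 5.0)
    group_tuning: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_TUNING)
    )
    flicker_snr: Mapping[str, float] | None = None
    participant_gain_sd: float = 1.5
    eye_gain_sd: float = 1.0
    noise_psd_1hz: float = 30.0
    noise_alpha: float = 1.0
    common_noise_psd_1hz: float = 60.0
    # file inputs: CSV with columns participant_id, eye, path (plus a cohort CSV)
    manifest: str | None = None
    cohort_csv: str | None = None
    # analysis parameters
    filter_low: float = 4.0
    filter_high: float = 40.0
    reversal_rate: float = 15.0
    duration: float = 3.0
    n_starts: int = 125
    refit_n_starts: int = 10
    bootstrap_reps: int = 200
    tuning_permutation_reps: int = 0  #: 0 disables the (costly) shape permutations
    mc_perm_reps: int = 10_000
    icc_reps: int = 200
    splithalf_perm_reps: int = 10_000
    exclude_categorical_acuity: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("sf_list", "jitter_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "group_tuning" in d:
            d["group_tuning"] = {g: tuple(v) for g, v in d["group_tuning"].items()}
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sf_list"] = list(d["sf_list"])
        d["jitter_range"] = list(d["jitter_range"])
        d["group_tuning"] = {g: list(v) for g, v in d["group_tuning"].items()}
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def ground_truth(self) -> GroundTruth:
        kwargs: dict[str, Any] = dict(
            group_tuning=dict(self.group_tuning),
            participant_gain_sd=self.participant_gain_sd,
            eye_gain_sd=self.eye_gain_sd,
            noise_psd_1hz=self.noise_psd_1hz,
            noise_alpha=self.noise_alpha,
            common_noise_psd_1hz=self.common_noise_psd_1hz,
        )
        if self.flicker_snr is not None:
            kwargs["flicker_snr"] = dict(self.flicker_snr)
        return GroundTruth(**kwargs)


def analyze_recording(
    recording: ContinuousRecording,
    *,
    filter_low: float = 4.0,
    filter_high: float = 40.0,
) -> tuple[EpochSet, SSVEPCurve]:
    """Laplacian -> band-pass -> epochs -> averages -> PSD -> SNR curve for one eye."""
    referenced = laplacian_reference(recording)
    filtered = bandpass_filter(referenced, filter_low, filter_high, recording.sampling_rate)
    epoch_set = extract_epochs(filtered, recording.events)
    averages = average_epochs(epoch_set)
    snr_by_sf = {}
    eye = next(iter(epoch_set.keys()))[0]
    for key, avg in averages.items():
        cond = epoch_set.conditions[key]
        psd = power_spectrum(
            avg,
            recording.sampling_rate,
            check_on_grid=cond.reversal_rate,
            metadata={"n_epochs_averaged": epoch_set.epochs[key].shape[0]},
        )
        snr_by_sf[key[1]] = snr_db(psd, cond.reversal_rate)
    return epoch_set, build_ssvep_curve(snr_by_sf, eye=eye)


def _simulated_recordings(config: PipelineConfig):
    """Yield ((participant_id, eye), recording) for the whole simulated cohort."""
    gt = config.ground_truth()
    cohort, eye_truth = sample_cohort(config.n_per_group, gt, seed=config.seed)
    keys = list(eye_truth)
    seeds = np.random.SeedSequence(config.seed).generate_state(2 * len(keys)) % (2**31)

    def recordings():
        for i, key in enumerate(keys):
            schedule = make_stim_schedule(
                config.sf_list,
                n_cycles=config.n_cycles,
                jitter_range=config.jitter_range,
                eye=key[1],
                seed=int(seeds[2 * i]),
                sampling_rate=config.sampling_rate,
                reversal_rate=config.reversal_rate,
                duration=config.duration,
            )
            yield key, simulate_recording(schedule, eye_truth[key], seed=int(seeds[2 * i + 1]))

    return cohort, recordings


def _file_recordings(config: PipelineConfig):
    from .io import read_cohort_csv, read_recording

    manifest = pd.read_csv(config.manifest, dtype={"participant_id": str, "eye": str})
    cohort = read_cohort_csv(config.cohort_csv) if config.cohort_csv else None

    def recordings():
        for row in manifest.itertuples():
            yield (row.participant_id, row.eye), read_recording(row.path)

    return cohort, recordings


def run_pipeline(config: PipelineConfig, *, keep_epochs: bool = True) -> dict:
    """Execute the full analysis and return a JSON-serializable bundle.

    Stages run in order (preprocess, spectrum, tuning, stats, reliability);
    a stage failure raises with the stage name and the offending eye.  With
    identical config the deterministic stages reproduce bit-for-bit.
    """
    cohort, recordings = (
        _file_recordings(config) if config.manifest else _simulated_recordings(config)
    )

    curve_rows = []
    auc_rows = []
    epoch_sets = {}
    meta = (
        cohort.set_index(["participant_id", "eye"]).to_dict("index") if cohort is not None else {}
    )
    for key, recording in recordings():
        try:
            epoch_set, curve = analyze_recording(
                recording, filter_low=config.filter_low, filter_high=config.filter_high
            )
        except Exception as exc:
            raise RuntimeError(f"preprocess/spectrum failed for eye {key}: {exc}") from exc
        group = meta.get(key, {}).get("group", "unknown")
        pid, eye = key
        for sf, s in zip(curve.spatial_frequencies, curve.snr):
            curve_rows.append(
                {"participant_id": pid, "group": group, "eye": eye, "cpd": float(sf), "snr_db": float(s)}
            )
        auc_rows.append(
            {
                "participant_id": pid,
                "group": group,
                "eye": eye,
                "auc": curve.auc,
                "flicker_snr": curve.flicker_snr,
                "below_noise_fraction": curve.below_noise_fraction,
            }
        )
        if keep_epochs:
            epoch_sets[key] = epoch_set
    curves = pd.DataFrame(curve_rows)
    aucs = pd.DataFrame(auc_rows)

    bundle: dict[str, Any] = {
        "provenance": {
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": config.config_hash,
            "seed": config.seed,
        },
        "warnings": [],
        "curves": curves,
        "aucs": aucs,
    }

    # ---- tuning fits per group -------------------------------------------
    tuning_block: dict[str, Any] = {}
    groups = sorted(g for g in curves["group"].unique() if g != "unknown")
    fit_df = curves.rename(columns={"participant_id": "participant"})
    for g in groups:
        sub = fit_df[fit_df["group"] == g]
        fit = fit_tuning(sub, n_starts=config.n_starts, seed=config.seed)
        entry = {
            "f_max": fit.f_max,
            "g_max": fit.g_max,
            "beta": fit.beta,
            "residual_sd": fit.residual_sd,
            "loglik": fit.loglik,
            "n_starts_converged": fit.n_starts_converged,
            "extrapolated": fit.extrapolated,
        }
        if config.bootstrap_reps > 0 and sub["participant"].nunique() >= 2:
            boot = bootstrap_tuning_se(
                sub,
                reps=config.bootstrap_reps,
                seed=config.seed,
                n_starts=config.refit_n_starts,
            )
            entry["bootstrap_se"] = boot.se
            entry["bootstrap_failed"] = boot.n_failed
        tuning_block[g] = entry
    if config.tuning_permutation_reps > 0:
        perms = {}
        for i, ga in enumerate(groups):
            for gb in groups[i + 1 :]:
                res = permute_tuning_difference(
                    fit_df[fit_df["group"] == ga],
                    fit_df[fit_df["group"] == gb],
                    reps=config.tuning_permutation_reps,
                    seed=config.seed,
                    n_starts=config.refit_n_starts,
                )
                perms[f"{ga} vs {gb}"] = {
                    "observed": res.observed,
                    "p_value": res.p_value,
                    "n_failed": res.n_failed,
                }
        tuning_block["permutations"] = perms
    bundle["tuning"] = tuning_block

    # ---- group statistics on the AUC -------------------------------------
    if cohort is not None and len(groups) >= 2:
        logmar, converted = acuity_to_logmar(cohort["acuity_raw"])
        cohort = cohort.assign(acuity_logmar=logmar, acuity_converted=converted)
        bundle["descriptives"] = cohort_descriptives(cohort)
        eyes = aucs.merge(
            cohort[["participant_id", "eye", "acuity_logmar", "acuity_converted", "age"]],
            on=["participant_id", "eye"],
        )
        if config.exclude_categorical_acuity:
            eyes = eyes[~eyes["acuity_converted"]]
        omnibus = fit_group_lmm(eyes)
        contrasts = pairwise_emmeans(omnibus)
        perm_p = {}
        for i, ga in enumerate(groups):
            for gb in groups[i + 1 :]:
                pair = eyes[eyes["group"].isin([ga, gb])]
                res = monte_carlo_perm_test(
                    pair["auc"].to_numpy(),
                    pair["group"].to_numpy(),
                    pair["participant_id"].to_numpy(),
                    reps=config.mc_perm_reps,
                    seed=config.seed,
                )
                perm_p[f"{ga} vs {gb}"] = {"observed_diff": res.observed_diff, "p": res.p}
        acuity_assoc = fit_association_lmm(
            eyes, response_col="acuity_logmar", predictor_col="auc"
        )
        controls = eyes[eyes["group"] == "Control"]
        age_assoc = (
            fit_association_lmm(controls, response_col="auc", predictor_col="age")
            if len(controls) >= 4
            else None
        )
        bundle["group_comparison"] = {
            "F": omnibus.F,
            "df_num": omnibus.df_num,
            "df_den": omnibus.df_den,
            "p": omnibus.p,
            "partial_eta_sq": omnibus.partial_eta_sq,
            "r2_marginal": omnibus.r2_marginal,
            "emmeans": omnibus.emmeans,
            "singular": omnibus.singular,
            "contrasts": contrasts,
            "permutation": perm_p,
        }
        bundle["associations"] = {
            "acuity_vs_auc": dataclasses.asdict(acuity_assoc),
            "auc_vs_age_controls": dataclasses.asdict(age_assoc) if age_assoc else None,
        }

    # ---- reliability ------------------------------------------------------
    if keep_epochs and epoch_sets:
        auc_matrix = resample_segments_auc(epoch_sets, reps=config.icc_reps, seed=config.seed)
        icc = icc2_single(auc_matrix.to_numpy())
        split = split_half_reliability(
            epoch_sets, reps=config.splithalf_perm_reps, seed=config.seed
        )
        bundle["reliability"] = {
            "icc": icc.icc,
            "icc_ci": list(icc.ci),
            "icc_p": icc.p,
            "split_half_r": split.r,
            "split_half_r_p": split.r_p,
            "perm_mean_diff": split.perm.mean_diff,
            "perm_se": split.perm.se,
            "perm_ci": list(split.perm.ci),
            "perm_p": split.perm.p,
        }
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict("records")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def save_results(bundle: dict, out_dir: str | Path) -> Path:
    """Write results.json plus tidy CSV side tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("curves", "aucs"):
        if name in bundle:
            bundle[name].to_csv(out / f"{name}.csv", index=False)
    gc = bundle.get("group_comparison")
    if gc is not None and isinstance(gc.get("contrasts"), pd.DataFrame):
        gc["contrasts"].to_csv(out / "contrasts.csv", index=False)
    slim = {k: v for k, v in bundle.items() if k not in ("curves", "aucs")}
    if "descriptives" in slim:
        slim["descriptives"] = slim["descriptives"].reset_index()
    with open(out / "results.json", "w") as fh:
        json.dump(_jsonable(slim), fh, indent=2)
    return out / "results.json"
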