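"""Reliability of the ssVEP AUC: segment resampling and split-half retest.

Two complementary views of measurement consistency:

* segment resampling — per eye, draw the original number of epochs per
  condition with replacement, rerun the production averaging -> PSD -> SNR
  -> AUC path, and quantify agreement across resamples with the
  two-way random-effects, single-measurement, absolute-agreement intraclass
  correlation ICC(2,1) (eyes as targets, resample replicates as raters);
* split half — recompute the AUC separately from run 1 and run 2 (10-epoch
  averages each), correlate across eyes, and test for a systematic run
  difference with a sign-flip permutation paired t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Hashable, Mapping

import numpy as np
import pandas as pd
import pingouin as pg

from .preprocess import EpochSet, average_epochs, power_spectrum
from .spectrum import build_ssvep_curve, snr_db

__all__ = [
    "ICCResult",
    "PairedPermResult",
    "SplitHalfResult",
    "resample_segments_auc",
    "icc2_single",
    "split_half_reliability",
    "perm_paired_ttest",
    "auc_from_epochs",
]


def _curve_from_averages(
    averages: Mapping[tuple[str, float], np.ndarray],
    epoch_set: EpochSet,
    n_epochs: Mapping[tuple[str, float], int],
):
    snr_by_sf = {}
    for key, avg in averages.items():
        cond = epoch_set.conditions[key]
        psd = power_spectrum(
            avg,
            epoch_set.sampling_rate,
            check_on_grid=None,
            metadata={"n_epochs_averaged": n_epochs[key]},
        )
        snr_by_sf[key[1]] = snr_db(psd, cond.reversal_rate)
    return build_ssvep_curve(snr_by_sf)


def auc_from_epochs(epoch_set: EpochSet, run: int | None = None) -> float:
    """AUC of one eye's curve through the standard pipeline (optionally one run)."""
    averages = average_epochs(epoch_set, run=run)
    n_epochs = {
        k: int((epoch_set.runs[k] == run).sum()) if run is not None else epoch_set.epochs[k].shape[0]
        for k in averages
    }
    return _curve_from_averages(averages, epoch_set, n_epochs).auc


def resample_segments_auc(
    epoch_sets: Mapping[Hashable, EpochSet],
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap the AUC over stimulation segments, per eye.

    Per replicate and eye, each condition's epochs are drawn with
    replacement keeping the original count, re-averaged, and pushed through
    the production PSD -> SNR -> curve -> AUC path.  Returns an
    (eyes x reps) table, deterministic under ``seed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    eye_ids = list(epoch_sets)
    out = np.empty((len(eye_ids), reps))
    child_seeds = np.random.SeedSequence(seed).spawn(len(eye_ids))
    for i, eye_id in enumerate(eye_ids):
        es = epoch_sets[eye_id]
        if not es.epochs:
            raise ValueError(f"eye {eye_id!r} has no epochs")
        rng = np.random.default_rng(child_seeds[i])
        keys = sorted(es.epochs, key=lambda k: k[1])
        for r in range(reps):
            averages = {}
            n_epochs = {}
            for key in keys:
                arr = es.epochs[key]
                idx = rng.integers(0, arr.shape[0], size=arr.shape[0])
                averages[key] = arr[idx].mean(axis=0)
                n_epochs[key] = arr.shape[0]
            out[i, r] = _curve_from_averages(averages, es, n_epochs).auc
    if eye_ids and all(isinstance(i, tuple) for i in eye_ids):
        index = pd.MultiIndex.from_tuples(eye_ids, names=["participant", "eye"])
    else:
        index = pd.Index(eye_ids, name="eye")
    return pd.DataFrame(out, index=index, columns=range(reps))


@dataclass
class ICCResult:
    icc: float
    ci: tuple[float, float]
    p: float
    n_targets: int
    n_raters: int


def icc2_single(matrix: np.ndarray | pd.DataFrame) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    Rows are targets (eyes), columns raters (resample replicates).  The
    F-based 95% CI and p-value follow the classical two-way ANOVA
    decomposition (as implemented in pingouin).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least a 2 x 2 matrix of targets x raters")
    if not np.all(np.isfinite(m)):
        raise ValueError("missing cells are not supported")
    n, k = m.shape
    long = pd.DataFrame(
        {
            "target": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": m.ravel(),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pingouin warns on degenerate ANOVA cells
        table = pg.intraclass_corr(
            data=long, targets="target", raters="rater", ratings="score"
        )
    typed = table.set_index("Type")
    key = "ICC2" if "ICC2" in typed.index else "ICC(A,1)"  # pingouin renamed the row
    row = typed.loc[key]
    icc = float(row["ICC"])
    if not np.isfinite(icc):
        raise ValueError("degenerate ANOVA: ICC undefined for this matrix")
    ci_col = "CI95%" if "CI95%" in typed.columns else "CI95"
    lo, hi = (float(v) for v in row[ci_col])
    return ICCResult(icc=icc, ci=(lo, hi), p=float(row["pval"]), n_targets=n, n_raters=k)


@dataclass
class PairedPermResult:
    """Sign-flip permutation paired t test with bootstrap CI of the mean diff."""

    mean_diff: float
    se: float
    ci: tuple[float, float]
    p: float
    reps: int
    seed: int


def perm_paired_ttest(
    x: np.ndarray,
    y: np.ndarray,
    reps: int = 10_000,
    seed: int = 0,
) -> PairedPermResult:
    """Permutation paired t test via independent sign flips of the differences.

    Two-sided p = (1 + #{|null mean| >= |observed mean|}) / (reps + 1);
    the SE and 95% CI of the mean difference come from a pair-level
    bootstrap with the same number of replicates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length with n >= 3 pairs")
    d = x - y
    observed = float(d.mean())
    rng = np.random.default_rng(seed)
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return PairedPermResult(mean_diff=0.0, se=0.0, ci=(0.0, 0.0), p=1.0, reps=reps, seed=seed)
    signs = rng.choice([-1.0, 1.0], size=(reps, d.size))
    null = (signs * d).mean(axis=1)
    # tiny slack so sign patterns tying |observed| in exact arithmetic count
    tol = 1e-9 * max(1.0, float(np.abs(d).max()))
    p = float((1 + np.sum(np.abs(null) >= abs(observed) - tol)) / (reps + 1))
    boot_idx = rng.integers(0, d.size, size=(reps, d.size))
    boot_means = d[boot_idx].mean(axis=1)
    se = float(boot_means.std(ddof=1))
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    return PairedPermResult(
        mean_diff=observed, se=se, ci=(float(lo), float(hi)), p=p, reps=reps, seed=seed
    )


@dataclass
class SplitHalfResult:
    """Run-1 vs run-2 test-retest agreement across eyes."""

    auc: pd.DataFrame  #: per-eye auc_run1 / auc_run2
    r: float
    r_p: float
    perm: PairedPermResult


def split_half_reliability(
    epoch_sets: Mapping[Hashable, EpochSet],
    reps: int = 10_000,
    seed: int = 0,
) -> SplitHalfResult:
    """Split-half reliability: the pipeline applied to each run independently.

    Both runs must be present for every eye; the correlation is uncorrected
    (no Spearman-Brown step-up).
    """
    rows = []
    for eye_id, es in epoch_sets.items():
        for key in es.runs:
            present = set(np.unique(es.runs[key]))
            if present != {1, 2}:
                raise ValueError(f"eye {eye_id!r}, condition {key}: runs {sorted(present)} (need both 1 and 2)")
        rows.append(
            {"eye": eye_id, "auc_run1": auc_from_epochs(es, run=1), "auc_run2": auc_from_epochs(es, run=2)}
        )
    table = pd.DataFrame(rows).set_index("eye")
    a1 = table["auc_run1"].to_numpy()
    a2 = table["auc_run2"].to_numpy()
    if np.array_equal(a1, a2):
        r, r_p = 1.0, 0.0  # identical halves: degenerate perfect agreement
    else:
        from .stats import pearson_corr

        r, r_p = pearson_corr(a1, a2)
    perm = perm_paired_ttest(a1, a2, reps=reps, seed=seed)
    return SplitHalfResult(auc=table, r=r, r_p=r_p, perm=perm)
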