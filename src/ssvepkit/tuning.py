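"""Log-parabola spatial-frequency tuning: fitting and resampling inference.

The tuning model is a parabola in log2 spatial frequency,

    S(f) = G_max - 10*log10(2) * ( 2*(log2 f - log2 F_max) / beta )^2 ,

with F_max the preferred spatial frequency (cpd), G_max the peak SNR (dB)
and beta the full width at half maximum in octaves — "half maximum" meaning
half the *linear* peak gain, i.e. a 10*log10(2) ~ 3.01 dB drop at
f = F_max * 2**(+-beta/2).

Fitting maximizes a Gaussian likelihood with a common residual SD (the
profile-likelihood equivalent of least squares) over a stratified multistart
grid with seeded jitter, plus one data-driven start obtained in closed form:
the model is a quadratic in log2 f, so an unconstrained polynomial fit gives
the exact unbounded optimum whenever its curvature is negative.

Uncertainty and group tests resample *participants* (both eyes of a drawn
participant travel together), matching the dependence structure of
two-eyes-per-participant designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "HALF_MAX_DB",
    "ParameterBounds",
    "TuningFit",
    "BootstrapSE",
    "PermutationResult",
    "log_parabola",
    "fit_tuning",
    "bootstrap_tuning_se",
    "permute_tuning_difference",
]

#: dB drop from the peak at half the linear gain: 10*log10(2).
HALF_MAX_DB: float = 10.0 * math.log10(2.0)

PARAM_NAMES = ("f_max", "g_max", "beta")


def log_parabola(
    f: np.ndarray | float,
    f_max: float,
    g_max: float,
    beta: float,
) -> np.ndarray | float:
    """Evaluate the tuning curve (dB) at spatial frequency ``f`` (cpd)."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("spatial frequency must be positive")
    if f_max <= 0 or beta <= 0:
        raise ValueError("f_max and beta must be positive")
    x = 2.0 * (np.log2(f) - math.log2(f_max)) / beta
    out = g_max - HALF_MAX_DB * x * x
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ParameterBounds:
    """Box constraints for the fit (defaults deliberately wide: fitted peaks
    may fall below the 0.5 cpd stimulus floor in severe degeneration)."""

    f_max: tuple[float, float] = (0.01, 50.0)
    g_max: tuple[float, float] = (-10.0, 40.0)
    beta: tuple[float, float] = (0.05, 20.0)

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")
        if self.f_max[0] <= 0 or self.beta[0] <= 0:
            raise ValueError("f_max and beta lower bounds must be positive")


DEFAULT_BOUNDS = ParameterBounds()


@dataclass
class TuningFit:
    """Fitted log-parabola parameters with fit diagnostics."""

    f_max: float
    g_max: float
    beta: float
    residual_sd: float
    loglik: float
    n_obs: int
    n_starts: int
    n_starts_converged: int
    extrapolated: bool  #: peak outside the sampled spatial-frequency range
    se: dict[str, float] | None = None
    bounds: ParameterBounds = field(default_factory=ParameterBounds)

    def predict(self, f: np.ndarray | float) -> np.ndarray | float:
        return log_parabola(f, self.f_max, self.g_max, self.beta)

    @property
    def params(self) -> dict[str, float]:
        return {"f_max": self.f_max, "g_max": self.g_max, "beta": self.beta}


def _model(p: np.ndarray, x: np.ndarray) -> np.ndarray:
    l, g, b = p
    u = 2.0 * (x - l) / b
    return g - HALF_MAX_DB * u * u


def _residuals(p: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return y - _model(p, x)


def _jacobian(p: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    l, g, b = p
    u = 2.0 * (x - l) / b
    jac = np.empty((len(x), 3))
    jac[:, 0] = -4.0 * HALF_MAX_DB * u / b  # d r / d l
    jac[:, 1] = -1.0  # d r / d g
    jac[:, 2] = -2.0 * HALF_MAX_DB * u * u / b  # d r / d beta
    return jac


def _quadratic_start(x: np.ndarray, y: np.ndarray) -> np.ndarray | None:
    """Closed-form unconstrained optimum via the quadratic reparametrization."""
    if len(np.unique(x)) < 3:
        return None
    a2, a1, a0 = np.polyfit(x, y, 2)
    if a2 >= 0:
        return None
    l = -a1 / (2.0 * a2)
    g = a0 - a1 * a1 / (4.0 * a2)
    b = 2.0 * math.sqrt(-HALF_MAX_DB / a2)
    return np.array([l, g, b])


def _start_grid(
    x: np.ndarray,
    y: np.ndarray,
    bounds: ParameterBounds,
    n_starts: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Stratified grid (log-spaced F_max and beta, data-quantile G_max) + jitter."""
    n_axis = max(1, round(n_starts ** (1.0 / 3.0)))
    l_lo, l_hi = (math.log2(v) for v in bounds.f_max)
    b_lo, b_hi = bounds.beta
    ls = np.linspace(l_lo, l_hi, n_axis + 2)[1:-1]
    gs = np.quantile(y, np.linspace(0.1, 0.9, n_axis))
    bs = np.exp(np.linspace(math.log(b_lo), math.log(b_hi), n_axis + 2)[1:-1])
    starts = []
    for l in ls:
        for g in gs:
            for b in bs:
                jit = rng.uniform(-0.5, 0.5, 3)
                starts.append(
                    np.array(
                        [
                            np.clip(l + jit[0], l_lo, l_hi),
                            np.clip(g + jit[1], *bounds.g_max),
                            np.clip(b * math.exp(0.2 * jit[2]), b_lo, b_hi),
                        ]
                    )
                )
    return starts


def fit_tuning(
    data: pd.DataFrame,
    bounds: ParameterBounds = DEFAULT_BOUNDS,
    n_starts: int = 125,
    seed: int = 0,
    *,
    cpd_col: str = "cpd",
    snr_col: str = "snr_db",
) -> TuningFit:
    """Fit the log parabola to pooled (cpd, SNR) observations of one group.

    ``n_starts`` controls the stratified multistart grid; the closed-form
    quadratic start is always appended, so even ``n_starts=0`` attempts one
    optimization.  With more starts the attained log-likelihood can only
    improve.  Raises if every start fails.
    """
    sf = np.asarray(data[cpd_col], dtype=float)
    y = np.asarray(data[snr_col], dtype=float)
    if np.any(sf <= 0):
        raise ValueError("tuning fits use pattern conditions only (cpd > 0)")
    if len(np.unique(sf)) < 3 or len(y) < 3:
        raise ValueError("need >= 3 observations at >= 3 distinct spatial frequencies")
    x = np.log2(sf)

    rng = np.random.default_rng(seed)
    starts = _start_grid(x, y, bounds, n_starts, rng) if n_starts > 0 else []
    q = _quadratic_start(x, y)
    if q is not None:
        lo = np.array([math.log2(bounds.f_max[0]), bounds.g_max[0], bounds.beta[0]])
        hi = np.array([math.log2(bounds.f_max[1]), bounds.g_max[1], bounds.beta[1]])
        starts.append(np.clip(q, lo, hi))
    if not starts:
        starts.append(
            np.array([np.median(x), float(np.max(y)), (bounds.beta[0] + bounds.beta[1]) / 2.0])
        )

    lb = np.array([math.log2(bounds.f_max[0]), bounds.g_max[0], bounds.beta[0]])
    ub = np.array([math.log2(bounds.f_max[1]), bounds.g_max[1], bounds.beta[1]])
    best = None
    best_cost = np.inf
    n_conv = 0
    errors: list[str] = []
    for x0 in starts:
        try:
            res = least_squares(
                _residuals,
                x0,
                jac=_jacobian,
                bounds=(lb, ub),
                method="trf",
                args=(x, y),
                x_scale=[1.0, 5.0, 1.0],
            )
        except Exception as exc:  # pragma: no cover - optimizer hard failure
            errors.append(str(exc))
            continue
        if res.success:
            n_conv += 1
        if res.cost < best_cost:
            best_cost = res.cost
            best = res
    if best is None:
        raise RuntimeError(f"all {len(starts)} starts failed to converge: {errors[:3]}")

    l, g, b = best.x
    n = len(y)
    sse = 2.0 * best.cost
    sigma2 = max(sse / n, np.finfo(float).tiny)
    loglik = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    f_max = 2.0**l
    return TuningFit(
        f_max=float(f_max),
        g_max=float(g),
        beta=float(b),
        residual_sd=float(math.sqrt(sigma2)),
        loglik=float(loglik),
        n_obs=n,
        n_starts=len(starts),
        n_starts_converged=n_conv,
        extrapolated=bool(f_max < sf.min() or f_max > sf.max()),
        bounds=bounds,
    )


def _resample_participants(
    data: pd.DataFrame,
    participant_col: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw participants with replacement; both eyes travel together."""
    ids = data[participant_col].unique()
    drawn = rng.choice(ids, size=len(ids), replace=True)
    by_id = dict(tuple(data.groupby(participant_col, sort=False)))
    return pd.concat([by_id[i] for i in drawn], ignore_index=True)


@dataclass
class BootstrapSE:
    """Participant-bootstrap SEs: the SD of refitted parameter estimates."""

    se: dict[str, float]
    estimates: pd.DataFrame  #: one row of (f_max, g_max, beta) per successful resample
    reps: int
    n_failed: int
    seed: int


def bootstrap_tuning_se(
    data: pd.DataFrame,
    reps: int = 1000,
    seed: int = 0,
    *,
    participant_col: str = "participant",
    n_starts: int = 10,
    bounds: ParameterBounds = DEFAULT_BOUNDS,
    cpd_col: str = "cpd",
    snr_col: str = "snr_db",
) -> BootstrapSE:
    """Participant-level bootstrap of the tuning fit (SE = SD over resamples).

    Failed refits are excluded and counted in ``n_failed``.
    """
    if data[participant_col].nunique() < 2:
        raise ValueError("participant bootstrap needs >= 2 participants")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    fit_seeds = np.random.SeedSequence(seed).generate_state(reps) % (2**31)
    rows = []
    n_failed = 0
    for r in range(reps):
        sample = _resample_participants(data, participant_col, rng)
        try:
            fit = fit_tuning(
                sample, bounds=bounds, n_starts=n_starts, seed=int(fit_seeds[r]),
                cpd_col=cpd_col, snr_col=snr_col,
            )
        except (ValueError, RuntimeError):
            n_failed += 1
            continue
        rows.append(fit.params)
    est = pd.DataFrame(rows, columns=list(PARAM_NAMES))
    if len(est) < 2:
        raise RuntimeError("too few successful bootstrap refits to form an SE")
    se = {name: float(est[name].std(ddof=1)) for name in PARAM_NAMES}
    return BootstrapSE(se=se, estimates=est, reps=reps, n_failed=n_failed, seed=seed)


@dataclass
class PermutationResult:
    """Group-difference permutation test on tuning parameters."""

    observed: dict[str, float]
    null: dict[str, np.ndarray]
    p_value: dict[str, float]
    reps: int
    n_failed: int
    seed: int


def permute_tuning_difference(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    reps: int = 1000,
    seed: int = 0,
    *,
    participant_col: str = "participant",
    n_starts: int = 10,
    bounds: ParameterBounds = DEFAULT_BOUNDS,
    cpd_col: str = "cpd",
    snr_col: str = "snr_db",
) -> PermutationResult:
    """Two-sided permutation test of per-parameter group differences (A - B).

    Participant labels are shuffled between the pooled groups (eyes stay with
    their participant), both groups are refitted per replicate, and
    p = (1 + #{|null| >= |observed|}) / (reps + 1).
    """
    if group_a.empty or group_b.empty:
        raise ValueError("both groups must be non-empty")
    fit_kw = dict(bounds=bounds, n_starts=n_starts, cpd_col=cpd_col, snr_col=snr_col)
    fit_a = fit_tuning(group_a, seed=seed, **fit_kw)
    fit_b = fit_tuning(group_b, seed=seed, **fit_kw)
    observed = {k: fit_a.params[k] - fit_b.params[k] for k in PARAM_NAMES}

    ids_a = list(group_a[participant_col].unique())
    ids_b = list(group_b[participant_col].unique())
    overlap = set(ids_a) & set(ids_b)
    if overlap:
        raise ValueError(f"participants appear in both groups: {sorted(overlap)[:3]}")
    pooled = pd.concat([group_a, group_b], ignore_index=True)
    by_id = dict(tuple(pooled.groupby(participant_col, sort=False)))
    all_ids = np.array(ids_a + ids_b)
    n_a = len(ids_a)

    rng = np.random.default_rng(seed)
    fit_seeds = np.random.SeedSequence(seed + 1).generate_state(2 * reps) % (2**31)
    null = {k: [] for k in PARAM_NAMES}
    n_failed = 0
    for r in range(reps):
        perm = rng.permutation(all_ids)
        da = pd.concat([by_id[i] for i in perm[:n_a]], ignore_index=True)
        db = pd.concat([by_id[i] for i in perm[n_a:]], ignore_index=True)
        try:
            fa = fit_tuning(da, seed=int(fit_seeds[2 * r]), **fit_kw)
            fb = fit_tuning(db, seed=int(fit_seeds[2 * r + 1]), **fit_kw)
        except (ValueError, RuntimeError):
            n_failed += 1
            continue
        for k in PARAM_NAMES:
            null[k].append(fa.params[k] - fb.params[k])

    null_arr = {k: np.asarray(v) for k, v in null.items()}
    n_ok = len(next(iter(null_arr.values())))
    p = {
        k: float((1 + np.sum(np.abs(null_arr[k]) >= abs(observed[k]))) / (n_ok + 1))
        for k in PARAM_NAMES
    }
    return PermutationResult(
        observed=observed, null=null_arr, p_value=p, reps=reps, n_failed=n_failed, seed=seed
    )
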