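"""Cohort descriptives, mixed-model group comparisons and validity analyses.

Groups are compared on the per-eye AUC with a linear mixed model: group as a
fixed effect and a random intercept per participant, because the two eyes of
one participant are not independent observations.  The omnibus test is a
type III F with Satterthwaite denominator df; post hoc contrasts compare
estimated marginal means with Bonferroni-Holm correction.  Robustness
replications use Monte-Carlo permutation tests that shuffle *participants*
(both eyes travel together).

Categorical visual-acuity entries follow the clinical convention
hand movements (HM) = 2.3 logMAR, perception of light (PL) = 2.7 logMAR;
converted entries are flagged so analyses can be rerun without them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from ._lmm import LMMFit, RandomInterceptLMM

__all__ = [
    "HM_LOGMAR",
    "PL_LOGMAR",
    "GroupComparisonResult",
    "AssociationResult",
    "PermTestResult",
    "acuity_to_logmar",
    "cohort_descriptives",
    "fit_group_lmm",
    "pairwise_emmeans",
    "monte_carlo_perm_test",
    "holm_adjust",
    "pearson_corr",
    "fit_association_lmm",
]

HM_LOGMAR = 2.3
PL_LOGMAR = 2.7
_CATEGORICAL = {"HM": HM_LOGMAR, "PL": PL_LOGMAR}


def acuity_to_logmar(raw):
    """Convert raw acuity entries to numeric logMAR.

    Numeric values pass through; "HM" -> 2.3 and "PL" -> 2.7 (case
    insensitive); missing values propagate.  For scalar input returns
    ``(logmar, was_converted)``; for array-like input returns a
    ``(values, converted)`` pair of aligned arrays, where ``converted``
    flags the categorical entries for sensitivity reruns.
    """

    def _one(v):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return np.nan, False
        if isinstance(v, str):
            key = v.strip().upper()
            if key in _CATEGORICAL:
                return _CATEGORICAL[key], True
            try:
                return float(v), False
            except ValueError:
                raise ValueError(f"unrecognized acuity category: {v!r}") from None
        return float(v), False

    if np.isscalar(raw) or raw is None:
        return _one(raw)
    pairs = [_one(v) for v in raw]
    values = np.array([p[0] for p in pairs], dtype=float)
    converted = np.array([p[1] for p in pairs], dtype=bool)
    if isinstance(raw, pd.Series):
        return pd.Series(values, index=raw.index), pd.Series(converted, index=raw.index)
    return values, converted


def cohort_descriptives(
    cohort: pd.DataFrame,
    *,
    group_col: str = "group",
    participant_col: str = "participant_id",
    acuity_col: str = "acuity_logmar",
    extra_participant_cols: tuple[str, ...] = ("age", "disease_duration"),
) -> pd.DataFrame:
    """Mean and sample SD (n-1) per group and overall.

    Acuity is summarized over eye-level rows; age and disease duration over
    participant-level rows (one row per participant).  ``cohort`` must
    already carry numeric acuity (see :func:`acuity_to_logmar`).
    """
    if cohort.empty:
        raise ValueError("empty cohort table")
    rows = {}
    labels = list(dict.fromkeys(cohort[group_col]))
    for label in labels + ["All"]:
        sub = cohort if label == "All" else cohort[cohort[group_col] == label]
        if sub.empty:
            raise ValueError(f"empty group: {label!r}")
        row = {
            "n_eyes": len(sub),
            "n_participants": sub[participant_col].nunique(),
            "acuity_mean": sub[acuity_col].mean(),
            "acuity_sd": sub[acuity_col].std(ddof=1),
        }
        per_part = sub.drop_duplicates(participant_col)
        for col in extra_participant_cols:
            if col in sub.columns:
                row[f"{col}_mean"] = per_part[col].mean()
                row[f"{col}_sd"] = per_part[col].std(ddof=1)
        rows[label] = row
    out = pd.DataFrame(rows).T
    out.index.name = group_col
    return out


# --------------------------------------------------------------------------
# mixed-model group comparison


@dataclass
class GroupComparisonResult:
    """Omnibus group test on a per-eye outcome with participant random intercepts."""

    F: float
    df_num: float
    df_den: float
    p: float
    partial_eta_sq: float
    r2_marginal: float
    groups: list[str]
    emmeans: dict[str, float]
    tau2: float
    sigma2: float
    singular: bool
    contrasts: pd.DataFrame | None = None
    _model: RandomInterceptLMM = field(repr=False, default=None)
    _coef_index: dict[str, int] = field(repr=False, default_factory=dict)


def _group_design(groups: pd.Series) -> tuple[np.ndarray, list[str], dict[str, int]]:
    """Treatment-coded design: intercept + one dummy per non-reference group."""
    labels = sorted(pd.unique(groups))
    ref = "Control" if "Control" in labels else labels[0]
    others = [g for g in labels if g != ref]
    X = np.ones((len(groups), 1 + len(others)))
    coef_index = {ref: -1}
    for j, g in enumerate(others, start=1):
        X[:, j] = (groups == g).to_numpy(dtype=float)
        coef_index[g] = j
    return X, [ref] + others, coef_index


def fit_group_lmm(
    data: pd.DataFrame,
    *,
    response_col: str = "auc",
    group_col: str = "group",
    participant_col: str = "participant_id",
) -> GroupComparisonResult:
    """REML fit of ``response ~ group + (1 | participant)`` with type III F.

    ``partial_eta_sq`` derives from the F statistic and its dfs;
    ``r2_marginal`` is the fixed-effect variance over the total
    (fixed + random-intercept + residual) variance.  A singular fit
    (tau^2 on the zero boundary) is reported, not fatal.
    """
    if data[group_col].nunique() < 2:
        raise ValueError("need at least two groups")
    mixed = data.groupby(participant_col)[group_col].nunique()
    if (mixed > 1).any():
        raise ValueError("group must be constant within participant")
    y = data[response_col].to_numpy(dtype=float)
    X, labels, coef_index = _group_design(data[group_col])
    model = RandomInterceptLMM(y, X, data[participant_col].to_numpy())
    fit = model.fit()

    k = X.shape[1]
    L = np.zeros((k - 1, k))
    for i in range(1, k):
        L[i - 1, i] = 1.0
    F, df_num, df_den, p = model.ftest(L)

    fitted_fixed = X @ fit.beta
    var_fixed = float(np.var(fitted_fixed, ddof=1))
    r2_marginal = var_fixed / (var_fixed + fit.tau2 + fit.sigma2)
    emmeans = {
        g: float(fit.beta[0] + (fit.beta[j] if j >= 0 else 0.0))
        for g, j in coef_index.items()
    }
    return GroupComparisonResult(
        F=F,
        df_num=df_num,
        df_den=df_den,
        p=p,
        partial_eta_sq=F * df_num / (F * df_num + df_den),
        r2_marginal=r2_marginal,
        groups=labels,
        emmeans={g: emmeans[g] for g in labels},
        tau2=fit.tau2,
        sigma2=fit.sigma2,
        singular=fit.singular,
        _model=model,
        _coef_index=coef_index,
    )


def pairwise_emmeans(result: GroupComparisonResult) -> pd.DataFrame:
    """All pairwise estimated-marginal-mean contrasts, Holm-adjusted.

    With a single categorical fixed effect the EMMs are the model-implied
    group means; contrast SEs and Satterthwaite dfs come from the fitted
    covariance.  The returned table is also attached to ``result.contrasts``.
    """
    if len(result.groups) < 2:
        raise ValueError("need at least two groups for contrasts")
    model = result._model
    fit = model.fit_
    k = fit.beta.shape[0]
    rows = []
    for ga, gb in itertools.combinations(result.groups, 2):
        c = np.zeros(k)
        ja, jb = result._coef_index[ga], result._coef_index[gb]
        if ja >= 0:
            c[ja] += 1.0
        if jb >= 0:
            c[jb] -= 1.0
        est = float(c @ fit.beta)
        se = float(np.sqrt(c @ fit.cov_beta @ c))
        df = model.satterthwaite_df(c)
        t = est / se
        p_raw = float(2.0 * sstats.t.sf(abs(t), df))
        rows.append({"pair": f"{ga} - {gb}", "estimate": est, "se": se, "df": df, "t": t, "p_raw": p_raw})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = holm_adjust(table["p_raw"].to_numpy())
    result.contrasts = table
    return table


# --------------------------------------------------------------------------
# permutation and classical helpers


@dataclass
class PermTestResult:
    observed_diff: float
    p: float
    reps: int
    seed: int


def monte_carlo_perm_test(
    values: np.ndarray,
    labels: np.ndarray,
    participants: np.ndarray,
    reps: int = 100_000,
    seed: int = 0,
) -> PermTestResult:
    """Monte-Carlo permutation test of a two-group difference in means.

    The statistic is the difference of eye-level group means; shuffling
    happens at the participant level so eyes never separate.  Two-sided
    p = (1 + #{|null| >= |observed|}) / (reps + 1).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    participants = np.asarray(participants)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {list(uniq)}")
    pids, codes = np.unique(participants, return_inverse=True)
    sums = np.bincount(codes, weights=values, minlength=len(pids))
    counts = np.bincount(codes, minlength=len(pids)).astype(float)
    p_label = np.empty(len(pids), dtype=object)
    p_label[codes] = labels  # group constant within participant
    is_a = p_label == uniq[0]
    n_a = int(is_a.sum())
    if n_a == 0 or n_a == len(pids):
        raise ValueError("one group is empty at the participant level")

    def stat(mask_a):
        sa, ca = sums[mask_a].sum(), counts[mask_a].sum()
        sb, cb = sums.sum() - sa, counts.sum() - ca
        return sa / ca - sb / cb

    observed = stat(is_a)
    rng = np.random.default_rng(seed)
    n_part = len(pids)
    null = np.empty(reps)
    block = 20_000  # bound memory for large rep counts
    for start in range(0, reps, block):
        stop = min(start + block, reps)
        keys = rng.random((stop - start, n_part))
        order = np.argsort(keys, axis=1)[:, :n_a]
        sa = sums[order].sum(axis=1)
        ca = counts[order].sum(axis=1)
        null[start:stop] = sa / ca - (sums.sum() - sa) / (counts.sum() - ca)
    # tiny slack so relabelings tying |observed| in exact arithmetic count
    tol = 1e-9 * max(1.0, float(np.abs(values).max()))
    p = float((1 + np.sum(np.abs(null) >= abs(observed) - tol)) / (reps + 1))
    return PermTestResult(observed_diff=float(observed), p=p, reps=reps, seed=seed)


def holm_adjust(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def pearson_corr(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = sstats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class AssociationResult:
    """Slope of ``response ~ predictor + (1 | participant)``."""

    slope: float
    se: float
    df: float
    p: float
    response: str
    predictor: str
    tau2: float
    sigma2: float
    n_obs: int
    n_participants: int


def fit_association_lmm(
    data: pd.DataFrame,
    *,
    response_col: str,
    predictor_col: str,
    participant_col: str = "participant_id",
) -> AssociationResult:
    """REML association between two per-eye variables with paired eyes.

    The acuity-validity analysis regresses logMAR on AUC (slope in logMAR
    per AUC unit); the age-confound analysis regresses AUC on age.  Both are
    this one model with different column choices.
    """
    sub = data[[response_col, predictor_col, participant_col]].dropna()
    x = sub[predictor_col].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"constant predictor: {predictor_col!r}")
    X = np.column_stack([np.ones_like(x), x])
    model = RandomInterceptLMM(sub[response_col].to_numpy(dtype=float), X, sub[participant_col].to_numpy())
    fit = model.fit()
    c = np.array([0.0, 1.0])
    se = float(np.sqrt(max(c @ fit.cov_beta @ c, 0.0)))
    df = model.satterthwaite_df(c)
    t = fit.beta[1] / se if se > 0 else np.inf * np.sign(fit.beta[1])
    return AssociationResult(
        slope=float(fit.beta[1]),
        se=se,
        df=df,
        p=float(2.0 * sstats.t.sf(abs(t), df)),
        response=response_col,
        predictor=predictor_col,
        tau2=fit.tau2,
        sigma2=fit.sigma2,
        n_obs=fit.n_obs,
        n_participants=fit.n_groups,
    )
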