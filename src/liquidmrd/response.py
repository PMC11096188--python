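"""Pathological-complete-response prediction from ctDNA dynamics.

Mutant genomic equivalents (MGE) before and after neoadjuvant chemotherapy
carry the response signal: responders present higher pre-treatment burden and
clear it almost completely, so both the pre-treatment level and the pre/post
change discriminate pCR. The model layer offers two routes to a multivariable
logistic model — a manual route (Cramér's-V screening of discretized
predictors, then inclusion by McFadden pseudo-R² impact) and automated
AIC-based selection (forward, backward, and bidirectional stepwise) — and
scores every candidate by ROC AUC, keeping the best. The chosen model is
checked against chance with DeLong's test, internally validated by
leave-one-out cross-validation on pooled out-of-fold probabilities, and
turned into a classifier at the Youden-optimal probability cutoff.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit
from sklearn.metrics import roc_auc_score

__all__ = [
    "ModelInput",
    "LogisticFit",
    "FittedModel",
    "YoudenResult",
    "DelongResult",
    "cramers_v",
    "fit_logistic",
    "roc_auc",
    "delong_test",
    "delong_pvalue",
    "youden_cutoff",
    "loocv_auc",
    "select_model",
    "build_final_model",
    "mge_fold_change",
    "inputs_to_frame",
]

SELECTION_MODES = ("manual", "forward", "reverse", "stepwise")

#: Minimum Cramér's V for a predictor to survive manual screening.
MANUAL_V_THRESHOLD = 0.1
#: Minimum McFadden pseudo-R² gain for manual inclusion of a predictor.
MANUAL_R2_GAIN = 0.01


@dataclass(frozen=True)
class ModelInput:
    """One patient's MGE levels, optional covariates and pCR outcome."""

    patient_id: str
    mge_pre: float
    mge_post: float
    outcome: bool
    covariates: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mge_pre < 0 or self.mge_post < 0:
            raise ValueError("MGE values must be >= 0")

    @property
    def mge_change(self) -> float:
        return self.mge_pre - self.mge_post


def cramers_v(x, y) -> float:
    """Cramér's V between two categorical vectors.

    V = sqrt(chi2 / (n * (min(r, c) - 1))) on the contingency table, with the
    uncorrected chi-squared statistic.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must be equal-length vectors of size >= 2")
    table = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy()
    r, c = table.shape
    if min(r, c) < 2:
        raise ValueError("Cramér's V undefined: a variable has a single level")
    chi2 = stats.chi2_contingency(table, correction=False)[0]
    n = table.sum()
    return float(np.sqrt(chi2 / (n * (min(r, c) - 1))))


@dataclass(frozen=True)
class LogisticFit:
    predictors: tuple[str, ...]
    coefficients: dict[str, float]  # includes "intercept"
    fitted_probs: np.ndarray
    aic: float
    log_likelihood: float
    mcfadden_r2: float
    separation_flag: bool


def _logit_mle(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Maximum-likelihood logistic fit with separation detection.

    Returns (params, fitted probabilities, separation flag). Small cohorts
    make complete separation likely; the fit is then reported with a warning
    flag instead of failing.
    """
    separation = False
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception:
            res = model.fit(disp=0, method="bfgs", maxiter=500)
            separation = True
        probs = np.asarray(res.predict(X), dtype=float)
    if not separation and X.shape[1] > 1:
        pos, neg = probs[y == 1], probs[y == 0]
        if pos.size and neg.size and pos.min() > 1 - 1e-6 and neg.max() < 1e-6:
            separation = True
    return np.asarray(res.params, dtype=float), probs, separation


def fit_logistic(
    data: pd.DataFrame, predictors: list[str], outcome_col: str = "outcome"
) -> LogisticFit:
    """Fit a logistic regression of the outcome on the named predictors."""
    y = data[outcome_col].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    for p in predictors:
        if data[p].nunique() < 2:
            raise ValueError(f"predictor {p!r} is constant")
    X = np.column_stack(
        [np.ones(len(data))] + [data[p].to_numpy(dtype=float) for p in predictors]
    )
    params, probs, separation = _logit_mle(X, y)

    eps = 1e-12
    llf = float(np.sum(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps)))
    p1 = y.mean()
    llnull = float(len(y) * (p1 * np.log(p1 + eps) + (1 - p1) * np.log(1 - p1 + eps)))
    k = len(predictors) + 1
    coef = {"intercept": float(params[0])}
    coef.update({p: float(b) for p, b in zip(predictors, params[1:])})
    return LogisticFit(
        predictors=tuple(predictors),
        coefficients=coef,
        fitted_probs=probs,
        aic=2 * k - 2 * llf,
        log_likelihood=llf,
        mcfadden_r2=1.0 - llf / llnull if llnull != 0 else 0.0,
        separation_flag=separation,
    )


def roc_auc(probabilities, outcomes) -> float:
    """ROC AUC: the concordance probability, ties counted one half."""
    outcomes = np.asarray(outcomes, dtype=int)
    if len(np.unique(outcomes)) < 2:
        raise ValueError("both outcome classes must be present")
    return float(roc_auc_score(outcomes, np.asarray(probabilities, dtype=float)))


@dataclass(frozen=True)
class DelongResult:
    auc: float
    variance: float
    z: float
    p_value: float
    degenerate: bool


def delong_test(probabilities, outcomes) -> DelongResult:
    """DeLong's test of H0: AUC = 0.5 for a single ROC curve.

    Uses the placement-value decomposition: the AUC variance is
    S10/m + S01/n where S10 and S01 are sample variances of the per-case and
    per-control placement values. When the placement variance is zero
    (perfect or fully tied rankings) the boundary p-value is reported with a
    degeneracy flag.
    """
    scores = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    pos, neg = scores[y == 1], scores[y == 0]
    if pos.size < 2 or neg.size < 2:
        raise ValueError("both classes need >= 2 members")
    # psi matrix: 1 if case > control, 0.5 if tied
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)  # placements of cases among controls
    v01 = psi.mean(axis=0)
    var = float(np.var(v10, ddof=1) / pos.size + np.var(v01, ddof=1) / neg.size)
    if var <= 0:
        p = 1.0 if auc == 0.5 else 0.0
        z = 0.0 if auc == 0.5 else np.inf * np.sign(auc - 0.5)
        return DelongResult(auc=auc, variance=var, z=float(z), p_value=p, degenerate=True)
    z = (auc - 0.5) / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return DelongResult(auc=auc, variance=var, z=float(z), p_value=p, degenerate=False)


def delong_pvalue(probabilities, outcomes) -> float:
    """Two-sided DeLong p-value against a random (AUC = 0.5) model."""
    return delong_test(probabilities, outcomes).p_value


@dataclass(frozen=True)
class YoudenResult:
    threshold: float
    sensitivity: float
    specificity: float
    youden_index: float


def youden_cutoff(probabilities, outcomes) -> YoudenResult:
    """Probability cutoff maximizing the Youden index (sens + spec - 1).

    Candidate thresholds are the observed probabilities (prediction rule:
    probability >= threshold). Ties on J are broken toward the highest
    sensitivity, then the lowest threshold — favoring detection.
    """
    scores = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    best: YoudenResult | None = None
    for t in sorted(np.unique(scores)):
        pred = scores >= t
        sens = float((pred & (y == 1)).sum() / n_pos)
        spec = float((~pred & (y == 0)).sum() / n_neg)
        j = sens + spec - 1.0
        cand = YoudenResult(float(t), sens, spec, j)
        if (
            best is None
            or cand.youden_index > best.youden_index + 1e-12
            or (
                abs(cand.youden_index - best.youden_index) <= 1e-12
                and (
                    cand.sensitivity > best.sensitivity + 1e-12
                    or (
                        abs(cand.sensitivity - best.sensitivity) <= 1e-12
                        and cand.threshold < best.threshold
                    )
                )
            )
        ):
            best = cand
    assert best is not None
    return best


def loocv_auc(
    data: pd.DataFrame, predictors: list[str], outcome_col: str = "outcome"
) -> float:
    """Leave-one-out cross-validated AUC.

    The model is refit n times leaving one patient out; the n out-of-fold
    probabilities are pooled and scored by a single AUC. A training fold that
    loses one outcome class entirely falls back to the class prevalence.
    """
    n = len(data)
    if n < 6:
        raise ValueError("LOOCV requires n >= 6")
    y = data[outcome_col].to_numpy(dtype=int)
    oof = np.empty(n)
    for i in range(n):
        train = data.drop(data.index[i])
        y_tr = train[outcome_col].to_numpy(dtype=float)
        if len(np.unique(y_tr)) < 2 or any(
            train[p].nunique() < 2 for p in predictors
        ):
            oof[i] = y_tr.mean()
            continue
        fit = fit_logistic(train, predictors, outcome_col)
        row = data.iloc[i]
        eta = fit.coefficients["intercept"] + sum(
            fit.coefficients[p] * float(row[p]) for p in predictors
        )
        oof[i] = float(expit(eta))
    return roc_auc(oof, y)


@dataclass(frozen=True)
class FittedModel:
    mode: str
    selected_predictors: tuple[str, ...]
    coefficients: dict[str, float]
    auc: float
    auc_loocv: float | None
    delong_p: float | None
    youden_cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    intercept_only_flag: bool = False
    separation_flag: bool = False


def _median_split(values: np.ndarray) -> np.ndarray:
    """Two-bin discretization at the median (high = 1), for V screening."""
    return (values > np.median(values)).astype(int)


def inputs_to_frame(
    inputs: list[ModelInput],
    covariates: list[str] | None = None,
    exclude_ids: list[str] | None = None,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Design frame from patient inputs.

    Continuous MGE predictors are log10(x+1)-transformed (signed for the
    pre-minus-post change, which can be negative); categorical covariates are
    dummy-coded against their first level.
    """
    exclude = set(exclude_ids or [])
    kept = [m for m in inputs if m.patient_id not in exclude]
    if len(kept) < 2:
        raise ValueError("need at least two patients after exclusions")
    rows = []
    for m in kept:
        row: dict[str, object] = {
            "patient_id": m.patient_id,
            "mge_pre": m.mge_pre,
            "mge_post": m.mge_post,
            "mge_change": m.mge_change,
            "outcome": int(m.outcome),
        }
        row.update(m.covariates)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("patient_id")
    if log_transform:
        for col in ("mge_pre", "mge_post"):
            df[col] = np.log10(df[col] + 1.0)
        df["mge_change"] = np.sign(df["mge_change"]) * np.log10(
            np.abs(df["mge_change"]) + 1.0
        )
    for cov in covariates or []:
        if df[cov].dtype == object or str(df[cov].dtype) == "category":
            dummies = pd.get_dummies(df[cov], prefix=cov, drop_first=True, dtype=float)
            df = pd.concat([df.drop(columns=[cov]), dummies], axis=1)
    return df


def _candidate_columns(df: pd.DataFrame, predictors: list[str] | None) -> list[str]:
    if predictors is not None:
        return list(predictors)
    return [c for c in df.columns if c not in ("outcome", "mge_change")]


def _aic_of(df: pd.DataFrame, preds: list[str]) -> float:
    if not preds:
        y = df["outcome"].to_numpy(dtype=float)
        p1 = y.mean()
        eps = 1e-12
        llf = len(y) * (p1 * np.log(p1 + eps) + (1 - p1) * np.log(1 - p1 + eps))
        return 2 - 2 * llf
    return fit_logistic(df, preds).aic


def _forward_aic(df: pd.DataFrame, candidates: list[str]) -> list[str]:
    selected: list[str] = []
    remaining = list(candidates)
    current = _aic_of(df, selected)
    while remaining:
        trials = [(p, _aic_of(df, selected + [p])) for p in remaining]
        best_p, best_aic = min(trials, key=lambda t: t[1])
        if best_aic < current - 1e-9:
            selected.append(best_p)
            remaining.remove(best_p)
            current = best_aic
        else:
            break
    return selected


def _backward_aic(df: pd.DataFrame, candidates: list[str]) -> list[str]:
    selected = list(candidates)
    current = _aic_of(df, selected)
    while selected:
        trials = [
            (p, _aic_of(df, [q for q in selected if q != p])) for p in selected
        ]
        best_p, best_aic = min(trials, key=lambda t: t[1])
        if best_aic < current - 1e-9:
            selected.remove(best_p)
            current = best_aic
        else:
            break
    return selected


def _stepwise_aic(df: pd.DataFrame, candidates: list[str]) -> list[str]:
    selected: list[str] = []
    current = _aic_of(df, selected)
    while True:
        moves: list[tuple[str, str, float]] = []
        for p in candidates:
            if p not in selected:
                moves.append(("add", p, _aic_of(df, selected + [p])))
        for p in selected:
            moves.append(("drop", p, _aic_of(df, [q for q in selected if q != p])))
        if not moves:
            break
        action, p, best_aic = min(moves, key=lambda t: t[2])
        if best_aic < current - 1e-9:
            if action == "add":
                selected.append(p)
            else:
                selected.remove(p)
            current = best_aic
        else:
            break
    return selected


def _manual_selection(df: pd.DataFrame, candidates: list[str]) -> list[str]:
    """Cramér's-V screening then inclusion by pseudo-R² impact.

    Continuous predictors are median-split into two bins for the screening
    step; survivors are ranked by V and added to the model one at a time,
    each kept only if it improves McFadden pseudo-R² by at least
    ``MANUAL_R2_GAIN``.
    """
    y = df["outcome"].to_numpy(dtype=int)
    screened: list[tuple[str, float]] = []
    for p in candidates:
        vals = df[p].to_numpy(dtype=float)
        binned = _median_split(vals) if df[p].nunique() > 2 else vals.astype(int)
        if len(np.unique(binned)) < 2:
            continue
        v = cramers_v(binned, y)
        if v >= MANUAL_V_THRESHOLD:
            screened.append((p, v))
    screened.sort(key=lambda t: -t[1])
    selected: list[str] = []
    current_r2 = 0.0
    for p, _ in screened:
        fit = fit_logistic(df, selected + [p])
        if fit.mcfadden_r2 > current_r2 + MANUAL_R2_GAIN:
            selected.append(p)
            current_r2 = fit.mcfadden_r2
    return selected


_SELECTORS = {
    "manual": _manual_selection,
    "forward": _forward_aic,
    "reverse": _backward_aic,
    "stepwise": _stepwise_aic,
}


def select_model(
    inputs: list[ModelInput] | pd.DataFrame,
    mode: str = "stepwise",
    predictors: list[str] | None = None,
    covariates: list[str] | None = None,
    exclude_ids: list[str] | None = None,
    with_loocv: bool = True,
) -> FittedModel:
    """Build and score the model selected by one strategy.

    Accepts either raw patient inputs (converted via :func:`inputs_to_frame`)
    or an already-prepared design frame with an ``outcome`` column.
    """
    if mode not in _SELECTORS:
        raise ValueError(f"mode must be one of {SELECTION_MODES}")
    if isinstance(inputs, pd.DataFrame):
        df = inputs
    else:
        df = inputs_to_frame(inputs, covariates=covariates, exclude_ids=exclude_ids)
    candidates = _candidate_columns(df, predictors)
    selected = _SELECTORS[mode](df, candidates)

    if not selected:
        prev = float(df["outcome"].mean())
        return FittedModel(
            mode=mode,
            selected_predictors=(),
            coefficients={"intercept": float(np.log(prev / (1 - prev)))}
            if 0 < prev < 1
            else {"intercept": 0.0},
            auc=0.5,
            auc_loocv=None,
            delong_p=None,
            youden_cutoff=prev,
            sensitivity_at_cutoff=1.0,
            specificity_at_cutoff=0.0,
            intercept_only_flag=True,
        )

    fit = fit_logistic(df, selected)
    y = df["outcome"].to_numpy(dtype=int)
    auc = roc_auc(fit.fitted_probs, y)
    try:
        dl_p = delong_pvalue(fit.fitted_probs, y)
    except ValueError:
        dl_p = None
    yj = youden_cutoff(fit.fitted_probs, y)
    auc_cv = (
        loocv_auc(df, selected) if with_loocv and len(df) >= 6 else None
    )
    return FittedModel(
        mode=mode,
        selected_predictors=fit.predictors,
        coefficients=fit.coefficients,
        auc=auc,
        auc_loocv=auc_cv,
        delong_p=dl_p,
        youden_cutoff=yj.threshold,
        sensitivity_at_cutoff=yj.sensitivity,
        specificity_at_cutoff=yj.specificity,
        separation_flag=fit.separation_flag,
    )


def build_final_model(
    inputs: list[ModelInput] | pd.DataFrame,
    modes: tuple[str, ...] = SELECTION_MODES,
    **kwargs,
) -> FittedModel:
    """Run every selection strategy and keep the model maximizing the AUC."""
    candidates = [select_model(inputs, mode=m, **kwargs) for m in modes]
    return max(candidates, key=lambda m: m.auc)


def mge_fold_change(
    median_change_responders: float, median_change_nonresponders: float
) -> float:
    """Ratio of median MGE changes (responders / non-responders), 2 decimals."""
    if median_change_nonresponders <= 0:
        raise ValueError("non-responder median change must be > 0")
    return round(median_change_responders / median_change_nonresponders, 2)


def exhaustive_best_subset(df: pd.DataFrame, candidates: list[str]) -> list[str]:
    """AIC-best subset by brute-force enumeration (small candidate sets only).

    Used as an independent check on the greedy AIC searches.
    """
    best_subset: list[str] = []
    best_aic = _aic_of(df, [])
    for k in range(1, len(candidates) + 1):
        for combo in itertools.combinations(candidates, k):
            aic = _aic_of(df, list(combo))
            if aic < best_aic - 1e-9:
                best_aic = aic
                best_subset = list(combo)
    return best_subset
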