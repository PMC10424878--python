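"""Model fitting and evaluation for the descriptor-based sepsis risk models.

Seven logistic regression models — every non-empty subset of the descriptors
{Lambda, Delta, C}, always with an intercept — are validated with stratified
10-fold cross-validation.  Discrimination is measured by the AUROC of the
pooled out-of-fold probabilities; sensitivity and specificity are reported
at the cutoff maximising their sum (Youden).  Calibration is summarised by
the slope and intercept of a logistic recalibration of the outcome on the
predicted log-odds (ideal 1 and 0; DistSlope and DistIntercept are the
absolute deviations).  Schemes and models are compared with a normalized
rank-average score in [0, 1] (1 = best in every contributing comparison).
The prediction task additionally supports a multivariable Cox proportional
hazards model (T, S) ~ Lambda + Delta + C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

DESCRIPTOR_PREDICTORS = {
    "lambda_mean": "Lambda",
    "lambda_trend": "Delta",
    "n_changes": "C",
}


@dataclass(frozen=True)
class ModelSpec:
    """A predictor subset of {lambda_mean, lambda_trend, n_changes} plus intercept."""

    predictors: tuple[str, ...]

    def __post_init__(self):
        if not self.predictors:
            raise ValueError("a model needs at least one predictor")
        unknown = set(self.predictors) - set(DESCRIPTOR_PREDICTORS)
        if unknown:
            raise ValueError(f"unknown predictor(s): {sorted(unknown)}")

    @property
    def name(self) -> str:
        return "S~" + "+".join(DESCRIPTOR_PREDICTORS[p] for p in self.predictors)


def all_model_specs() -> list[ModelSpec]:
    """The 7 models: every non-empty subset of {Lambda, Delta, C}."""
    keys = list(DESCRIPTOR_PREDICTORS)
    specs = []
    for mask in range(1, 8):
        preds = tuple(k for i, k in enumerate(keys) if mask >> i & 1)
        specs.append(ModelSpec(predictors=preds))
    specs.sort(key=lambda s: (len(s.predictors), s.name))
    return specs


@dataclass
class LogisticCVResult:
    spec: ModelSpec
    probabilities: np.ndarray  # pooled out-of-fold, aligned with input rows
    coefficients: pd.DataFrame  # full-data refit: coef, odds_ratio, ci_low, ci_high, p_value
    seed: int
    separation_flagged: bool = False


class _RidgeLogitResult:
    """Minimal statsmodels-like wrapper for the separation fallback fit."""

    def __init__(self, X: np.ndarray, y: np.ndarray):
        from sklearn.linear_model import LogisticRegression

        # X already carries the constant column; keep a mild ridge for identifiability
        model = LogisticRegression(C=1e3, fit_intercept=False, max_iter=2000)
        model.fit(X, y)
        self.params = model.coef_.ravel()
        self._model = model

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._model.predict_proba(X)[:, 1]


def _fit_logit(X: np.ndarray, y: np.ndarray):
    """Unpenalized logistic fit; ridge-stabilised fallback under (near-)separation."""
    flagged = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", sm.tools.sm_exceptions.ConvergenceWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:
            flagged = True
            res = _RidgeLogitResult(X, y)
    return res, flagged


def fit_logistic_cv(
    rows: pd.DataFrame, spec: ModelSpec, k_folds: int = 10, seed: int = 0
) -> LogisticCVResult:
    """Out-of-fold predicted probabilities plus a full-data coefficient table.

    Folds are stratified by outcome and deterministic given ``seed``.  Every
    row receives exactly one out-of-fold probability; odds ratios carry Wald
    95% confidence intervals from the full-data refit.
    """
    y = rows["outcome"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    X = sm.add_constant(rows[list(spec.predictors)].to_numpy(dtype=float), has_constant="add")

    proba = np.full(len(y), np.nan)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    flagged = False
    for train_idx, test_idx in skf.split(X, y):
        res, f = _fit_logit(X[train_idx], y[train_idx])
        flagged |= f
        proba[test_idx] = res.predict(X[test_idx])
    proba = np.clip(proba, 1e-12, 1 - 1e-12)

    full, f = _fit_logit(X, y)
    flagged |= f
    params = np.asarray(full.params)
    try:
        ci = np.asarray(full.conf_int())
        pvalues = np.asarray(full.pvalues)
    except Exception:  # regularized fallback lacks a covariance matrix
        ci = np.column_stack([params, params]) * np.nan
        pvalues = np.full_like(params, np.nan)
    names = ["intercept", *spec.predictors]
    coef = pd.DataFrame(
        {
            "term": names,
            "coef": params,
            "odds_ratio": np.exp(params),
            "or_ci_low": np.exp(ci[:, 0]),
            "or_ci_high": np.exp(ci[:, 1]),
            "p_value": pvalues,
        }
    )
    return LogisticCVResult(
        spec=spec, probabilities=proba, coefficients=coef, seed=seed, separation_flagged=flagged
    )


def discrimination_metrics(
    probabilities: np.ndarray, outcomes: np.ndarray
) -> tuple[float, float, float, float]:
    """(AUROC, cutoff, sensitivity, specificity).

    AUROC is the Mann-Whitney concordance probability (ties count half).
    The cutoff is the predicted probability maximising sensitivity +
    specificity; the lowest such probability on ties.  A case is called
    positive when its probability >= cutoff.
    """
    y = np.asarray(outcomes, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    auroc = float(roc_auc_score(y, p))
    fpr, tpr, thresholds = roc_curve(y, p)
    youden = tpr - fpr
    best = np.flatnonzero(youden == youden.max())[-1]  # thresholds descend: last = lowest
    cutoff = float(min(thresholds[best], 1.0))
    sens = float(tpr[best])
    spec = float(1.0 - fpr[best])
    return auroc, cutoff, sens, spec


def calibration_metrics(
    probabilities: np.ndarray, outcomes: np.ndarray
) -> tuple[float, float, float, float]:
    """(slope, intercept, DistSlope, DistIntercept) of a logistic recalibration.

    The outcome is regressed on the log-odds of the predicted probability;
    ideal slope 1, ideal intercept 0.  Probabilities at {0, 1} are clipped
    to (1e-12, 1 - 1e-12) with a warning.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if ((p <= 0) | (p >= 1)).any():
        warnings.warn("degenerate probabilities clipped for calibration", stacklevel=2)
        p = np.clip(p, 1e-12, 1 - 1e-12)
    logodds = np.log(p / (1 - p))
    if np.ptp(logodds) == 0:
        warnings.warn("zero-variance predictor: calibration slope undefined", stacklevel=2)
        return float("nan"), float("nan"), float("nan"), float("nan")
    X = sm.add_constant(logodds)
    res, _ = _fit_logit(X, y)
    intercept, slope = float(res.params[0]), float(res.params[1])
    return slope, intercept, abs(slope - 1.0), abs(intercept)


@dataclass
class EvaluationResult:
    """All metrics for one (task, variant, scheme, model) cell."""

    task: str
    variant: str
    scheme: str
    model: str
    auroc: float
    cutoff: float
    sensitivity: float
    specificity: float
    calib_slope: float
    calib_intercept: float
    dist_slope: float
    dist_intercept: float
    seed: int
    coefficients: pd.DataFrame = field(repr=False, default=None)


def evaluate_cell(
    rows: pd.DataFrame,
    spec: ModelSpec,
    task: str = "",
    variant: str = "prospective",
    scheme_id: str = "",
    k_folds: int = 10,
    seed: int = 0,
) -> EvaluationResult:
    """Fit one logistic model with CV and compute all evaluation metrics."""
    cv = fit_logistic_cv(rows, spec, k_folds=k_folds, seed=seed)
    y = rows["outcome"].to_numpy(dtype=int)
    auroc, cutoff, sens, specf = discrimination_metrics(cv.probabilities, y)
    slope, intercept, dslope, dintercept = calibration_metrics(cv.probabilities, y)
    return EvaluationResult(
        task=task,
        variant=variant,
        scheme=scheme_id,
        model=spec.name,
        auroc=auroc,
        cutoff=cutoff,
        sensitivity=sens,
        specificity=specf,
        calib_slope=slope,
        calib_intercept=intercept,
        dist_slope=dslope,
        dist_intercept=dintercept,
        seed=seed,
        coefficients=cv.coefficients,
    )


def results_table(results: list[EvaluationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {k: getattr(r, k) for k in (
                "task", "variant", "scheme", "model", "auroc", "cutoff",
                "sensitivity", "specificity", "calib_slope", "calib_intercept",
                "dist_slope", "dist_intercept", "seed",
            )}
            for r in results
        ]
    )


def _normalized_ranks(values: np.ndarray) -> np.ndarray:
    """Mid-rank normalized to [0, 1]: best (largest) -> 1, worst -> 0."""
    ranks = stats.rankdata(values, method="average")
    n = len(values)
    if n == 1:
        return np.ones(1)
    return (ranks - 1) / (n - 1)


def ranking_scores(
    grid: pd.DataFrame, contributing_models: list[str] | None = None
) -> tuple[pd.Series, pd.Series]:
    """Normalized rank-average scores (s_w per scheme, s_m per model).

    ``grid`` is a tidy frame with columns scheme, model, auroc, complete
    over its scheme x model cross.  s_w averages, over the contributing
    models, the normalized rank of the scheme's AUROC among all schemes
    within that model (best = 1, worst = 0, mid-ranks on ties); s_m is the
    analogous average over all schemes of within-scheme model ranks.
    Invariant under strictly monotone transforms of the AUROCs.
    """
    schemes = sorted(grid["scheme"].unique())
    models = sorted(grid["model"].unique())
    pivot = grid.pivot_table(index="scheme", columns="model", values="auroc")
    missing = [
        (s, m) for s in schemes for m in models if pd.isna(pivot.reindex(schemes)[m].get(s))
    ]
    if missing:
        raise ValueError(f"incomplete evaluation grid; missing cells: {missing[:10]}")
    contributing = contributing_models if contributing_models is not None else models
    unknown = set(contributing) - set(models)
    if unknown:
        raise ValueError(f"contributing models not in grid: {sorted(unknown)}")

    s_w = pd.Series(0.0, index=pivot.index, name="s_w")
    for m in contributing:
        s_w += _normalized_ranks(pivot[m].to_numpy())
    s_w /= len(contributing)

    s_m = pd.Series(0.0, index=pivot.columns, name="s_m")
    for s in pivot.index:
        s_m += _normalized_ranks(pivot.loc[s].to_numpy())
    s_m /= len(pivot.index)
    return s_w, s_m


def fit_cox_ph(rows: pd.DataFrame) -> dict:
    """Multivariable Cox PH fit (T, S) ~ Lambda + Delta + C on prediction rows.

    Returns hazard ratios with 95% CIs per descriptor and the omnibus
    likelihood-ratio test of all descriptor coefficients being zero.
    """
    data = rows[["time_to_event", "outcome", *DESCRIPTOR_PREDICTORS]].astype(float)
    if (data["outcome"] == 0).all():
        raise ValueError("all-censored data: Cox model inestimable")
    if (data["time_to_event"] <= 0).any():
        raise ValueError("time_to_event must be positive")
    constant = [c for c in DESCRIPTOR_PREDICTORS if data[c].nunique() <= 1]
    usable = [c for c in DESCRIPTOR_PREDICTORS if c not in constant]
    if not usable:
        raise ValueError("all predictors constant: Cox model inestimable")
    cph = CoxPHFitter()
    cph.fit(
        data[["time_to_event", "outcome", *usable]],
        duration_col="time_to_event",
        event_col="outcome",
    )
    summary = cph.summary
    lrt = cph.log_likelihood_ratio_test()
    return {
        "hazard_ratios": summary["exp(coef)"].to_dict(),
        "hr_ci_low": summary["exp(coef) lower 95%"].to_dict(),
        "hr_ci_high": summary["exp(coef) upper 95%"].to_dict(),
        "p_values": summary["p"].to_dict(),
        "omnibus_p": float(lrt.p_value),
        "dropped_constant": constant,
    }


def descriptor_group_tests(rows: pd.DataFrame) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of each descriptor between the two outcome groups.

    Returns one row per descriptor with group mean +- sd and the two-sided
    rank-sum p-value (p = 1 with a note when both groups are constant and
    identical).
    """
    g1 = rows[rows["outcome"] == 1]
    g0 = rows[rows["outcome"] == 0]
    if g1.empty or g0.empty:
        raise ValueError("both groups must be non-empty")
    out = []
    for col, label in DESCRIPTOR_PREDICTORS.items():
        x = g1[col].to_numpy(dtype=float)
        y = g0[col].to_numpy(dtype=float)
        note = ""
        if np.ptp(x) == 0 and np.ptp(y) == 0 and (len(x) == 0 or len(y) == 0 or x[0] == y[0]):
            p = 1.0
            note = "zero variance in both groups"
        else:
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        out.append(
            {
                "descriptor": label,
                "mean_sepsis": float(np.mean(x)),
                "sd_sepsis": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
                "mean_control": float(np.mean(y)),
                "sd_control": float(np.std(y, ddof=1)) if len(y) > 1 else 0.0,
                "p_value": p,
                "note": note,
            }
        )
    return pd.DataFrame(out)


def combination_chi2_tests(freq: pd.DataFrame) -> pd.DataFrame:
    """Chi-squared test per criterion combination on person-minute counts.

    ``freq`` is the tidy output of descriptors.combination_frequencies with
    exactly two groups; each combination is tested in a 2x2 table of
    (minutes in combination vs not) x group.
    """
    groups = sorted(freq["group"].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    totals = freq.groupby("group")["minutes"].sum().to_dict()
    rows = []
    for combo, sub in freq.groupby("combination"):
        counts = sub.set_index("group")["minutes"].to_dict()
        table = np.array(
            [
                [counts[g], totals[g] - counts[g]]
                for g in groups
            ]
        )
        if (table.sum(axis=0) == 0).any():
            p = 1.0
        else:
            p = float(stats.chi2_contingency(table, correction=False).pvalue)
        rows.append({"combination": combo, "p_value": p})
    return pd.DataFrame(rows)
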