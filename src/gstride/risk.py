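"""Fall-risk statistics: univariate logistic cut-offs, multivariable
logistic models, and repeated-split cross-validated classification.

The cohort table is a plain :class:`pandas.DataFrame` with one row per
participant, a binary ``faller`` column, clinical variables and the
per-participant gait summaries.  Three canonical predictor sets are
provided: a conventional clinical model, an IMU-kinematics model and a
mixed model, plus the two single-test reference models (4-m walk speed,
SPPB total).

Every classifier here is a maximum-likelihood logistic regression
(statsmodels); a univariate cut-off is the predictor value where the
fitted fall probability crosses 0.5, i.e. ``-intercept/coefficient``.
Evaluation follows a repeated random-subsampling scheme: 50 unstratified
70/30 train/test splits, the confusion-matrix counts averaged over
repeats, and the summary statistics derived from the averaged matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import expit

logger = logging.getLogger(__name__)

#: Canonical predictor sets of the three published models plus the two
#: single-test reference models.
MODEL_SPECS: dict[str, list[str]] = {
    "conv": ["FES1", "FRG_Total", "TUG", "GDS", "Speed_4m_walk", "SPPB_Total", "Age"],
    "imu": [
        "Total_distance",
        "GCT_STD",
        "Pushing_pct",
        "Swing_pct",
        "Loading_pct",
        "FootFlat_pct",
        "FootFlat_pct_STD",
        "Toe_off_angle",
        "Heel_strike_angle",
        "Heel_strike_angle_STD",
        "Cadence",
        "StepSpeed",
        "StrideLength",
        "Clearance",
        "Clearance_STD",
    ],
    "mix": [
        "FES1",
        "SPPB_equilibrium",
        "FRG_strength",
        "FRG_physical_activity",
        "StepSpeed",
        "FootFlat_pct_STD",
    ],
    "speed4m": ["Speed_4m_walk"],
    "sppb": ["SPPB_Total"],
}


@dataclass
class ModelSpec:
    """A named list of predictor columns."""

    name: str
    predictors: list[str]

    @classmethod
    def canonical(cls, name: str) -> "ModelSpec":
        if name not in MODEL_SPECS:
            raise KeyError(f"unknown model {name!r}; choose from {sorted(MODEL_SPECS)}")
        return cls(name=name, predictors=list(MODEL_SPECS[name]))


@dataclass
class CutoffResult:
    """Univariate logistic cut-off: the predictor value at p(fall)=0.5.

    A negative coefficient means larger values of the variable lower the
    fall probability (the cut-off separates from above); positive, the
    reverse.
    """

    variable: str
    cutoff: float
    intercept: float
    coefficient: float
    z: float
    p: float
    separation: bool = False

    def classify(self, x) -> np.ndarray:
        """Cut-off classification; identical to thresholding the fitted
        probability at 0.5 (sign-aware)."""
        x = np.asarray(x, dtype=float)
        if self.coefficient > 0:
            return (x >= self.cutoff).astype(int)
        return (x <= self.cutoff).astype(int)


@dataclass
class FitResult:
    """Multivariable logistic fit: per-term log-odds, Wald 95% CI, p."""

    name: str
    params: pd.DataFrame  # index: term; columns: coef, ci_low, ci_high, z, p
    llf: float
    deviance: float
    n_obs: int
    converged: bool
    separation: bool

    def predict(self, cohort: pd.DataFrame) -> np.ndarray:
        terms = [t for t in self.params.index if t != "Intercept"]
        x = _design(cohort, terms)
        eta = x @ self.params["coef"].to_numpy()
        return expit(eta)


@dataclass
class EvalStats:
    """Averaged confusion matrix and its derived statistics.

    ``tp/fp/tn/fn`` are mean counts over the repeats; undefined ratios
    (zero denominator) are reported as NaN, never as 0.
    """

    tp: float
    fp: float
    tn: float
    fn: float
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    prevalence: float
    f1: float
    auc: float | None = None
    n_repeats: int = 1
    test_fraction: float = 1.0
    n_test: int = 0
    total_test_observations: int = 0
    total_test_observations_nominal: float = 0.0
    seed: int | None = None

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# fitting plumbing


def _design(cohort: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    missing = [c for c in predictors if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing predictor columns: {missing}")
    cols = cohort[predictors].to_numpy(dtype=float) if predictors else np.empty((len(cohort), 0))
    if np.isnan(cols).any():
        bad = [c for c in predictors if cohort[c].isna().any()]
        raise ValueError(f"missing values in predictors: {bad}")
    return np.column_stack([np.ones(len(cohort)), cols])


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        culprits = []
        for j in range(1, x.shape[1]):
            keep = [k for k in range(x.shape[1]) if k != j]
            if np.linalg.matrix_rank(x[:, keep]) == rank:
                culprits.append(names[j - 1])
        raise ValueError(
            f"rank-deficient design (rank {rank} < {x.shape[1]}); "
            f"collinear or constant columns: {culprits or names}"
        )


class _RidgeLogitFit:
    """Result of the ridge-stabilized fallback fit (separation only).

    Mirrors the slice of the statsmodels results API the callers use;
    Wald statistics come from the penalized Hessian, so they are
    indicative only (the separation flag travels with them).
    """

    def __init__(self, y, x, alpha=1e-3, maxiter=200, tol=1e-10):
        k = x.shape[1]
        beta = np.zeros(k)
        h = np.eye(k)
        for _ in range(maxiter):
            p = expit(x @ beta)
            w = p * (1.0 - p) + 1e-12
            grad = x.T @ (y - p) - alpha * beta
            h = (x * w[:, None]).T @ x + alpha * np.eye(k)
            step = np.linalg.solve(h, grad)
            beta = beta + step
            if np.linalg.norm(step) < tol:
                break
        self.params = beta
        cov = np.linalg.inv(h)
        se = np.sqrt(np.diag(cov))
        self.bse = se
        self.tvalues = beta / se
        self.pvalues = 2.0 * sps.norm.sf(np.abs(self.tvalues))
        p = np.clip(expit(x @ beta), 1e-12, 1 - 1e-12)
        self.llf = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        self.mle_retvals = {"converged": False}

    def conf_int(self, alpha=0.05):
        zq = sps.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - zq * self.bse, self.params + zq * self.bse])


def _fit_logit(y: np.ndarray, x: np.ndarray):
    """MLE logistic fit, robust to (quasi-)separation.

    Returns (results, separation_flag).  Under separation the unpenalized
    MLE diverges; a weakly ridge-penalized fit is then reported with the
    flag set (coefficients unstable, but the decision boundary - the final
    iterate's probability-0.5 crossing - stays well defined and
    sign-stable).
    """
    separation = False
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, x).fit(disp=0, maxiter=100)
            converged = bool(res.mle_retvals.get("converged", True))
            if not converged or np.abs(x @ res.params).max() > 30:
                separation = True
        except Exception:
            separation = True
    if separation:
        res = _RidgeLogitFit(y, x)
    return res, separation


def fit_univariate_cutoff(cohort: pd.DataFrame, variable: str) -> CutoffResult:
    """Fit ``faller ~ variable`` and return the probability-0.5 cut-off.

    Raises on a constant variable or a single-class cohort; complete
    separation is reported via the ``separation`` flag, not an error.
    """
    y = cohort["faller"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit a cut-off")
    x = cohort[variable].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"variable {variable!r} is constant; no cut-off exists")
    design = np.column_stack([np.ones_like(x), x])
    res, separation = _fit_logit(y, design)
    b0, b1 = res.params
    return CutoffResult(
        variable=variable,
        cutoff=cutoff_from_coefficients(b0, b1),
        intercept=float(b0),
        coefficient=float(b1),
        z=float(res.tvalues[1]),
        p=float(res.pvalues[1]),
        separation=separation,
    )


def cutoff_from_coefficients(intercept: float, coefficient: float) -> float:
    """Predictor value where the logistic probability crosses 0.5."""
    if coefficient == 0:
        raise ZeroDivisionError("zero slope: the fitted probability never crosses 0.5")
    return -float(intercept) / float(coefficient)


def cutoff_table(cohort: pd.DataFrame, variables: list[str] | None = None) -> pd.DataFrame:
    """Univariate cut-offs for every requested (default: every numeric,
    non-constant) variable, one row each."""
    if variables is None:
        variables = [
            c
            for c in cohort.columns
            if c != "faller"
            and pd.api.types.is_numeric_dtype(cohort[c])
            and np.ptp(cohort[c].to_numpy(dtype=float)) > 0
        ]
    rows = [asdict(fit_univariate_cutoff(cohort, v)) for v in variables]
    return pd.DataFrame(rows)


def fit_model(cohort: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Multivariable MLE logistic fit of ``faller`` on the spec's columns."""
    y = cohort["faller"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    x = _design(cohort, spec.predictors)
    if len(cohort) <= x.shape[1]:
        raise ValueError(
            f"n={len(cohort)} too small for {x.shape[1]} terms (incl. intercept)"
        )
    _check_rank(x, spec.predictors)
    res, separation = _fit_logit(y, x)
    ci = res.conf_int(alpha=0.05)
    ci = np.asarray(ci)
    terms = ["Intercept"] + list(spec.predictors)
    params = pd.DataFrame(
        {
            "coef": np.asarray(res.params),
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "z": np.asarray(res.tvalues),
            "p": np.asarray(res.pvalues),
        },
        index=terms,
    )
    return FitResult(
        name=spec.name,
        params=params,
        llf=float(res.llf),
        deviance=float(-2.0 * res.llf),
        n_obs=len(cohort),
        converged=bool(res.mle_retvals.get("converged", True)) if res.mle_retvals else True,
        separation=separation,
    )


# ---------------------------------------------------------------------------
# evaluation


def derive_stats(tp: float, fp: float, tn: float, fn: float) -> dict:
    """Confusion-matrix statistics; NaN marks an undefined ratio."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + tn + fn
    if total <= 0:
        raise ValueError("empty confusion matrix")

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    sens = ratio(tp, tp + fn)
    ppv = ratio(tp, tp + fp)
    return {
        "accuracy": (tp + tn) / total,
        "sensitivity": sens,
        "specificity": ratio(tn, tn + fp),
        "ppv": ppv,
        "npv": ratio(tn, tn + fn),
        "prevalence": (tp + fn) / total,
        "f1": ratio(2 * ppv * sens, ppv + sens)
        if np.isfinite(ppv) and np.isfinite(sens)
        else float("nan"),
    }


def confusion_from_rates(
    sensitivity: float, specificity: float, prevalence: float, total: float = 1.0
) -> tuple[float, float, float, float]:
    """(tp, fp, tn, fn) implied by sensitivity/specificity/prevalence."""
    tp = prevalence * sensitivity * total
    fn = prevalence * (1 - sensitivity) * total
    tn = (1 - prevalence) * specificity * total
    fp = (1 - prevalence) * (1 - specificity) * total
    return tp, fp, tn, fn


def _auc(y: np.ndarray, p: np.ndarray) -> float:
    """Rank (Mann-Whitney) AUC with tie correction."""
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    r = sps.rankdata(p)
    return (r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def cross_validate(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    n_repeats: int = 50,
    train_fraction: float = 0.7,
    threshold: float = 0.5,
    seed: int | None = None,
    average: str = "matrix",
) -> EvalStats:
    """Repeated random-subsampling evaluation of a logistic model.

    Each repeat draws an unstratified random split (test size
    ``round((1-train_fraction)*n)``), fits on the training part and
    classifies the held-out rows at the probability ``threshold``.  A
    repeat whose training part lacks a class is redrawn (logged).  With
    ``average='matrix'`` (default) the confusion counts are averaged over
    repeats and the statistics derived from the averaged matrix;
    ``average='stats'`` averages the per-repeat statistics instead.

    The nominal total test count ``n_repeats * (1-train_fraction) * n`` is
    reported alongside the realized integer count.
    """
    n = len(cohort)
    if n < 20:
        raise ValueError("cohort too small for repeated-split evaluation (n < 20)")
    y_all = cohort["faller"].to_numpy(dtype=float)
    if len(np.unique(y_all)) < 2:
        raise ValueError("both classes must be present")
    test_fraction = 1.0 - train_fraction
    n_test = int(round(test_fraction * n))
    if n_test < 1 or n_test >= n:
        raise ValueError("train_fraction leaves an empty train or test set")

    x_all = _design(cohort, spec.predictors)
    _check_rank(x_all, spec.predictors)
    rng = np.random.default_rng(seed)

    mats = np.zeros((n_repeats, 4))  # tp fp tn fn
    per_stats: list[dict] = []
    aucs = []
    redraws = 0
    for rep in range(n_repeats):
        for _ in range(1000):
            perm = rng.permutation(n)
            test_idx, train_idx = perm[:n_test], perm[n_test:]
            if len(np.unique(y_all[train_idx])) == 2:
                break
            redraws += 1
        else:
            raise RuntimeError("could not draw a two-class training split")
        res, _ = _fit_logit(y_all[train_idx], x_all[train_idx])
        eta = x_all[test_idx] @ res.params
        p = expit(eta)
        pred = (p >= threshold).astype(float)
        yt = y_all[test_idx]
        tp = float(np.sum((pred == 1) & (yt == 1)))
        fp = float(np.sum((pred == 1) & (yt == 0)))
        tn = float(np.sum((pred == 0) & (yt == 0)))
        fn = float(np.sum((pred == 0) & (yt == 1)))
        mats[rep] = (tp, fp, tn, fn)
        per_stats.append(derive_stats(tp, fp, tn, fn))
        aucs.append(_auc(yt, p))
    if redraws:
        logger.info("redrew %d single-class training splits", redraws)

    tp, fp, tn, fn = mats.mean(axis=0)
    if average == "matrix":
        stats = derive_stats(tp, fp, tn, fn)
    elif average == "stats":
        stats = {
            k: float(np.nanmean([s[k] for s in per_stats])) for k in per_stats[0]
        }
    else:
        raise ValueError("average must be 'matrix' or 'stats'")

    return EvalStats(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        auc=float(np.nanmean(aucs)),
        n_repeats=n_repeats,
        test_fraction=test_fraction,
        n_test=n_test,
        total_test_observations=n_repeats * n_test,
        total_test_observations_nominal=n_repeats * test_fraction * n,
        seed=seed,
        **stats,
    )


def probability_report(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    fit: FitResult | None = None,
    bins: int = 20,
    threshold: float = 0.5,
    fig_path=None,
) -> pd.DataFrame:
    """Class-conditional histograms of the fitted fall probability.

    Returns a table with one row per bin on [0, 1] and faller/non-faller
    counts; optionally renders the two histograms with the decision
    threshold marked.
    """
    if fit is None:
        fit = fit_model(cohort, spec)
    p = fit.predict(cohort)
    y = cohort["faller"].to_numpy(dtype=int)
    edges = np.linspace(0.0, 1.0, bins + 1)
    h_f, _ = np.histogram(p[y == 1], bins=edges)
    h_nf, _ = np.histogram(p[y == 0], bins=edges)
    table = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "fallers": h_f,
            "nonfallers": h_nf,
        }
    )
    if fig_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        width = edges[1] - edges[0]
        ax.bar(edges[:-1], h_nf, width=width, align="edge", alpha=0.6,
               color="tab:green", label="non-fallers")
        ax.bar(edges[:-1], h_f, width=width, align="edge", alpha=0.6,
               color="tab:red", label="fallers")
        ax.axvline(threshold, color="k", ls="--", lw=1, label=f"threshold {threshold}")
        ax.set_xlabel("fitted fall probability")
        ax.set_ylabel("participants")
        ax.set_title(f"model: {fit.name}")
        ax.legend()
        fig.tight_layout()
        fig.savefig(fig_path, dpi=120)
        plt.close(fig)
    return table


def describe_cohort(
    cohort: pd.DataFrame,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group descriptive report with two-sample tests.

    Continuous variables: per-group min-max, mean +- SD and Welch-free
    pooled t statistic; categorical variables (default: the binary 0/1
    columns): per-group frequencies with a chi-square statistic.
    """
    if categorical is None:
        categorical = [
            c
            for c in cohort.columns
            if c != "faller" and set(pd.unique(cohort[c])) <= {0, 1}
        ]
    g1 = cohort[cohort["faller"] == 1]
    g0 = cohort[cohort["faller"] == 0]
    rows = []
    for c in cohort.columns:
        if c == "faller" or not pd.api.types.is_numeric_dtype(cohort[c]):
            continue
        a, b = g1[c].to_numpy(dtype=float), g0[c].to_numpy(dtype=float)
        if c in categorical:
            tab = pd.crosstab(cohort["faller"], cohort[c])
            if tab.shape[1] < 2 or (tab.to_numpy().sum(axis=0) == 0).any():
                stat, p = 0.0, 1.0
            else:
                stat, p = sps.chi2_contingency(tab, correction=False)[:2]
            rows.append(
                {
                    "variable": c,
                    "test": "chi2",
                    "faller_mean": a.mean(),
                    "nonfaller_mean": b.mean(),
                    "faller_sd": np.nan,
                    "nonfaller_sd": np.nan,
                    "faller_min": np.nan,
                    "faller_max": np.nan,
                    "nonfaller_min": np.nan,
                    "nonfaller_max": np.nan,
                    "statistic": float(stat),
                    "p": float(p),
                }
            )
        else:
            stat, p = sps.ttest_ind(a, b)
            rows.append(
                {
                    "variable": c,
                    "test": "t",
                    "faller_mean": a.mean(),
                    "nonfaller_mean": b.mean(),
                    "faller_sd": a.std(ddof=1),
                    "nonfaller_sd": b.std(ddof=1),
                    "faller_min": a.min(),
                    "faller_max": a.max(),
                    "nonfaller_min": b.min(),
                    "nonfaller_max": b.max(),
                    "statistic": float(stat),
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows)
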