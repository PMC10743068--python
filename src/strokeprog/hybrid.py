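"""Tabular and hybrid outcome experiments.

Dichotomized 90-day mRS prediction from clinical variables: the ASTRAL
comparator, logistic-regression experiments with 2/5/8 variables (the
5-variable set optionally taking its occlusion flag from a trained
Siamese occlusion model instead of an expert read), Bayesian
hyperparameter search, normalized coefficient profiles, paired t-tests
between experiments and VIF collinearity diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern, WhiteKernel
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .training import MetricRecord, evaluate, kfold_cv

# Column dictionary for cohort tables (delimited text, one row per patient).
COLUMNS = {
    "age": "age in years",
    "nihss": "baseline NIHSS, integer 0-42",
    "delay": "onset-to-admission delay in hours",
    "visual_defect": "visual-field defect flag (NIHSS item 3 > 0), 0/1",
    "loc": "decreased level of consciousness flag (NIHSS item 1a), 0/1",
    "glucose": "admission glucose in mg/dL",
    "aspects": "baseline ASPECTS, integer 0-10",
    "occlusion": "large-vessel occlusion: expert flag 0/1 or model probability",
    "mrs90": "90-day modified Rankin Scale, integer 0-6",
}

# Physiologically plausible bounds used by the outlier rule (configurable).
PHYSIOLOGICAL_BOUNDS = {
    "age": (18.0, 110.0),
    "nihss": (0, 42),
    "delay": (0.0, 48.0),
    "visual_defect": (0, 1),
    "loc": (0, 1),
    "glucose": (30.0, 800.0),
    "aspects": (0, 10),
    "occlusion": (0.0, 1.0),
    "mrs90": (0, 6),
}

ASTRAL_VARIABLES = ("age", "nihss", "delay", "visual_defect", "loc", "glucose")

# ASTRAL point scheme as a configuration table: (kind, parameters, points).
ASTRAL_SCHEME = {
    "age": ("per_unit", 5, 1),            # 1 point per 5 completed years
    "nihss": ("per_unit", 1, 1),          # 1 point per NIHSS point
    "delay": ("threshold_gt", 3.0, 2),    # > 3 h from onset: 2 points
    "visual_defect": ("flag", None, 2),   # visual-field defect: 2 points
    "loc": ("flag", None, 3),             # decreased consciousness: 3 points
    "glucose": ("outside", (66.0, 131.0), 1),  # >131 or <66 mg/dL: 1 point
}


@dataclass
class ExperimentDef:
    """A named tabular experiment: which predictors, and whether the
    occlusion variable comes from an expert read or the imaging model."""

    name: str
    variables: tuple[str, ...]
    occlusion_source: str = "expert"   # expert | model

    def __post_init__(self):
        if self.occlusion_source not in ("expert", "model"):
            raise ValueError(f"unknown occlusion source {self.occlusion_source!r}")
        unknown = set(self.variables) - (set(COLUMNS) - {"mrs90"})
        if unknown:
            raise ValueError(f"unknown predictors {sorted(unknown)}")


EXPERIMENTS = {
    "astral": ExperimentDef("astral", ASTRAL_VARIABLES),
    "lr_2vars": ExperimentDef("lr_2vars", ("age", "nihss")),
    "lr_5vars": ExperimentDef(
        "lr_5vars", ("age", "nihss", "glucose", "aspects", "occlusion")),
    "lr_5vars_sn": ExperimentDef(
        "lr_5vars_sn", ("age", "nihss", "glucose", "aspects", "occlusion"),
        occlusion_source="model"),
    "lr_8vars": ExperimentDef("lr_8vars", ASTRAL_VARIABLES + ("aspects", "occlusion")),
}


# ---------------------------------------------------------------------------
# outcome and comparator
# ---------------------------------------------------------------------------

def dichotomize_mrs(mrs90):
    """Poor outcome (1) iff mRS at 90 days > 2; good (0) iff <= 2."""
    arr = np.asarray(mrs90)
    if not np.issubdtype(arr.dtype, np.number) or np.any((arr < 0) | (arr > 6)) \
            or np.any(arr != np.floor(arr)):
        raise ValueError("mrs90 must be integers in 0..6")
    out = (arr > 2).astype(int)
    return int(out) if np.isscalar(mrs90) else out


def astral_score(rec, scheme: dict = ASTRAL_SCHEME) -> int:
    """Integer ASTRAL points for one record (mapping or pandas row); the raw
    score is the ranking statistic, higher = worse prognosis."""
    total = 0
    for var, (kind, param, points) in scheme.items():
        if var not in rec or pd.isna(rec[var]):
            raise ValueError(f"missing ASTRAL variable {var!r}")
        v = rec[var]
        if kind == "per_unit":
            total += points * int(np.floor(v / param))
        elif kind == "threshold_gt":
            total += points * int(v > param)
        elif kind == "flag":
            total += points * int(bool(v))
        elif kind == "outside":
            lo, hi = param
            total += points * int(v < lo or v > hi)
        else:
            raise ValueError(f"unknown scheme entry kind {kind!r}")
    return int(total)


def astral_scores(cohort: pd.DataFrame) -> np.ndarray:
    return np.array([astral_score(row) for _, row in cohort.iterrows()])


# ---------------------------------------------------------------------------
# cohort cleaning
# ---------------------------------------------------------------------------

def clean_cohort(cohort: pd.DataFrame,
                 bounds: dict = PHYSIOLOGICAL_BOUNDS) -> pd.DataFrame:
    """Complete-case analysis: drop any record with a missing value or a
    value outside the physiological bounds table."""
    missing = set(COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort is missing columns {sorted(missing)}")
    keep = cohort[list(COLUMNS)].notna().all(axis=1)
    for col, (lo, hi) in bounds.items():
        keep &= cohort[col].isna() | ((cohort[col] >= lo) & (cohort[col] <= hi))
    out = cohort.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError("no complete in-range records remain")
    return out


# ---------------------------------------------------------------------------
# Bayesian hyperparameter search (GP expected improvement)
# ---------------------------------------------------------------------------

@dataclass
class SearchSpace:
    log10_c: tuple[float, float] = (-3.0, 3.0)
    penalties: tuple[str, ...] = ("l1", "l2")


def _make_lr(C: float, penalty: str) -> LogisticRegression:
    import sklearn
    new_api = tuple(int(p) for p in sklearn.__version__.split(".")[:2]) >= (1, 8)
    if new_api:  # 'penalty' deprecated in favour of l1_ratio
        return LogisticRegression(C=C, l1_ratio=1.0 if penalty == "l1" else 0.0,
                                  solver="liblinear", max_iter=2000)
    return LogisticRegression(C=C, penalty=penalty, solver="liblinear",
                              max_iter=2000)


def _inner_cv_auc(x, y, log10_c, penalty, seed, k=5):
    from sklearn.model_selection import StratifiedKFold
    clf = _make_lr(10.0 ** log10_c, penalty)
    aucs = []
    for tr, te in StratifiedKFold(k, shuffle=True, random_state=seed).split(x, y):
        if len(np.unique(y[te])) < 2:
            continue
        clf.fit(x[tr], y[tr])
        aucs.append(roc_auc_score(y[te], clf.predict_proba(x[te])[:, 1]))
    if not aucs:
        raise ValueError("no evaluable inner fold")
    return float(np.mean(aucs))


def bayes_opt_lr(x, y, budget: int = 25, seed: int = 0,
                 space: SearchSpace | None = None):
    """Tune (C, penalty) for a liblinear logistic regression by maximizing
    inner 5-fold CV AUC with a Gaussian-process expected-improvement loop.

    Returns (best_params dict, trial history).  budget = 0 falls back to the
    fixed default C = 1, penalty = l2 (logged via warning).
    """
    space = space or SearchSpace()
    if budget == 0:
        warnings.warn("optimization budget 0: using default C=1, penalty=l2",
                      stacklevel=2)
        return {"C": 1.0, "penalty": "l2"}, []
    if budget < 0:
        raise ValueError("budget must be >= 0")
    rng = np.random.default_rng(seed)
    lo, hi = space.log10_c
    n_init = min(budget, max(4, budget // 4))
    trials = []  # (log10_c, penalty_idx, auc)

    def observe(lc, pi):
        auc = _inner_cv_auc(x, y, lc, space.penalties[pi], seed)
        trials.append((lc, pi, auc))

    for _ in range(n_init):
        observe(rng.uniform(lo, hi), rng.integers(len(space.penalties)))
    gp = GaussianProcessRegressor(
        kernel=Matern(length_scale=[1.0, 1.0], nu=2.5)
        + WhiteKernel(noise_level=1e-4),
        normalize_y=True, random_state=seed)
    for _ in range(budget - n_init):
        z = np.array([[lc, pi] for lc, pi, _ in trials], dtype=float)
        f = np.array([a for _, _, a in trials])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(z, f)
        cand = np.column_stack([
            rng.uniform(lo, hi, 256),
            rng.integers(len(space.penalties), size=256).astype(float)])
        mu, sd = gp.predict(cand, return_std=True)
        best = f.max()
        sd = np.maximum(sd, 1e-9)
        imp = mu - best
        zz = imp / sd
        ei = imp * stats.norm.cdf(zz) + sd * stats.norm.pdf(zz)
        pick = cand[int(np.argmax(ei))]
        observe(float(pick[0]), int(pick[1]))
    lc, pi, _ = max(trials, key=lambda t: t[2])
    return {"C": float(10.0 ** lc), "penalty": space.penalties[pi]}, trials


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    experiment: ExperimentDef
    records: list[MetricRecord]
    fold_coefficients: list[np.ndarray] = field(default_factory=list)
    fold_params: list[dict] = field(default_factory=list)

    @property
    def variable_names(self):
        return self.experiment.variables

    def fold_aucs(self):
        return np.array([r.auc for r in self.records])

    def fold_f1s(self):
        return np.array([r.f1 for r in self.records])


def run_lr_experiment(exp: ExperimentDef | str, cohort: pd.DataFrame,
                      k: int = 10, seed: int = 0, budget: int = 25,
                      occlusion_model_values=None) -> ExperimentResult:
    """k-fold CV of one experiment on a cleaned cohort.

    Logistic experiments: per training fold, standardize predictors
    (fold-fit), tune (C, penalty) by Bayesian optimization on inner 5-fold
    AUC, refit on the fold, score the test fold; coefficients recorded per
    fold in the fold-fit standardized scale.  The ASTRAL comparator ranks by
    its raw score, with its F1 cut chosen on each training fold.
    """
    if isinstance(exp, str):
        exp = EXPERIMENTS[exp]
    cohort = cohort.reset_index(drop=True)
    y = dichotomize_mrs(cohort["mrs90"].to_numpy())
    if exp.name == "astral":
        scores = astral_scores(cohort).astype(float)

        def fit_predict(tr, te):
            cuts = np.unique(scores[tr])
            f1s = [f1_score(y[tr], scores[tr] >= c, zero_division=0)
                   for c in cuts]
            cut = cuts[int(np.argmax(f1s))]
            # squash to (0,1) around the fold cut so the 0.5 threshold in
            # `evaluate` reproduces `score >= cut`; ranking is unchanged
            return 1.0 / (1.0 + np.exp(-(scores[te] - cut + 0.5)))

        records = kfold_cv(np.zeros(len(y)), y, fit_predict, k=k, seed=seed)
        return ExperimentResult(exp, records)

    data = cohort.loc[:, list(exp.variables)].copy()
    if "occlusion" in exp.variables and exp.occlusion_source == "model":
        if occlusion_model_values is None:
            raise ValueError("lr experiments with occlusion_source='model' "
                             "need occlusion_model_values")
        vals = np.asarray(occlusion_model_values, dtype=float)
        if len(vals) != len(data):
            raise ValueError("occlusion_model_values must align with cohort")
        data["occlusion"] = vals
    x_all = data.to_numpy(dtype=float)
    result = ExperimentResult(exp, [])

    def fit_predict(tr, te):
        scaler = StandardScaler().fit(x_all[tr])
        with warnings.catch_warnings():
            # constant predictors scale to 0; coefficient stays ~0
            warnings.simplefilter("ignore", RuntimeWarning)
            xtr = np.nan_to_num(scaler.transform(x_all[tr]))
            xte = np.nan_to_num(scaler.transform(x_all[te]))
        params, _ = bayes_opt_lr(xtr, y[tr], budget=budget, seed=seed)
        clf = _make_lr(params["C"], params["penalty"])
        clf.fit(xtr, y[tr])
        result.fold_coefficients.append(clf.coef_[0].copy())
        result.fold_params.append(params)
        return clf.predict_proba(xte)[:, 1]

    result.records = kfold_cv(np.zeros(len(y)), y, fit_predict, k=k, seed=seed)
    return result


def predict_occlusion_feature(model, cta_mips) -> np.ndarray:
    """Per-patient occlusion probability from a trained occlusion classifier,
    for use as the occlusion variable (probability form)."""
    arr = np.asarray(cta_mips, dtype=np.float32)
    if arr.ndim != 4:
        raise ValueError("expected a (N, C, rows, cols) MIP batch")
    probs = model.predict_proba(arr)
    return np.asarray(probs, dtype=float)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def normalized_coefficients(fold_coefficients, names) -> pd.DataFrame:
    """Per-variable mean and std of |coefficient| / sum(|coefficients|)
    across folds, sorted by decreasing mean.  All-zero folds are excluded
    with a warning."""
    rows = []
    for coefs in fold_coefficients:
        coefs = np.abs(np.asarray(coefs, dtype=float))
        if len(coefs) != len(names):
            raise ValueError("coefficient vector does not match names")
        if coefs.sum() == 0:
            warnings.warn("all-zero coefficient fold excluded", stacklevel=2)
            continue
        rows.append(coefs / coefs.sum())
    if not rows:
        raise ValueError("no usable folds")
    mat = np.stack(rows)
    out = pd.DataFrame({
        "variable": list(names),
        "mean": mat.mean(axis=0),
        "std": mat.std(axis=0, ddof=1) if len(rows) > 1 else np.zeros(mat.shape[1]),
    }).sort_values("mean", ascending=False).reset_index(drop=True)
    return out


def paired_t_test(metric_a, metric_b, alpha: float = 0.05):
    """Two-sided paired t-test on fold-aligned metric vectors.

    Returns (p_value, significant flag, direction), direction in
    {'a_higher', 'b_higher', 'equal'} by mean.  Conventions: all differences
    exactly zero -> p = 1; zero variance with nonzero mean -> p = 0 with a
    warning.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two fold-aligned vectors of length >= 2")
    d = a - b
    mean = d.mean()
    direction = "a_higher" if mean > 0 else "b_higher" if mean < 0 else "equal"
    if np.all(d == 0):
        return 1.0, False, "equal"
    if np.allclose(d.std(ddof=1), 0.0):
        warnings.warn("zero-variance nonzero differences: p reported as 0",
                      stacklevel=2)
        return 0.0, True, direction
    p = float(stats.ttest_rel(a, b).pvalue)
    return p, p < alpha, direction


def vif(design, names=None, flag_threshold: float = 10.0) -> pd.DataFrame:
    """Variance inflation factor 1/(1-R^2_j) per predictor of a standardized
    design matrix; perfect collinearity reports inf; VIF > 10 is flagged."""
    x = np.asarray(design, dtype=float)
    if x.ndim != 2 or x.shape[0] <= x.shape[1]:
        raise ValueError("need an n x p matrix with n > p")
    if np.any(x.std(axis=0) == 0):
        raise ValueError("constant column in design matrix")
    names = list(names) if names is not None else [f"x{j}" for j in range(x.shape[1])]
    vals = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j in range(x.shape[1]):
            v = variance_inflation_factor(x, j)
            vals.append(np.inf if (not np.isfinite(v) or v > 1e12) else float(v))
    return pd.DataFrame({"variable": names, "vif": vals,
                         "flagged": [v > flag_threshold for v in vals]})


# ---------------------------------------------------------------------------
# comparison report
# ---------------------------------------------------------------------------

def comparison_report(results: dict[str, ExperimentResult],
                      alpha: float = 0.05):
    """Per-experiment fold metrics plus a pairwise t-test matrix on fold
    AUCs.  Returns (metrics DataFrame, t-test DataFrame)."""
    rows = []
    for name, res in results.items():
        aucs, f1s = res.fold_aucs(), res.fold_f1s()
        rows.append({"experiment": name, "auc_mean": aucs.mean(),
                     "auc_std": aucs.std(ddof=1) if len(aucs) > 1 else 0.0,
                     "f1_mean": f1s.mean(),
                     "f1_std": f1s.std(ddof=1) if len(f1s) > 1 else 0.0,
                     "folds": len(aucs)})
    metrics = pd.DataFrame(rows)
    names = list(results)
    trows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            p, sig, direction = paired_t_test(results[a].fold_aucs(),
                                              results[b].fold_aucs(), alpha)
            trows.append({"experiment_a": a, "experiment_b": b, "p_value": p,
                          "significant": sig, "direction": direction})
    return metrics, pd.DataFrame(trows)


def export_report(results: dict[str, ExperimentResult], out_prefix: str,
                  alpha: float = 0.05):
    """Write the comparison report as tab-delimited text:
    <prefix>_metrics.tsv and <prefix>_ttests.tsv."""
    metrics, ttests = comparison_report(results, alpha)
    metrics.to_csv(f"{out_prefix}_metrics.tsv", sep="\t", index=False)
    ttests.to_csv(f"{out_prefix}_ttests.tsv", sep="\t", index=False)
    return metrics, ttests
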