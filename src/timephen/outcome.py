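"""Patient-level aggregation and the clinical outcome layer.

Per-core phenotype assignments are collapsed to patient-level *carriage*
indicators (patient has >=1 core of a phenotype) and *purity* flags (all
analyzed cores share it).  Patients lost to follow-up within 36 months
without relapse are excluded.  A reference logistic model on the routine
risk factors (FIGO stage, grade, LVSI) is compared against an
immune-optimized model selected by exhaustive subset search: every non-empty
combination of candidate covariates is fitted and scored by repeated
stratified two-fold cross-validated misclassification (probability cut 0.5),
and the subset with the lowest mean error wins (ties: fewer features, then
lexicographic).  Models are compared by ROC AUC, Youden-index
stratification (sens/spec/PPV/NPV), paired patient-level bootstrap
outperformance counts, and Kaplan-Meier relapse-free survival of the
high/low-risk strata.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import rankdata

from .cell_data import Cohort
from .synthetic import ARCHETYPE_NAMES

FIGO_CODE = {"IA": 0, "IB": 1, "II": 2}
REFERENCE_COVARIATES = ("figo", "grade", "lvsi")
CARRIAGE_COVARIATES = tuple(f"carriage_{n}" for n in ARCHETYPE_NAMES)


# --------------------------------------------------------------------------
# patient aggregation
# --------------------------------------------------------------------------


def aggregate_patients(assignments: pd.DataFrame, cohort: Cohort) -> pd.DataFrame:
    """Patient-level feature table from per-core phenotype assignments.

    Encodes FIGO as ordered integer (IA=0, IB=1, II=2), grade as binary
    (G2=1), LVSI as binary; adds carriage and purity indicators per
    phenotype.  Patients with no assigned cores are dropped with a warning.
    """
    cores = cohort.cores[["core_id", "patient_id"]]
    joined = assignments.merge(cores, on="core_id", how="inner")

    rows = []
    for pid, grp in joined.groupby("patient_id", sort=False):
        phenos = list(grp["semantic_name"])
        row = {"patient_id": pid, "n_cores": len(phenos)}
        for name in ARCHETYPE_NAMES:
            carried = name in phenos
            row[f"carriage_{name}"] = int(carried)
            row[f"purity_{name}"] = int(carried and all(p == name for p in phenos))
        rows.append(row)
    feats = pd.DataFrame(rows)

    clin = cohort.patients.copy()
    missing = set(clin["patient_id"]) - set(feats["patient_id"])
    if missing:
        warnings.warn(f"{len(missing)} patients have no assigned cores; excluded")
    out = feats.merge(clin, on="patient_id", how="inner")
    out["figo"] = out["figo_stage"].map(FIGO_CODE)
    out["grade"] = (out["grade"] == "G2").astype(int)
    out["lvsi"] = out["lvsi"].astype(int)
    return out


def filter_followup(patients: pd.DataFrame, min_months: float = 36.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop non-relapsed patients with follow-up shorter than ``min_months``.

    Relapsed patients are always retained.  Returns (retained, excluded).
    """
    short = (~patients["relapse"].astype(bool)) & (patients["followup_months"] < min_months)
    return patients[~short].copy(), patients[short].copy()


# --------------------------------------------------------------------------
# logistic regression (IRLS)
# --------------------------------------------------------------------------


@dataclass
class LogisticFit:
    features: tuple[str, ...]
    coef: pd.Series  # index: intercept + features
    se: pd.Series
    converged: bool
    ridged: bool
    n_iter: int

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        X = np.column_stack(
            [np.ones(len(table))] + [table[f].to_numpy(dtype=float) for f in self.features]
        )
        return 1.0 / (1.0 + np.exp(-X @ self.coef.to_numpy()))


def _irls(X: np.ndarray, y: np.ndarray, ridge: float, tol: float = 1e-8, max_iter: int = 100):
    beta = np.zeros(X.shape[1])
    penalty = ridge * np.eye(X.shape[1])
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1.0 - p), 1e-10)
        XtW = X.T * w
        H = XtW @ X + penalty
        g = X.T @ (y - p) - ridge * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta, H, True, it
    return beta, H, False, max_iter


def fit_logistic(table: pd.DataFrame, outcome: str | np.ndarray, features) -> LogisticFit:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    Converges when the largest coefficient change drops below 1e-8 (<=100
    iterations).  Quasi-separated fits that fail to converge or produce a
    singular information matrix are refitted with a tiny ridge (1e-6) and
    flagged.  An all-one-class outcome is an error.
    """
    features = tuple(features)
    y = (table[outcome] if isinstance(outcome, str) else pd.Series(outcome)).to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    X = np.column_stack([np.ones(len(y))] + [table[f].to_numpy(dtype=float) for f in features])

    ridged = False
    try:
        beta, H, converged, n_iter = _irls(X, y, ridge=0.0)
        if not converged or not np.isfinite(beta).all():
            raise np.linalg.LinAlgError
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        ridged = True
        beta, H, converged, n_iter = _irls(X, y, ridge=1e-6)
        cov = np.linalg.pinv(H)

    idx = ["intercept"] + list(features)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return LogisticFit(
        features=features,
        coef=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        converged=converged,
        ridged=ridged,
        n_iter=n_iter,
    )


# --------------------------------------------------------------------------
# exhaustive subset search with repeated stratified CV
# --------------------------------------------------------------------------


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    assignment = np.empty(len(y), dtype=np.int64)
    for cls in (0, 1):
        idx = np.nonzero(y == cls)[0]
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    return [np.nonzero(assignment == f)[0] for f in range(folds)]


def cv_misclassification(
    table: pd.DataFrame,
    outcome: str,
    features,
    folds: int = 2,
    repeats: int = 20,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Mean held-out misclassification (cut-off 0.5) over repeats x folds.

    Folds are stratified by outcome; a training fold that still ends up
    single-class triggers a refold with fresh randomness (logged).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    y = table[outcome].to_numpy(dtype=float)
    errors = []
    for _ in range(repeats):
        for _attempt in range(10):
            fold_idx = _stratified_folds(y, folds, rng)
            if all(len(np.unique(y[np.concatenate(fold_idx[:f] + fold_idx[f + 1:])])) == 2
                   for f in range(folds)):
                break
            warnings.warn("single-class training fold; refolding with new seed")
        for f in range(folds):
            test = fold_idx[f]
            train = np.concatenate(fold_idx[:f] + fold_idx[f + 1:])
            fit = fit_logistic(table.iloc[train], outcome, features)
            pred = fit.predict_proba(table.iloc[test]) >= 0.5
            errors.append(float((pred != (y[test] == 1)).mean()))
    return float(np.mean(errors))


@dataclass
class SearchResult:
    best_features: tuple[str, ...]
    best_error: float
    table: pd.DataFrame  # subset, size, mean_error


def exhaustive_search(
    table: pd.DataFrame,
    outcome: str,
    candidates,
    folds: int = 2,
    repeats: int = 20,
    rng: np.random.Generator | int | None = None,
) -> SearchResult:
    """Evaluate every non-empty candidate subset by repeated-CV error.

    Ties on the minimum mean error are broken toward fewer features, then
    lexicographically.  Candidate sets above 20 features are refused.
    """
    candidates = tuple(candidates)
    if len(candidates) > 20:
        raise ValueError("more than 20 candidate features (2^20 guard)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    rows = []
    for size in range(1, len(candidates) + 1):
        for subset in combinations(candidates, size):
            err = cv_misclassification(
                table, outcome, subset, folds=folds, repeats=repeats, rng=rng
            )
            rows.append({"subset": subset, "size": size, "mean_error": err})
    result = pd.DataFrame(rows)
    best = result.sort_values(
        by=["mean_error", "size", "subset"], kind="mergesort"
    ).iloc[0]
    return SearchResult(
        best_features=tuple(best["subset"]), best_error=float(best["mean_error"]), table=result
    )


# --------------------------------------------------------------------------
# ROC / Youden / predictive values
# --------------------------------------------------------------------------


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """AUC via the Mann-Whitney rank identity (half credit for ties).

    Also returns ROC points (fpr, tpr, threshold) at every distinct score.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    pts = [{"threshold": np.inf, "fpr": 0.0, "tpr": 0.0}]
    for t in np.unique(scores)[::-1]:
        pred = scores >= t
        pts.append(
            {
                "threshold": float(t),
                "fpr": float((pred & (labels == 0)).sum() / n0),
                "tpr": float((pred & (labels == 1)).sum() / n1),
            }
        )
    return float(auc), pd.DataFrame(pts)


@dataclass
class Stratification:
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    confusion: dict[str, int] = field(default_factory=dict)


def youden_stratify(scores, labels) -> Stratification:
    """Cut-off maximizing Youden's J = sens + spec - 1 (ties: higher spec)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")

    best = None
    # candidate cut-offs: every distinct score, plus +inf (classify none positive)
    for t in list(np.unique(scores)) + [np.inf]:
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        sens = tp / n1
        spec = (n0 - fp) / n0
        j = sens + spec - 1.0
        key = (j, spec)
        if best is None or key > best[0]:
            best = (key, t, tp, fp)
    (_, _), cutoff, tp, fp = best
    fn, tn = n1 - tp, n0 - fp
    return Stratification(
        cutoff=float(cutoff),
        sensitivity=tp / n1,
        specificity=tn / n0,
        ppv=tp / (tp + fp) if tp + fp else float("nan"),
        npv=tn / (tn + fn) if tn + fn else float("nan"),
        confusion={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    )


def ppv_npv_from_rates(sens: float, spec: float, prevalence: float) -> tuple[float, float]:
    """Bayes-theorem predictive values from sensitivity, specificity, prevalence."""
    for v in (sens, spec, prevalence):
        if not 0.0 <= v <= 1.0:
            raise ValueError("arguments must be in [0, 1]")
    ppv_den = sens * prevalence + (1.0 - spec) * (1.0 - prevalence)
    npv_den = spec * (1.0 - prevalence) + (1.0 - sens) * prevalence
    ppv = sens * prevalence / ppv_den if ppv_den > 0 else float("nan")
    npv = spec * (1.0 - prevalence) / npv_den if npv_den > 0 else float("nan")
    return ppv, npv


# --------------------------------------------------------------------------
# paired bootstrap model comparison
# --------------------------------------------------------------------------


@dataclass
class BootstrapComparison:
    B: int
    a_wins: int  # strict AUC_A > AUC_B
    b_wins: int
    ties: int
    auc_a_p5: float
    auc_a_p95: float
    auc_b_p5: float
    auc_b_p95: float


def _auc_rows(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise rank AUC for matrices of scores/labels (ties half-credit)."""
    ranks = rankdata(scores, axis=1)
    n1 = labels.sum(axis=1)
    n0 = labels.shape[1] - n1
    pos_rank_sum = (ranks * labels).sum(axis=1)
    return (pos_rank_sum - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def bootstrap_compare(
    scores_a,
    scores_b,
    labels,
    B: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> BootstrapComparison:
    """Paired patient-level bootstrap of two models' AUCs.

    Each replicate resamples patients with replacement (redrawn until both
    classes are present), computes both AUCs on the same resample, and
    counts strict outperformance; exact AUC ties are excluded from both
    win counts.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(int)
    n = len(y)

    idx = rng.integers(0, n, size=(B, n))
    bad = np.nonzero((y[idx].sum(axis=1) == 0) | (y[idx].sum(axis=1) == n))[0]
    while bad.size:
        idx[bad] = rng.integers(0, n, size=(bad.size, n))
        s = y[idx[bad]].sum(axis=1)
        bad = bad[(s == 0) | (s == len(y))]

    yb = y[idx]
    auc_a = _auc_rows(sa[idx], yb)
    auc_b = _auc_rows(sb[idx], yb)
    a_wins = int((auc_a > auc_b).sum())
    b_wins = int((auc_b > auc_a).sum())
    return BootstrapComparison(
        B=B,
        a_wins=a_wins,
        b_wins=b_wins,
        ties=B - a_wins - b_wins,
        auc_a_p5=float(np.percentile(auc_a, 5)),
        auc_a_p95=float(np.percentile(auc_a, 95)),
        auc_b_p5=float(np.percentile(auc_b, 5)),
        auc_b_p95=float(np.percentile(auc_b, 95)),
    )


# --------------------------------------------------------------------------
# Kaplan-Meier and enrichment
# --------------------------------------------------------------------------


def km_estimate(times, events, groups) -> tuple[dict, float, float]:
    """Product-limit survival per group plus a two-group log-rank test.

    Returns ``(curves, chi2, p)`` where curves maps group label to a
    DataFrame with ``time`` and ``survival`` columns.  With one group the
    log-rank statistic is NaN.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    groups = np.asarray(groups)
    if (times < 0).any():
        raise ValueError("negative times")

    curves = {}
    for g in np.unique(groups):
        mask = groups == g
        if not mask.any():
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})

    labels = np.unique(groups)
    if len(labels) == 2:
        m = groups == labels[0]
        res = logrank_test(times[m], times[~m], events[m], events[~m])
        return curves, float(res.test_statistic), float(res.p_value)
    return curves, float("nan"), float("nan")


def _log_table_prob(table: np.ndarray) -> float:
    """Log hypergeometric probability of an r x c table given its margins."""
    n = table.sum()
    return (
        gammaln(table.sum(axis=1) + 1).sum()
        + gammaln(table.sum(axis=0) + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


@dataclass
class EnrichmentResult:
    p_value: float
    method: str  # "exact" (2x2) or "monte_carlo"


def enrichment_test(
    table, n_mc: int = 20000, rng: np.random.Generator | int | None = None
) -> EnrichmentResult:
    """Fisher exact test of independence for a contingency table.

    2x2 tables use the exact hypergeometric test; larger tables use a seeded
    Monte Carlo over tables with fixed margins (probability-based two-sided
    rule), flagged in the ``method`` field.
    """
    from scipy import stats

    table = np.asarray(table, dtype=np.int64)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if table.sum() == 0:
        raise ValueError("all-zero table")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("table has an all-zero row or column")

    if table.shape == (2, 2):
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return EnrichmentResult(p_value=float(p), method="exact")

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    dist = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    obs_logp = _log_table_prob(table)
    samples = dist.rvs(n_mc, random_state=rng)
    logps = np.array([_log_table_prob(s) for s in samples])
    hits = int((logps <= obs_logp + 1e-9).sum())
    return EnrichmentResult(p_value=(hits + 1) / (n_mc + 1), method="monte_carlo")


# --------------------------------------------------------------------------
# subgroup evaluation
# --------------------------------------------------------------------------


def subgroup_evaluate(
    patients: pd.DataFrame,
    fit_a: LogisticFit,
    fit_b: LogisticFit,
    stratifier: str,
    outcome: str = "relapse",
    min_events: int = 5,
) -> pd.DataFrame:
    """Refit-free per-stratum AUC of two fixed models.

    Patients are split by the stratifier column (unknown values form their
    own stratum); strata with a single outcome class are skipped with a
    flag, and strata with fewer than ``min_events`` events are flagged
    low-power.
    """
    rows = []
    for level, grp in patients.groupby(stratifier, sort=True):
        y = grp[outcome].astype(int).to_numpy()
        events = int(y.sum())
        if events == 0 or events == len(y):
            rows.append(
                {"stratum": level, "n": len(grp), "events": events,
                 "auc_a": float("nan"), "auc_b": float("nan"), "flag": "skipped_one_class"}
            )
            continue
        auc_a, _ = roc_auc(fit_a.predict_proba(grp), y)
        auc_b, _ = roc_auc(fit_b.predict_proba(grp), y)
        rows.append(
            {"stratum": level, "n": len(grp), "events": events,
             "auc_a": auc_a, "auc_b": auc_b,
             "flag": "low_power" if events < min_events else ""}
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# end-to-end model comparison
# --------------------------------------------------------------------------


@dataclass
class ModelReport:
    features: tuple[str, ...]
    coef: dict[str, float]
    cv_error: float | None
    auc: float
    stratification: Stratification


def compare_models(
    patients: pd.DataFrame,
    outcome: str = "relapse",
    reference: tuple[str, ...] = REFERENCE_COVARIATES,
    candidates: tuple[str, ...] | None = None,
    folds: int = 2,
    repeats: int = 20,
    B: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> tuple[ModelReport, ModelReport, BootstrapComparison, SearchResult]:
    """Reference vs immune-optimized model comparison on a patient table.

    Returns (reference report, optimized report, bootstrap comparison,
    search result).  Candidates default to the reference covariates plus
    the five phenotype carriage indicators.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    candidates = candidates or (tuple(reference) + CARRIAGE_COVARIATES)
    table = patients.copy()
    table[outcome] = table[outcome].astype(int)

    search = exhaustive_search(table, outcome, candidates, folds=folds, repeats=repeats, rng=rng)
    ref_err = cv_misclassification(table, outcome, reference, folds=folds, repeats=repeats, rng=rng)

    def _report(feats, cv_error):
        fit = fit_logistic(table, outcome, feats)
        scores = fit.predict_proba(table)
        auc, _ = roc_auc(scores, table[outcome])
        strat = youden_stratify(scores, table[outcome])
        return ModelReport(
            features=tuple(feats),
            coef=fit.coef.to_dict(),
            cv_error=cv_error,
            auc=auc,
            stratification=strat,
        ), scores

    ref_report, ref_scores = _report(reference, ref_err)
    opt_report, opt_scores = _report(search.best_features, search.best_error)
    boot = bootstrap_compare(opt_scores, ref_scores, table[outcome], B=B, rng=rng)
    return ref_report, opt_report, boot, search
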