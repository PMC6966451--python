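"""TAD-based prognostic modeling with repeated LASSO Cox regression.

Pipeline: cohorts with >= 100 patients and >= 10% lethal outcomes are
modeled from binary features (CNV presence in enriched TADs, age above the
training median, sex). Each repetition splits patients 2/3 train : 1/3
test, fits an L1-penalized Cox model with the regularization strength
chosen by 5-fold cross-validation, keeps the ten features with the largest
|coefficient|, and scores Harrell's concordance index (c-index) on the
test third. Across K repetitions, each run i receives a weight

    w_i = (1/K) * exp(ln2 * devCI_i / 0.1)   if CI_i >= 0.5, else 0

with devCI_i = CI_i - mean(CI): a run 0.1 of c-index above the mean counts
twice as much. Normalized weights w'_i aggregate per-feature selection
indicators into P_j = sum_i w'_i * I_{j,i}; the ten features with the
largest P_j enter an unpenalized Cox model pruned by backward elimination
(Wald p <= 0.05), whose coefficients define per-patient risk scores,
median-split risk groups, and Kaplan-Meier / log-rank stratification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv
from statsmodels.stats.multitest import multipletests

from .genome_io import SurvivalRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ModelRun",
    "FinalModel",
    "RiskStratification",
    "eligible_cohorts",
    "encode_features",
    "concordance_index",
    "run_repeated_models",
    "aggregate_features",
    "fit_final_model",
    "stratify_and_test",
    "evaluate_external",
    "reliability_flag",
]


@dataclass
class ModelRun:
    """One train/test repetition of the penalized Cox procedure."""

    index: int
    train_ids: list[str]
    test_ids: list[str]
    selected: tuple[str, ...]
    coefficients: pd.Series
    alpha: float
    ci: float
    failed: bool = False

    def __post_init__(self):
        if not self.failed:
            if len(self.selected) > 10:
                raise ValueError("at most ten selected features per run")
            if not (0.0 <= self.ci <= 1.0):
                raise ValueError("c-index out of [0, 1]")


@dataclass
class FinalModel:
    """Backward-eliminated Cox model over the aggregated top features."""

    features: list[str]
    coefficients: pd.Series
    hazard_ratios: pd.Series
    p_values: pd.Series
    q_values: pd.Series
    empty: bool = False

    def risk_scores(self, X: pd.DataFrame) -> pd.Series:
        missing = [f for f in self.features if f not in X.columns]
        if missing:
            raise ValueError(f"missing feature column(s): {missing}")
        if not self.features:
            raise ValueError("model has no features")
        return X[self.features].astype(float) @ self.coefficients


@dataclass
class RiskStratification:
    """Median-split risk groups with Kaplan-Meier and log-rank results."""

    scores: pd.Series
    groups: pd.Series  # "high" | "low"
    logrank_stat: float
    logrank_p: float
    km_tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def _records_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "cancer_type": [r.cancer_type for r in records],
            "time": [r.time for r in records],
            "event": [r.event for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
        }
    ).set_index("patient_id")


def eligible_cohorts(
    records: list[SurvivalRecord],
    patients_with_cnvs: set[str] | None = None,
    min_patients: int = 100,
    min_event_rate: float = 0.10,
) -> list[str]:
    """Cancer types with >= 100 patients and >= 10% lethal outcomes.

    Patients without any filtered CNVs are excluded before counting when
    ``patients_with_cnvs`` is given.
    """
    df = _records_frame(records)
    if patients_with_cnvs is not None:
        df = df[df.index.isin(patients_with_cnvs)]
    out = []
    for ctype, sub in df.groupby("cancer_type", sort=True):
        if len(sub) >= min_patients and sub["event"].mean() >= min_event_rate:
            out.append(ctype)
    return out


def encode_features(
    records: list[SurvivalRecord],
    tad_matrix: pd.DataFrame,
    median_age: float | None = None,
    drop_constant: bool = True,
) -> pd.DataFrame:
    """Binary feature table: enriched-TAD presence columns + age_high + sex.

    ``age_high`` is 1 iff age is strictly larger than ``median_age`` (the
    training-set median; defaults to the median over ``records``); sex is
    1 for females, 0 for males. Constant columns are dropped with a
    warning.
    """
    df = _records_frame(records)
    df = df[df.index.isin(tad_matrix.index)]
    X = tad_matrix.loc[df.index].astype(np.int8).copy()
    if median_age is None:
        median_age = float(df["age"].median())
    X["age_high"] = (df["age"] > median_age).astype(np.int8)
    X["sex"] = (df["sex"] == "female").astype(np.int8)
    if drop_constant:
        constant = [c for c in X.columns if X[c].nunique() == 1]
        if constant:
            logger.warning("dropping constant feature column(s): %s", constant)
            X = X.drop(columns=constant)
    return X


def concordance_index(scores, records: list[SurvivalRecord] | pd.DataFrame) -> float:
    """Harrell's c-index over comparable pairs; score ties count 0.5.

    Higher scores must indicate higher risk (shorter survival). Raises if
    there is no comparable pair.
    """
    df = records if isinstance(records, pd.DataFrame) else _records_frame(records)
    scores = np.asarray(pd.Series(scores).loc[df.index] if isinstance(scores, pd.Series) else scores,
                        dtype=float)
    event = df["event"].to_numpy(dtype=bool)
    time = df["time"].to_numpy(dtype=float)
    if not event.any():
        raise ValueError("no comparable pairs: no events")
    try:
        ci, concordant, discordant, tied_risk, _ = concordance_index_censored(event, time, scores)
    except Exception as exc:
        raise ValueError(f"no comparable pairs ({exc})") from None
    if concordant + discordant + tied_risk == 0:
        raise ValueError("no comparable pairs")
    return float(ci)


def _top_by_abs(coefs: pd.Series, k: int = 10) -> tuple[pd.Series, tuple[str, ...]]:
    nz = coefs[coefs != 0.0]
    order = sorted(nz.index, key=lambda f: (-abs(nz[f]), f))[:k]
    return nz.loc[order], tuple(order)


def _fit_coxnet_run(
    X_tr: pd.DataFrame,
    y_tr,
    rng: np.random.Generator,
    folds: int,
    top: int,
    n_alphas: int = 25,
) -> tuple[pd.Series, tuple[str, ...], float]:
    """L1 Cox path fit; lambda by minimum cross-validated prediction error.

    The path is computed on the full training set; each alpha is scored by
    held-out concordance over ``folds`` folds and the alpha with the best
    mean score ("minimum prediction error") is retained. If the optimizer
    fails to converge, features are ranked by their order of appearance in
    the regularization path instead.
    """
    Xv = X_tr.to_numpy(dtype=float)
    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas,
                                  alpha_min_ratio=0.01, fit_baseline_model=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        path.fit(Xv, y_tr)
    alphas = np.asarray(path.alphas_)

    n = len(X_tr)
    idx = rng.permutation(n)
    fold_sizes = np.full(folds, n // folds)
    fold_sizes[: n % folds] += 1
    scores = np.zeros((folds, len(alphas)))
    valid = np.ones(len(alphas), dtype=bool)
    pos = 0
    for f, fs in enumerate(fold_sizes):
        test_idx = idx[pos : pos + fs]
        train_idx = np.setdiff1d(idx, test_idx)
        pos += fs
        ev = y_tr["event"][test_idx]
        if not ev.any() or not y_tr["event"][train_idx].any():
            scores[f] = np.nan
            continue
        est = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(Xv[train_idx], y_tr[train_idx])
        fitted = np.asarray(est.alphas_)
        for a, alpha in enumerate(alphas):
            j = np.argmin(np.abs(fitted - alpha))
            if not np.isclose(fitted[j], alpha, rtol=1e-3):
                valid[a] = False
                continue
            pred = Xv[test_idx] @ est.coef_[:, j]
            ci = concordance_index_censored(ev, y_tr["time"][test_idx], pred)[0]
            scores[f, a] = ci
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean_scores = np.nanmean(scores, axis=0)
    mean_scores[~valid] = -np.inf
    if not np.isfinite(mean_scores).any():
        raise RuntimeError("cross-validation failed on every fold")
    best = int(np.nanargmax(mean_scores))
    alpha = float(alphas[best])
    coefs = pd.Series(path.coef_[:, best], index=X_tr.columns)
    if (coefs != 0).sum() == 0:
        # fully shrunk model: fall back to the order of appearance in the
        # regularization path (first alpha at which each coefficient
        # becomes nonzero)
        appear = np.argmax(path.coef_ != 0, axis=1).astype(float)
        never = ~(path.coef_ != 0).any(axis=1)
        appear[never] = np.inf
        order = sorted(
            [f for f, a in zip(X_tr.columns, appear) if np.isfinite(a)],
            key=lambda f: (appear[X_tr.columns.get_loc(f)], f),
        )[:top]
        sel = tuple(order)
        last = pd.Series(path.coef_[:, -1], index=X_tr.columns)
        return last.loc[list(sel)] if sel else pd.Series(dtype=float), sel, alpha
    coefs_top, sel = _top_by_abs(coefs, top)
    return coefs_top, sel, alpha


def run_repeated_models(
    features: pd.DataFrame,
    records: list[SurvivalRecord],
    K: int = 1000,
    split: float = 2 / 3,
    folds: int = 5,
    top: int = 10,
    seed: int | np.random.Generator = 0,
    feature_selector=None,
) -> list[ModelRun]:
    """Repeat the split / LASSO Cox / c-index procedure K times.

    ``feature_selector(train_ids) -> list of column names`` optionally
    recomputes the eligible feature set per training split (the enrichment
    recomputation hook); by default all columns are candidates. Runs whose
    training set has no events, or whose optimizer fails, are recorded as
    failed and excluded from aggregation.
    """
    master = np.random.default_rng(seed)
    df = _records_frame(records)
    df = df.loc[features.index]
    y_all = Surv.from_arrays(event=df["event"].astype(bool), time=df["time"])
    ids = np.asarray(features.index)
    runs: list[ModelRun] = []
    n_train = int(round(split * len(ids)))
    for i in range(K):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        perm = rng.permutation(len(ids))
        tr, te = perm[:n_train], perm[n_train:]
        train_ids, test_ids = ids[tr].tolist(), ids[te].tolist()
        cols = list(features.columns)
        if feature_selector is not None:
            cols = list(feature_selector(train_ids))
        X_tr = features.iloc[tr][cols]
        keep = [c for c in cols if X_tr[c].nunique() > 1]
        X_tr = X_tr[keep]
        y_tr, y_te = y_all[tr], y_all[te]
        failed_run = ModelRun(i, train_ids, test_ids, (), pd.Series(dtype=float),
                              np.nan, np.nan, failed=True)
        if not y_tr["event"].any() or not y_te["event"].any() or not keep:
            logger.info("run %d failed: degenerate split", i)
            runs.append(failed_run)
            continue
        try:
            coefs, sel, alpha = _fit_coxnet_run(X_tr, y_tr, rng, folds, top)
        except Exception as exc:  # noqa: BLE001 - record and move on
            logger.info("run %d failed: %s", i, exc)
            runs.append(failed_run)
            continue
        if sel:
            pred = features.iloc[te][list(sel)].to_numpy(dtype=float) @ coefs.loc[list(sel)].to_numpy()
        else:
            pred = np.zeros(len(te))
        ci = concordance_index_censored(y_te["event"], y_te["time"], pred)[0]
        runs.append(ModelRun(i, train_ids, test_ids, sel, coefs, alpha, float(ci)))
    return runs


def aggregate_features(runs: list[ModelRun]) -> pd.DataFrame:
    """Aggregate per-run selections into normalized feature weights P_j.

    K is the number of completed runs. Runs with CI < 0.5 get zero weight;
    all-zero weights raise ("no informative runs"). Returns a frame
    (feature, P) sorted by decreasing P with ties broken by name.
    """
    done = [r for r in runs if not r.failed]
    if not done:
        raise ValueError("no completed runs")
    K = len(done)
    cis = np.array([r.ci for r in done])
    dev = cis - cis.mean()
    w = np.where(cis >= 0.5, (1.0 / K) * np.exp(np.log(2.0) * dev / 0.1), 0.0)
    if w.sum() == 0:
        raise ValueError("no informative runs: every c-index is below 0.5")
    w_norm = w / w.sum()
    universe = sorted({f for r in done for f in r.selected})
    P = {}
    for f in universe:
        P[f] = float(sum(wi for wi, r in zip(w_norm, done) if f in r.selected))
    out = pd.DataFrame({"feature": universe, "P": [P[f] for f in universe]})
    out = out.sort_values(["P", "feature"], ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)


def _fit_cox(X: pd.DataFrame, df: pd.DataFrame, penalizer: float = 0.0) -> CoxPHFitter:
    data = X.astype(float).copy()
    data["time"] = df["time"]
    data["event"] = df["event"]
    cph = CoxPHFitter(penalizer=penalizer)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(data, duration_col="time", event_col="event")
    return cph


def fit_final_model(
    features: pd.DataFrame,
    records: list[SurvivalRecord],
    candidates: list[str] | None = None,
    p_threshold: float = 0.05,
) -> FinalModel:
    """Unpenalized Cox fit with backward stepwise elimination.

    Candidates (<= 10) are iteratively pruned by dropping the feature with
    the largest Wald p-value until all remaining p <= 0.05. Exactly
    duplicated columns are reduced to the alphabetically first before
    fitting. Reported q-values are Benjamini-Hochberg adjusted; if the
    elimination empties the model an empty, flagged FinalModel is
    returned.
    """
    df = _records_frame(records).loc[features.index]
    cols = list(candidates) if candidates is not None else list(features.columns)
    if len(cols) > 10:
        raise ValueError("at most ten candidate features")
    # deterministic collinearity guard: drop exact duplicates, keep first by name
    cols = sorted(cols)
    seen: dict[tuple, str] = {}
    kept = []
    for c in cols:
        key = tuple(features[c].to_numpy().tolist())
        if key in seen:
            logger.warning("dropping %s: identical to %s", c, seen[key])
            continue
        seen[key] = c
        kept.append(c)
    cols = [c for c in kept if features[c].nunique() > 1]

    while cols:
        try:
            cph = _fit_cox(features[cols], df)
        except Exception:  # convergence trouble: stabilize with a tiny ridge
            cph = _fit_cox(features[cols], df, penalizer=1e-6)
        p = cph.summary["p"]
        worst = sorted(p.index, key=lambda f: (-p[f], f))[0]
        if p[worst] <= p_threshold:
            break
        cols = [c for c in cols if c != worst]
    if not cols:
        empty = pd.Series(dtype=float)
        return FinalModel([], empty, empty, empty, empty, empty=True)
    summary = cph.summary
    pvals = summary["p"]
    qvals = pd.Series(multipletests(pvals.values, method="fdr_bh")[1], index=pvals.index)
    return FinalModel(
        features=cols,
        coefficients=summary["coef"],
        hazard_ratios=summary["exp(coef)"],
        p_values=pvals,
        q_values=qvals,
    )


def stratify_and_test(model: FinalModel, features: pd.DataFrame,
                      records: list[SurvivalRecord]) -> RiskStratification:
    """Median-split risk stratification with Kaplan-Meier and log-rank test.

    Risk score = sum of coefficient * feature value; scores <= median go
    to the low-risk group. Refuses when every score is identical.
    """
    if not model.features:
        raise ValueError("model has no features; stratification refused")
    df = _records_frame(records).loc[features.index]
    scores = model.risk_scores(features)
    if scores.nunique() == 1:
        raise ValueError("all risk scores identical; stratification refused")
    median = scores.median()
    groups = pd.Series(np.where(scores <= median, "low", "high"), index=scores.index)
    km_tables = {}
    for g in ("low", "high"):
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(df.loc[mask, "time"], df.loc[mask, "event"], label=g)
        km_tables[g] = kmf.survival_function_
    lo, hi = groups == "low", groups == "high"
    res = logrank_test(df.loc[lo, "time"], df.loc[hi, "time"],
                       event_observed_A=df.loc[lo, "event"],
                       event_observed_B=df.loc[hi, "event"])
    return RiskStratification(
        scores=scores,
        groups=groups,
        logrank_stat=float(res.test_statistic),
        logrank_p=float(res.p_value),
        km_tables=km_tables,
    )


def evaluate_external(model: FinalModel, features: pd.DataFrame,
                      records: list[SurvivalRecord]) -> float:
    """Concordance of the frozen final model on an independent cohort."""
    scores = model.risk_scores(features)  # raises listing missing columns
    df = _records_frame(records).loc[features.index]
    return concordance_index(scores, df)


def reliability_flag(runs: list[ModelRun], lo: float = 0.55, hi: float = 0.8) -> bool:
    """True iff the median test c-index across completed runs is in [0.55, 0.8]."""
    done = [r for r in runs if not r.failed]
    if not done:
        raise ValueError("no completed runs")
    med = float(np.median([r.ci for r in done]))
    return lo <= med <= hi
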