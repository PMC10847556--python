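"""Screening decisions: cross-validation folds, threshold selection, joint
screening definitions, and clinical-variable logistic models.

Splits are keyed by participant id; a ~10% holdout is drawn first and the
remaining participants are stratified by presence of aortic stenosis
(AS >= 1) into eight folds. Decision thresholds maximize sensitivity +
specificity on the training data subject to sensitivity > 50%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

JOINT_DEFINITIONS = {
    1: "grade >= 3 regurgitation or grade >= 1 stenosis",
    2: "grade >= 4 regurgitation or grade >= 1 stenosis",
    3: "symptomatic grade >= 3 regurgitation or grade >= 1 stenosis",
}

#: Clinical-variable logistic model formulas per target. ``murmur`` is the
#: audio-derived predictor: max grade for AR and MS, the mitral-position
#: grade for MR, and the multiposition AVPG output for AS (which also gets
#: a gender x murmur interaction).
CLINICAL_FORMULAS = {
    "AR>=3": ["murmur", "age", "gender_female", "breathless_uphill", "heart_rate"],
    "MR>=3": ["murmur", "age", "heart_rate"],
    "AS>=1": ["murmur", "gender_female", "murmur:gender_female"],
    "MS>=1": ["murmur", "age", "heart_rate"],
}


@dataclass
class FoldPlan:
    fold_of: dict          # participant id -> fold index 0..n_folds-1
    holdout: list          # participant ids
    n_folds: int

    def fold_ids(self, k):
        return [pid for pid, f in self.fold_of.items() if f == k]


def make_folds(participant_ids, as_positive, n_folds: int = 8,
               holdout_frac: float = 0.10, seed: int = 0) -> FoldPlan:
    """Participant-level stratified folds plus a holdout set.

    ``as_positive`` is the stratification variable (AS >= 1). Fold counts
    of positives differ by at most one. Deterministic under seed.
    """
    pids = list(participant_ids)
    pos = np.asarray(as_positive, dtype=bool)
    if len(pids) != len(pos):
        raise ValueError("ids and labels must align")
    if len(pids) < n_folds:
        raise ValueError(f"{len(pids)} participants < {n_folds} folds")
    rng = np.random.default_rng(seed)
    n_holdout = int(round(holdout_frac * len(pids)))

    pos_ids = [p for p, y in zip(pids, pos) if y]
    neg_ids = [p for p, y in zip(pids, pos) if not y]
    rng.shuffle(pos_ids)
    rng.shuffle(neg_ids)
    if len(pos_ids) < n_folds:
        warnings.warn(f"only {len(pos_ids)} stratification-positive participants "
                      f"for {n_folds} folds")

    # holdout drawn first, stratified
    n_hold_pos = int(round(holdout_frac * len(pos_ids)))
    n_hold_neg = n_holdout - n_hold_pos
    holdout = pos_ids[:n_hold_pos] + neg_ids[:n_hold_neg]
    rest_pos = pos_ids[n_hold_pos:]
    rest_neg = neg_ids[n_hold_neg:]

    fold_of = {}
    for i, pid in enumerate(rest_pos):
        fold_of[pid] = i % n_folds
    for i, pid in enumerate(rest_neg):
        fold_of[pid] = i % n_folds
    return FoldPlan(fold_of, holdout, n_folds)


def select_threshold(scores, labels):
    """Threshold maximizing sensitivity + specificity with sensitivity > 0.5.

    Candidates are midpoints of sorted unique scores; ties break toward
    higher specificity, then the lower threshold. If no candidate attains
    sensitivity > 0.5, the minimum score is returned (sensitivity 1) with
    a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    cands = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.array([])
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    best = None  # (youden, spec, -thr)
    best_thr = None
    for thr in cands:
        pred = scores >= thr
        sens = (pred & labels).sum() / n_pos
        spec = (~pred & ~labels).sum() / n_neg
        if sens <= 0.5:
            continue
        key = (sens + spec, spec, -thr)
        if best is None or key > best:
            best = key
            best_thr = float(thr)
    if best_thr is None:
        warnings.warn("no threshold attains sensitivity > 50%; returning min score")
        return float(uniq[0])
    return best_thr


def symptomatic_flag(clinical_row) -> bool:
    """Breathless at rest or walking calmly on level ground, or mMRC >= 2."""
    def _b(v):
        return (not pd.isna(v)) and bool(v)
    mmrc = clinical_row.get("mmrc", np.nan)
    return (_b(clinical_row.get("breathless_rest", np.nan))
            or _b(clinical_row.get("breathless_level", np.nan))
            or ((not pd.isna(mmrc)) and mmrc >= 2))


def joint_positive(as_grade, ms_grade, ar_grade, mr_grade, symptomatic: bool,
                   definition: int) -> bool:
    """Positive-class membership for the three joint-screening definitions."""
    stenosis = as_grade >= 1 or ms_grade >= 1
    if definition == 1:
        return stenosis or ar_grade >= 3 or mr_grade >= 3
    if definition == 2:
        return stenosis or ar_grade >= 4 or mr_grade >= 4
    if definition == 3:
        return stenosis or (symptomatic and (ar_grade >= 3 or mr_grade >= 3))
    raise ValueError("definition must be 1, 2, or 3")


def joint_screen(table: pd.DataFrame, predictor_col: str, definition: int,
                 threshold: float):
    """Per-participant joint-screening decisions.

    ``table`` needs echo grade columns AS/MS/AR/MR, the predictor column
    (max predicted murmur grade), and the clinical columns behind the
    symptomatic definition. Rows with missing echo grades are excluded with
    a log entry. Returns a DataFrame with class membership and decisions.
    """
    rows = []
    for _, r in table.iterrows():
        if any(pd.isna(r[c]) for c in ("AS", "MS", "AR", "MR")):
            warnings.warn(f"participant {r['participant_id']}: missing echo grade; excluded")
            continue
        sym = symptomatic_flag(r)
        rows.append({
            "participant_id": r["participant_id"],
            "positive_class": joint_positive(r["AS"], r["MS"], r["AR"], r["MR"], sym, definition),
            "screen_positive": bool(r[predictor_col] >= threshold),
            "symptomatic": sym,
            "score": float(r[predictor_col]),
        })
    return pd.DataFrame(rows)


def impute_mode(df: pd.DataFrame, columns) -> pd.DataFrame:
    """Fill missing categorical answers with the most frequent answer."""
    out = df.copy()
    for c in columns:
        if c in out.columns and out[c].isna().any():
            mode = out[c].mode(dropna=True)
            out[c] = out[c].fillna(mode.iloc[0] if len(mode) else 0)
    return out


@dataclass
class LogisticModelSpec:
    target: str
    covariates: list
    coefficients: np.ndarray   # aligned [intercept] + covariates
    std_errors: np.ndarray
    p_values: np.ndarray

    def predict_proba(self, design: np.ndarray) -> np.ndarray:
        z = design @ self.coefficients[1:] + self.coefficients[0]
        return 1.0 / (1.0 + np.exp(-z))


def _clinical_design(table: pd.DataFrame, covariates):
    cols = []
    for cov in covariates:
        if ":" in cov:
            a, b = cov.split(":")
            cols.append(table[a].to_numpy(float) * table[b].to_numpy(float))
        else:
            cols.append(table[cov].to_numpy(float))
    return np.column_stack(cols)


def fit_clinical_model(target: str, table: pd.DataFrame,
                       covariates=None) -> LogisticModelSpec:
    """Maximum-likelihood logistic regression of a VHD target.

    ``table`` must contain a binary column named ``target`` (e.g. "AS>=1"),
    a ``murmur`` column holding the audio predictor appropriate to the
    target, and the clinical covariates. Missing categorical answers are
    mode-imputed here; continuous covariates are used untransformed.
    """
    if covariates is None:
        covariates = CLINICAL_FORMULAS[target]
    y = table[target].to_numpy(dtype=float)
    base_cols = sorted({c for cov in covariates for c in cov.split(":")})
    work = impute_mode(table, [c for c in base_cols
                               if c in ("breathless_rest", "breathless_level",
                                        "breathless_uphill", "mmrc", "gender_female")])
    # continuous covariates: fill with column mean (same most-frequent spirit)
    for c in base_cols:
        if work[c].isna().any():
            work[c] = work[c].fillna(work[c].mean())
    design = _clinical_design(work, covariates)
    exog = sm.add_constant(design, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
    except Exception as exc:  # separation / non-convergence
        raise RuntimeError(f"logistic fit failed for {target}: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(f"logistic fit did not converge for {target} (separation?)")
    return LogisticModelSpec(target, list(covariates), np.asarray(res.params),
                             np.asarray(res.bse), np.asarray(res.pvalues))


def predict_clinical(spec: LogisticModelSpec, table: pd.DataFrame) -> np.ndarray:
    base_cols = sorted({c for cov in spec.covariates for c in cov.split(":")})
    work = impute_mode(table, base_cols)
    for c in base_cols:
        if work[c].isna().any():
            work[c] = work[c].fillna(work[c].mean())
    return spec.predict_proba(_clinical_design(work, spec.covariates))


def symptom_subgroup_test(detected_symptomatic, missed_symptomatic):
    """Compare symptomatic prevalence among detected vs missed cases.

    Arguments are boolean vectors over true positives and false negatives.
    Returns ``(prevalence_tp, prevalence_fn, p_value)``; the test is the
    two-sided Fisher exact test on the 2x2 table, with p = nan (flagged by
    the caller) when a subset is empty.
    """
    tp = np.asarray(detected_symptomatic, dtype=bool)
    fn = np.asarray(missed_symptomatic, dtype=bool)
    prev_tp = float(tp.mean()) if tp.size else float("nan")
    prev_fn = float(fn.mean()) if fn.size else float("nan")
    if tp.size == 0 or fn.size == 0:
        return prev_tp, prev_fn, float("nan")
    table = [[int(tp.sum()), int((~tp).sum())],
             [int(fn.sum()), int((~fn).sum())]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return prev_tp, prev_fn, float(p)
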