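"""Multiposition prediction of the aortic valve mean pressure gradient.

A linear model maps the four predicted murmur grades (aortic, pulmonic,
tricuspid, mitral: MG_A..MG_M) plus noise-indicator terms to AVPGmean in
mm Hg. Terms are products of factors; murmur-grade factors may appear up
to second degree, noise indicators are 0/1 multipliers. Model selection is
two-phase stepwise search by the Bayesian information criterion: phase 1
over squared murmur-grade terms starting from the four linear base terms,
phase 2 over noise-indicator interaction terms.

``PRINTED_MODEL`` is the published fitted model (its printed terms; the
source equation elides further terms behind an ellipsis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .metrics import auc as _auc

MG_FACTORS = ("MG_A", "MG_P", "MG_T", "MG_M")
NOISE_FACTORS = ("noise_A", "noise_P", "noise_T", "noise_M")
_POSITION_OF = {f: i for i, f in enumerate(MG_FACTORS)}
_NOISE_POSITION = {f: i for i, f in enumerate(NOISE_FACTORS)}


@dataclass
class LinearModelSpec:
    """Term list + coefficients; each term is a tuple of factor names."""

    terms: list
    coefficients: list
    intercept: float

    def __post_init__(self):
        canon = [tuple(sorted(t)) for t in self.terms]
        if len(set(canon)) != len(canon):
            raise ValueError("duplicate terms in model spec")
        for t in self.terms:
            for pos in range(4):
                deg = sum(1 for f in t if f == MG_FACTORS[pos])
                if deg > 2:
                    raise ValueError(f"murmur-grade degree > 2 in term {t}")

    def to_json_dict(self):
        return {"terms": [list(t) for t in self.terms],
                "coefficients": list(map(float, self.coefficients)),
                "intercept": float(self.intercept)}

    @classmethod
    def from_json_dict(cls, d):
        return cls([tuple(t) for t in d["terms"]], d["coefficients"], d["intercept"])


#: The published multiposition model (printed terms only):
#: AVPGmean = 3.5 + 0.6 MG_A^2 + 1.1 MG_P^2 + 0.5 MG_T
#:            + 0.9 MG_A^2 noise_P + 8.9 MG_M noise_A noise_P noise_T
PRINTED_MODEL = LinearModelSpec(
    terms=[
        ("MG_A", "MG_A"),
        ("MG_P", "MG_P"),
        ("MG_T",),
        ("MG_A", "MG_A", "noise_P"),
        ("MG_M", "noise_A", "noise_P", "noise_T"),
    ],
    coefficients=[0.6, 1.1, 0.5, 0.9, 8.9],
    intercept=3.5,
)


def _term_value(term, mg, noise):
    v = 1.0
    for f in term:
        if f in _POSITION_OF:
            v *= mg[_POSITION_OF[f]]
        elif f in _NOISE_POSITION:
            v *= noise[_NOISE_POSITION[f]]
        else:
            raise KeyError(f"unknown factor {f!r}")
    return v


def evaluate(spec: LinearModelSpec, mg, noise):
    """Evaluate the model; noisy positions' grades are forced to 0 first."""
    mg = np.asarray(mg, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if noise.all():
        raise ValueError("all four positions noisy; participant excluded")
    mg = np.where(noise > 0, 0.0, mg)
    val = spec.intercept
    for term, coef in zip(spec.terms, spec.coefficients):
        val += coef * _term_value(term, mg, noise)
    return float(val)


def design_matrix(terms, mg_matrix, noise_matrix):
    """Columns of term values for n observations (noisy grades zeroed)."""
    mg = np.asarray(mg_matrix, dtype=float)
    noise = np.asarray(noise_matrix, dtype=float)
    mg = np.where(noise > 0, 0.0, mg)
    cols = []
    for term in terms:
        v = np.ones(mg.shape[0])
        for f in term:
            if f in _POSITION_OF:
                v = v * mg[:, _POSITION_OF[f]]
            else:
                v = v * noise[:, _NOISE_POSITION[f]]
        cols.append(v)
    return np.column_stack(cols) if cols else np.empty((mg.shape[0], 0))


@dataclass
class OlsFit:
    spec: LinearModelSpec
    std_errors: np.ndarray
    p_values: np.ndarray       # aligned with [intercept] + terms
    bic: float
    rss: float
    n: int


def bic_from_rss(rss: float, n: int, n_terms: int) -> float:
    """BIC = n ln(RSS/n) + k ln(n), k = terms + intercept + variance."""
    k = n_terms + 2
    return float(n * np.log(rss / n) + k * np.log(n))


def fit_ols(terms, mg_matrix, noise_matrix, y) -> OlsFit:
    """Ordinary least squares of AVPGmean on the given terms."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if n <= len(terms) + 1:
        raise ValueError("need more observations than parameters")
    design = sm.add_constant(design_matrix(terms, mg_matrix, noise_matrix), has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design ({rank} < {design.shape[1]}) for terms {terms}")
    res = sm.OLS(y, design).fit()
    rss = float(res.ssr)
    spec = LinearModelSpec(list(terms), list(res.params[1:]), float(res.params[0]))
    return OlsFit(spec, np.asarray(res.bse), np.asarray(res.pvalues),
                  bic_from_rss(rss, n, len(terms)), rss, n)


def _candidate_squares():
    return [(f, f) for f in MG_FACTORS]


def _noise_candidates(current_terms):
    """Phase-2 pool: noise main effects plus current-term x single-noise
    interactions (the search space is kept first-order in noise factors)."""
    pool = [(nf,) for nf in NOISE_FACTORS]
    for term in current_terms:
        if any(f in _NOISE_POSITION for f in term):
            continue
        for nf in NOISE_FACTORS:
            pool.append(tuple(sorted(term + (nf,))))
    # the published model's saturated-noise mitral rescue term family
    pool.append(("MG_M", "noise_A", "noise_P", "noise_T"))
    return pool


def _stepwise_phase(terms, pool, mg, noise, y, alpha, frozen=()):
    """Greedy BIC descent over single-term additions/removals."""
    terms = [tuple(sorted(t)) for t in terms]
    pool = [tuple(sorted(t)) for t in pool]
    current = fit_ols(terms, mg, noise, y)
    while True:
        best = None  # (bic, order_index, new_terms)
        order = 0
        for cand in pool:
            if cand in current.spec.terms:
                continue
            try:
                trial = fit_ols(current.spec.terms + [cand], mg, noise, y)
            except np.linalg.LinAlgError:
                order += 1
                continue
            # addition requires the added term to be significant
            if trial.p_values[-1] < alpha and trial.bic < current.bic - 1e-12:
                if best is None or trial.bic < best[0] - 1e-12:
                    best = (trial.bic, order, trial)
            order += 1
        for k, term in enumerate(current.spec.terms):
            if term in frozen:
                order += 1
                continue
            # removal candidates: terms that lost significance
            if current.p_values[1 + k] <= alpha:
                order += 1
                continue
            reduced = [t for t in current.spec.terms if t != term]
            trial = fit_ols(reduced, mg, noise, y)
            if trial.bic < current.bic - 1e-12:
                if best is None or trial.bic < best[0] - 1e-12:
                    best = (trial.bic, order, trial)
            order += 1
        if best is None:
            return current
        current = best[2]


def stepwise_select(mg_matrix, noise_matrix, y, alpha: float = 0.05) -> OlsFit:
    """Two-phase BIC stepwise selection.

    Phase 1 starts from the four murmur-grade base terms and searches over
    squared terms; phase 2 searches over noise-indicator terms with the
    phase-1 terms still removable. Deterministic: ties break toward the
    lowest-index candidate.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty data")
    base = [(f,) for f in MG_FACTORS]
    phase1 = _stepwise_phase(base, _candidate_squares(), mg_matrix, noise_matrix, y, alpha)
    noise_arr = np.asarray(noise_matrix)
    if not noise_arr.any():
        return phase1
    phase2 = _stepwise_phase(phase1.spec.terms, _noise_candidates(phase1.spec.terms),
                             mg_matrix, noise_matrix, y, alpha)
    return phase2


def threshold_sweep_auc(predictions, avpg_values, thresholds=range(7, 31),
                        n_boot: int = 1000, seed: int = 0, level: float = 0.95):
    """AUC for predicting AVPGmean > u over a threshold range, with seeded
    percentile-bootstrap CIs (participants resampled)."""
    pred = np.asarray(predictions, dtype=float)
    avpg = np.asarray(avpg_values, dtype=float)
    rng = np.random.default_rng(seed)
    out = {}
    alpha = 1.0 - level
    any_ok = False
    for u in thresholds:
        labels = avpg > u
        if labels.all() or not labels.any():
            warnings.warn(f"threshold {u} mm Hg skipped: degenerate class")
            continue
        any_ok = True
        point = _auc(pred, labels)
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(pred), len(pred))
            lb = labels[idx]
            if lb.all() or not lb.any():
                continue
            boots.append(_auc(pred[idx], lb))
        lo, hi = (np.quantile(boots, [alpha / 2, 1 - alpha / 2])
                  if boots else (np.nan, np.nan))
        out[int(u)] = {"auc": point, "ci_low": float(lo), "ci_high": float(hi)}
    if not any_ok:
        raise ValueError("degenerate class at every threshold")
    return out
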