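"""Clinical association of TF expression and activity.

Three layers, mirroring how master regulators are linked to the clinic:
Pearson correlation of TF expression with ordinal pathology grades
(inflammation and fibrosis, 0-3, treated as numeric), a single-covariate
Cox proportional-hazards model for native-liver survival, and per-sample
regulon activity correlated with ssGSEA cell-infiltration scores.

The Cox fit maximizes the partial likelihood by Newton-Raphson with
Breslow handling of tied event times; perfect separation or non-convergence
is reported through the ``converged`` flag rather than an exception.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .activity import _RegulonScorer
from .network import Regulon

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "CoxResult",
    "pearson_assoc",
    "cox_fit",
    "ssgsea_scores",
    "per_sample_activity",
    "activity_cell_correlation",
]


@dataclass
class AssociationResult:
    r: float
    p: float
    n: int


@dataclass
class CoxResult:
    beta: float
    hr: float
    se: float
    p: float
    converged: bool


def pearson_assoc(x, y) -> AssociationResult:
    """Pearson r with two-sided t-based p on pairwise-complete samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("Pearson correlation needs at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    res = stats.pearsonr(x, y)
    return AssociationResult(float(res.statistic), float(res.pvalue), len(x))


def cox_fit(time, event, covariate, tol: float = 1e-8, max_iter: int = 50) -> CoxResult:
    """Single-covariate Cox proportional hazards (Breslow ties).

    Reports the log hazard ratio per covariate unit, its Wald p-value and a
    convergence flag. A monotone partial likelihood (perfect separation)
    surfaces as ``converged=False`` with the last iterate.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(covariate, dtype=float)
    if (time <= 0).any():
        raise ValueError("survival times must be positive")
    if event.sum() < 1:
        raise ValueError("at least one event is required")
    if np.ptp(x[event == 1]) == 0 and np.ptp(x) == 0:
        raise ValueError("constant covariate: hazard ratio not identifiable")

    order = np.argsort(time, kind="stable")
    time, event, x = time[order], event[order], x[order]
    # group tied times; Breslow: all tied events share one risk-set term
    utimes, first = np.unique(time, return_index=True)
    bounds = np.append(first, len(time))

    beta, converged = 0.0, False
    for _ in range(max_iter):
        ebx = np.exp(beta * x)
        # reverse cumulative sums: risk set at time t = samples with time >= t
        s0 = np.cumsum(ebx[::-1])[::-1]
        s1 = np.cumsum((x * ebx)[::-1])[::-1]
        s2 = np.cumsum((x * x * ebx)[::-1])[::-1]
        score, info = 0.0, 0.0
        for k in range(len(utimes)):
            lo, hi = bounds[k], bounds[k + 1]
            ev = event[lo:hi] == 1
            d = int(ev.sum())
            if d == 0:
                continue
            m1, m2 = s1[lo] / s0[lo], s2[lo] / s0[lo]
            score += x[lo:hi][ev].sum() - d * m1
            info += d * (m2 - m1 * m1)
        if info <= 1e-12:
            break
        step = score / info
        beta += step
        if abs(beta) > 50:  # monotone likelihood
            break
        if abs(step) < tol:
            converged = True
            break
    se = 1.0 / np.sqrt(info) if info > 1e-12 else np.inf
    p = 2.0 * stats.norm.sf(abs(beta) / se) if np.isfinite(se) else 1.0
    return CoxResult(float(beta), float(np.exp(beta)), float(se), float(p), converged)


def ssgsea_scores(
    expr: pd.DataFrame,
    sets: dict[str, list],
    alpha_weight: float = 0.25,
    min_genes: int = 3,
    normalize: bool = True,
) -> pd.DataFrame:
    """Single-sample gene-set enrichment scores (samples x sets).

    Per sample, genes are ranked by expression descending; the score is the
    sum over ranks of the difference between the in-set ECDF weighted by
    rank^alpha_weight (rank counted from the bottom, so the top gene has the
    largest weight) and the unweighted out-set ECDF. With ``normalize`` the
    matrix is divided by its global score range.
    """
    if not sets:
        raise ValueError("empty gene-set collection")
    genes = expr.index
    n = len(genes)
    usable = {}
    for name, members in sets.items():
        idx = genes.get_indexer([g for g in dict.fromkeys(members) if g in genes])
        if len(idx) < min_genes:
            logger.warning("set %s dropped: %d mapped genes < %d", name, len(idx), min_genes)
            continue
        usable[name] = idx
    if not usable:
        raise ValueError("no gene set maps enough genes into the matrix")

    values = expr.to_numpy(dtype=float)
    rank_weight = (np.arange(n, 0, -1, dtype=float)) ** alpha_weight  # position 0 = top
    raw = np.empty((values.shape[1], len(usable)))
    for s in range(values.shape[1]):
        order = np.argsort(-values[:, s], kind="stable")
        in_sorted_pos = np.empty(n, dtype=np.intp)
        in_sorted_pos[order] = np.arange(n)
        for j, idx in enumerate(usable.values()):
            member = np.zeros(n, dtype=bool)
            member[in_sorted_pos[idx]] = True
            w = np.where(member, rank_weight, 0.0)
            p_in = np.cumsum(w) / w.sum()
            p_out = np.cumsum(~member) / (n - member.sum())
            raw[s, j] = (p_in - p_out).sum()
    out = pd.DataFrame(raw, index=expr.columns, columns=list(usable))
    if normalize:
        span = raw.max() - raw.min()
        if span > 0:
            out = out / span
    return out


def per_sample_activity(
    expr: pd.DataFrame,
    regulons: dict[str, Regulon],
    min_targets: int = 10,
) -> pd.DataFrame:
    """Per-sample TF activity: enrichment on one-vs-rest z signatures.

    Each sample's signature is its expression standardized against the
    cohort mean and standard deviation per gene; regulon enrichment of that
    signature gives one activity value per (sample, TF).
    """
    values = expr.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (values - mu) / sd
    scorer = _RegulonScorer(regulons, expr.index, min_targets)
    act = np.vstack([scorer.score(z[:, s]) for s in range(values.shape[1])])
    return pd.DataFrame(act, index=expr.columns, columns=scorer.tfs)


def activity_cell_correlation(activity: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson r/p for every (TF, cell type) pair over shared samples."""
    shared = activity.index.intersection(scores.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared samples between activity and scores")
    rows = []
    for tf in activity.columns:
        for ct in scores.columns:
            res = pearson_assoc(activity.loc[shared, tf], scores.loc[shared, ct])
            rows.append({"tf": tf, "cell_type": ct, "r": res.r, "p": res.p, "n": res.n})
    return pd.DataFrame(rows)
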