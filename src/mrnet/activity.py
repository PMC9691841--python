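"""Regulon-based protein activity inference from case/control signatures.

A differential-expression signature (per-gene z-score from a Welch t-test,
cases minus controls) is scored against each TF's regulon with an analytic
rank-based enrichment statistic: the signature is rank-transformed to
normal quantiles and each regulon's weighted, mode-signed average quantile
is normalized so that random regulons score ~N(0, 1). Significance comes
from a sample-permutation null: labels are shuffled, the signature and all
enrichment scores recomputed, each TF's null standardized, and the
standardized nulls pooled across TFs for tail resolution. Master regulators
(MRs) are the TFs passing a BH-adjusted significance cut, and consensus MRs
are those significant with a concordant activity sign in every cohort.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import Regulon

logger = logging.getLogger(__name__)

__all__ = [
    "compute_signature",
    "area_nes",
    "permutation_pvalues",
    "select_mrs",
    "intersect_mrs",
]

_Z_CLIP = 8.0  # |z| cap for signatures from vanishing t-test p-values

ACTIVITY_COLUMNS = ["tf", "nes", "p", "p_adj", "direction"]


def _welch_z(values: np.ndarray, case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Per-gene Welch t -> z, sign positive when cases are higher.

    Computed as sign(t) * isf(one-sided p of |t|) so that swapping the two
    groups negates every z exactly (bitwise), a property the downstream
    enrichment statistics inherit.
    """
    a, b = values[:, case], values[:, control]
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    floor = va + vb == 0
    if floor.any():
        logger.warning("variance floor applied to %d zero-variance genes", int(floor.sum()))
    va = np.maximum(va, 1e-12)
    vb = np.maximum(vb, 1e-12)
    se2 = va / na + vb / nb
    t = (ma - mb) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    z = np.sign(t) * stats.norm.isf(stats.t.sf(np.abs(t), df))
    return np.clip(z, -_Z_CLIP, _Z_CLIP)


def _split_labels(labels: pd.Series):
    lab = labels.to_numpy()
    case = lab == "case"
    control = lab == "control"
    if case.sum() < 2 or control.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    return case, control


def compute_signature(expr: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Case-vs-control differential signature: one signed z per gene."""
    labels = labels.reindex(expr.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some expression samples")
    case, control = _split_labels(labels)
    z = _welch_z(expr.to_numpy(dtype=float), case, control)
    return pd.Series(z, index=expr.index, name="z")


def _normal_scores(n: int) -> np.ndarray:
    """Normal quantiles of i/(n+1), symmetrized so g[k] == -g[n-1-k] exactly."""
    g = stats.norm.ppf(np.arange(1, n + 1) / (n + 1))
    return (g - g[::-1]) / 2.0


def _quantile_transform(z: np.ndarray) -> np.ndarray:
    order = np.argsort(z, kind="stable")
    q = np.empty(len(z))
    q[order] = _normal_scores(len(z))
    return q


def area_nes(sig: pd.Series, regulon: Regulon, min_targets: int = 10) -> float:
    """Analytic rank-based enrichment score of one regulon on a signature.

    NES = sum_i w_i * mode_i * q(target_i) / sqrt(sum_i w_i^2), where q is
    the normal-quantile rank transform of the signature over its gene
    universe and w_i is the interaction likelihood. Under random regulons
    the score has mean ~0 and variance ~1.
    """
    q = pd.Series(_quantile_transform(sig.to_numpy(dtype=float)), index=sig.index)
    mask = np.fromiter((t in q.index for t in regulon.targets), dtype=bool, count=len(regulon))
    if int(mask.sum()) < min_targets:
        raise ValueError(
            f"regulon {regulon.tf}: only {int(mask.sum())} targets map into the signature "
            f"universe (minimum {min_targets})"
        )
    targets = [t for t, m in zip(regulon.targets, mask) if m]
    w = regulon.likelihoods[mask]
    modes = regulon.modes[mask]
    return float((w * modes * q.loc[targets].to_numpy()).sum() / np.sqrt((w * w).sum()))


class _RegulonScorer:
    """Vectorized enrichment of a fixed regulon set on many signatures."""

    def __init__(self, regulons: dict[str, Regulon], universe: pd.Index, min_targets: int = 10):
        pos = {g: i for i, g in enumerate(universe)}
        self.tfs, self.idx, self.wm, self.norm = [], [], [], []
        for tf, reg in regulons.items():
            keep = [(pos[t], m, w) for t, m, w in zip(reg.targets, reg.modes, reg.likelihoods)
                    if t in pos]
            if len(keep) < min_targets:
                logger.warning("TF %s skipped: %d mapped targets < %d", tf, len(keep), min_targets)
                continue
            ii = np.array([k[0] for k in keep], dtype=np.intp)
            wm = np.array([k[1] * k[2] for k in keep])  # mode * likelihood
            w = np.array([k[2] for k in keep])
            self.tfs.append(tf)
            self.idx.append(ii)
            self.wm.append(wm)
            self.norm.append(np.sqrt((w * w).sum()))
        if not self.tfs:
            raise ValueError("no regulon maps enough targets into the signature universe")
        self.scores_grid = _normal_scores(len(universe))

    def score(self, z: np.ndarray) -> np.ndarray:
        q = np.empty(len(z))
        q[np.argsort(z, kind="stable")] = self.scores_grid
        return np.array([(wm * q[ii]).sum() / nm
                         for ii, wm, nm in zip(self.idx, self.wm, self.norm)])


def permutation_pvalues(
    expr: pd.DataFrame,
    labels: pd.Series,
    regulons: dict[str, Regulon],
    n_perm: int = 1000,
    seed: int = 0,
    min_targets: int = 10,
) -> pd.DataFrame:
    """Activity table (tf, nes, p, p_adj, direction) with a permutation null.

    Each permutation shuffles the sample order of the labels, recomputes the
    signature and every regulon's enrichment score. Null scores are
    standardized per TF and pooled across TFs; the reported NES is the
    observed score on the same standardized scale and the two-sided p is the
    pooled-tail frequency with a pseudocount. BH adjustment across TFs.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100 (study default 1000)")
    labels = labels.reindex(expr.columns)
    case, control = _split_labels(labels)
    values = expr.to_numpy(dtype=float)
    scorer = _RegulonScorer(regulons, expr.index, min_targets)

    obs = scorer.score(_welch_z(values, case, control))
    rng = np.random.default_rng(seed)
    n = values.shape[1]
    null = np.empty((n_perm, len(obs)))
    for k in range(n_perm):
        while True:  # degenerate single-group shuffles cannot occur, but guard
            perm = rng.permutation(n)
            pc, pk = case[perm], control[perm]
            if pc.any() and pk.any():
                break
        null[k] = scorer.score(_welch_z(values, pc, pk))

    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    nes = (obs - mu) / sd
    pooled = np.abs((null - mu) / sd).ravel()
    pooled.sort()
    # two-sided pooled-tail p with pseudocount; minimum attainable is
    # 1 / (n_perm * n_tf + 1)
    exceed = len(pooled) - np.searchsorted(pooled, np.abs(nes), side="left")
    p = (1.0 + exceed) / (len(pooled) + 1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"tf": scorer.tfs, "nes": nes, "p": p, "p_adj": np.maximum(p_adj, p),
         "direction": np.where(nes > 0, "activated", "repressed")}
    )
    return table


def select_mrs(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Master regulators: rows with adjusted p < alpha, strongest |NES| first."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    sel = table[table["p_adj"] < alpha].copy()
    return sel.reindex(sel["nes"].abs().sort_values(ascending=False).index).reset_index(drop=True)


def intersect_mrs(tables: list[pd.DataFrame], alpha: float = 0.05) -> pd.DataFrame:
    """Consensus MRs: significant in every cohort with a concordant sign.

    TFs significant everywhere but with discordant NES signs are excluded
    and logged. Output columns: tf, direction, then nes_<k> / p_adj_<k> per
    cohort in input order.
    """
    if len(tables) < 2:
        raise ValueError("consensus needs at least 2 activity tables")
    sig = [t[t["p_adj"] < alpha].set_index("tf") for t in tables]
    common = set(sig[0].index)
    for s in sig[1:]:
        common &= set(s.index)
    rows, discordant = [], []
    for tf in sorted(common):
        signs = {np.sign(s.loc[tf, "nes"]) for s in sig}
        if len(signs) > 1:
            discordant.append(tf)
            continue
        row = {"tf": tf, "direction": "activated" if signs.pop() > 0 else "repressed"}
        for k, s in enumerate(sig, start=1):
            row[f"nes_{k}"] = float(s.loc[tf, "nes"])
            row[f"p_adj_{k}"] = float(s.loc[tf, "p_adj"])
        rows.append(row)
    if discordant:
        logger.warning("excluded %d discordant-direction TFs: %s",
                       len(discordant), ", ".join(discordant))
    cols = ["tf", "direction"] + [f"{c}_{k}" for k in range(1, len(sig) + 1)
                                  for c in ("nes", "p_adj")]
    out = pd.DataFrame(rows, columns=cols)
    out.attrs["discordant"] = discordant
    out.attrs["candidate_overlap"] = len(common)
    return out
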