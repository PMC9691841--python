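"""Transcriptional network deconvolution from expression via mutual information.

The reconstruction follows the classic information-theoretic recipe: pairwise
mutual information (MI) between each candidate regulator (TF) and every other
gene, an independence test against a permutation null with Bonferroni
correction over the number of tested pairs, and trimming of indirect edges
with the data processing inequality (DPI).

MI is estimated on copula margins: each profile is replaced by its ranks
mapped into (0, 1), so the estimate is exactly symmetric and exactly
invariant under strictly monotone transforms of either gene. The joint
density on the rank grid is a product Gaussian kernel with a Silverman-type
bandwidth, and MI is the average log density ratio over the data points,
clipped at zero. Because every copula margin lives on the same grid of n
rank points, the kernel matrix and the marginal density are computed once
per sample size and shared by all genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "MiNullModel",
    "estimate_mi",
    "fit_mi_null",
    "build_edge_list",
    "apply_dpi",
    "edges_to_regulons",
    "Regulon",
    "drop_constant_genes",
]

EDGE_COLUMNS = ["tf", "target", "mi", "p"]


@dataclass
class Regulon:
    """One TF's inferred targets with signed mode and confidence weight."""

    tf: str
    targets: list
    modes: np.ndarray       # Spearman sign/strength, in [-1, 1]
    likelihoods: np.ndarray  # MI / max MI within the regulon, in (0, 1]

    def __post_init__(self) -> None:
        self.modes = np.asarray(self.modes, dtype=float)
        self.likelihoods = np.asarray(self.likelihoods, dtype=float)
        if len(self.targets) != len(self.modes) or len(self.targets) != len(self.likelihoods):
            raise ValueError("targets, modes and likelihoods must have equal length")

    def __len__(self) -> int:
        return len(self.targets)


class _CopulaKernel:
    """Shared Gaussian kernel on the rank grid for a fixed sample size."""

    _cache: dict = {}

    def __new__(cls, n: int):
        if n in cls._cache:
            return cls._cache[n]
        self = super().__new__(cls)
        u = np.arange(1, n + 1) / (n + 1)
        h = u.std(ddof=1) * n ** (-1.0 / 6.0)
        diff = (u[:, None] - u[None, :]) / h
        self.kernel = np.exp(-0.5 * diff * diff) / (h * np.sqrt(2.0 * np.pi))
        # marginal density at each grid point: every gene's ranks are a
        # permutation of the grid, so this is gene-independent
        self.log_marginal = np.log(self.kernel.mean(axis=1))
        cls._cache[n] = self
        return self

    def mi(self, rx: np.ndarray, ry: np.ndarray) -> float:
        joint = self.kernel[np.ix_(rx, rx)] * self.kernel[np.ix_(ry, ry)]
        log_joint = np.log(joint.mean(axis=1))
        mi = log_joint.mean() - self.log_marginal[rx].mean() - self.log_marginal[ry].mean()
        return max(float(mi), 0.0)


def _ranks(x: np.ndarray, name: str = "vector") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D sample vector")
    if len(x) < 3:
        raise ValueError("MI estimation needs at least 3 samples")
    if np.ptp(x) == 0:
        raise ValueError(f"MI undefined for constant expression: {name}")
    return rankdata(x, method="ordinal").astype(np.intp) - 1


def estimate_mi(x: np.ndarray, y: np.ndarray, *, x_name: str = "x", y_name: str = "y") -> float:
    """Mutual information (nats) between two expression profiles.

    Symmetric, nonnegative, and exactly invariant under strictly monotone
    transforms of either argument (the estimate depends only on ranks).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    rx = _ranks(x, x_name)
    ry = _ranks(y, y_name)
    return _CopulaKernel(len(x)).mi(rx, ry)


@dataclass
class MiNullModel:
    """Permutation null for MI with an exponential right tail.

    The empirical null cannot reach p-values far below 1/n_perm, but the
    network threshold (1e-8 after Bonferroni) lives there; an exponential
    fit to the exceedances over the upper-5% quantile extrapolates the tail.
    """

    null_mi: np.ndarray       # sorted ascending
    tail_threshold: float     # empirical 95th percentile
    tail_rate: float          # exponential rate of exceedances
    tail_prob: float          # empirical mass at/above the threshold
    n_pairs_tested: int

    def pvalue(self, mi) -> np.ndarray:
        """Uncorrected right-tail p for an MI value (vectorized)."""
        mi = np.atleast_1d(np.asarray(mi, dtype=float))
        n = len(self.null_mi)
        # empirical survival below the tail threshold
        idx = np.searchsorted(self.null_mi, mi, side="left")
        p = (n - idx) / n
        in_tail = mi >= self.tail_threshold
        p[in_tail] = self.tail_prob * np.exp(-self.tail_rate * (mi[in_tail] - self.tail_threshold))
        return np.minimum(p, 1.0)

    def corrected_pvalue(self, mi) -> np.ndarray:
        """Bonferroni-corrected p: min(1, p * n_pairs_tested)."""
        return np.minimum(1.0, self.pvalue(mi) * self.n_pairs_tested)


def fit_mi_null(
    expr: pd.DataFrame,
    n_perm: int = 1000,
    n_pairs_tested: int | None = None,
    seed: int = 0,
) -> MiNullModel:
    """Fit the MI independence null by permuting random gene pairs.

    Each draw picks two distinct genes and destroys their dependence by
    shuffling the sample order of one; the MI of the shuffled pair is a
    draw from the independence null at this sample size.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    genes = expr.index.to_numpy()
    values = expr.to_numpy(dtype=float)
    n = values.shape[1]
    kern = _CopulaKernel(n)
    rng = np.random.default_rng(seed)
    rank_cache: dict = {}

    def ranks_of(i: int) -> np.ndarray:
        if i not in rank_cache:
            rank_cache[i] = _ranks(values[i], str(genes[i]))
        return rank_cache[i]

    null = np.empty(n_perm)
    for k in range(n_perm):
        i, j = rng.choice(len(genes), size=2, replace=False)
        ry = rng.permutation(ranks_of(j))
        null[k] = kern.mi(ranks_of(i), ry)
    null.sort()

    thr = float(np.quantile(null, 0.95))
    exceed = null[null > thr] - thr
    if len(exceed) < 20:
        raise ValueError(f"too few tail points ({len(exceed)}) to fit the MI null tail")
    rate = 1.0 / float(exceed.mean())
    tail_prob = float((null >= thr).mean())
    if n_pairs_tested is None:
        n_pairs_tested = len(genes) * (len(genes) - 1) // 2
    return MiNullModel(null, thr, rate, tail_prob, int(n_pairs_tested))


def drop_constant_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Remove zero-variance genes (MI is undefined for them)."""
    keep = expr.std(axis=1, ddof=0) > 0
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("dropping %d constant-expression genes before MI", n_drop)
    return expr.loc[keep]


def n_candidate_pairs(n_regulators: int, n_genes: int) -> int:
    """Bonferroni universe: every (regulator, other gene) pair."""
    return n_regulators * (n_genes - 1)


def build_edge_list(
    expr: pd.DataFrame,
    regulators,
    p_threshold: float = 1e-8,
    null: MiNullModel | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    p_corrected: bool = False,
) -> pd.DataFrame:
    """TF-gene edges whose MI passes the independence test.

    Returns a DataFrame (tf, target, mi, p); the reported p is always
    Bonferroni-corrected over the candidate-pair universe
    (|regulators| x (|genes|-1)). The threshold is applied to the raw tail
    p by default — the classic network-deconvolution convention, where a
    deliberately tiny per-pair cut (1e-8) already stands in for the
    multiplicity correction — or to the corrected p with ``p_corrected``.
    TF-TF pairs are retained (a DPI mediator may be a TF).
    """
    regulators = list(dict.fromkeys(regulators))
    if not regulators:
        raise ValueError("empty regulator list")
    expr = drop_constant_genes(expr)
    missing = [tf for tf in regulators if tf not in expr.index]
    if missing:
        logger.warning("dropping %d regulators absent from the expression matrix", len(missing))
        regulators = [tf for tf in regulators if tf not in missing]
        if not regulators:
            raise ValueError("no regulators left in the expression matrix")

    genes = expr.index.to_numpy()
    values = expr.to_numpy(dtype=float)
    n_samples = values.shape[1]
    kern = _CopulaKernel(n_samples)
    ranks = np.empty((len(genes), n_samples), dtype=np.intp)
    for i in range(len(genes)):
        ranks[i] = _ranks(values[i], str(genes[i]))

    n_pairs = n_candidate_pairs(len(regulators), len(genes))
    if null is None:
        null = fit_mi_null(expr, n_perm=n_perm, n_pairs_tested=n_pairs, seed=seed)

    gene_pos = {g: i for i, g in enumerate(genes)}
    rows_tf, rows_tg, rows_mi = [], [], []
    for tf in regulators:
        ti = gene_pos[tf]
        k_tf = kern.kernel[np.ix_(ranks[ti], ranks[ti])]
        lm_tf = kern.log_marginal[ranks[ti]].mean()
        for gi in range(len(genes)):
            if gi == ti:
                continue
            rg = ranks[gi]
            joint = k_tf * kern.kernel[np.ix_(rg, rg)]
            mi = np.log(joint.mean(axis=1)).mean() - lm_tf - kern.log_marginal[rg].mean()
            mi = max(float(mi), 0.0)
            rows_tf.append(tf)
            rows_tg.append(genes[gi])
            rows_mi.append(mi)

    mi_arr = np.asarray(rows_mi)
    p_corr = null.corrected_pvalue(mi_arr)
    keep = (p_corr if p_corrected else null.pvalue(mi_arr)) < p_threshold
    edges = pd.DataFrame(
        {"tf": np.asarray(rows_tf, dtype=object)[keep],
         "target": np.asarray(rows_tg, dtype=object)[keep],
         "mi": mi_arr[keep],
         "p": p_corr[keep]}
    )
    # de-duplicate symmetric TF-TF pairs, keeping one orientation
    seen = set()
    keep_rows = []
    for idx, (a, b) in enumerate(zip(edges["tf"], edges["target"])):
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        keep_rows.append(idx)
    return edges.iloc[keep_rows].reset_index(drop=True)


def apply_dpi(edges: pd.DataFrame, tolerance: float = 0.1) -> pd.DataFrame:
    """Trim indirect edges with the data processing inequality.

    An edge (x, y) is removed when some regulator z (z != x, y) closes a
    triangle in the ORIGINAL edge list with
    MI(x, y) < (1 - tolerance) * min[MI(x, z), MI(z, y)].
    Single pass: removals never cascade; ties keep the edge.
    """
    if not 0 <= tolerance < 1:
        raise ValueError("tolerance must be in [0, 1)")
    if edges.empty:
        return edges.copy()

    nodes = pd.unique(pd.concat([edges["tf"], edges["target"]], ignore_index=True))
    pos = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    mi_mat = np.zeros((n, n))
    present = np.zeros((n, n), dtype=bool)
    xi = edges["tf"].map(pos).to_numpy()
    yi = edges["target"].map(pos).to_numpy()
    mi = edges["mi"].to_numpy(dtype=float)
    mi_mat[xi, yi] = mi
    mi_mat[yi, xi] = mi
    present[xi, yi] = True
    present[yi, xi] = True

    reg_idx = np.array(sorted({pos[tf] for tf in edges["tf"]}), dtype=np.intp)
    slack = 1.0 - tolerance
    removed = np.zeros(len(edges), dtype=bool)
    for e in range(len(edges)):
        x, y = xi[e], yi[e]
        z = reg_idx[(reg_idx != x) & (reg_idx != y)]
        ok = present[x, z] & present[z, y]
        if not ok.any():
            continue
        z = z[ok]
        indirect = np.minimum(mi_mat[x, z], mi_mat[z, y])
        if (mi[e] < slack * indirect).any():
            removed[e] = True
    return edges.loc[~removed].reset_index(drop=True)


def edges_to_regulons(
    edges: pd.DataFrame,
    expr: pd.DataFrame,
    min_size: int = 25,
) -> dict[str, Regulon]:
    """Attach mode and confidence to edges and group them into regulons.

    Mode is the Spearman correlation between TF and target expression
    (its sign separates activation from repression); likelihood is the edge
    MI normalized by the strongest MI within the regulon, so the best
    supported interaction has weight exactly 1. TFs with fewer than
    ``min_size`` targets are dropped.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    regulons: dict[str, Regulon] = {}
    if edges.empty:
        return regulons
    ranks = pd.DataFrame(
        rankdata(expr.to_numpy(dtype=float), axis=1),
        index=expr.index, columns=expr.columns,
    )
    for tf, grp in edges.groupby("tf", sort=True):
        targets = [t for t in grp["target"] if t in expr.index]
        grp = grp[grp["target"].isin(targets)]
        if len(targets) < min_size:
            logger.warning("TF %s dropped: regulon size %d < %d", tf, len(targets), min_size)
            continue
        r_tf = ranks.loc[tf].to_numpy()
        r_tg = ranks.loc[grp["target"]].to_numpy()
        modes = _pearson_rows(r_tg, r_tf)
        mi = grp["mi"].to_numpy(dtype=float)
        regulons[tf] = Regulon(tf, list(grp["target"]), modes, mi / mi.max())
    return regulons


def _pearson_rows(rows: np.ndarray, vec: np.ndarray) -> np.ndarray:
    rows = rows - rows.mean(axis=1, keepdims=True)
    vec = vec - vec.mean()
    denom = np.sqrt((rows * rows).sum(axis=1) * (vec * vec).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rows @ vec) / denom
    return np.clip(np.nan_to_num(r), -1.0, 1.0)
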