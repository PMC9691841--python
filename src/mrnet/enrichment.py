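"""Over-representation analysis of gene lists against user gene sets.

Hypergeometric upper-tail test of a query list against each set in a
collection, restricted to sets whose in-universe size falls inside
configurable bounds (default 5..2000), with Benjamini-Hochberg FDR control
across the tested sets (Bonferroni available as an alternative).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["ora_test", "bh_adjust"]

ORA_COLUMNS = ["set_name", "overlap", "query_size", "set_size", "universe_size", "p", "q"]


def bh_adjust(p, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def ora_test(
    query,
    sets: dict[str, list],
    universe,
    size_bounds: tuple[int, int] = (5, 2000),
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in each gene set.

    p is the probability of observing at least the seen overlap when the
    query were drawn at random from the universe; sets whose in-universe
    size falls outside ``size_bounds`` are excluded before testing.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query:
        raise ValueError("empty query")
    outside = query - universe
    if outside:
        logger.warning("dropping %d query genes outside the universe", len(outside))
        query &= universe
        if not query:
            raise ValueError("no query gene lies in the universe")

    lo, hi = size_bounds
    rows = []
    for name, members in sets.items():
        in_universe = set(members) & universe
        if not lo <= len(in_universe) <= hi:
            continue
        overlap = len(query & in_universe)
        p = float(hypergeom.sf(overlap - 1, len(universe), len(in_universe), len(query)))
        rows.append({"set_name": name, "overlap": overlap, "query_size": len(query),
                     "set_size": len(in_universe), "universe_size": len(universe),
                     "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=ORA_COLUMNS[:-1])
    if len(out):
        out["q"] = np.maximum(bh_adjust(out["p"].to_numpy(), method=method), out["p"])
    else:
        out["q"] = np.array([], dtype=float)
    return out.sort_values("p", kind="stable").reset_index(drop=True)
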