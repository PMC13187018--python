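"""Over-representation analysis with Benjamini-Hochberg adjustment.

Each gene set is tested against a query list by the one-sided
hypergeometric tail P(overlap >= observed) within a stated gene universe
(by default the measured, post-filter genes rather than the whole genome);
raw p-values are adjusted across all tested sets by the BH step-up
procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import GeneSetCollection

__all__ = ["EnrichmentRow", "ora", "bh_adjust"]


@dataclass(frozen=True)
class EnrichmentRow:
    name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    adjusted_p: float

    def __post_init__(self) -> None:
        if self.overlap > min(self.set_size, self.query_size):
            raise ValueError("overlap exceeds set or query size")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order.

    q_i = min_{j >= i} p_(j) * m / j over the ascending order, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def ora(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query`` in each set.

    The query must be a subset of the universe; each gene set is
    intersected with the universe before testing. Returns one row per set,
    sorted by adjusted then raw p, with columns matching
    :class:`EnrichmentRow`.
    """
    universe = frozenset(universe)
    query = frozenset(query)
    if not universe:
        raise ValueError("universe must be non-empty")
    if not query:
        raise ValueError("query must be non-empty")
    stray = query - universe
    if stray:
        raise ValueError(f"query gene(s) outside universe: {sorted(stray)[:3]}")
    n_univ, n_query = len(universe), len(query)
    rows = []
    for name in collection:
        genes = collection[name] & universe
        k = len(genes & query)
        # P(X >= k) for X ~ Hypergeom(N=universe, K=set, n=query)
        p = 1.0 if k == 0 else float(hypergeom.sf(k - 1, n_univ, len(genes), n_query))
        rows.append((name, k, len(genes), p))
    if not rows:
        return pd.DataFrame(
            columns=["name", "overlap", "set_size", "query_size",
                     "universe_size", "p_value", "adjusted_p"]
        )
    adjusted = bh_adjust([r[3] for r in rows])
    df = pd.DataFrame(
        {
            "name": [r[0] for r in rows],
            "overlap": [r[1] for r in rows],
            "set_size": [r[2] for r in rows],
            "query_size": n_query,
            "universe_size": n_univ,
            "p_value": [r[3] for r in rows],
            "adjusted_p": adjusted,
        }
    )
    return df.sort_values(["adjusted_p", "p_value", "name"]).reset_index(drop=True)
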