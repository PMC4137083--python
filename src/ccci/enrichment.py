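"""Gene-set over-representation with exact one-sided tests and BH FDR.

Every enrichment question in the pipeline — GO-like terms, gold-standard
sets, ciliopathy genes, localization classes, TF target sets — reduces to
the same 2×2 question: does a community of size n drawn from a background of
N genes contain surprisingly many (k) of a set's K background members?  The
p-value is the exact upper hypergeometric tail; q-values are
Benjamini–Hochberg within one test family per collection.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError

log = logging.getLogger(__name__)

__all__ = ["fisher_one_sided", "bh_fdr", "enrich_communities"]


def fisher_one_sided(k, n: int, K: int, N: int):
    """P(X ≥ k) for X ~ Hypergeometric(N, K, n) — one-sided enrichment.

    Identical to the one-sided (greater) Fisher exact test on the 2×2 table
    [[k, K-k], [n-k, N-K-n+k]].  Exact, never normal-approximated.

    Parameters
    ----------
    k
        Observed overlap; scalar or array (vectorised over k).
    n
        Community (sample) size.
    K
        Set size within the background.
    N
        Background size.
    """
    k_arr = np.atleast_1d(np.asarray(k, dtype=int))
    if N < 0 or n < 0 or K < 0 or n > N or K > N:
        raise DataError(f"inconsistent counts n={n}, K={K}, N={N}")
    if (k_arr < 0).any() or (k_arr > min(n, K)).any():
        raise DataError(f"overlap k={k} outside [0, min(n={n}, K={K})]")
    p = stats.hypergeom.sf(k_arr - 1, N, K, n)
    p = np.clip(p, 0.0, 1.0)
    return float(p[0]) if np.isscalar(k) or np.ndim(k) == 0 else p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise DataError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def enrich_communities(
    communities: Mapping[int, frozenset[str] | set[str]],
    sets: Mapping[str, frozenset[str] | set[str]],
    background: set[str] | frozenset[str],
    min_community_size: int = 5,
    min_overlap: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every (community, set) pair against the background.

    Only communities with at least ``min_community_size`` members are
    tested; sets are intersected with the background first and skipped (with
    a warning) when the intersection is empty.  BH correction spans the
    whole family of emitted tests; a row is flagged significant when
    ``q < alpha`` and ``k >= min_overlap``.

    Returns a DataFrame with columns community_id, set_id, k, n, K, N,
    p_value, q_value, significant.
    """
    background = frozenset(background)
    if not background:
        raise DataError("empty background")
    N = len(background)
    comm_items = []
    for cid in sorted(communities):
        members = frozenset(communities[cid])
        outside = members - background
        if outside:
            raise DataError(
                f"community {cid} member {sorted(outside)[0]!r} not in background"
            )
        if len(members) >= min_community_size:
            comm_items.append((cid, members))
    set_items = []
    for sid in sorted(sets):
        in_bg = frozenset(sets[sid]) & background
        if not in_bg:
            log.warning("set %s disjoint from background; skipped", sid)
            continue
        set_items.append((sid, in_bg))
    rows = []
    for cid, members in comm_items:
        n = len(members)
        for sid, sgenes in set_items:
            K = len(sgenes)
            k = len(members & sgenes)
            rows.append((cid, sid, k, n, K, N, fisher_one_sided(k, n, K, N)))
    df = pd.DataFrame(
        rows, columns=["community_id", "set_id", "k", "n", "K", "N", "p_value"]
    )
    if df.empty:
        df["q_value"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return df
    df["q_value"] = bh_fdr(df["p_value"].to_numpy())
    df["significant"] = (df["q_value"] < alpha) & (df["k"] >= min_overlap)
    return df
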