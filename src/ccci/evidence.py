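"""Evidence integration: combined confidence scores and the interactome.

Per-pair evidence arrives as independent channel scores in [0, 1] (genomic
context, high-throughput experiments, co-expression, prior knowledge …).
Channels are combined probabilistically after removing a shared prior — the
noisy-OR convention used by functional-association databases — with the
option of excluding channels (e.g. text mining) from the combination.  The
interactome keeps pairs whose combined score clears a high-confidence
cutoff, drops singletons, and is summarised by its connected components and
a log–log degree-distribution fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections.abc import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULT_CUTOFF, DEFAULT_PRIOR
from .errors import DataError

__all__ = [
    "combine_channel_scores",
    "add_combined_scores",
    "Interactome",
    "build_interactome",
    "remove_singletons",
    "connected_components",
    "DegreeFit",
    "fit_power_law",
]


def combine_channel_scores(
    scores: Sequence[float],
    prior: float = DEFAULT_PRIOR,
    excluded: Iterable[int] = (),
) -> float:
    """Combine channel scores into one confidence value.

    Each non-excluded channel is prior-corrected, ``s' = max(0, (s - p) /
    (1 - p))``, corrected scores combine as a noisy OR, ``c' = 1 - prod(1 -
    s')``, and the prior is restored: ``c = c' * (1 - p) + p`` when any
    channel contributed, else 0.  The result is order-invariant and monotone
    non-decreasing in every channel.

    Parameters
    ----------
    scores
        Channel scores, each in [0, 1].
    prior
        Baseline probability p in [0, 1) shared by all channels.
    excluded
        0-based indices of channels to leave out of the combination.
    """
    if not 0.0 <= prior < 1.0:
        raise ValueError(f"prior {prior} outside [0, 1)")
    excluded = set(excluded)
    corrected = []
    for i, s in enumerate(scores):
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"channel score {s} at index {i} outside [0, 1]")
        if i in excluded:
            continue
        corrected.append(max(0.0, (s - prior) / (1.0 - prior)))
    if not corrected or all(s == 0.0 for s in corrected):
        return 0.0
    log_miss = sum(math.log1p(-s) for s in corrected if s < 1.0)
    c = 1.0 - (0.0 if any(s == 1.0 for s in corrected) else math.exp(log_miss))
    return min(1.0, c * (1.0 - prior) + prior)


def add_combined_scores(
    table: pd.DataFrame,
    prior: float = DEFAULT_PRIOR,
    excluded_channels: Iterable[str] = (),
) -> pd.DataFrame:
    """Vectorised combined score for an evidence table.

    ``table`` has gene_a, gene_b then one column per channel; returns a copy
    with a ``combined`` column.  ``excluded_channels`` are named columns.
    """
    channels = [c for c in table.columns if c not in ("gene_a", "gene_b", "combined")]
    excluded = set(excluded_channels)
    unknown = excluded - set(channels)
    if unknown:
        raise DataError(f"excluded channels not in table: {sorted(unknown)}")
    used = [c for c in channels if c not in excluded]
    out = table.copy()
    if not used:
        out["combined"] = 0.0
        return out
    s = out[used].to_numpy(dtype=float)
    if ((s < 0) | (s > 1)).any():
        raise DataError("channel scores outside [0, 1]")
    sp = np.clip((s - prior) / (1.0 - prior), 0.0, None)
    cprime = 1.0 - np.prod(1.0 - sp, axis=1)
    combined = np.where(sp.max(axis=1) > 0, cprime * (1.0 - prior) + prior, 0.0)
    out["combined"] = np.minimum(combined, 1.0)
    return out


@dataclass
class Interactome:
    """Undirected weighted gene graph plus the singletons dropped from it."""

    graph: nx.Graph
    singletons_removed: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (a, b, d["weight"]) if a < b else (b, a, d["weight"])
            for a, b, d in self.graph.edges(data=True)
        ]
        rows.sort()
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])


def build_interactome(
    table: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    universe: Iterable[str] | None = None,
) -> Interactome:
    """Threshold the evidence table into an interactome.

    Keeps pairs with ``combined >= cutoff`` (inclusive) whose two endpoints
    both lie in *universe*; universe genes left without any edge stay in the
    node set with degree 0 until :func:`remove_singletons`.
    """
    if "combined" not in table.columns:
        raise DataError("evidence table lacks a 'combined' column; "
                        "run add_combined_scores first")
    if universe is None:
        universe_set = set(table["gene_a"]) | set(table["gene_b"])
    else:
        universe_set = set(universe)
        if not universe_set:
            raise DataError("empty gene universe")
    g = nx.Graph()
    g.add_nodes_from(sorted(universe_set))
    kept = table[table["combined"] >= cutoff]
    for a, b, s in kept[["gene_a", "gene_b", "combined"]].itertuples(index=False):
        if a in universe_set and b in universe_set:
            g.add_edge(a, b, weight=float(s))
    return Interactome(graph=g)


def remove_singletons(net: Interactome) -> Interactome:
    """Move degree-0 nodes to ``singletons_removed``; edges are untouched."""
    g = net.graph.copy()
    singles = sorted(n for n, d in g.degree() if d == 0)
    g.remove_nodes_from(singles)
    return Interactome(graph=g, singletons_removed=list(net.singletons_removed) + singles)


def connected_components(net: Interactome) -> list[list[str]]:
    """Components as sorted member lists, largest first.

    Ties in size break on the smallest member id, so component 1 is always
    well defined.
    """
    comps = [sorted(c) for c in nx.connected_components(net.graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


@dataclass
class DegreeFit:
    """Power-law fit of the degree distribution.

    ``alpha`` is the slope of an ordinary least-squares fit of log10
    frequency on log10 degree (expected negative for scale-free networks);
    ``None`` when fewer than 3 distinct degrees are observed.
    """

    alpha: float | None
    r_squared: float | None
    points: list[tuple[int, int]]
    method: str = "ols"


def fit_power_law(net: Interactome, method: str = "ols") -> DegreeFit:
    """Fit ``frequency(k) ~ C * k**alpha`` to the degree distribution.

    ``method='ols'`` regresses log10 frequency on log10 degree over degrees
    ≥ 1 with non-zero frequency (the convention of interactive network-
    analysis tools).  ``method='mle'`` instead reports the continuous
    maximum-likelihood exponent ``-(1 + n / sum(log(k / (kmin - 0.5))))``
    with ``kmin`` the smallest observed degree, for cross-checking; r² is not defined there.
    """
    degrees = [d for _, d in net.graph.degree() if d >= 1]
    counts: dict[int, int] = {}
    for d in degrees:
        counts[d] = counts.get(d, 0) + 1
    points = sorted(counts.items())
    if len(points) < 3:
        return DegreeFit(alpha=None, r_squared=None, points=points, method=method)
    if method == "ols":
        x = np.log10([k for k, _ in points])
        y = np.log10([f for _, f in points])
        res = stats.linregress(x, y)
        return DegreeFit(
            alpha=float(res.slope),
            r_squared=float(res.rvalue**2),
            points=points,
            method="ols",
        )
    if method == "mle":
        k = np.asarray(degrees, dtype=float)
        alpha_hat = 1.0 + len(k) / np.sum(np.log(k / (k.min() - 0.5)))
        return DegreeFit(alpha=-float(alpha_hat), r_squared=None, points=points,
                         method="mle")
    raise ValueError(f"unknown power-law fit method {method!r}")
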