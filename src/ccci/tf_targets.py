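"""Transcription-factor target derivation and per-community enrichment.

A gene is a *candidate* target of a TF when a conserved binding site for
that TF overlaps the gene's regulatory window: the gene body plus 10 kb
beyond the 5' end and 3 kb beyond the 3' end (strand-aware, clipped at
zero, 0-based half-open, ≥1 bp overlap).  Candidates are then filtered by
co-expression with the TF — Pearson r at least ``r_min`` and a BH-adjusted
correlation test below ``q_max``, the family being every (TF, candidate)
pair of the run.  TFs left without targets are dropped.  Target sets feed
the generic enrichment machinery with a minimum of 5 targets per community.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .enrichment import bh_fdr, enrich_communities
from .errors import DataError

log = logging.getLogger(__name__)

__all__ = ["assign_candidates", "TFTargetSet", "coexpression_filter", "tf_enrichment"]


def gene_windows(
    models: pd.DataFrame, upstream: int = 10_000, downstream: int = 3_000
) -> pd.DataFrame:
    """Regulatory window per gene model, strand-aware and clipped at 0."""
    win = models.copy()
    plus = win["strand"] == "+"
    win["win_start"] = np.where(
        plus, win["start"] - upstream, win["start"] - downstream
    ).clip(min=0)
    win["win_end"] = np.where(plus, win["end"] + downstream, win["end"] + upstream)
    return win


def assign_candidates(
    sites: pd.DataFrame,
    models: pd.DataFrame,
    upstream: int = 10_000,
    downstream: int = 3_000,
    universe: set[str] | frozenset[str] | None = None,
) -> dict[str, frozenset[str]]:
    """Map each TF to the genes whose window one of its sites overlaps.

    ``sites`` and ``models`` are BED6 frames (``name`` = TF id for sites,
    gene id for models).  A site may hit several genes; genes outside
    *universe* (when given) are ignored.
    """
    for df, what in ((sites, "sites"), (models, "models")):
        if (df["end"] <= df["start"]).any():
            raise DataError(f"{what}: intervals must satisfy end > start")
    win = gene_windows(models, upstream, downstream)
    trees: dict[str, IntervalTree] = {}
    for chrom, ws, we, gene in win[["chrom", "win_start", "win_end", "name"]].itertuples(
        index=False
    ):
        if universe is not None and gene not in universe:
            continue
        trees.setdefault(chrom, IntervalTree()).addi(int(ws), int(we), gene)
    out: dict[str, set[str]] = {}
    for chrom, s, e, tf in sites[["chrom", "start", "end", "name"]].itertuples(
        index=False
    ):
        tree = trees.get(chrom)
        if tree is None:
            continue
        hits = {iv.data for iv in tree.overlap(int(s), int(e))}
        if hits:
            out.setdefault(tf, set()).update(hits)
    return {tf: frozenset(genes) for tf, genes in out.items()}


@dataclass
class TFTargetSet:
    """Candidate and filtered target sets of one TF."""

    tf: str
    candidate_targets: frozenset[str]
    targets: frozenset[str]
    correlations: dict[str, float]          # per kept target


def coexpression_filter(
    candidates: dict[str, frozenset[str]],
    expression: pd.DataFrame,
    r_min: float = 0.5,
    q_max: float = 0.05,
) -> dict[str, TFTargetSet]:
    """Keep candidates significantly co-expressed with their TF.

    The correlation test is the usual t-distributed test of Pearson r; BH
    correction runs over all (TF, candidate) pairs of the call.  TFs absent
    from the expression matrix are dropped with a warning, zero-variance
    profiles skip the pair, and TFs whose filtered target set is empty are
    dropped from the result.
    """
    if expression.shape[1] < 3:
        raise DataError("expression matrix needs at least 3 conditions")
    pairs: list[tuple[str, str, float, float]] = []   # tf, gene, r, p
    for tf in sorted(candidates):
        if tf not in expression.index:
            log.warning("TF %s absent from expression matrix; dropped", tf)
            continue
        x = expression.loc[tf].to_numpy(dtype=float)
        if np.std(x) == 0:
            log.warning("TF %s has a zero-variance profile; dropped", tf)
            continue
        for gene in sorted(candidates[tf]):
            if gene == tf or gene not in expression.index:
                continue
            y = expression.loc[gene].to_numpy(dtype=float)
            if np.std(y) == 0:
                log.warning("gene %s has zero variance; pair (%s, %s) skipped",
                            gene, tf, gene)
                continue
            r, p = stats.pearsonr(x, y)
            pairs.append((tf, gene, float(r), float(max(p, np.finfo(float).tiny))))
    if not pairs:
        return {}
    q = bh_fdr([p for _, _, _, p in pairs])
    kept: dict[str, dict[str, float]] = {}
    for (tf, gene, r, _), qv in zip(pairs, q):
        if r >= r_min and qv < q_max:
            kept.setdefault(tf, {})[gene] = r
    out: dict[str, TFTargetSet] = {}
    for tf in sorted(candidates):
        targets = kept.get(tf, {})
        if not targets:
            continue
        out[tf] = TFTargetSet(
            tf=tf,
            candidate_targets=candidates[tf],
            targets=frozenset(targets),
            correlations=targets,
        )
    return out


def tf_enrichment(
    communities,
    tf_sets: dict[str, TFTargetSet],
    background: set[str] | frozenset[str],
    min_community_size: int = 5,
    min_overlap: int = 5,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-community TF-target enrichment plus the per-TF sharing summary.

    Returns the enrichment table (one row per community × TF) and a per-TF
    summary with the number of communities each TF is enriched in —
    separating community-specific TFs from those shared by several.
    """
    sets = {tf: ts.targets & frozenset(background) for tf, ts in tf_sets.items()}
    sets = {tf: s for tf, s in sets.items() if s}
    table = enrich_communities(
        communities,
        sets,
        background,
        min_community_size=min_community_size,
        min_overlap=min_overlap,
        alpha=alpha,
    )
    if table.empty:
        summary = pd.DataFrame(columns=["tf", "n_enriched_communities", "shared"])
    else:
        counts = (
            table[table["significant"]]
            .groupby("set_id")["community_id"]
            .nunique()
            .reindex(sorted(sets), fill_value=0)
        )
        summary = pd.DataFrame(
            {
                "tf": counts.index,
                "n_enriched_communities": counts.to_numpy(),
                "shared": (counts > 1).to_numpy(),
            }
        ).reset_index(drop=True)
    return table, summary
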