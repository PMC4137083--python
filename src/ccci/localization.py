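"""Ciliary vs centrosomal sub-localization calls.

Curated evidence wins: genes present in a curated centrosome collection are
called centrosomal, then genes curated as ciliary are called ciliary.  The
remaining genes are voted on from high-throughput experiment membership:
with A = number of ciliary-group experiments containing the gene and B =
number of centrosomal-group experiments containing it,

    A > B + 1  ->  ciliary
    B > A + 1  ->  centrosomal
    |A - B| <= 1  ->  unknown

Nuclear localization is an independent flag, carried alongside the call.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable

import pandas as pd

from .errors import DataError

log = logging.getLogger(__name__)

__all__ = ["vote", "annotate_all"]

CILIARY_PREFIX = "cilia_exp"
CENTROSOMAL_PREFIX = "centro_exp"


def vote(A: int, B: int) -> str:
    """Experiment-count voting rule; total on non-negative (A, B)."""
    if A < 0 or B < 0:
        raise DataError(f"experiment counts must be non-negative (A={A}, B={B})")
    if A > B + 1:
        return "ciliary"
    if B > A + 1:
        return "centrosomal"
    return "unknown"


def annotate_all(
    genes: Iterable[str],
    centrosome_curated: set[str] | frozenset[str],
    cilium_curated: set[str] | frozenset[str],
    nuclear_set: set[str] | frozenset[str],
    experiments: pd.DataFrame,
    ciliary_cols: list[str] | None = None,
    centrosomal_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Assign every gene a localization call with provenance.

    Parameters
    ----------
    genes
        Genes to annotate (e.g. the interactome's nodes).
    centrosome_curated, cilium_curated
        Curated sets; curated membership takes precedence over voting, and a
        gene found in both resolves to unknown/unresolved with a warning.
    nuclear_set
        Genes with reported nuclear localization; sets an orthogonal flag.
    experiments
        0/1 matrix indexed by gene; ciliary-group / centrosomal-group
        columns are taken from ``ciliary_cols`` / ``centrosomal_cols`` or
        recognised by the ``cilia_exp`` / ``centro_exp`` prefixes.  Genes
        missing from the matrix count as absent everywhere (warned once).

    Returns
    -------
    DataFrame with columns gene, call, provenance, A, B, nuclear.
    """
    if ciliary_cols is None:
        ciliary_cols = [c for c in experiments.columns if c.startswith(CILIARY_PREFIX)]
    if centrosomal_cols is None:
        centrosomal_cols = [
            c for c in experiments.columns if c.startswith(CENTROSOMAL_PREFIX)
        ]
    if not ciliary_cols or not centrosomal_cols:
        raise DataError("experiment matrix lacks ciliary/centrosomal group columns")
    genes = sorted(set(genes))
    missing = [g for g in genes if g not in experiments.index]
    if missing:
        log.warning(
            "%d genes missing from the experiment matrix (treated as all-zero), "
            "e.g. %s", len(missing), missing[:3],
        )
    rows = []
    for g in genes:
        if g in experiments.index:
            A = int(experiments.loc[g, ciliary_cols].sum())
            B = int(experiments.loc[g, centrosomal_cols].sum())
        else:
            A = B = 0
        in_centro = g in centrosome_curated
        in_cilium = g in cilium_curated
        if in_centro and in_cilium:
            log.warning("gene %s curated in both collections; call unresolved", g)
            call, prov = "unknown", "unresolved"
        elif in_centro:
            call, prov = "centrosomal", "curated_centrosome_db"
        elif in_cilium:
            call, prov = "ciliary", "curated_go_cilium"
        else:
            call, prov = vote(A, B), "voted"
        rows.append((g, call, prov, A, B, g in nuclear_set))
    return pd.DataFrame(
        rows, columns=["gene", "call", "provenance", "A", "B", "nuclear"]
    )
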