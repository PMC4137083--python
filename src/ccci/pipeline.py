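"""End-to-end orchestration: simulate → build → cluster → enrich →
localize → supercomm → tf, with a machine-readable run summary.

Each stage is a thin call into the corresponding library module; running a
stage here is byte-identical to calling that module directly on the same
inputs.  The run summary JSON carries per-stage counts and the full
configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os

import pandas as pd

from . import enrichment, evidence, io, localization, mcode, supercommunity, synthetic
from . import tf_targets as tft
from .config import PipelineConfig
from .errors import DataError

log = logging.getLogger(__name__)

__all__ = ["run_all"]


def _require(path: str, stage: str) -> str:
    if not os.path.exists(path):
        raise DataError(f"stage {stage}: missing input file {path}")
    return path


def run_all(config: PipelineConfig, simulate: bool = True,
            paths: dict[str, str] | None = None) -> dict:
    """Run the whole pipeline and return the summary dict.

    With ``simulate=True`` (default) all inputs are generated into
    ``config.outdir`` first; otherwise ``paths`` must name existing input
    files under the keys used by :func:`ccci.synthetic.simulate_all`.
    Outputs (TSV tables + ``summary.json``) are written atomically into
    ``config.outdir``.
    """
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    if simulate:
        log.info("stage simulate: writing synthetic inputs to %s", outdir)
        paths = synthetic.simulate_all(config.sim, outdir)
    if paths is None:
        raise DataError("stage simulate: no input paths supplied and simulate=False")

    # --- build ------------------------------------------------------------
    table = io.read_evidence(_require(paths["evidence"], "build"))
    table = evidence.add_combined_scores(
        table, prior=config.prior, excluded_channels=config.excluded_channels
    )
    universe = pd.read_csv(_require(paths["universe"], "build"), sep="\t",
                           dtype={"gene": str})
    net = evidence.build_interactome(table, cutoff=config.cutoff,
                                     universe=universe["gene"])
    net = evidence.remove_singletons(net)
    comps = evidence.connected_components(net)
    fit = evidence.fit_power_law(net)
    io.write_tsv(net.edge_table(), os.path.join(outdir, "interactome.tsv"))
    comp_rows = [(g, i) for i, comp in enumerate(comps, 1) for g in comp]
    io.write_tsv(pd.DataFrame(comp_rows, columns=["gene", "component_id"]),
                 os.path.join(outdir, "components.tsv"))
    log.info("stage build: %d genes, %d edges, %d singletons removed",
             len(net.nodes), net.n_edges, len(net.singletons_removed))

    # --- cluster ----------------------------------------------------------
    communities = mcode.detect_communities(net.graph, config.mcode)
    memb = mcode.membership(communities)
    io.write_tsv(
        pd.DataFrame(
            sorted((g, c.id, c.complex_score) for c in communities for g in c.members),
            columns=["gene", "community_id", "complex_score"],
        ),
        os.path.join(outdir, "communities.tsv"),
    )
    io.write_tsv(
        pd.DataFrame(
            [(c.id, len(c.members), c.complex_score, c.seed) for c in communities],
            columns=["community_id", "size", "score", "seed_gene"],
        ),
        os.path.join(outdir, "communities_summary.tsv"),
    )
    log.info("stage cluster: %d communities", len(communities))

    # --- enrich (GO-like terms) -------------------------------------------
    background = set(net.graph.nodes)
    comm_map = {c.id: set(c.members) for c in communities}
    sets = {t: g for t, (_, g) in io.read_gmt(
        _require(paths["annotations"], "enrich")).items()}
    enr = enrichment.enrich_communities(
        comm_map, sets, background,
        min_community_size=config.min_community_size,
        alpha=config.enrich_alpha,
    )
    io.write_tsv(enr, os.path.join(outdir, "enrichment_terms.tsv"))

    # --- localize ---------------------------------------------------------
    experiments = io.read_experiments(_require(paths["experiments"], "localize"))
    centro = io.read_gene_list(_require(paths["centrosome_curated"], "localize"))
    cilia = io.read_gene_list(_require(paths["cilium_curated"], "localize"))
    nuclear = io.read_gene_list(_require(paths["nuclear"], "localize"))
    loc = localization.annotate_all(
        net.graph.nodes, centro, cilia, nuclear, experiments
    )
    io.write_tsv(loc, os.path.join(outdir, "localization.tsv"))
    loc_sets = {
        "ciliary": set(loc.loc[loc["call"] == "ciliary", "gene"]),
        "centrosomal": set(loc.loc[loc["call"] == "centrosomal", "gene"]),
        "nuclear": set(loc.loc[loc["nuclear"], "gene"]),
    }
    loc_sets = {k: v for k, v in loc_sets.items() if v}
    loc_enr = enrichment.enrich_communities(
        comm_map, loc_sets, background,
        min_community_size=config.min_community_size,
        alpha=config.enrich_alpha,
    )
    io.write_tsv(loc_enr, os.path.join(outdir, "enrichment_localization.tsv"))

    # --- supercomm --------------------------------------------------------
    cg = supercommunity.build_community_graph(
        net.graph, communities, min_size=config.min_community_size
    )
    io.write_tsv(cg.edge_table(), os.path.join(outdir, "community_graph.tsv"))
    scs = supercommunity.detect_supercommunities(cg, config.mcode)
    io.write_tsv(
        pd.DataFrame(
            sorted((sc.id, cid) for sc in scs for cid in sc.members),
            columns=["supercommunity_id", "community_id"],
        ),
        os.path.join(outdir, "supercommunities.tsv"),
    )
    log.info("stage supercomm: %d super-communities", len(scs))

    # --- tf ---------------------------------------------------------------
    sites = io.read_bed6(_require(paths["sites"], "tf"))
    models = io.read_bed6(_require(paths["models"], "tf"))
    expr = io.read_expression(_require(paths["expression"], "tf"))
    candidates = tft.assign_candidates(
        sites, models,
        upstream=config.tf_upstream, downstream=config.tf_downstream,
        universe=set(universe["gene"]),
    )
    tf_sets = tft.coexpression_filter(
        candidates, expr, r_min=config.tf_r_min, q_max=config.tf_q_max
    )
    tf_sets = {
        tf: ts for tf, ts in tf_sets.items()
        if ts.targets & background
    }
    io.write_gmt(
        {tf: ("targets", ts.targets) for tf, ts in tf_sets.items()},
        os.path.join(outdir, "tf_targets.gmt"),
    )
    tf_enr, tf_summary = tft.tf_enrichment(
        comm_map, tf_sets, background,
        min_community_size=config.min_community_size,
        min_overlap=config.tf_min_overlap,
        alpha=config.enrich_alpha,
    )
    io.write_tsv(tf_enr, os.path.join(outdir, "enrichment_tf.tsv"))
    io.write_tsv(tf_summary, os.path.join(outdir, "tf_summary.tsv"))

    # --- summary ----------------------------------------------------------
    summary = {
        "config": dataclasses.asdict(config),
        "genes": len(net.nodes),
        "edges": net.n_edges,
        "singletons": len(net.singletons_removed),
        "components": len(comps),
        "largest_component": len(comps[0]) if comps else 0,
        "degree_alpha": fit.alpha,
        "degree_fit_r2": fit.r_squared,
        "communities": len(communities),
        "communities_min_size": sum(
            1 for c in communities if len(c.members) >= config.min_community_size
        ),
        "community_graph_edges": cg.graph.number_of_edges(),
        "supercommunities": len(scs),
        "enriched_term_pairs": int(enr["significant"].sum()) if not enr.empty else 0,
        "enriched_localization_pairs": (
            int(loc_enr["significant"].sum()) if not loc_enr.empty else 0
        ),
        "tfs_with_targets": len(tf_sets),
        "enriched_tf_pairs": int(tf_enr["significant"].sum()) if not tf_enr.empty else 0,
        "localization_calls": loc["call"].value_counts().to_dict(),
    }
    io.atomic_write(
        os.path.join(outdir, "summary.json"),
        json.dumps(summary, indent=1, sort_keys=True) + "\n",
    )
    return summary
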