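"""Synthetic pipeline inputs with planted ground truth.

Everything the pipeline consumes can be generated here with a known answer
key: a gene universe with planted dense blocks (the communities MCODE
should recover), multi-channel evidence scores straddling the confidence
cutoff, noisy ciliary/centrosomal experiment memberships, GO-like term
collections with planted enrichments, curated localization subsamples, and
TF regulons realised both as binding-site intervals on a synthetic
chromosome and as correlated expression profiles.

A single RNG stream drives one simulation run; ``simulate_all`` draws in a
fixed, documented order (universe → evidence → experiments → annotations →
curated sets → TF data) so outputs are byte-identical for a given config.

Score model: channels of planted (intra-block or same-group) pairs are
Beta(8, 2) draws — and the strongest channel is raised, if ever needed, so
the pre-noise combined score clears 0.7 — while other sampled pairs draw
Beta(2, 8) channels that mostly fall below the cutoff.  Gaussian channel
noise is added last and clipped to [0, 1].
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io
from .config import DEFAULT_PRIOR, SimConfig
from .enrichment import fisher_one_sided
from .errors import ConfigError
from .evidence import combine_channel_scores

__all__ = [
    "GroundTruth",
    "generate_universe",
    "generate_evidence",
    "generate_localization_experiments",
    "generate_annotations",
    "generate_curated_sets",
    "generate_tf_data",
    "simulate_all",
]

GENE_BODY = 10_000       # bp, synthetic gene length
GENE_GAP = 30_000        # bp between consecutive gene bodies; > upstream+downstream
BACKGROUND = -1          # block id of non-planted genes

#: target for the deterministic boost guaranteeing planted pairs clear 0.7
_BOOST_TARGET = 0.75
_BOOST_TRIGGER = 0.72


@dataclass
class GroundTruth:
    """The answer key of one simulated universe."""

    partition: dict[str, int]                 # gene -> block id (BACKGROUND if none)
    localization: dict[str, str]              # gene -> ciliary|centrosomal|background
    regulons: dict[str, frozenset[str]] = field(default_factory=dict)
    enriched_terms: list[tuple[int, str]] = field(default_factory=list)

    def block_members(self) -> dict[int, frozenset[str]]:
        out: dict[int, set[str]] = {}
        for g, b in self.partition.items():
            if b != BACKGROUND:
                out.setdefault(b, set()).add(g)
        return {b: frozenset(m) for b, m in out.items()}

    def to_json(self) -> str:
        payload = {
            "partition": self.partition,
            "localization": self.localization,
            "regulons": {tf: sorted(r) for tf, r in sorted(self.regulons.items())},
            "enriched_terms": [[b, t] for b, t in self.enriched_terms],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            partition={g: int(b) for g, b in d["partition"].items()},
            localization=d["localization"],
            regulons={tf: frozenset(r) for tf, r in d["regulons"].items()},
            enriched_terms=[(int(b), t) for b, t in d["enriched_terms"]],
        )


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def generate_universe(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Gene table (gene, block) plus the full ground truth.

    Blocks are assigned to a random permutation of the universe; even-
    indexed blocks are truly ciliary, odd-indexed truly centrosomal,
    background genes carry neither label.  Planted regulons are drawn here
    too: the first ``min(n_tfs, n_blocks)`` TFs concentrate ~70% of their
    targets inside "their" block (one planted per-block regulon each), the
    rest sample targets uniformly.
    """
    if not isinstance(cfg, SimConfig):
        raise ConfigError("generate_universe: cfg must be a SimConfig")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)
    order = rng.permutation(cfg.n_genes)
    partition = {g: BACKGROUND for g in genes}
    pos = 0
    for block, size in enumerate(cfg.community_sizes):
        for idx in order[pos:pos + size]:
            partition[genes[idx]] = block
        pos += size
    localization = {}
    for g in genes:
        b = partition[g]
        if b == BACKGROUND:
            localization[g] = "background"
        else:
            localization[g] = "ciliary" if b % 2 == 0 else "centrosomal"
    truth = GroundTruth(partition=partition, localization=localization)
    # Planted regulons (drawn here so TF identity is part of the universe).
    # Regulons are pairwise disjoint and never contain a TF gene: each target
    # tracks exactly one TF's latent expression factor, so the planted
    # TF-target correlation structure is well defined.
    if cfg.n_tfs > 0:
        blocks = truth.block_members()
        tf_idx = rng.choice(cfg.n_genes, size=min(cfg.n_tfs, cfg.n_genes),
                            replace=False)
        tfs = [genes[i] for i in tf_idx]
        claimed: set[str] = set(tfs)
        for j, tf in enumerate(tfs):
            size = cfg.regulon_size
            chosen: list[str] = []
            if j in blocks:
                inside = sorted(blocks[j] - claimed)
                n_in = min(len(inside), max(1, round(0.7 * size)))
                if n_in > 0:
                    chosen += list(rng.choice(inside, size=n_in, replace=False))
            pool = sorted(set(genes) - claimed - set(chosen))
            n_out = min(size - len(chosen), len(pool))
            if n_out > 0:
                chosen += list(rng.choice(pool, size=n_out, replace=False))
            claimed.update(chosen)
            truth.regulons[tf] = frozenset(chosen)
    truth.enriched_terms = [
        (b, f"T{b:03d}")
        for b in range(min(len(cfg.community_sizes), cfg.n_terms))
    ]
    df = pd.DataFrame({"gene": genes, "block": [partition[g] for g in genes]})
    return df, truth


def _boost_row(row: np.ndarray, prior: float) -> np.ndarray:
    """Raise the strongest channel so the combined score hits the target."""
    target_c = (_BOOST_TARGET - prior) / (1.0 - prior)
    idx = int(np.argmax(row))
    rest = np.delete(row, idx)
    rest_corr = np.clip((rest - prior) / (1.0 - prior), 0.0, None)
    miss = float(np.prod(1.0 - rest_corr)) if rest.size else 1.0
    if miss <= 1.0 - target_c:       # already above target without this channel
        needed = 0.0
    else:
        needed = 1.0 - (1.0 - target_c) / miss
    new = max(row[idx], needed * (1.0 - prior) + prior)
    row = row.copy()
    row[idx] = min(new, 1.0)
    return row


def generate_evidence(
    universe: pd.DataFrame,
    truth: GroundTruth,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    prior: float = DEFAULT_PRIOR,
) -> pd.DataFrame:
    """Per-pair channel scores with planted dense blocks.

    Intra-block pairs are sampled with probability ``p_intra`` and receive
    high Beta(8, 2) channel scores guaranteed to combine above 0.7 before
    noise; pairs between blocks sharing a configured group are sampled at
    ``p_group`` with the same high scores; every other pair is sampled at
    ``p_inter`` with low Beta(2, 8) scores that mostly miss the cutoff.
    Unordered pairs appear at most once, in canonical (gene_a < gene_b)
    lexicographic order; no self-pairs.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    genes = universe["gene"].tolist()
    block = np.array([truth.partition[g] for g in genes])
    n = len(genes)
    ii, jj = np.triu_indices(n, k=1)
    bi, bj = block[ii], block[jj]
    intra = (bi == bj) & (bi != BACKGROUND)
    group = np.zeros(len(ii), dtype=bool)
    if cfg.block_groups:
        gid = {}
        for gnum, grp in enumerate(cfg.block_groups):
            for b in grp:
                gid[b] = gnum
        gi = np.array([gid.get(b, -1) for b in bi])
        gj = np.array([gid.get(b, -1) for b in bj])
        group = (~intra) & (gi >= 0) & (gi == gj)
    u = rng.random(len(ii))
    p_pair = np.where(intra, cfg.p_intra, np.where(group, cfg.p_group, cfg.p_inter))
    sampled = u < p_pair
    high = sampled & (intra | group)
    low = sampled & ~high
    k = cfg.n_channels
    scores = np.empty((int(sampled.sum()), k))
    sel = np.flatnonzero(sampled)
    is_high = high[sel]
    scores[is_high] = rng.beta(8.0, 2.0, size=(int(high.sum()), k))
    scores[~is_high] = rng.beta(2.0, 8.0, size=(int(low.sum()), k))
    # deterministic boost: planted pairs must combine above the cutoff
    for r in np.flatnonzero(is_high):
        if combine_channel_scores(scores[r], prior=prior) < _BOOST_TRIGGER:
            scores[r] = _boost_row(scores[r], prior)
    if cfg.channel_noise_sd > 0:
        scores = scores + rng.normal(0.0, cfg.channel_noise_sd, size=scores.shape)
    scores = np.clip(scores, 0.0, 1.0)
    ga = [genes[i] for i in ii[sel]]
    gb = [genes[j] for j in jj[sel]]
    df = pd.DataFrame({"gene_a": ga, "gene_b": gb})
    for c in range(k):
        df[f"channel_{c + 1}"] = scores[:, c]
    swap = df["gene_a"] > df["gene_b"]          # ids are pre-sorted; keep the guard
    df.loc[swap, ["gene_a", "gene_b"]] = df.loc[swap, ["gene_b", "gene_a"]].to_numpy()
    return df.sort_values(["gene_a", "gene_b"], ignore_index=True)


def generate_localization_experiments(
    universe: pd.DataFrame,
    truth: GroundTruth,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """0/1 gene × experiment matrix with symmetric flip noise.

    A truly ciliary gene appears in each ciliary-group experiment with
    probability ``1 - flip_prob`` and in each centrosomal-group experiment
    with probability ``flip_prob`` (and symmetrically); background genes
    appear anywhere with probability ``flip_prob``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    genes = universe["gene"].tolist()
    cols = [f"cilia_exp_{i + 1:02d}" for i in range(cfg.n_ciliary_exp)] + [
        f"centro_exp_{i + 1:02d}" for i in range(cfg.n_centrosomal_exp)
    ]
    p = np.full((len(genes), len(cols)), cfg.flip_prob)
    loc = np.array([truth.localization[g] for g in genes])
    nc = cfg.n_ciliary_exp
    p[loc == "ciliary", :nc] = 1.0 - cfg.flip_prob
    p[loc == "centrosomal", nc:] = 1.0 - cfg.flip_prob
    flags = (rng.random(p.shape) < p).astype(int)
    return pd.DataFrame(flags, index=pd.Index(genes, name="gene"), columns=cols)


def generate_annotations(
    universe: pd.DataFrame,
    truth: GroundTruth,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, tuple[str, frozenset[str]]]:
    """GO-like term collection with planted per-block enrichments.

    Each planted (block, term) pair seeds the term with ~60% of the block
    plus random genes, adding block members until the one-sided
    hypergeometric p against the full universe drops below 1e-4 — so the
    planted enrichment survives testing at p < 0.001.  Remaining terms are
    uniform draws of size 10–40 (capped by the universe).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    genes = universe["gene"].tolist()
    n_univ = len(genes)
    blocks = truth.block_members()
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    planted = dict(truth.enriched_terms)        # block -> term id
    for b in sorted(planted):
        term = planted[b]
        members = sorted(blocks[b])
        take = max(2, math.ceil(0.6 * len(members)))
        inside = list(rng.choice(members, size=min(take, len(members)), replace=False))
        outside_pool = sorted(set(genes) - set(members))
        n_extra = min(10, len(outside_pool))
        extra = list(rng.choice(outside_pool, size=n_extra, replace=False))
        remaining = [g for g in members if g not in inside]
        while True:
            K = len(inside) + len(extra)
            p = fisher_one_sided(len(inside), len(members), K, n_univ)
            if p < 1e-4 or not remaining:
                break
            inside.append(remaining.pop())
        sets[term] = (f"planted block {b}", frozenset(inside + extra))
    for t in range(len(planted), cfg.n_terms):
        size = int(rng.integers(10, 41))
        size = min(size, n_univ)
        idx = rng.choice(n_univ, size=size, replace=False)
        sets[f"T{t:03d}"] = ("random term", frozenset(genes[i] for i in idx))
    return sets


def generate_curated_sets(
    universe: pd.DataFrame,
    truth: GroundTruth,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    curated_fraction: float = 0.3,
    nuclear_fraction: float = 0.2,
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """Curated centrosome / cilium subsamples plus a nuclear list.

    Curated sets subsample the corresponding ground-truth class (emulating
    an incomplete curated database); the nuclear list is an independent
    random subset of the universe.
    Returns (centrosome_curated, cilium_curated, nuclear).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    genes = universe["gene"].tolist()

    def sub(pool: list[str], frac: float) -> frozenset[str]:
        size = int(round(frac * len(pool)))
        if size == 0 or not pool:
            return frozenset()
        return frozenset(rng.choice(sorted(pool), size=size, replace=False))

    centro = sub([g for g in genes if truth.localization[g] == "centrosomal"],
                 curated_fraction)
    cilia = sub([g for g in genes if truth.localization[g] == "ciliary"],
                curated_fraction)
    nuclear = sub(genes, nuclear_fraction)
    return centro, cilia, nuclear


def generate_tf_data(
    universe: pd.DataFrame,
    truth: GroundTruth,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene models, binding sites and an expression matrix for the regulons.

    Gene models are 10 kb bodies separated by 30 kb gaps on one synthetic
    chromosome — wide enough that the 10 kb / 3 kb regulatory windows of
    neighbouring genes never touch.  Every true target carries at least one
    site for its TF inside its window (body, upstream or near-3' placement);
    a configurable fraction of spurious sites land in windows of non-target
    genes, and one decoy per TF sits in the dead zone between windows.
    Expression ties each regulon to its TF through a shared latent factor
    with ``expr_noise_sd`` Gaussian noise, giving an expected TF–target
    Pearson correlation of ``1 / (1 + sd^2)``; all other genes are
    independent noise.

    Returns (models, sites, expression).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    genes = universe["gene"].tolist()
    starts = {}
    rows = []
    for i, g in enumerate(genes):
        start = GENE_GAP + i * (GENE_BODY + GENE_GAP)
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append(("chrS", start, start + GENE_BODY, g, 0, strand))
        starts[g] = (start, start + GENE_BODY, strand)
    models = pd.DataFrame(rows, columns=io.BED6_COLUMNS)

    def site_in_window(g: str) -> tuple[int, int]:
        start, end, strand = starts[g]
        mode = rng.integers(0, 3)
        if mode == 0:                                   # gene body
            pos = start + GENE_BODY // 2
        elif mode == 1:                                 # 5 kb upstream of the 5' end
            pos = start - 5_000 if strand == "+" else end + 5_000 - 10
        else:                                           # 1.5 kb past the 3' end
            pos = end + 1_500 if strand == "+" else start - 1_510
        return pos, pos + 10

    site_rows = []
    for tf in sorted(truth.regulons):
        regulon = sorted(truth.regulons[tf])
        for g in regulon:
            s, e = site_in_window(g)
            site_rows.append(("chrS", s, e, tf, 0, "."))
        # spurious sites: in-window hits on genes outside the regulon
        n_fp = int(round(cfg.fp_site_rate * len(regulon)))
        pool = sorted(set(genes) - set(regulon) - {tf})
        if n_fp > 0 and pool:
            for g in rng.choice(pool, size=min(n_fp, len(pool)), replace=False):
                s, e = site_in_window(g)
                site_rows.append(("chrS", s, e, tf, 0, "."))
        # one decoy in the inter-window dead zone after a random gene
        gi = int(rng.integers(0, len(genes)))
        _, end_i, _ = starts[genes[gi]]
        pos = end_i + 14_000 + int(rng.integers(0, 2_000))
        site_rows.append(("chrS", pos, pos + 10, tf, 0, "."))
    sites = pd.DataFrame(site_rows, columns=io.BED6_COLUMNS)
    sites["strand"] = "+"          # site strand is irrelevant to assignment

    cols = [f"cond_{c + 1:02d}" for c in range(cfg.n_conditions)]
    expr = pd.DataFrame(
        rng.normal(size=(len(genes), cfg.n_conditions)),
        index=pd.Index(genes, name="gene"),
        columns=cols,
    )
    assigned: set[str] = set()
    for tf in sorted(truth.regulons):
        latent = rng.normal(size=cfg.n_conditions)
        expr.loc[tf] = latent + cfg.expr_noise_sd * rng.normal(size=cfg.n_conditions)
        for g in sorted(truth.regulons[tf]):
            if g in assigned or g in truth.regulons:     # TFs keep their own profile
                continue
            expr.loc[g] = latent + cfg.expr_noise_sd * rng.normal(
                size=cfg.n_conditions
            )
            assigned.add(g)
    return models, sites, expr


def simulate_all(cfg: SimConfig, outdir: str) -> dict[str, str]:
    """Generate and write every pipeline input; returns the path map.

    One RNG stream, fixed draw order; identical configs produce
    byte-identical files.
    """
    rng = np.random.default_rng(cfg.seed)
    os.makedirs(outdir, exist_ok=True)
    universe, truth = generate_universe(cfg, rng)
    evidence = generate_evidence(universe, truth, cfg, rng)
    experiments = generate_localization_experiments(universe, truth, cfg, rng)
    annotations = generate_annotations(universe, truth, cfg, rng)
    centro, cilia, nuclear = generate_curated_sets(universe, truth, cfg, rng)
    models, sites, expr = generate_tf_data(universe, truth, cfg, rng)

    paths = {k: os.path.join(outdir, v) for k, v in {
        "universe": "universe.tsv",
        "evidence": "evidence.tsv",
        "experiments": "experiments.tsv",
        "annotations": "annotations.gmt",
        "centrosome_curated": "curated_centrosome.txt",
        "cilium_curated": "curated_cilium.txt",
        "nuclear": "nuclear.txt",
        "models": "gene_models.bed",
        "sites": "tf_sites.bed",
        "expression": "expression.tsv",
        "truth": "truth.json",
    }.items()}
    io.write_tsv(universe, paths["universe"])
    evidence = evidence.copy()
    for c in evidence.columns[2:]:
        evidence[c] = evidence[c].map(lambda v: f"{v:.6f}")
    io.atomic_write(paths["evidence"], evidence.to_csv(sep="\t", index=False))
    io.write_tsv(experiments, paths["experiments"], index=True)
    io.write_gmt(annotations, paths["annotations"])
    io.write_gene_list(centro, paths["centrosome_curated"])
    io.write_gene_list(cilia, paths["cilium_curated"])
    io.write_gene_list(nuclear, paths["nuclear"])
    io.write_bed6(models, paths["models"])
    io.write_bed6(sites, paths["sites"])
    expr_out = expr.copy().round(6)
    io.atomic_write(paths["expression"], expr_out.to_csv(sep="\t"))
    io.atomic_write(paths["truth"], truth.to_json() + "\n")
    return paths
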