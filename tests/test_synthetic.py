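"""The planted-structure generator: determinism, contracts, calibration."""

import math
import os

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ccci import ConfigError, SimConfig
from ccci.evidence import add_combined_scores
from ccci.synthetic import (
    BACKGROUND,
    GENE_BODY,
    GENE_GAP,
    GroundTruth,
    generate_annotations,
    generate_evidence,
    generate_localization_experiments,
    generate_tf_data,
    generate_universe,
    simulate_all,
)
from ccci.tf_targets import assign_candidates


class TestConfig:
    def test_oversized_blocks_rejected(self):
        with pytest.raises(ConfigError, match="community_sizes"):
            SimConfig(n_genes=10, community_sizes=(8, 8))

    def test_bad_probability_names_field(self):
        with pytest.raises(ConfigError, match="p_intra"):
            SimConfig(p_intra=1.5)


class TestUniverse:
    def test_counts_forced_by_config(self):
        cfg = SimConfig(n_genes=100, community_sizes=(10, 10), seed=1)
        universe, truth = generate_universe(cfg)
        assert len(universe) == 100
        in_blocks = (universe["block"] != BACKGROUND).sum()
        assert in_blocks == 20
        blocks = truth.block_members()
        assert sorted(len(m) for m in blocks.values()) == [10, 10]
        assert len(set().union(*blocks.values())) == 20  # disjoint

    def test_same_seed_identical(self):
        cfg = SimConfig(seed=9)
        u1, t1 = generate_universe(cfg)
        u2, t2 = generate_universe(cfg)
        pd.testing.assert_frame_equal(u1, u2)
        assert t1.partition == t2.partition and t1.regulons == t2.regulons

    def test_regulon_targets_exist(self):
        cfg = SimConfig(seed=2)
        universe, truth = generate_universe(cfg)
        genes = set(universe["gene"])
        for tf, regulon in truth.regulons.items():
            assert tf in genes
            assert regulon <= genes and tf not in regulon


class TestEvidence:
    def test_degenerate_probabilities(self):
        cfg = SimConfig(n_genes=40, community_sizes=(6, 6), p_intra=1.0,
                        p_inter=0.0, channel_noise_sd=0.0, seed=4)
        universe, truth = generate_universe(cfg)
        table = generate_evidence(universe, truth, cfg)
        blocks = truth.block_members()
        n_expected = sum(len(m) * (len(m) - 1) // 2 for m in blocks.values())
        assert len(table) == n_expected
        combined = add_combined_scores(table)["combined"]
        assert (combined >= 0.7).all()
        # every pair is intra-block
        part = truth.partition
        for a, b in table[["gene_a", "gene_b"]].itertuples(index=False):
            assert part[a] == part[b] != BACKGROUND

    def test_scores_clipped_and_pairs_canonical(self, small_evidence):
        channels = [c for c in small_evidence.columns if c.startswith("channel")]
        vals = small_evidence[channels].to_numpy()
        assert (vals >= 0).all() and (vals <= 1).all()
        assert (small_evidence["gene_a"] < small_evidence["gene_b"]).all()
        assert not small_evidence.duplicated(["gene_a", "gene_b"]).any()

    def test_intra_edge_count_within_binomial_bounds(self):
        cfg = SimConfig(n_genes=80, community_sizes=(10, 12, 14), p_intra=0.7,
                        p_inter=0.0, seed=6)
        universe, truth = generate_universe(cfg)
        table = generate_evidence(universe, truth, cfg)
        n_pairs = sum(s * (s - 1) // 2 for s in cfg.community_sizes)
        mean = cfg.p_intra * n_pairs
        sd = math.sqrt(n_pairs * cfg.p_intra * (1 - cfg.p_intra))
        assert abs(len(table) - mean) <= 3 * sd

    def test_group_wiring_adds_cross_block_pairs(self):
        cfg = SimConfig(n_genes=60, community_sizes=(8, 8, 8), p_intra=1.0,
                        p_inter=0.0, block_groups=((0, 1),), p_group=1.0,
                        channel_noise_sd=0.0, seed=8)
        universe, truth = generate_universe(cfg)
        table = generate_evidence(universe, truth, cfg)
        part = truth.partition
        cross = sum(
            1
            for a, b in table[["gene_a", "gene_b"]].itertuples(index=False)
            if part[a] != part[b]
        )
        assert cross == 8 * 8  # every block-0 × block-1 pair, no others


class TestExperiments:
    def test_noiseless_limit(self):
        cfg = SimConfig(n_genes=30, community_sizes=(5, 5), flip_prob=0.0,
                        seed=1)
        universe, truth = generate_universe(cfg)
        m = generate_localization_experiments(universe, truth, cfg)
        nc = cfg.n_ciliary_exp
        for g, loc in truth.localization.items():
            A = m.loc[g][:nc].sum()
            B = m.loc[g][nc:].sum()
            if loc == "ciliary":
                assert (A, B) == (10, 0)
            elif loc == "centrosomal":
                assert (A, B) == (0, 7)
            else:
                assert (A, B) == (0, 0)

    def test_binary_entries_and_shape(self, small_experiments, small_cfg):
        vals = small_experiments.to_numpy()
        assert set(np.unique(vals)) <= {0, 1}
        assert small_experiments.shape[1] == (
            small_cfg.n_ciliary_exp + small_cfg.n_centrosomal_exp
        )

    def test_symmetric_flip_balances_counts(self):
        cfg = SimConfig(n_genes=200, community_sizes=(50, 50), flip_prob=0.5,
                        seed=2)
        universe, truth = generate_universe(cfg)
        m = generate_localization_experiments(universe, truth, cfg)
        # with p = 0.5 every flag is a coin toss: overall fill rate ~ 0.5
        assert m.to_numpy().mean() == pytest.approx(0.5, abs=0.03)


class TestAnnotations:
    def test_planted_term_strongly_enriched(self, small_cfg, small_universe):
        from ccci.enrichment import fisher_one_sided

        universe, truth = small_universe
        sets = generate_annotations(universe, truth, small_cfg,
                                    np.random.default_rng(5))
        blocks = truth.block_members()
        for b, term in truth.enriched_terms:
            _, genes = sets[term]
            k = len(genes & blocks[b])
            p = fisher_one_sided(k, len(blocks[b]), len(genes), len(universe))
            assert p < 1e-3

    def test_every_member_in_universe(self, small_cfg, small_universe):
        universe, truth = small_universe
        sets = generate_annotations(universe, truth, small_cfg,
                                    np.random.default_rng(5))
        genes = set(universe["gene"])
        assert len(sets) == small_cfg.n_terms
        for _, (_, members) in sets.items():
            assert members <= genes

    def test_uniform_terms_have_uniform_pvalues(self):
        """Under the null (random term, random community) the hypergeometric
        p-value is stochastically ≥ uniform; a KS test must not reject
        superuniformity grossly (discreteness makes it conservative)."""
        from ccci.enrichment import fisher_one_sided

        rng = np.random.default_rng(17)
        N, n, K = 200, 40, 30
        ps = []
        for _ in range(400):
            community = rng.choice(N, size=n, replace=False)
            term = rng.choice(N, size=K, replace=False)
            k = len(set(community) & set(term))
            ps.append(fisher_one_sided(k, n, K, N))
        # superuniform: empirical CDF at t must not exceed t by much
        ps = np.sort(ps)
        for t in (0.01, 0.05, 0.1, 0.5):
            frac = np.searchsorted(ps, t, side="right") / len(ps)
            se = math.sqrt(t * (1 - t) / len(ps))
            assert frac <= t + 4 * se


class TestTFData:
    def test_bed_contracts_and_window_layout(self, small_cfg, small_universe):
        universe, truth = small_universe
        models, sites, expr = generate_tf_data(universe, truth, small_cfg,
                                               np.random.default_rng(6))
        assert (models["end"] - models["start"] == GENE_BODY).all()
        assert (models["end"] > models["start"]).all()
        assert (sites["end"] > sites["start"]).all()
        starts = models["start"].sort_values().to_numpy()
        assert (np.diff(starts) == GENE_BODY + GENE_GAP).all()

    def test_true_targets_have_candidate_sites_and_decoys_do_not(
        self, small_cfg, small_universe
    ):
        universe, truth = small_universe
        models, sites, expr = generate_tf_data(universe, truth, small_cfg,
                                               np.random.default_rng(6))
        cands = assign_candidates(sites, models,
                                  universe=set(universe["gene"]))
        for tf, regulon in truth.regulons.items():
            assert regulon <= cands[tf]
        # decoy placement: windows reach at most 10 kb beyond a gene body,
        # so any site further than that from every body is unassigned
        win = models.copy()
        hit_any = []
        for s, e in sites[["start", "end"]].itertuples(index=False):
            near = ((s < win["end"] + 10_000) & (e > win["start"] - 10_000)).any()
            hit_any.append(near)
        n_decoys = (~np.asarray(hit_any)).sum()
        assert n_decoys == len(truth.regulons)  # one decoy per TF

    def test_target_tf_correlation_matches_attenuation(self):
        """Shared-latent-factor construction: E[r] ≈ 1 / (1 + sd²)."""
        cfg = SimConfig(n_genes=60, community_sizes=(8,), n_tfs=3,
                        regulon_size=12, n_conditions=200,
                        expr_noise_sd=0.5, seed=11)
        universe, truth = generate_universe(cfg)
        _, _, expr = generate_tf_data(universe, truth, cfg)
        rs = []
        claimed = set()
        for tf in sorted(truth.regulons):
            for g in sorted(truth.regulons[tf]):
                if g in claimed or g in truth.regulons:
                    continue
                claimed.add(g)
                rs.append(stats.pearsonr(expr.loc[tf], expr.loc[g])[0])
        expected = 1 / (1 + cfg.expr_noise_sd**2)
        assert np.mean(rs) == pytest.approx(expected, abs=0.05)


class TestDeterminism:
    def test_simulate_all_byte_identical(self, tmp_path):
        cfg = SimConfig(n_genes=50, community_sizes=(6, 7), n_terms=10,
                        n_tfs=3, seed=123)
        p1 = simulate_all(cfg, str(tmp_path / "a"))
        p2 = simulate_all(cfg, str(tmp_path / "b"))
        assert p1.keys() == p2.keys()
        for key in p1:
            with open(p1[key], "rb") as f1, open(p2[key], "rb") as f2:
                assert f1.read() == f2.read(), f"{key} differs between runs"

    def test_truth_round_trips_through_json(self, tmp_path):
        cfg = SimConfig(n_genes=30, community_sizes=(5,), n_tfs=2, seed=3)
        paths = simulate_all(cfg, str(tmp_path))
        with open(paths["truth"]) as fh:
            truth = GroundTruth.from_json(fh.read())
        _, expected = generate_universe(cfg, np.random.default_rng(cfg.seed))
        assert truth.partition == expected.partition
        assert truth.regulons == expected.regulons
        assert os.path.getsize(paths["evidence"]) > 0
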