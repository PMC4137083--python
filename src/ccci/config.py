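"""Simulation and pipeline configuration objects."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from .errors import ConfigError

#: STRING-style prior probability of a random pair interacting; subtracted
#: from every channel before probabilistic combination and added back at the
#: end.  Exposed everywhere as a parameter.
DEFAULT_PRIOR = 0.041

#: High-confidence combined-score cutoff.
DEFAULT_CUTOFF = 0.7


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic-data generator.

    The defaults describe the benchmark conditions used throughout the test
    suite: four planted blocks dense enough to survive the 0.7 confidence
    cutoff, 10 ciliary-group and 7 centrosomal-group presence/absence
    experiments, and a handful of planted regulons.
    """

    n_genes: int = 100
    community_sizes: tuple[int, ...] = (8, 10, 12, 15)
    p_intra: float = 0.9
    p_inter: float = 0.01
    n_channels: int = 4
    channel_noise_sd: float = 0.05
    n_terms: int = 40
    n_ciliary_exp: int = 10
    n_centrosomal_exp: int = 7
    flip_prob: float = 0.1
    n_tfs: int = 8
    regulon_size: int = 10
    fp_site_rate: float = 0.4
    expr_noise_sd: float = 0.5
    n_conditions: int = 30
    # Optional grouping of planted blocks: pairs of genes whose blocks share
    # a group are cross-linked at p_group with high-score channels, giving
    # the community-wise network dense regions (super-community structure).
    block_groups: tuple[tuple[int, ...], ...] | None = None
    p_group: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        def bad(name: str, why: str) -> ConfigError:
            return ConfigError(f"SimConfig.{name}: {why}")

        if self.n_genes <= 0:
            raise bad("n_genes", "must be a positive count")
        if not self.community_sizes or any(s <= 0 for s in self.community_sizes):
            raise bad("community_sizes", "all block sizes must be positive")
        if sum(self.community_sizes) > self.n_genes:
            raise bad(
                "community_sizes",
                f"sum {sum(self.community_sizes)} exceeds n_genes {self.n_genes}",
            )
        for name in ("p_intra", "p_inter", "flip_prob", "p_group", "fp_site_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise bad(name, f"probability {v} outside [0, 1]")
        for name in ("channel_noise_sd", "expr_noise_sd"):
            if getattr(self, name) < 0:
                raise bad(name, "must be non-negative")
        for name in (
            "n_channels",
            "n_terms",
            "n_ciliary_exp",
            "n_centrosomal_exp",
            "n_tfs",
            "regulon_size",
            "n_conditions",
        ):
            if getattr(self, name) < 0:
                raise bad(name, "must be a non-negative count")
        if self.n_conditions > 0 and self.n_tfs > 0 and self.n_conditions < 3:
            raise bad("n_conditions", "need at least 3 conditions to correlate")
        if self.block_groups is not None:
            n_blocks = len(self.community_sizes)
            seen: set[int] = set()
            for grp in self.block_groups:
                for b in grp:
                    if not 0 <= b < n_blocks:
                        raise bad("block_groups", f"block index {b} out of range")
                    if b in seen:
                        raise bad("block_groups", f"block {b} listed twice")
                    seen.add(b)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"SimConfig: unknown fields {sorted(unknown)}")
        d = dict(d)
        if "community_sizes" in d:
            d["community_sizes"] = tuple(d["community_sizes"])
        if d.get("block_groups") is not None:
            d["block_groups"] = tuple(tuple(g) for g in d["block_groups"])
        return cls(**d)


@dataclass(frozen=True)
class MCODEParams:
    """Molecular-complex-detection parameters (clusterMaker 1.9 defaults)."""

    include_loops: bool = False
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False
    fluff_cutoff: float = 0.2

    def __post_init__(self) -> None:
        if self.degree_cutoff < 0 or self.k_core < 0 or self.max_depth < 0:
            raise ConfigError("MCODEParams: counts must be non-negative")
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ConfigError("MCODEParams.node_score_cutoff: outside [0, 1]")
        if not 0.0 <= self.fluff_cutoff <= 1.0:
            raise ConfigError("MCODEParams.fluff_cutoff: outside [0, 1]")


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, with provenance defaults."""

    outdir: str = "ccci_out"
    sim: SimConfig = field(default_factory=SimConfig)
    prior: float = DEFAULT_PRIOR
    cutoff: float = DEFAULT_CUTOFF
    excluded_channels: tuple[str, ...] = ()
    mcode: MCODEParams = field(default_factory=MCODEParams)
    min_community_size: int = 5
    enrich_alpha: float = 0.05
    tf_upstream: int = 10_000
    tf_downstream: int = 3_000
    tf_r_min: float = 0.5
    tf_q_max: float = 0.05
    tf_min_overlap: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.prior < 1.0:
            raise ConfigError("PipelineConfig.prior: must lie in [0, 1)")
        if not 0.0 <= self.cutoff <= 1.0:
            raise ConfigError("PipelineConfig.cutoff: must lie in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig.from_dict(d["sim"])
        if "mcode" in d and isinstance(d["mcode"], dict):
            d["mcode"] = MCODEParams(**d["mcode"])
        if "excluded_channels" in d:
            d["excluded_channels"] = tuple(d["excluded_channels"])
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"PipelineConfig: unknown fields {sorted(unknown)}")
        return cls(**d)
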