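"""End-to-end orchestration: simulate (or load) -> filter -> profile ->
infer both section networks -> randomize -> align/alpha-scan -> core and
function report.

Every stochastic stage receives a seed derived deterministically from the
master seed and the stage name, so stages can be re-run in isolation and a
rerun with the same config produces an identical report.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .alignment import align, alpha_scan, compare_to_random
from .containers import DEFAULT_NETWORK_VARIABLES, ValidationError
from .corefunc import (
    aligned_to_self,
    apply_rules,
    compare_profiles,
    core_decompose,
    function_profile,
)
from .inference import build_network, network_stats
from .io import (
    read_abiotic_table,
    read_otu_table,
    read_rules,
    read_similarity_matrix,
    write_json,
    write_network,
)
from .profiles import filter_min_samples, filter_replicate_consistency
from .simulate import SimulationConfig, simulate_dataset

log = logging.getLogger("occnet.pipeline")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(master) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """All stage parameters, with the study's values as defaults."""

    seed: int
    out_dir: str = "occnet_run"
    # input paths; None means simulate
    otu_path: str | None = None
    abiotic_path: str | None = None
    identity_path: str | None = None
    rules_path: str | None = None
    simulate: dict = field(default_factory=dict)
    # filters
    min_reps: int = 2
    min_samples: int = 5
    minocc: int = 10
    # inference
    n_pos: int = 1000
    n_neg: int = 1000
    n_perm: int = 1000
    q_threshold: float = 0.05
    variables: tuple = DEFAULT_NETWORK_VARIABLES
    # alignment
    alpha_grid: tuple = tuple(round(0.1 * k, 1) for k in range(11))
    edge_bonus: float = 0.5
    n_random: int = 20
    # flags / profiles
    decile: float = 0.10
    abundance_cut: float = 0.001
    rarefaction_depth: int = 3900
    rarefaction_step: int = 389
    rarefaction_iters: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValidationError("config must set a master seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        declared = [self.otu_path, self.abiotic_path]
        if any(declared) and not all(declared):
            raise ValidationError(
                "otu_path and abiotic_path must both be given to run on real "
                "data (or neither, to simulate)"
            )
        for p in (self.otu_path, self.abiotic_path, self.identity_path, self.rules_path):
            if p is not None and not Path(p).exists():
                raise ValidationError(f"input path does not exist: {p}")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in order and return the machine-readable report."""
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": cfg.seed, "stages": []}

    # -- stage: inputs ---------------------------------------------------
    if cfg.otu_path is None:
        sim_kwargs = dict(cfg.simulate)
        sim_kwargs.setdefault("seed", stage_seed(cfg.seed, "simulate"))
        sim_cfg = SimulationConfig(**sim_kwargs)
        data = simulate_dataset(sim_cfg)
        table, abiotic = data.table, data.gradient
        identity, rules, truth = data.identity, data.rules, data.truth
        log.info("stage=simulate n_otus=%d n_samples=%d", *table.shape)
        report["stages"].append({"stage": "simulate", "n_otus": table.shape[0]})
    else:
        table = read_otu_table(cfg.otu_path)
        abiotic = read_abiotic_table(cfg.abiotic_path)
        identity = (
            read_similarity_matrix(cfg.identity_path) if cfg.identity_path else None
        )
        rules = read_rules(cfg.rules_path) if cfg.rules_path else None
        truth = None
        report["stages"].append({"stage": "load", "n_otus": table.shape[0]})

    # -- stage: filters --------------------------------------------------
    n0 = table.shape[0]
    table = filter_replicate_consistency(table, cfg.min_reps)
    n1 = table.shape[0]
    log.info("stage=filter event=replicate_consistency kept=%d of %d", n1, n0)
    report["stages"].append(
        {"stage": "filter_replicate_consistency", "before": n0, "after": n1}
    )

    # -- stage: per-section networks -------------------------------------
    nets = {}
    for section in (1, 2):
        sliced = table.section_slice(section)
        n_before = sliced.shape[0]
        sliced = filter_min_samples(sliced, cfg.min_samples)
        log.info(
            "stage=filter_min_samples section=%d kept=%d of %d",
            section, sliced.shape[0], n_before,
        )
        net = build_network(
            sliced,
            abiotic,
            variables=cfg.variables,
            min_samples=0,  # already applied above, logged
            minocc=cfg.minocc,
            n_pos=cfg.n_pos,
            n_neg=cfg.n_neg,
            n_perm=cfg.n_perm,
            q_threshold=cfg.q_threshold,
            seed=stage_seed(cfg.seed, f"network_section{section}"),
        )
        nets[section] = net
        stats = network_stats(net, verdict=net.n_nodes >= 30)
        write_network(net, out / f"network_section{section}.graphml")
        write_network(net, out / f"network_section{section}_edges.tsv", format="edge-tsv")
        signs = net.edge_sign_counts()
        report["stages"].append(
            {
                "stage": f"network_section{section}",
                "n_otus_filtered": sliced.shape[0],
                "n_nodes": net.n_nodes,
                "n_otu_nodes": len(net.otu_nodes),
                "n_variable_nodes": len(net.variable_nodes),
                "n_edges": net.n_edges,
                "n_copresence": signs["copresence"],
                "n_exclusion": signs["exclusion"],
                "clustering_coefficient": stats.clustering_coefficient,
                "characteristic_path_length": stats.characteristic_path_length,
                "density": stats.density,
                "heterogeneity": stats.heterogeneity,
                "degree_distribution": stats.degree_distribution_verdict,
            }
        )

    net1, net2 = nets[1], nets[2]
    if net1.n_edges == 0 or net2.n_edges == 0:
        report["warning"] = "empty network; downstream stages skipped"
        write_json(report, out / "report.json")
        return report

    # -- stage: alignment -------------------------------------------------
    scan_table, consensus_alpha, results = alpha_scan(
        net1, net2, seqsim=identity, grid=list(cfg.alpha_grid),
        edge_bonus=cfg.edge_bonus,
    )
    log.info("stage=alpha_scan consensus_alpha=%s", consensus_alpha)
    best = results[consensus_alpha]
    random_cmp = compare_to_random(
        net1, net2, n_random=cfg.n_random, alpha=consensus_alpha,
        seqsim=identity, seed=stage_seed(cfg.seed, "compare_to_random"),
        edge_bonus=cfg.edge_bonus,
    )
    report["stages"].append(
        {
            "stage": "alignment",
            "alpha_scan": scan_table.to_dict(orient="records"),
            "consensus_alpha": consensus_alpha,
            "EC": best.ec,
            "SS": best.ss,
            "n_aligned": best.n_aligned,
            "random_comparison": random_cmp,
        }
    )

    # -- stage: core / function -------------------------------------------
    decomposition = core_decompose(net1, net2)
    count, fraction = aligned_to_self(best, decomposition.core)
    labels = apply_rules(rules, table.taxonomy) if rules is not None else {}
    half = int(table.sample_meta["site"].max()) // 2
    all_sites = sorted(table.sample_meta["site"].unique())
    s1_sites = [s for s in all_sites if s <= half]
    s2_sites = [s for s in all_sites if s > half]
    profiles = {}
    comparison = None
    if labels:
        profiles["core"] = function_profile(
            decomposition.core, table, labels, all_sites, group="core"
        )
        profiles["noncore1"] = function_profile(
            decomposition.noncore1, table, labels, s1_sites, group="noncore1"
        )
        profiles["noncore2"] = function_profile(
            decomposition.noncore2, table, labels, s2_sites, group="noncore2"
        )
        profiles["community"] = function_profile(
            table.otu_ids, table, labels, all_sites, group="community"
        )
        comparison = compare_profiles(
            [profiles["core"], profiles["noncore1"], profiles["noncore2"]]
        )
    report["stages"].append(
        {
            "stage": "core_function",
            "n_core": len(decomposition.core),
            "n_noncore1": len(decomposition.noncore1),
            "n_noncore2": len(decomposition.noncore2),
            "aligned_to_self_count": count,
            "aligned_to_self_fraction": fraction,
            "function_means": {
                name: prof.mean.to_dict() for name, prof in profiles.items()
            },
            "function_sds": {
                name: prof.sd.to_dict() for name, prof in profiles.items()
            },
            "function_comparison": (
                comparison.reset_index().to_dict(orient="records")
                if comparison is not None
                else None
            ),
        }
    )

    # -- stage: truth-based evaluation (simulated runs only) --------------
    if truth is not None:
        f1 = {}
        for section, net in nets.items():
            predicted = net.edges_as_set()
            actual = truth.edge_set(section)
            tp = len(predicted & actual)
            prec = tp / len(predicted) if predicted else 0.0
            rec = tp / len(actual) if actual else 0.0
            f1[section] = (
                2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
            )
        swaps = truth.roleswap_map
        recovered = sum(
            1 for a, b in swaps.items() if best.mapping.get(a) == b
        )
        report["stages"].append(
            {
                "stage": "truth_evaluation",
                "edge_f1_section1": f1[1],
                "edge_f1_section2": f1[2],
                "roleswap_recovered": recovered,
                "roleswap_total": len(swaps),
            }
        )

    write_json(report, out / "report.json")
    return report
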