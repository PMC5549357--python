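"""End-to-end orchestration: simulate -> consensus -> cutoff -> benchmark ->
communities -> pathways -> microarray, from one structured config.

A single top-level seed derives one child seed per stage through
``numpy.random.SeedSequence`` spawning, so any stage can be rerun in
isolation and the whole run is reproducible byte-for-byte.  Every stage
communicates through written artifacts; the JSON manifest records the
parameters, per-stage seeds and SHA-256 checksums of everything written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import benchmark as bench
from . import consensus as cons
from . import io as cio
from . import microarray as ma
from . import network as net
from . import pathways as pw
from . import synthetic as syn
from .config import SimConfig

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_full_pipeline", "stage_seeds"]

_STAGES = (
    "simulate",
    "consensus",
    "benchmark",
    "communities",
    "pathways",
    "microarray",
)


class PipelineValidationError(ValueError):
    """Configuration problem detected before any stage runs."""


@dataclass
class PipelineConfig:
    out_dir: str = "consenrank_run"
    mode: str = "synthetic"  # or "user-data"
    seed: int = 0

    # synthetic mode
    sim: dict = field(default_factory=dict)

    # user-data mode input paths
    lists_path: str | None = None
    edges_path: str | None = None
    gmt_path: str | None = None
    studies_path: str | None = None
    reference_path: str | None = None

    # stage parameters
    fractions: tuple = (0.01, 0.05, 0.10, 0.20)
    cutoff: float = 0.9
    k_min: int = 3
    k_max: int = 12
    k_override: int | None = None
    q_threshold: float = 0.05
    n_mc: int = 500
    bootstrap_reps: int = 200
    pathway_planted_fraction: float = 0.8

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        if isinstance(cfg.fractions, list):
            cfg.fractions = tuple(cfg.fractions)
        return cfg

    def validate(self) -> None:
        if self.mode not in ("synthetic", "user-data"):
            raise PipelineValidationError(f"unknown mode {self.mode!r}")
        for f in self.fractions:
            if not 0 < f <= 1:
                raise PipelineValidationError(f"fraction {f} outside (0, 1]")
        if not 0 <= self.cutoff <= 1:
            raise PipelineValidationError("cutoff must lie in [0, 1]")
        if self.k_min < 3 or self.k_max < self.k_min:
            raise PipelineValidationError("need 3 <= k_min <= k_max")
        if self.mode == "user-data":
            for attr in ("lists_path", "edges_path", "gmt_path", "studies_path", "reference_path"):
                p = getattr(self, attr)
                if p is None:
                    raise PipelineValidationError(f"user-data mode requires {attr}")
                if not Path(p).exists():
                    raise PipelineValidationError(f"{attr}={p!r} does not exist")


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds derived from the top-level seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(_STAGES, children)
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to out_dir)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict = {
        "config": {k: v for k, v in asdict(config).items()},
        "stage_seeds": seeds,
        "stages": {},
        "artifacts": {},
    }

    def _finish_stage(name: str, t0: float, **info) -> None:
        logger.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)
        manifest["stages"][name] = info

    def _write(name: str, writer, *args) -> Path:
        path = out / name
        writer(*args, path)
        manifest["artifacts"][name] = _sha256(path)
        return path

    try:
        # ---- stage: inputs -------------------------------------------------
        t0 = time.perf_counter()
        if config.mode == "synthetic":
            sim = SimConfig(**{**config.sim, "seed": seeds["simulate"]})
            lists, positives = syn.simulate_method_lists(sim)
            edges, planted = syn.simulate_network(sim)
            studies_raw, ma_truth = syn.simulate_microarray_studies(sim)
            collection = syn.simulate_pathway_collection(
                sim, communities=planted, planted_fraction=config.pathway_planted_fraction
            )
            reference = positives
            _write("ranked_lists.tsv", cio.write_ranked_lists, lists)
            _write("edges.tsv", cio.write_string_edges, edges)
            _write("studies.tsv", cio.write_study_tables, studies_raw)
            _write("pathways.gmt", cio.write_gmt, collection)
            _write(
                "truth.json",
                cio.write_truth,
                {
                    "positives": sorted(positives),
                    "planted_communities": [sorted(c) for c in planted],
                    "de_pool": ma_truth["de_pool"],
                },
            )
            universe = sim.gene_universe()
            _finish_stage("simulate", t0, sim_config=sim.to_dict())
        else:
            lists = cio.read_ranked_lists(config.lists_path)
            edges = cio.read_string_edges(config.edges_path)
            studies_raw = cio.read_study_tables(config.studies_path)
            collection = cio.read_gmt(config.gmt_path)
            reference = set(
                json.loads(Path(config.reference_path).read_text())["genes"]
            )
            universe = sorted({g for rl in lists for g in rl.gene_ids})
            _finish_stage("simulate", t0, mode="user-data")

        # ---- stage: consensus ---------------------------------------------
        t0 = time.perf_counter()
        table = cons.consensus_scores(lists)
        curve = cons.rational_cutoff(table, reference)
        _write("consensus.tsv", cio.write_consensus_table, table)
        _write(
            "cutoff_curve.tsv",
            lambda df, path: df.to_csv(path, sep="\t", index=False),
            curve.df,
        )
        _finish_stage(
            "consensus",
            t0,
            n_genes=table.n_genes,
            n_methods=table.n_methods,
            selected_rank=curve.selected_rank,
            selected_index=curve.selected_index,
        )

        # ---- stage: benchmark ----------------------------------------------
        t0 = time.perf_counter()
        report = bench.enrichment_metrics(table, reference, config.fractions)
        ref_set = set(reference)
        per_method = {}
        for rl in lists:
            ranks = np.array(
                [r for r, g in enumerate(rl.gene_ids, start=1) if g in ref_set],
                dtype=float,
            )
            per_method[rl.method_id] = (
                bench.bedroc_score(ranks, len(rl), alpha=100.0) if len(ranks) else float("nan")
            )
        _write(
            "benchmark.tsv",
            lambda df, path: df.to_csv(path, sep="\t", index=False),
            report.per_fraction,
        )
        _finish_stage(
            "benchmark",
            t0,
            auac=report.auac,
            roc=report.roc,
            consensus_bedroc_alpha100=bench.bedroc_score(
                np.sort(table.ranks_of(reference).to_numpy(dtype=float)),
                table.n_genes,
                alpha=100.0,
            ),
            per_method_bedroc_alpha100=per_method,
        )

        # ---- stage: communities --------------------------------------------
        t0 = time.perf_counter()
        network = net.build_network(edges, cutoff=config.cutoff)
        scan = net.scan_k(
            network, range(config.k_min, config.k_max + 1), k_override=config.k_override
        )
        partition = scan.partition()
        profiles = net.community_profiles(partition, table, reference)
        _write(
            "communities.tsv",
            lambda df, path: df.to_csv(path, sep="\t"),
            profiles.drop(columns="genes"),
        )
        _write(
            "community_members.tsv",
            lambda part, path: _write_members(part, path),
            partition,
        )
        _finish_stage(
            "communities",
            t0,
            n_nodes=network.n_nodes,
            n_edges=network.n_edges,
            selected_k=scan.selected_k,
            n_communities=len(partition),
            s_index=partition.s_index(),
        )

        # ---- stage: pathways -----------------------------------------------
        t0 = time.perf_counter()
        cmap = pw.community_pathway_map(
            partition, collection, universe, q_threshold=config.q_threshold
        )
        if len(cmap):
            scores = pw.pathway_scores(cmap, profiles, table, network, collection)
            _write(
                "pathway_scores.tsv",
                lambda df, path: df.to_csv(path, sep="\t"),
                scores,
            )
            top_pathway = scores.index[0]
        else:
            top_pathway = None
        ref_in_net = sorted(set(reference) & network.nodes)
        if ref_in_net:
            comp = pw.component_significance(
                ref_in_net,
                network,
                allow_missing=0,
                n_mc=max(100, config.n_mc),
                seed=seeds["pathways"],
            )
            comp_size, comp_p = comp.observed_size, comp.pvalue
        else:
            logger.warning("no reference gene in the network; skipping component test")
            comp_size, comp_p = None, None
        _finish_stage(
            "pathways",
            t0,
            n_links=len(cmap),
            top_pathway=top_pathway,
            component_size=comp_size,
            component_pvalue=comp_p,
        )

        # ---- stage: microarray ----------------------------------------------
        t0 = time.perf_counter()
        scored = ma.score_study_genes(studies_raw)
        ma_table = ma.microarray_consensus(scored)
        overlaps = ma.cross_study_overlaps(scored, table)
        weights = ma.community_microarray_weights(partition, ma_table)
        _write(
            "microarray_consensus.tsv",
            lambda t, path: t.df.to_csv(path, sep="\t"),
            ma_table,
        )
        _finish_stage(
            "microarray",
            t0,
            class_counts=ma_table.class_counts(),
            all_way_overlap=overlaps["all_way_count"],
            community_weights=weights,
        )
    except Exception as exc:  # annotate which stage failed, then re-raise
        done = set(manifest["stages"])
        failed = next((s for s in _STAGES if s not in done), "unknown")
        manifest["failed_stage"] = failed
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _write_members(partition, path) -> None:
    multi = partition.multi_membership_genes()
    rows = ["community_id\tgene_id\tmulti_membership"]
    for i, comm in enumerate(partition.communities, start=1):
        for g in sorted(comm):
            rows.append(f"{i}\t{g}\t{int(g in multi)}")
    Path(path).write_text("\n".join(rows) + "\n")
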