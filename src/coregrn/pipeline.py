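"""End-to-end orchestration: enumerate, simulate, rank, perturb, annotate.

The pipeline is driven by a :class:`PipelineConfig` (grids, simulator and
assignment settings, seeds) applied to a :class:`PipelineInputs` bundle
(expression matrix, binding table, curated database, ranked TF lists, optional
pathway gene sets).  Candidate simulations use per-candidate seeds derived
deterministically from the master seed and candidate topology id, so the
manifest is identical regardless of evaluation order or worker count.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from coregrn.data_model import (
    ActivityMatrix,
    BindingTable,
    ExpressionMatrix,
    GeneNetwork,
    HyperParams,
    PathwayAnnotation,
    PerturbationResult,
    SamplingRanges,
    TargetSelectionRule,
    TFTargetDB,
    read_binding_table,
    read_expression,
    read_gmt,
    read_ranked_list,
)
from coregrn.grn_builder import (
    MIN_NETWORK_TFS,
    deduplicate_topologies,
    enumerate_candidates,
)
from coregrn.netopt import (
    ScoredCandidate,
    StabilityResult,
    rank_candidates,
    rerank_stability,
    score_candidate,
)
from coregrn.pathway_annot import annotate_network_tfs
from coregrn.perturb_analysis import (
    PCAProjection,
    kd_screen,
    project_pca,
    rank_destabilizers,
    train_state_mapper,
)
from coregrn.racipe_sim import simulate_knockdown
from coregrn.target_db import build_merged_db
from coregrn.tf_activity import differential_genes, infer_activity, significant_genes

log = logging.getLogger(__name__)


@dataclass
class PipelineInputs:
    """All external inputs of one pipeline run."""

    expr: ExpressionMatrix
    binding: BindingTable
    curated: TFTargetDB
    ranked_lists: list[list[str]]
    pathways: dict[str, set[str]] | None = None

    @classmethod
    def from_files(
        cls,
        expr_path: str | Path,
        labels_path: str | Path,
        binding_path: str | Path,
        curated_path: str | Path,
        ranked_list_paths: Sequence[str | Path],
        pathways_path: str | Path | None = None,
    ) -> "PipelineInputs":
        for p in [expr_path, labels_path, binding_path, curated_path, *ranked_list_paths]:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        return cls(
            expr=read_expression(expr_path, labels_path),
            binding=read_binding_table(binding_path),
            curated=TFTargetDB.from_gene_sets(read_gmt(curated_path)),
            ranked_lists=[read_ranked_list(p) for p in ranked_list_paths],
            pathways=read_gmt(pathways_path) if pathways_path else None,
        )


@dataclass
class PipelineConfig:
    """Hyperparameter grids and stage settings of one pipeline run."""

    binding_grid: tuple[float, ...] = (0.05, 0.06, 0.07, 0.08, 0.09, 0.10, 0.12, 0.14, 0.16, 0.18, 0.20)
    k_grid: tuple[int, ...] = (5, 10, 15, 20)
    cutoff_grid: tuple[float, ...] = tuple(round(0.05 * i, 2) for i in range(20))
    n_models: int = 10_000
    n_null: int = 1000
    alpha: float = 0.05
    seed: int = 17
    stability_repeats: int = 10
    stability_top: int = 10
    kd_factor: float = 0.95
    p_max: float = 0.1
    deg_alpha: float = 0.05
    min_targets: int = 8
    min_tfs: int = MIN_NETWORK_TFS
    rule: TargetSelectionRule = field(default_factory=TargetSelectionRule)
    ranges: SamplingRanges = field(default_factory=SamplingRanges)

    def __post_init__(self) -> None:
        if not self.binding_grid or not self.k_grid or not self.cutoff_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if self.n_models < 1 or self.n_null < 1:
            raise ValueError("n_models and n_null must be >= 1")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "rule" in raw:
            raw["rule"] = TargetSelectionRule(**raw["rule"])
        if "ranges" in raw:
            raw["ranges"] = SamplingRanges(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in raw["ranges"].items()
            })
        for key in ("binding_grid", "k_grid", "cutoff_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def provenance(self) -> dict:
        def enc(v):
            if isinstance(v, (TargetSelectionRule, SamplingRanges)):
                return v.__dict__
            return v

        payload = {k: enc(v) for k, v in self.__dict__.items()}
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()
        return {"config": payload, "config_hash": digest}


def _candidate_seed(master_seed: int, candidate_id: int) -> int:
    """Deterministic per-candidate seed, independent of evaluation order."""
    return int(np.random.SeedSequence([master_seed, candidate_id]).generate_state(1)[0] % (2**31))


@dataclass
class OptimizeResult:
    """Outcome of the network-optimization stage."""

    optimal_network: GeneNetwork
    optimal_hyperparams: HyperParams
    optimal_activity: ActivityMatrix
    optimal_scored: ScoredCandidate
    manifest: pd.DataFrame
    stability: StabilityResult | None
    provenance: dict


def _activity_for(
    inputs: PipelineInputs, config: PipelineConfig, hp: HyperParams, tfs: Sequence[str]
) -> ActivityMatrix:
    db = build_merged_db(
        inputs.binding,
        inputs.curated,
        hp.binding_threshold,
        config.rule,
        config.min_targets,
        restrict_to_genes=inputs.expr.genes,
    )
    return infer_activity(inputs.expr, db, sorted(tfs))


def run_optimize(inputs: PipelineInputs, config: PipelineConfig) -> OptimizeResult:
    """Enumerate, simulate and rank candidates; return the optimal network.

    Every candidate topology is scored once (duplicated topologies reached
    from different hyperparameter triples share the score but keep their own
    manifest rows).  The stability check re-ranks the top
    ``config.stability_top`` unique topologies over ``config.stability_repeats``
    repeats when at least two are available and repeats >= 2.
    """
    candidates = enumerate_candidates(
        inputs.ranked_lists,
        inputs.binding,
        inputs.curated,
        inputs.expr,
        binding_grid=config.binding_grid,
        k_grid=config.k_grid,
        cutoff_grid=config.cutoff_grid,
        rule=config.rule,
        min_targets=config.min_targets,
        min_tfs=config.min_tfs,
    )
    if not candidates:
        raise RuntimeError(
            "no candidate networks survived; the tightest filters are the "
            f">= {config.min_tfs}-TF component rule and the correlation cutoffs "
            f"{config.cutoff_grid}"
        )
    unique, back_ref = deduplicate_topologies(candidates)
    log.info("%d candidates, %d unique topologies", len(candidates), len(unique))

    # first hyperparameter triple observed per unique topology drives its activity
    first_hp: dict[int, HyperParams] = {}
    for (hp, _net), uid in zip(candidates, back_ref):
        first_hp.setdefault(uid, hp)

    scored: dict[int, ScoredCandidate] = {}
    activities: dict[int, ActivityMatrix] = {}
    for uid, net in enumerate(unique):
        act = _activity_for(inputs, config, first_hp[uid], net.nodes)
        activities[uid] = act
        scored[uid] = score_candidate(
            net,
            act,
            candidate_id=uid,
            n_models=config.n_models,
            n_null=config.n_null,
            alpha=config.alpha,
            seed=_candidate_seed(config.seed, uid),
            ranges=config.ranges,
            kd_factor=config.kd_factor,
        )

    from coregrn.data_model import CandidateScore

    per_candidate: list[CandidateScore] = []
    for cid, ((hp, net), uid) in enumerate(zip(candidates, back_ref)):
        base = scored[uid].score
        per_candidate.append(
            CandidateScore(
                candidate_id=cid,
                accuracy=base.accuracy,
                flexibility=base.flexibility,
                n_edges=net.n_edges,
            )
        )
    ranked = rank_candidates(per_candidate)
    rows = []
    for s in ranked:
        hp, net = candidates[s.candidate_id]
        rows.append(
            {
                "candidate_id": s.candidate_id,
                "topology_id": back_ref[s.candidate_id],
                "binding_threshold": hp.binding_threshold,
                "n_tfs_per_method": hp.n_tfs_per_method,
                "corr_cutoff": hp.corr_cutoff,
                "n_nodes": net.n_nodes,
                "n_edges": net.n_edges,
                "accuracy": s.accuracy,
                "flexibility": s.flexibility,
                "accuracy_rank": s.accuracy_rank,
                "flexibility_rank": s.flexibility_rank,
                "combined_index": s.combined_index,
            }
        )
    manifest = pd.DataFrame(rows)

    top_cid = int(manifest.iloc[0]["candidate_id"])
    top_uid = back_ref[top_cid]
    optimal_hp, optimal_net = candidates[top_cid]

    stability = None
    top_uids = list(dict.fromkeys(manifest["topology_id"]))[: config.stability_top]
    if config.stability_repeats >= 2 and len(top_uids) >= 2:
        stability = rerank_stability(
            [(uid, unique[uid], activities[uid]) for uid in top_uids],
            n_repeats=config.stability_repeats,
            n_models=config.n_models,
            n_null=config.n_null,
            alpha=config.alpha,
            seed=config.seed,
            ranges=config.ranges,
            kd_factor=config.kd_factor,
        )

    prov = config.provenance()
    prov.update(
        n_candidates=len(candidates),
        n_unique_topologies=len(unique),
        optimal_candidate_id=top_cid,
        optimal_topology_id=top_uid,
    )
    return OptimizeResult(
        optimal_network=optimal_net,
        optimal_hyperparams=optimal_hp,
        optimal_activity=activities[top_uid],
        optimal_scored=scored[top_uid],
        manifest=manifest,
        stability=stability,
        provenance=prov,
    )


@dataclass
class PerturbReport:
    """Knockdown screen, significance tests, projections and annotations."""

    results: list[PerturbationResult]
    destabilizers: pd.DataFrame  # single KDs, descending control-state proportion
    pca: PCAProjection
    annotation: PathwayAnnotation | None
    provenance: dict

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "genes": "+".join(r.genes),
                "n_genes": len(r.genes),
                "control": r.proportions.control,
                "case": r.proportions.case,
                "p_value": r.p_value,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)


def run_perturb(
    inputs: PipelineInputs,
    config: PipelineConfig,
    optimize_result: OptimizeResult,
    pca_top_pairs: int = 3,
) -> PerturbReport:
    """Single/double knockdown screen plus PCA projection and pathway annotation.

    Reuses the optimal candidate's unperturbed ensemble and state assignment to
    train the ridge mapper; the screen covers all single-TF knockdowns and all
    unordered pairs among the union of the top/bottom five single
    destabilizers.
    """
    net = optimize_result.optimal_network
    sc = optimize_result.optimal_scored
    mapper = train_state_mapper(sc.ensemble, sc.assignment, ridge_penalty=1.0)
    results = kd_screen(net, sc.ensemble, mapper, kd_factor=config.kd_factor)
    destab = rank_destabilizers(results)

    pairs = [r for r in results if len(r.genes) == 2]
    pairs_by_impact = sorted(
        pairs,
        key=lambda r: -abs(r.proportions.control - sc.proportions.control),
    )[:pca_top_pairs]
    kd_mats = []
    for r in pairs_by_impact:
        kd = simulate_knockdown(net, sc.ensemble, r.genes, kd_factor=config.kd_factor)
        kd_mats.append(kd.normalized()[kd.converged])
    pca = project_pca(sc.ensemble.normalized()[sc.ensemble.converged], kd_mats)

    annotation = None
    if inputs.pathways:
        deg_table = differential_genes(inputs.expr, alpha=config.deg_alpha)
        degs = significant_genes(deg_table)
        db = build_merged_db(
            inputs.binding,
            inputs.curated,
            optimize_result.optimal_hyperparams.binding_threshold,
            config.rule,
            config.min_targets,
            restrict_to_genes=inputs.expr.genes,
        )
        annotation = annotate_network_tfs(
            net.nodes, db, degs, inputs.pathways, p_max=config.p_max
        )

    prov = config.provenance()
    prov.update(
        n_single_kd=sum(1 for r in results if len(r.genes) == 1),
        n_double_kd=sum(1 for r in results if len(r.genes) == 2),
    )
    return PerturbReport(
        results=results,
        destabilizers=destab,
        pca=pca,
        annotation=annotation,
        provenance=prov,
    )
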