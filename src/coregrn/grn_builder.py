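"""Candidate GRN enumeration over the hyperparameter grid.

A candidate network connects TF pairs supported by the merged TF-target
database, signed by the Spearman correlation of their inferred activities, and
pruned to the largest weakly-connected component.  Candidates are enumerated
over a grid of (binding probability threshold, TFs per ranking method,
correlation cutoff).
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import networkx as nx
import pandas as pd

from coregrn.data_model import (
    DEFAULT_BINDING_GRID,
    DEFAULT_CUTOFF_GRID,
    DEFAULT_K_GRID,
    BindingTable,
    ExpressionMatrix,
    GeneNetwork,
    HyperParams,
    NetworkEdge,
    TargetSelectionRule,
    TFTargetDB,
)
from coregrn.target_db import build_merged_db
from coregrn.tf_activity import activity_spearman, infer_activity

log = logging.getLogger(__name__)

#: candidates must retain at least this many TFs after component pruning
MIN_NETWORK_TFS = 15
#: largest weakly-connected component must contain more than this TF fraction
COMPONENT_FRACTION = 0.80


def combine_tf_lists(
    ranked_lists: Sequence[Sequence[str]],
    k: int,
    db: TFTargetDB | None = None,
) -> set[str]:
    """Union of the top-``k`` TFs from each ranked list.

    When ``db`` is given the union is restricted to TFs present in it (i.e.
    those that survived the minimum-target filter).  If ``k`` exceeds a list's
    length the whole list is used with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not ranked_lists or any(len(lst) == 0 for lst in ranked_lists):
        raise ValueError("ranked lists must be non-empty")
    combined: set[str] = set()
    for i, lst in enumerate(ranked_lists):
        if k > len(lst):
            log.warning("k=%d exceeds list %d length %d; using whole list", k, i, len(lst))
        combined.update(lst[:k])
    if db is not None:
        combined = {tf for tf in combined if tf in db}
    return combined


def build_candidate(
    tfs: set[str],
    db: TFTargetDB,
    corr: pd.DataFrame,
    cutoff: float,
    min_tfs: int = MIN_NETWORK_TFS,
    allow_self_loops: bool = False,
) -> GeneNetwork | None:
    """Build one candidate network at a correlation cutoff, or None if discarded.

    A directed edge A->B exists iff B is a target of A in ``db``, both are in
    ``tfs``, and |rho(A,B)| > ``cutoff``; the edge sign is the correlation's
    sign.  Self-loops are excluded by default (a row's rank correlation with
    itself is 1 and carries no sign information).  The largest
    weakly-connected component is retained if it holds more than 80% of the
    connected TFs; otherwise, or when it has fewer than ``min_tfs`` TFs, the
    candidate is discarded.
    """
    edges: list[NetworkEdge] = []
    for a in sorted(tfs):
        if a not in db:
            continue
        targets = db.targets(a)
        for b in sorted(tfs):
            if b == a and not allow_self_loops:
                continue
            if b not in targets:
                continue
            if a not in corr.index or b not in corr.index:
                raise KeyError(f"correlation matrix does not cover TF pair ({a},{b})")
            rho = float(corr.loc[a, b])
            if abs(rho) > cutoff and rho != 0.0:
                sign = 1 if rho > 0 else -1
                edges.append(
                    NetworkEdge(a, b, sign, db.record(a, b).provenance, rho)
                )
    connected = sorted({n for e in edges for n in (e.source, e.target)})
    if not connected:
        return None
    g = nx.DiGraph()
    g.add_nodes_from(connected)
    g.add_edges_from((e.source, e.target) for e in edges)
    components = sorted(nx.weakly_connected_components(g), key=lambda c: (-len(c), sorted(c)))
    largest = components[0]
    if len(largest) <= COMPONENT_FRACTION * len(connected):
        return None
    if len(largest) < min_tfs:
        return None
    kept_nodes = [n for n in connected if n in largest]
    kept_edges = [e for e in edges if e.source in largest and e.target in largest]
    return GeneNetwork(kept_nodes, kept_edges)


def enumerate_candidates(
    ranked_lists: Sequence[Sequence[str]],
    binding: BindingTable,
    curated: TFTargetDB,
    expr: ExpressionMatrix,
    binding_grid: Sequence[float] = DEFAULT_BINDING_GRID,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    cutoff_grid: Sequence[float] = DEFAULT_CUTOFF_GRID,
    rule: TargetSelectionRule = TargetSelectionRule(),
    min_targets: int = 8,
    min_tfs: int = MIN_NETWORK_TFS,
) -> list[tuple[HyperParams, GeneNetwork]]:
    """Enumerate candidate networks over the full hyperparameter grid.

    For each binding threshold the merged database (and hence the activities
    and their correlations) is rebuilt; for each TF count the combined TF set
    is formed; for each correlation cutoff one candidate is built.  Discarded
    combinations are omitted.  Deterministic given identical inputs.
    """
    if not binding_grid or not k_grid or not cutoff_grid:
        raise ValueError("hyperparameter grids must be non-empty")
    out: list[tuple[HyperParams, GeneNetwork]] = []
    for bt in binding_grid:
        db = build_merged_db(
            binding, curated, bt, rule, min_targets, restrict_to_genes=expr.genes
        )
        for k in k_grid:
            tfs = combine_tf_lists(ranked_lists, k, db)
            if len(tfs) < 2:
                log.info("binding=%g k=%d: fewer than 2 usable TFs; skipped", bt, k)
                continue
            try:
                act = infer_activity(expr, db, sorted(tfs))
                corr = activity_spearman(act)
            except (ValueError, KeyError) as exc:
                raise type(exc)(
                    f"hyperparameters (binding={bt}, k={k}): {exc}"
                ) from exc
            for cutoff in cutoff_grid:
                net = build_candidate(tfs, db, corr, cutoff, min_tfs=min_tfs)
                if net is not None:
                    out.append((HyperParams(bt, k, cutoff), net))
    log.info("retained %d candidate networks", len(out))
    return out


def deduplicate_topologies(
    candidates: Sequence[tuple[HyperParams, GeneNetwork]],
) -> tuple[list[GeneNetwork], list[int]]:
    """Unique signed topologies plus a back-reference per candidate.

    Returns ``(unique_networks, indices)`` where ``indices[i]`` locates
    candidate ``i``'s topology in ``unique_networks``.  Saves simulating the
    same topology reached from different hyperparameter triples.
    """
    unique: list[GeneNetwork] = []
    keys: dict[tuple, int] = {}
    indices: list[int] = []
    for _, net in candidates:
        key = net.topology_key()
        if key not in keys:
            keys[key] = len(unique)
            unique.append(net)
        indices.append(keys[key])
    return unique, indices
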