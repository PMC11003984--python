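import numpy as np
import pytest

import coregrn as cg
from coregrn.data_model import GeneNetwork, NetworkEdge


@pytest.fixture(scope="session")
def planted():
    """Default planted bistable system (20 TFs, seed 17)."""
    return cg.make_planted_system()


@pytest.fixture(scope="session")
def planted_expr(planted):
    return cg.emit_expression(planted)


@pytest.fixture(scope="session")
def planted_db(planted, planted_expr):
    from coregrn.target_db import build_merged_db

    return build_merged_db(
        planted.binding, planted.curated_db, 0.1, restrict_to_genes=planted_expr.genes
    )


@pytest.fixture(scope="session")
def planted_activity(planted, planted_expr, planted_db):
    return cg.infer_activity(planted_expr, planted_db, planted.tfs)


@pytest.fixture(scope="session")
def toggle_net():
    """Classic two-gene mutual-inhibition toggle switch."""
    return GeneNetwork(
        ["A", "B"],
        [
            NetworkEdge("A", "B", -1, "curated", -1.0),
            NetworkEdge("B", "A", -1, "curated", -1.0),
        ],
    )


@pytest.fixture(scope="session")
def planted_ensemble(planted):
    """One 1000-model ensemble of the planted core, shared across tests."""
    return cg.simulate_ensemble(planted.network, n_models=1000, seed=11)


@pytest.fixture(scope="session")
def planted_assignment(planted_ensemble, planted_activity):
    return cg.assign_states(planted_ensemble, planted_activity, n_null=500, seed=5)


def bipartite_toggle(n_tfs: int, prefix_a: str = "P", prefix_b: str = "Q") -> GeneNetwork:
    """Scaled mutual-inhibition network used by scoring tests."""
    half = n_tfs // 2
    a = [f"{prefix_a}{i}" for i in range(half)]
    b = [f"{prefix_b}{i}" for i in range(half)]
    edges = []
    for i in range(half):
        edges.append(NetworkEdge(a[i], b[i], -1, "curated", -1.0))
        edges.append(NetworkEdge(b[i], a[i], -1, "curated", -1.0))
        edges.append(NetworkEdge(a[i], b[(i + 1) % half], -1, "curated", -1.0))
        edges.append(NetworkEdge(b[i], a[(i + 1) % half], -1, "curated", -1.0))
    return GeneNetwork(a + b, edges)


@pytest.fixture(scope="session")
def e2e_run(planted, planted_expr):
    """Reduced-scale end-to-end pipeline run shared by recovery tests.

    20 TFs, a 2 x 2 x 3 hyperparameter grid and 1000-model ensembles keep the
    full optimization + perturbation pass within a few minutes.
    """
    from coregrn.pipeline import PipelineConfig, PipelineInputs, run_optimize, run_perturb

    inputs = PipelineInputs(
        expr=planted_expr,
        binding=cg.emit_binding_table(planted),
        curated=planted.curated_db,
        ranked_lists=cg.emit_ranked_tf_lists(planted),
    )
    # k values bracket the planted core size: top-k union covers all planted TFs
    # only when k >= n_tfs, and k below the 15-TF rule can yield no candidate
    config = PipelineConfig(
        binding_grid=(0.1, 0.2),
        k_grid=(20, 25),
        cutoff_grid=(0.2, 0.4, 0.6),
        n_models=1000,
        n_null=200,
        seed=17,
        stability_repeats=2,
        stability_top=2,
    )
    opt = run_optimize(inputs, config)
    rep = run_perturb(inputs, config, opt)
    return {"inputs": inputs, "config": config, "optimize": opt, "perturb": rep}
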