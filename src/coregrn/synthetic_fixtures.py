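"""Fully synthetic inputs with the statistical structure the pipeline assumes.

The planted world is a bistable core of two mutually inhibiting, internally
activating TF modules: each gene is repressed by two genes of the opposite
module and activated by its intra-module ring predecessor.  A random-parameter
ODE ensemble of this motif populates two well-separated expression clusters,
matching a two-state control/case experiment.  Around the core the generator
emits every input the pipeline consumes:

* a log2 expression matrix with two well-separated states plus per-gene noise
  (module-A genes high in the control state, module-B genes high in the case
  state; decoy TFs carry no signal),
* a curated TF-target database with dropout and spurious entries,
* a TF-gene binding-probability table where planted pairs score U(0.5, 1) and
  background pairs U(0, 0.3), so planted targets always out-rank background
  and a threshold of 0.3 separates them exactly,
* ranked TF lists emulating external selection methods (planted TFs near the
  top with per-method rank jitter, decoys below).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from coregrn.data_model import (
    CASE,
    CONTROL,
    BindingTable,
    ExpressionMatrix,
    GeneNetwork,
    NetworkEdge,
    TFTargetDB,
)


@dataclass
class PlantedSystem:
    """Ground truth of one synthetic experiment."""

    network: GeneNetwork  # planted TF-TF core
    module_a: list[str]  # high in the control state
    module_b: list[str]  # high in the case state (the planted case drivers)
    decoys: list[str]
    tf_targets: dict[str, list[str]]  # planted non-TF targets per TF
    curated_db: TFTargetDB
    binding: BindingTable
    effect_size: float
    noise_sd: float
    dropout: float
    spurious_rate: float
    seed: int
    baseline: float = 8.0

    @property
    def tfs(self) -> list[str]:
        return self.module_a + self.module_b

    @property
    def genes(self) -> list[str]:
        targets = [t for tf in self.tfs for t in self.tf_targets[tf]]
        return self.tfs + self.decoys + targets

    @property
    def case_drivers(self) -> list[str]:
        return list(self.module_b)

    def planted_edges(self) -> set[tuple[str, str]]:
        return self.network.edge_set()


def _core_edges(module_a: list[str], module_b: list[str]) -> list[NetworkEdge]:
    """Mutual-inhibition-dominant bistable core with internal activation.

    Each gene is inhibited by two genes of the opposite module (its
    counterpart and the counterpart's ring successor) and activated by its
    intra-module ring predecessor.  Inhibition dominance matters: genes are
    constitutively on unless repressed, so random-parameter ensembles populate
    the two antagonistic module states; purely activation-driven modules
    almost never self-ignite when each link is functional in only about half
    the models.
    """
    m = len(module_a)
    edges: list[NetworkEdge] = []
    for i in range(m):
        for mod_s, mod_t in ((module_a, module_b), (module_b, module_a)):
            edges.append(NetworkEdge(mod_s[i], mod_t[i], -1, "curated", -1.0))
            edges.append(NetworkEdge(mod_s[i], mod_t[(i + 1) % m], -1, "curated", -1.0))
        for mod in (module_a, module_b):
            edges.append(NetworkEdge(mod[i], mod[(i + 1) % m], 1, "curated", 1.0))
    return edges


def make_planted_system(
    n_tfs: int = 20,
    targets_per_tf: int = 10,
    effect_size: float = 2.0,
    noise_sd: float = 0.5,
    dropout: float = 0.1,
    spurious_rate: float = 0.01,
    seed: int = 17,
    n_decoys: int = 5,
    n_background: int = 30,
) -> PlantedSystem:
    """Build a reproducible planted system.

    ``effect_size`` is the centroid separation in units of ``noise_sd``;
    ``dropout`` is the per-entry omission probability applied independently to
    the curated database and the binding table; ``spurious_rate`` is the
    per-(TF, non-target) probability of a spurious curated entry.
    """
    if n_tfs < 4 or n_tfs % 2:
        raise ValueError("n_tfs must be an even integer >= 4")
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")
    if not 0 <= spurious_rate < 1:
        raise ValueError("spurious_rate must be in [0, 1)")
    if noise_sd < 0 or effect_size < 0:
        raise ValueError("noise_sd and effect_size must be >= 0")
    rng = np.random.default_rng(seed)
    half = n_tfs // 2
    module_a = [f"TFA{i + 1:02d}" for i in range(half)]
    module_b = [f"TFB{i + 1:02d}" for i in range(half)]
    decoys = [f"DEC{i + 1:02d}" for i in range(n_decoys)]
    tfs = module_a + module_b

    network = GeneNetwork(tfs, _core_edges(module_a, module_b))

    tf_targets = {
        tf: [f"{tf}_T{j + 1:02d}" for j in range(targets_per_tf)] for tf in tfs
    }
    all_genes = tfs + decoys + [t for tf in tfs for t in tf_targets[tf]]

    # true regulon per TF: network out-neighbours plus its dedicated targets
    out_neighbours = {tf: [] for tf in tfs}
    for e in network.edges:
        out_neighbours[e.source].append(e.target)
    true_sets = {tf: out_neighbours[tf] + tf_targets[tf] for tf in tfs}

    # curated database: dropout per entry, spurious additions from the rest
    curated_sets: dict[str, set[str]] = {}
    for tf in tfs:
        kept = {t for t in true_sets[tf] if rng.random() > dropout}
        non_targets = [g for g in all_genes if g not in true_sets[tf] and g != tf]
        spurious = {g for g in non_targets if rng.random() < spurious_rate}
        curated_sets[tf] = kept | spurious
    curated_db = TFTargetDB.from_gene_sets(curated_sets, provenance="curated")

    # binding table: planted pairs strong, random background pairs weak
    rows: list[tuple[str, str, float]] = []
    for tf in tfs:
        for t in true_sets[tf]:
            if rng.random() > dropout:
                rows.append((tf, t, float(rng.uniform(0.5, 1.0))))
    for tf in tfs + decoys:
        pool = [g for g in all_genes if g != tf and g not in set(true_sets.get(tf, ()))]
        bg = rng.choice(len(pool), size=min(n_background, len(pool)), replace=False)
        existing = {(r[0], r[1]) for r in rows}
        for j in bg:
            pair = (tf, pool[j])
            if pair not in existing:
                rows.append((tf, pool[j], float(rng.uniform(0.0, 0.3))))
    binding = BindingTable(
        pd.DataFrame(rows, columns=["tf", "gene", "probability"]).sort_values(
            ["tf", "gene"], ignore_index=True
        )
    )

    return PlantedSystem(
        network=network,
        module_a=module_a,
        module_b=module_b,
        decoys=decoys,
        tf_targets=tf_targets,
        curated_db=curated_db,
        binding=binding,
        effect_size=effect_size,
        noise_sd=noise_sd,
        dropout=dropout,
        spurious_rate=spurious_rate,
        seed=seed,
    )


def emit_expression(
    sys: PlantedSystem,
    n_samples_per_state: tuple[int, int] = (11, 9),
) -> ExpressionMatrix:
    """Two-state log2 expression with per-gene Gaussian noise around centroids.

    Module-A TFs and their targets sit ``effect_size * noise_sd`` above their
    module-B counterparts in the control state and below them in the case
    state; decoy TFs have no state effect.
    """
    n_ctrl, n_case = n_samples_per_state
    if n_ctrl < 2 or n_case < 2:
        raise ValueError("need >= 2 samples per state")
    rng = np.random.default_rng(sys.seed + 1)
    delta = sys.effect_size * sys.noise_sd
    genes = sys.genes
    half_shift = {}
    for g in genes:
        owner = g.split("_")[0] if "_T" in g else g
        if owner in sys.module_a:
            half_shift[g] = +delta / 2.0
        elif owner in sys.module_b:
            half_shift[g] = -delta / 2.0
        else:  # decoys
            half_shift[g] = 0.0
    samples = [f"ctrl{i + 1:02d}" for i in range(n_ctrl)] + [
        f"case{i + 1:02d}" for i in range(n_case)
    ]
    labels = {s: (CONTROL if s.startswith("ctrl") else CASE) for s in samples}
    shift = np.array([half_shift[g] for g in genes])[:, None]
    state_sign = np.array([1.0] * n_ctrl + [-1.0] * n_case)[None, :]
    centroid = sys.baseline + shift * state_sign
    noise = rng.normal(0.0, sys.noise_sd, (len(genes), len(samples))) if sys.noise_sd else 0.0
    data = pd.DataFrame(centroid + noise, index=genes, columns=samples)
    return ExpressionMatrix(data, pd.Series(labels))


def emit_binding_table(sys: PlantedSystem) -> BindingTable:
    """The system's TF-gene binding probability table."""
    return BindingTable(sys.binding.table.copy())


def emit_curated_db(sys: PlantedSystem) -> TFTargetDB:
    """The system's curated TF-target database (with dropout/spurious applied)."""
    return sys.curated_db


def emit_ranked_tf_lists(
    sys: PlantedSystem,
    n_methods: int = 3,
    noise_swaps: int = 3,
) -> list[list[str]]:
    """Ranked TF lists standing in for external selection methods.

    Each list ranks the planted TFs first (order jittered per method by
    ``noise_swaps`` random adjacent transpositions) followed by the decoys.
    """
    rng = np.random.default_rng(sys.seed + 2)
    lists = []
    for _ in range(n_methods):
        order = list(sys.tfs)
        for _ in range(noise_swaps):
            if len(order) > 1:
                i = int(rng.integers(0, len(order) - 1))
                order[i], order[i + 1] = order[i + 1], order[i]
        lists.append(order + list(sys.decoys))
    return lists
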