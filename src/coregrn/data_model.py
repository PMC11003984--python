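"""Core domain types and flat-file readers/writers shared by all pipeline stages.

Conventions
-----------
* Gene/TF identifiers are case-sensitive symbols; no aliasing layer.
* Edge signs are +1 (activation) / -1 (inhibition); the on-disk code is
  1 = activation, 2 = inhibition, matching common GRN-simulator topology files.
* Sample labels are the two strings ``"control"`` and ``"case"``.
* All tabular interchange is tab-delimited text; gene sets travel as GMT.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

ACTIVATION = 1
INHIBITION = -1

#: on-disk interaction codes (Cytoscape-importable edge lists)
_SIGN_TO_CODE = {ACTIVATION: 1, INHIBITION: 2}
_CODE_TO_SIGN = {1: ACTIVATION, 2: INHIBITION}

CONTROL = "control"
CASE = "case"
STATES = (CONTROL, CASE)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkEdge:
    """A directed, signed regulatory interaction between two TFs."""

    source: str
    target: str
    sign: int  # +1 activation, -1 inhibition
    provenance: str = "curated"  # "curated" | "atac"
    correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATION, INHIBITION):
            raise ValueError(f"edge sign must be +1 or -1, got {self.sign!r}")
        if not -1.0 <= self.correlation <= 1.0:
            raise ValueError(f"correlation out of [-1,1]: {self.correlation}")
        if self.correlation != 0.0 and np.sign(self.correlation) != self.sign:
            raise ValueError(
                f"edge sign {self.sign} inconsistent with correlation "
                f"{self.correlation} for {self.source}->{self.target}"
            )


class GeneNetwork:
    """Directed signed TF-TF graph (a candidate or optimal GRN).

    Node identifiers are unique; at most one edge per ordered (source, target)
    pair; every edge endpoint is a node.
    """

    def __init__(self, nodes: Iterable[str], edges: Iterable[NetworkEdge] = ()) -> None:
        self.nodes: list[str] = list(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        self.edges: list[NetworkEdge] = list(edges)
        node_set = set(self.nodes)
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.source not in node_set or e.target not in node_set:
                raise ValueError(f"edge endpoint not a node: {e.source}->{e.target}")
            key = (e.source, e.target)
            if key in seen:
                raise ValueError(f"duplicate edge {e.source}->{e.target}")
            seen.add(key)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_index(self) -> dict[tuple[str, str], NetworkEdge]:
        return {(e.source, e.target): e for e in self.edges}

    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges}

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(
                e.source,
                e.target,
                sign=e.sign,
                provenance=e.provenance,
                correlation=e.correlation,
            )
        return g

    def subgraph(self, keep: Iterable[str]) -> "GeneNetwork":
        keep_set = set(keep)
        nodes = [n for n in self.nodes if n in keep_set]
        edges = [e for e in self.edges if e.source in keep_set and e.target in keep_set]
        return GeneNetwork(nodes, edges)

    def topology_key(self) -> tuple:
        """Hashable identity of the signed topology (ignores provenance/correlation)."""
        return (
            tuple(sorted(self.nodes)),
            tuple(sorted((e.source, e.target, e.sign) for e in self.edges)),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return sorted(self.nodes) == sorted(other.nodes) and sorted(
            map(dataclasses.astuple, self.edges)
        ) == sorted(map(dataclasses.astuple, other.edges))

    def __repr__(self) -> str:
        return f"GeneNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


# ---------------------------------------------------------------------------
# TF-target databases and binding tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetRecord:
    """One target gene of a TF, with provenance and optional binding probability."""

    provenances: frozenset[str]
    probability: float | None = None

    def __post_init__(self) -> None:
        if self.probability is not None and not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"binding probability out of [0,1]: {self.probability}")

    @property
    def provenance(self) -> str:
        """Display provenance; curated wins ties when a target has both sources."""
        return "curated" if "curated" in self.provenances else sorted(self.provenances)[0]


class TFTargetDB:
    """Map TF -> target genes, with per-target provenance and optional probability."""

    def __init__(self, data: Mapping[str, Mapping[str, TargetRecord]] | None = None) -> None:
        self._data: dict[str, dict[str, TargetRecord]] = {
            tf: dict(targets) for tf, targets in (data or {}).items() if targets
        }

    @classmethod
    def from_gene_sets(
        cls,
        gene_sets: Mapping[str, Iterable[str]],
        provenance: str = "curated",
        probabilities: Mapping[str, Mapping[str, float]] | None = None,
    ) -> "TFTargetDB":
        data: dict[str, dict[str, TargetRecord]] = {}
        for tf, genes in gene_sets.items():
            recs = {}
            for g in genes:
                prob = None
                if probabilities is not None:
                    prob = probabilities.get(tf, {}).get(g)
                recs[g] = TargetRecord(frozenset({provenance}), prob)
            if recs:
                data[tf] = recs
        return cls(data)

    @property
    def tfs(self) -> list[str]:
        return sorted(self._data)

    def __contains__(self, tf: str) -> bool:
        return tf in self._data

    def __len__(self) -> int:
        return len(self._data)

    def __iter__(self):
        return iter(sorted(self._data))

    def targets(self, tf: str) -> set[str]:
        return set(self._data[tf])

    def record(self, tf: str, gene: str) -> TargetRecord:
        return self._data[tf][gene]

    def records(self, tf: str) -> dict[str, TargetRecord]:
        return dict(self._data[tf])

    def gene_sets(self) -> dict[str, set[str]]:
        return {tf: set(targets) for tf, targets in self._data.items()}

    def restrict_targets(self, genes: Iterable[str]) -> "TFTargetDB":
        """Drop targets not in ``genes`` (e.g. genes absent from the expression matrix)."""
        keep = set(genes)
        return TFTargetDB(
            {
                tf: {g: r for g, r in targets.items() if g in keep}
                for tf, targets in self._data.items()
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TFTargetDB):
            return NotImplemented
        return self._data == other._data

    def __repr__(self) -> str:
        n_targets = sum(len(t) for t in self._data.values())
        return f"TFTargetDB(n_tfs={len(self._data)}, n_targets={n_targets})"


@dataclass
class BindingTable:
    """TF-gene binding probabilities derived upstream from open-chromatin motif scans.

    One row per (TF, gene); probabilities in [0, 1].
    """

    table: pd.DataFrame  # columns: tf, gene, probability

    def __post_init__(self) -> None:
        required = ["tf", "gene", "probability"]
        if list(self.table.columns[:3]) != required:
            raise ValueError(f"binding table must have columns {required}")
        if self.table.duplicated(["tf", "gene"]).any():
            raise ValueError("duplicate (tf, gene) row in binding table")
        probs = self.table["probability"].to_numpy(float)
        if np.isnan(probs).any() or (probs < 0).any() or (probs > 1).any():
            raise ValueError("binding probabilities must lie in [0,1]")

    @property
    def tfs(self) -> list[str]:
        return sorted(self.table["tf"].unique())

    def for_tf(self, tf: str) -> pd.DataFrame:
        return self.table[self.table["tf"] == tf]


# ---------------------------------------------------------------------------
# expression / activity matrices
# ---------------------------------------------------------------------------


def _validate_labels(samples: Sequence[str], labels: Mapping[str, str]) -> pd.Series:
    missing = [s for s in samples if s not in labels]
    if missing:
        raise ValueError(f"samples missing from label file: {missing}")
    bad = {s: v for s, v in labels.items() if v not in STATES}
    if bad:
        raise ValueError(f"labels must be one of {STATES}, got {bad}")
    return pd.Series({s: labels[s] for s in samples}, name="label")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 expression with two-group sample labels."""

    data: pd.DataFrame  # genes x samples
    labels: pd.Series  # sample -> "control" | "case"

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene rows: {dupes}")
        self.labels = _validate_labels(list(self.data.columns), dict(self.labels))

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def group_samples(self, state: str) -> list[str]:
        return [s for s in self.samples if self.labels[s] == state]

    def require_min_group_size(self, n: int = 2) -> None:
        for state in STATES:
            k = len(self.group_samples(state))
            if k < n:
                raise ValueError(f"group {state!r} has {k} samples; need >= {n}")


@dataclass
class ActivityMatrix:
    """TFs x samples matrix of inferred TF activities, aligned to an expression matrix."""

    data: pd.DataFrame  # TFs x samples
    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = _validate_labels(list(self.data.columns), dict(self.labels))

    @property
    def tfs(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def group_samples(self, state: str) -> list[str]:
        return [s for s in self.samples if self.labels[s] == state]

    def zscored(self) -> "ActivityMatrix":
        """Per-TF z-score across samples (constant rows map to 0)."""
        vals = self.data.to_numpy(float)
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (vals - mu) / sd
        return ActivityMatrix(
            pd.DataFrame(z, index=self.data.index, columns=self.data.columns),
            self.labels,
        )


# ---------------------------------------------------------------------------
# selection rules and hyperparameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetSelectionRule:
    """Rule for how many open-chromatin targets to keep per TF.

    Below ``n_tsh`` passing genes all are kept; above it, only the top
    ``n_tsh + (n_genes - n_tsh) * top_fraction`` by binding probability.
    """

    n_tsh: int = 50
    top_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.n_tsh < 0:
            raise ValueError("n_tsh must be >= 0")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")


@dataclass(frozen=True)
class HyperParams:
    """One point of the candidate-network construction grid."""

    binding_threshold: float
    n_tfs_per_method: int
    corr_cutoff: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.binding_threshold <= 1.0:
            raise ValueError("binding_threshold must be in [0,1]")
        if self.n_tfs_per_method < 1:
            raise ValueError("n_tfs_per_method must be >= 1")
        if not 0.0 <= self.corr_cutoff < 1.0:
            raise ValueError("corr_cutoff must be in [0,1)")


# default binding-probability threshold grid (eleven values)
DEFAULT_BINDING_GRID: tuple[float, ...] = (
    0.05, 0.06, 0.07, 0.08, 0.09, 0.10, 0.12, 0.14, 0.16, 0.18, 0.20,
)
# correlation cutoffs 0.0 .. 0.95 in 0.05 steps (twenty values)
DEFAULT_CUTOFF_GRID: tuple[float, ...] = tuple(round(0.05 * i, 2) for i in range(20))
# per-method TF counts; configurable
DEFAULT_K_GRID: tuple[int, ...] = (5, 10, 15, 20)


# ---------------------------------------------------------------------------
# ensemble-simulation containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SamplingRanges:
    """Uniform sampling ranges for the random kinetic parameters.

    ``g``: maximum production rate; ``k``: degradation rate; ``n``: integer Hill
    coefficient; ``lam``: fold change (inhibitory fold changes are reciprocals
    of draws from the same range); ``threshold_span``: the Hill threshold is
    drawn from (span[0]*M, span[1]*M) where M is the median unregulated level.
    """

    g: tuple[float, float] = (1.0, 100.0)
    k: tuple[float, float] = (0.1, 1.0)
    n: tuple[int, int] = (1, 6)
    lam: tuple[float, float] = (1.0, 100.0)
    threshold_span: tuple[float, float] = (0.02, 1.98)
    median_threshold: float | None = None  # M; estimated when None

    def __post_init__(self) -> None:
        for name in ("g", "k", "lam", "threshold_span"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"range {name} must satisfy min < max")
        if self.n[0] > self.n[1]:
            raise ValueError("n range must satisfy min <= max")
        if self.median_threshold is not None and self.median_threshold <= 0:
            raise ValueError("median threshold M must be > 0")


@dataclass
class RacipeParams:
    """Kinetic parameters of one ODE model, aligned to a network's gene/edge order."""

    g: np.ndarray  # (n_genes,) max production rates
    k: np.ndarray  # (n_genes,) degradation rates
    n: np.ndarray  # (n_edges,) integer Hill coefficients
    lam: np.ndarray  # (n_edges,) fold changes (>1 excitatory, (0,1) inhibitory)
    x0: np.ndarray  # (n_edges,) Hill thresholds

    def validate(self, edge_signs: np.ndarray) -> None:
        if (self.g <= 0).any() or (self.k <= 0).any() or (self.x0 <= 0).any():
            raise ValueError("G, k and thresholds must be > 0")
        if ((self.n < 1) | (self.n > 6)).any():
            raise ValueError("Hill coefficients must be integers in 1..6")
        pos = edge_signs > 0
        if (self.lam[pos] <= 1).any() or (self.lam[~pos] >= 1).any() or (
            self.lam[~pos] <= 0
        ).any():
            raise ValueError("fold changes inconsistent with edge signs")


@dataclass
class RacipeEnsemble:
    """Random-parameter ODE ensemble of one network topology.

    ``states`` holds raw steady-state levels (models x genes); ``normalized()``
    yields the log2 + per-gene z-scored matrix used for all downstream
    comparisons with experimental activity profiles.
    """

    network: GeneNetwork
    params: list[RacipeParams]
    states: np.ndarray  # (n_models, n_genes) raw steady-state levels
    converged: np.ndarray  # (n_models,) bool
    seed: int
    norm_reference: tuple[np.ndarray, np.ndarray] | None = None  # (mean, sd) in log2 space
    inits: np.ndarray | None = None  # (n_models, n_genes) initial conditions

    def __post_init__(self) -> None:
        if self.states.shape[0] != len(self.params):
            raise ValueError("state matrix rows must match number of parameter sets")
        if self.states.shape[1] != self.network.n_nodes:
            raise ValueError("state matrix columns must match number of genes")

    @property
    def genes(self) -> list[str]:
        return list(self.network.nodes)

    @property
    def n_models(self) -> int:
        return self.states.shape[0]

    def normalized(self) -> np.ndarray:
        """log2 then per-gene z-score across converged models.

        When ``norm_reference`` is set (knockdown ensembles), the stored
        unperturbed mean/sd are reused so perturbed and unperturbed profiles
        live in the same standardized space.
        """
        with np.errstate(divide="ignore"):
            logged = np.log2(np.maximum(self.states, 1e-12))
        if self.norm_reference is not None:
            mu, sd = self.norm_reference
        else:
            ok = self.converged
            mu = logged[ok].mean(axis=0)
            sd = logged[ok].std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        return (logged - mu) / sd

    def log2_norm_reference(self) -> tuple[np.ndarray, np.ndarray]:
        with np.errstate(divide="ignore"):
            logged = np.log2(np.maximum(self.states[self.converged], 1e-12))
        mu = logged.mean(axis=0)
        sd = logged.std(axis=0)
        return mu, np.where(sd == 0, 1.0, sd)


# ---------------------------------------------------------------------------
# state assignment and scoring containers
# ---------------------------------------------------------------------------

UNASSIGNED = "unassigned"


@dataclass
class StateAssignment:
    """Per-model assignment to an experimental state via the distance/null test."""

    states: np.ndarray  # (n_models,) of {"control","case","unassigned"}
    p_values: pd.DataFrame  # n_models x 2, columns "control","case"
    alpha: float = 0.05

    def proportions(self) -> "StateProportions":
        n = len(self.states)
        if n == 0:
            raise ValueError("empty assignment")
        return StateProportions(
            control=float(np.mean(self.states == CONTROL)),
            case=float(np.mean(self.states == CASE)),
            unassigned=float(np.mean(self.states == UNASSIGNED)),
        )


@dataclass(frozen=True)
class StateProportions:
    """Proportions of ensemble models per state; sums to 1 within 1e-9."""

    control: float
    case: float
    unassigned: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.control, self.case, self.unassigned)
        if any(v < -1e-12 for v in vals):
            raise ValueError("proportions must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {sum(vals)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.control, self.case, self.unassigned])


@dataclass
class CandidateScore:
    """Accuracy/flexibility scores and rank indices of one candidate network."""

    candidate_id: int
    accuracy: float
    flexibility: float
    n_edges: int = 0
    accuracy_rank: int | None = None
    flexibility_rank: int | None = None

    @property
    def combined_index(self) -> int:
        if self.accuracy_rank is None or self.flexibility_rank is None:
            raise ValueError("candidate not yet ranked")
        return self.accuracy_rank + self.flexibility_rank


@dataclass
class PerturbationResult:
    """Outcome of one in-silico knockdown (single gene or gene pair)."""

    genes: tuple[str, ...]
    proportions: StateProportions
    p_value: float

    def __post_init__(self) -> None:
        if not 1 <= len(self.genes) <= 2:
            raise ValueError("knockdown sets have size 1 or 2")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value out of [0,1]")


@dataclass
class PathwayAnnotation:
    """TF -> (most representative pathway or None, Fisher p-value)."""

    annotations: dict[str, tuple[str | None, float]]
    p_max: float = 0.1

    def __post_init__(self) -> None:
        for tf, (pathway, p) in self.annotations.items():
            if pathway is not None and p > self.p_max:
                raise ValueError(f"{tf} annotated with p={p} > {self.p_max}")

    def pathway(self, tf: str) -> str | None:
        return self.annotations[tf][0]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, labels_path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV plus a 2-column sample/label TSV.

    Raises on non-numeric cells, duplicate gene rows, or samples missing from
    the label file.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression value in {path}: {exc}") from exc
    labels = read_labels(labels_path)
    return ExpressionMatrix(df, pd.Series(labels))


def read_labels(path: str | Path) -> dict[str, str]:
    lab = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"], dtype=str)
    if lab["sample"].duplicated().any():
        raise ValueError("duplicate sample in label file")
    return dict(zip(lab["sample"], lab["label"]))


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, label in labels.items():
            fh.write(f"{sample}\t{label}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets (name, description, members...).

    Duplicate set names are unioned; sets with no members are dropped; a line
    with fewer than 3 fields is an error.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields (<3)")
            name = fields[0]
            members = {f for f in fields[2:] if f}
            if not members:
                continue
            sets.setdefault(name, set()).update(members)
    return sets


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            members = sorted(gene_sets[name])
            fh.write("\t".join([name, description, *members]) + "\n")


def read_binding_table(path: str | Path) -> BindingTable:
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str, 1: str})
    df.columns = ["tf", "gene", "probability"]
    df["probability"] = df["probability"].astype(float)
    return BindingTable(df)


def write_binding_table(binding: BindingTable, path: str | Path) -> None:
    binding.table.to_csv(path, sep="\t", index=False)


_NETWORK_HEADER = ["source", "interaction", "target", "provenance", "correlation"]


def write_network(net: GeneNetwork, path: str | Path) -> None:
    """Write a 5-column TSV edge list (interaction code 1=activation, 2=inhibition).

    Isolated nodes are preserved in a trailing comment block so the round trip
    is an identity.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(_NETWORK_HEADER) + "\n")
        for e in net.edges:
            fh.write(
                f"{e.source}\t{_SIGN_TO_CODE[e.sign]}\t{e.target}\t"
                f"{e.provenance}\t{e.correlation:.10g}\n"
            )
        connected = {n for e in net.edges for n in (e.source, e.target)}
        for node in net.nodes:
            if node not in connected:
                fh.write(f"#node\t{node}\n")


def read_network(path: str | Path) -> GeneNetwork:
    nodes: list[str] = []
    edges: list[NetworkEdge] = []
    seen_nodes: set[str] = set()

    def add_node(n: str) -> None:
        if n not in seen_nodes:
            seen_nodes.add(n)
            nodes.append(n)

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _NETWORK_HEADER:
            raise ValueError(f"unexpected network header {header}")
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#node\t"):
                add_node(line.split("\t")[1])
                continue
            src, code, tgt, prov, corr = line.split("\t")
            try:
                sign = _CODE_TO_SIGN[int(code)]
            except (KeyError, ValueError):
                raise ValueError(f"{path}:{lineno}: unknown sign code {code!r}") from None
            add_node(src)
            add_node(tgt)
            edges.append(NetworkEdge(src, tgt, sign, prov, float(corr)))
    return GeneNetwork(nodes, edges)


def read_ranked_list(path: str | Path) -> list[str]:
    """Read a ranked TF list: one identifier per line, best first."""
    with open(path) as fh:
        out = [line.strip() for line in fh if line.strip()]
    if len(set(out)) != len(out):
        raise ValueError(f"duplicate TF in ranked list {path}")
    return out


def write_ranked_list(tfs: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.writelines(f"{tf}\n" for tf in tfs)


def write_activity(act: ActivityMatrix, path: str | Path) -> None:
    act.data.to_csv(path, sep="\t")


def read_activity(path: str | Path, labels_path: str | Path) -> ActivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    return ActivityMatrix(df, pd.Series(read_labels(labels_path)))


def db_to_gmt(db: TFTargetDB, path: str | Path) -> None:
    write_gmt(db.gene_sets(), path)


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
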