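"""Knockdown screening on the optimal network.

Unperturbed models labeled by the distance/null assignment train a ridge
regression mapping standardized expression to the class indicator
(control = 0, case = 1, threshold 0.5); every knockdown ensemble is then
classified by this mapper, proportion shifts are tested with a Pearson
chi-squared test, and profiles can be projected onto the unperturbed
principal components for visualization.
"""

from __future__ import annotations

import itertools
import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Ridge

from coregrn.data_model import (
    CASE,
    CONTROL,
    GeneNetwork,
    PerturbationResult,
    RacipeEnsemble,
    StateAssignment,
    StateProportions,
    warn,
)
from coregrn.racipe_sim import simulate_knockdown

log = logging.getLogger(__name__)


@dataclass
class StateMapper:
    """Linear (ridge) decision rule over standardized expression profiles."""

    coef: np.ndarray  # (n_genes,)
    intercept: float
    threshold: float = 0.5
    n_control: int = 0
    n_case: int = 0
    penalty: float = 1.0

    def decision(self, profiles: np.ndarray) -> np.ndarray:
        return profiles @ self.coef + self.intercept

    def predict(self, profiles: np.ndarray) -> np.ndarray:
        """Class labels: 0 = control, 1 = case."""
        return (self.decision(profiles) >= self.threshold).astype(int)

    def proportions(self, profiles: np.ndarray) -> StateProportions:
        pred = self.predict(profiles)
        return StateProportions(
            control=float(np.mean(pred == 0)), case=float(np.mean(pred == 1))
        )


def train_state_mapper(
    ensemble: RacipeEnsemble,
    assignment: StateAssignment,
    ridge_penalty: float = 1.0,
    min_per_class: int = 10,
) -> StateMapper:
    """Fit the ridge state mapper on assigned unperturbed models only."""
    profiles = ensemble.normalized()
    y = np.where(assignment.states == CASE, 1, 0)
    mask = (assignment.states == CONTROL) | (assignment.states == CASE)
    n_ctrl = int(np.sum(assignment.states == CONTROL))
    n_case = int(np.sum(assignment.states == CASE))
    if n_ctrl < min_per_class or n_case < min_per_class:
        raise ValueError(
            f"need >= {min_per_class} assigned models per class, "
            f"got control={n_ctrl}, case={n_case}"
        )
    model = Ridge(alpha=ridge_penalty)
    model.fit(profiles[mask], y[mask])
    return StateMapper(
        coef=np.asarray(model.coef_, float),
        intercept=float(model.intercept_),
        n_control=n_ctrl,
        n_case=n_case,
        penalty=ridge_penalty,
    )


def kd_significance(
    unperturbed_counts: tuple[int, int], kd_counts: tuple[int, int]
) -> float:
    """Pearson chi-squared p (no continuity correction) for a 2x2 state table.

    Rows are (control, case) counts under the unperturbed and knockdown
    conditions.  A zero row or column margin leaves the test undefined; p is
    returned as 1 with a warning.
    """
    table = np.array([unperturbed_counts, kd_counts], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warn("zero margin in contingency table; chi-squared undefined, returning p=1")
        return 1.0
    res = stats.chi2_contingency(table, correction=False)
    return float(res.pvalue)


def kd_screen(
    net: GeneNetwork,
    ensemble: RacipeEnsemble,
    mapper: StateMapper,
    kd_sets: Sequence[Iterable[str]] | None = None,
    kd_factor: float = 0.95,
    n_top: int = 5,
) -> list[PerturbationResult]:
    """Screen single (and optionally double) knockdowns with the ridge mapper.

    With ``kd_sets`` None, all single-TF knockdowns are screened first; the
    union of the top-``n_top`` and bottom-``n_top`` TFs ranked by
    control-state proportion (descending) then defines all unordered pairs
    for double knockdowns.  The chi-squared p-value of each result contrasts
    the mapper's (control, case) counts against the unperturbed ones.
    """
    base = mapper.proportions(ensemble.normalized()[ensemble.converged])
    auto_pairs = kd_sets is None
    if auto_pairs:
        kd_sets = [(tf,) for tf in net.nodes]
    results: list[PerturbationResult] = []
    for genes in kd_sets:
        results.append(
            _run_kd(net, ensemble, mapper, tuple(genes), kd_factor, base)
        )
    if auto_pairs:
        singles = sorted(
            results, key=lambda r: (-r.proportions.control, r.genes)
        )
        chosen = [r.genes[0] for r in singles[:n_top]] + [
            r.genes[0] for r in singles[-n_top:]
        ]
        seen = sorted(set(chosen), key=chosen.index)
        for pair in itertools.combinations(seen, 2):
            results.append(_run_kd(net, ensemble, mapper, pair, kd_factor, base))
    return results


def _run_kd(
    net: GeneNetwork,
    ensemble: RacipeEnsemble,
    mapper: StateMapper,
    genes: tuple[str, ...],
    kd_factor: float,
    base: StateProportions,
) -> PerturbationResult:
    kd = simulate_knockdown(net, ensemble, genes, kd_factor=kd_factor)
    props = mapper.proportions(kd.normalized()[kd.converged])
    n_base = int(np.sum(ensemble.converged))
    n_kd = int(np.sum(kd.converged))
    p = kd_significance(
        (round(base.control * n_base), round(base.case * n_base)),
        (round(props.control * n_kd), round(props.case * n_kd)),
    )
    return PerturbationResult(genes=genes, proportions=props, p_value=p)


def rank_destabilizers(results: Sequence[PerturbationResult]) -> pd.DataFrame:
    """Single-KD results ordered by control-state proportion, descending.

    Genes at the top destabilize the case state (their knockdown enlarges the
    control-state population); genes at the bottom destabilize the control
    state.  Deterministic: ties break by gene name.
    """
    singles = [r for r in results if len(r.genes) == 1]
    rows = [
        {
            "gene": r.genes[0],
            "control": r.proportions.control,
            "case": r.proportions.case,
            "p_value": r.p_value,
        }
        for r in singles
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["control", "gene"], ascending=[False, True], ignore_index=True
    )


@dataclass
class PCAProjection:
    """2-D projection fitted on the unperturbed ensemble."""

    unperturbed: np.ndarray  # (n_models, 2)
    perturbed: list[np.ndarray]
    explained_variance_ratio: np.ndarray


def project_pca(
    unperturbed_matrix: np.ndarray,
    perturbed_matrices: Sequence[np.ndarray] = (),
) -> PCAProjection:
    """Project profiles onto the first two PCs of the unperturbed matrix.

    Components and centering are fitted on the unperturbed profiles only;
    perturbed profiles are transformed with the same loadings.
    """
    from sklearn.decomposition import PCA

    unperturbed_matrix = np.asarray(unperturbed_matrix, float)
    if unperturbed_matrix.shape[1] < 2:
        raise ValueError("need at least 2 genes for a 2-D projection")
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(unperturbed_matrix)
    projected = [pca.transform(np.asarray(m, float)) for m in perturbed_matrices]
    return PCAProjection(
        unperturbed=scores,
        perturbed=projected,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
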