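"""Candidate-network scoring: state assignment, accuracy, flexibility, ranking.

A simulated model is assigned to an experimental state by comparing its
distance to the nearest same-state activity profile against a null of
gene-label-shuffled copies of the model's own profile; the model joins the
state with the smallest permutation p-value provided that p <= alpha,
otherwise it is unassigned.  Accuracy is the assigned fraction; flexibility is
the mean Euclidean shift of the two-state proportions over all single-gene
knockdowns.  Candidates are ordered by the sum of their accuracy and
flexibility rank indices.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from coregrn.data_model import (
    CASE,
    CONTROL,
    UNASSIGNED,
    ActivityMatrix,
    CandidateScore,
    GeneNetwork,
    RacipeEnsemble,
    SamplingRanges,
    StateAssignment,
    StateProportions,
)
from coregrn.racipe_sim import simulate_ensemble, simulate_knockdown

log = logging.getLogger(__name__)

_CHUNK = 64


def _aligned_profiles(ensemble: RacipeEnsemble, activity: ActivityMatrix):
    """Simulated profiles and per-state sample profiles in the shared z-space."""
    if set(ensemble.genes) != set(activity.tfs):
        raise ValueError(
            "gene sets of ensemble and activity matrix differ: "
            f"{sorted(set(ensemble.genes) ^ set(activity.tfs))}"
        )
    actz = activity.zscored()
    # align activity rows to the ensemble's gene order
    act = actz.data.loc[ensemble.genes]
    sim = ensemble.normalized()
    samples = {
        state: act[actz.group_samples(state)].to_numpy(float).T  # (n_samples, genes)
        for state in (CONTROL, CASE)
    }
    return sim, samples


def _min_dist_sq(profiles: np.ndarray, samples: np.ndarray) -> np.ndarray:
    """Squared distance from each profile to its nearest sample profile."""
    p2 = np.einsum("ij,ij->i", profiles, profiles)
    s2 = np.einsum("ij,ij->i", samples, samples)
    d2 = p2[:, None] + s2[None, :] - 2.0 * profiles @ samples.T
    return np.maximum(d2.min(axis=1), 0.0)


def assign_states(
    ensemble: RacipeEnsemble,
    activity: ActivityMatrix,
    n_null: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> StateAssignment:
    """Assign each converged model to control/case/unassigned via permutation nulls.

    For each model and each state the observed statistic is the Euclidean
    distance to the nearest same-state sample profile; the null shuffles the
    model's own gene labels ``n_null`` times (one permutation set per model,
    shared across the two states) and p is the fraction of null distances <=
    the observed one.  The model is mapped to the smallest-p state when that p
    <= alpha.  Non-converged models are unassigned with p-values of 1.
    """
    sim, samples = _aligned_profiles(ensemble, activity)
    m, n_genes = sim.shape
    rng = np.random.default_rng(seed)
    p_vals = np.ones((m, 2))
    conv_idx = np.flatnonzero(ensemble.converged)
    d_obs = {
        state: np.sqrt(_min_dist_sq(sim[conv_idx], samples[state]))
        for state in (CONTROL, CASE)
    }
    for start in range(0, conv_idx.size, _CHUNK):
        rows = conv_idx[start : start + _CHUNK]
        c = rows.size
        idx = rng.permuted(
            np.tile(np.arange(n_genes), (c * n_null, 1)), axis=1
        )
        owner = np.repeat(np.arange(c), n_null)
        null_profiles = sim[rows][owner[:, None], idx]  # (c*n_null, genes)
        for j, state in enumerate((CONTROL, CASE)):
            d_null = np.sqrt(_min_dist_sq(null_profiles, samples[state]))
            d_null = d_null.reshape(c, n_null)
            obs = d_obs[state][start : start + c]
            p_vals[rows, j] = np.mean(d_null <= obs[:, None], axis=1)
    states = np.full(m, UNASSIGNED, dtype=object)
    best = np.argmin(p_vals, axis=1)
    # tie in p: the smaller observed distance wins, then control
    ties = p_vals[:, 0] == p_vals[:, 1]
    if ties.any():
        d_ctrl = np.full(m, np.inf)
        d_case = np.full(m, np.inf)
        d_ctrl[conv_idx] = d_obs[CONTROL]
        d_case[conv_idx] = d_obs[CASE]
        best[ties] = (d_case[ties] < d_ctrl[ties]).astype(int)
    p_best = p_vals[np.arange(m), best]
    ok = ensemble.converged & (p_best <= alpha)
    states[ok & (best == 0)] = CONTROL
    states[ok & (best == 1)] = CASE
    return StateAssignment(
        states=states,
        p_values=pd.DataFrame(p_vals, columns=[CONTROL, CASE]),
        alpha=alpha,
    )


def accuracy(assignment: StateAssignment) -> tuple[float, StateProportions]:
    """Fraction of models assigned to either experimental state, with proportions."""
    props = assignment.proportions()
    return props.control + props.case, props


def flexibility(
    unperturbed: StateProportions,
    kd_props: Sequence[StateProportions],
) -> float:
    """Mean Euclidean shift of the (control, case) proportion pair over knockdowns.

    f = (1/n) * sum_i sqrt((m_ctrl^u - m_ctrl^KDi)^2 + (m_case^u - m_case^KDi)^2),
    one term per network TF; ranges over [0, sqrt(2)].
    """
    if not kd_props:
        raise ValueError("need at least one knockdown's proportions")
    shifts = [
        np.hypot(unperturbed.control - kp.control, unperturbed.case - kp.case)
        for kp in kd_props
    ]
    return float(np.mean(shifts))


@dataclass
class ScoredCandidate:
    """Full scoring output of one candidate network."""

    score: CandidateScore
    proportions: StateProportions
    kd_proportions: dict[str, StateProportions]
    ensemble: RacipeEnsemble
    assignment: StateAssignment


def score_candidate(
    net: GeneNetwork,
    activity: ActivityMatrix,
    candidate_id: int = 0,
    n_models: int = 10_000,
    n_null: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    ranges: SamplingRanges = SamplingRanges(),
    kd_factor: float = 0.95,
) -> ScoredCandidate:
    """Simulate a candidate and compute its accuracy and flexibility.

    The flexibility stage re-simulates the ensemble once per TF with that TF
    knocked down and re-assigns states with the same distance/null machinery
    (seed offset per TF for the null permutations).
    """
    ensemble = simulate_ensemble(net, ranges, n_models=n_models, seed=seed)
    assignment = assign_states(ensemble, activity, n_null=n_null, alpha=alpha, seed=seed)
    acc, props = accuracy(assignment)
    kd_props: dict[str, StateProportions] = {}
    for i, tf in enumerate(net.nodes):
        kd = simulate_knockdown(net, ensemble, [tf], kd_factor=kd_factor)
        kd_assign = assign_states(
            kd, activity, n_null=n_null, alpha=alpha, seed=seed + i + 1
        )
        kd_props[tf] = kd_assign.proportions()
    flex = flexibility(props, list(kd_props.values()))
    score = CandidateScore(
        candidate_id=candidate_id,
        accuracy=acc,
        flexibility=flex,
        n_edges=net.n_edges,
    )
    return ScoredCandidate(score, props, kd_props, ensemble, assignment)


def rank_candidates(scores: Sequence[CandidateScore]) -> list[CandidateScore]:
    """Rank candidates by combined accuracy + flexibility ordering indices.

    Rank 1 goes to the highest accuracy and, independently, to the highest
    flexibility; the combined index is the sum of the two rank indices and the
    returned list is in ascending combined order.  Ties (in either metric and
    in the combined index) break by higher accuracy, then fewer edges, then
    candidate id, so the ordering is deterministic.
    """
    if not scores:
        raise ValueError("no candidates to rank")
    def tie_key(s: CandidateScore):
        return (-s.accuracy, s.n_edges, s.candidate_id)

    by_acc = sorted(scores, key=lambda s: (-s.accuracy, s.n_edges, s.candidate_id))
    by_flex = sorted(scores, key=lambda s: (-s.flexibility, *tie_key(s)))
    for rank, s in enumerate(by_acc, 1):
        s.accuracy_rank = rank
    for rank, s in enumerate(by_flex, 1):
        s.flexibility_rank = rank
    return sorted(scores, key=lambda s: (s.combined_index, *tie_key(s)))


@dataclass
class StabilityResult:
    """Repeat-scoring of the top candidates and top-vs-rival t-tests."""

    combined_scores: pd.DataFrame  # repeats x candidates (combined index per repeat)
    p_values: pd.Series  # rival candidate id -> two-sided t-test p
    stable: bool  # top differs from every rival at p < 0.05


def rerank_stability(
    networks: Sequence[tuple[int, GeneNetwork, ActivityMatrix]],
    n_repeats: int = 10,
    n_models: int = 10_000,
    n_null: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    ranges: SamplingRanges = SamplingRanges(),
    kd_factor: float = 0.95,
) -> StabilityResult:
    """Re-simulate and re-rank the top candidates over independent repeats.

    ``networks`` is (candidate id, network, activity matrix for its TF set)
    with the presumed top candidate first.  Each repeat re-scores every
    candidate with a fresh seed and assigns combined indices within the
    repeat; a two-sided t-test then compares the top candidate's combined
    scores against each rival's.
    """
    if len(networks) < 2:
        raise ValueError("need >= 2 candidates for a stability check")
    if n_repeats < 2:
        raise ValueError("need >= 2 repeats")
    ids = [cid for cid, _, _ in networks]
    rows = []
    for r in range(n_repeats):
        scores = []
        for cid, net, activity in networks:
            rep_seed = int(
                np.random.SeedSequence([seed, r, cid]).generate_state(1)[0] % (2**31)
            )
            sc = score_candidate(
                net,
                activity,
                candidate_id=cid,
                n_models=n_models,
                n_null=n_null,
                alpha=alpha,
                seed=rep_seed,
                ranges=ranges,
                kd_factor=kd_factor,
            )
            scores.append(sc.score)
        ranked = rank_candidates(scores)
        rows.append({s.candidate_id: s.combined_index for s in ranked})
    table = pd.DataFrame(rows, columns=ids)
    top = ids[0]
    p_values = {}
    for rival in ids[1:]:
        res = stats.ttest_ind(table[top], table[rival])
        p = float(res.pvalue)
        p_values[rival] = 1.0 if np.isnan(p) else p
    p_series = pd.Series(p_values, name="p_value")
    return StabilityResult(
        combined_scores=table,
        p_values=p_series,
        stable=bool((p_series < 0.05).all()),
    )
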