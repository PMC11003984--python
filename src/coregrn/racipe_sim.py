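"""Random-parameter ensemble ODE simulation of a signed regulatory network.

Each gene Y follows

    dY/dt = G_Y / prod(lambda+_in) * prod_i Hs(X_i, X_iY0, n_i, lambda_i) - k_Y * Y,

where Hs is the shifted Hill function and the product of incoming excitatory
fold changes normalizes G_Y to be the true maximum production rate.  An
ensemble samples kinetic parameters uniformly per model, integrates each model
from one random log-uniform initial condition to a fixed point, and reports
the steady-state matrix.  Knockdowns re-simulate the same parameter sets with
the perturbed gene's production rate scaled down.

The integrator is fixed-step Euler (dt = 0.02, t_max = 100) with a relative
derivative convergence test, vectorized across models, with one retry from a
fresh random initial condition for non-converged models.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable

import numpy as np

from coregrn.data_model import (
    GeneNetwork,
    RacipeEnsemble,
    RacipeParams,
    SamplingRanges,
)

log = logging.getLogger(__name__)

DT = 0.02
T_MAX = 100.0
CONV_TOL = 1e-3
_EPS = 1e-9


def shifted_hill(x, x0: float, n, lam):
    """Shifted Hill regulation factor: lam + (1 - lam) / (1 + (x/x0)^n).

    Equals 1 when the regulator is absent (x = 0) and saturates at ``lam``;
    lam > 1 for activation, 0 < lam < 1 for inhibition.
    """
    x = np.asarray(x, float)
    if np.any(np.asarray(x0) <= 0):
        raise ValueError("Hill threshold x0 must be > 0")
    return lam + (1.0 - lam) / (1.0 + (x / x0) ** n)


def estimate_median_threshold(
    ranges: SamplingRanges = SamplingRanges(),
    n_draws: int = 100_000,
    seed: int = 0,
) -> float:
    """Median unregulated expression level M = median(G/k) by Monte Carlo.

    This is the half-functional placement of Hill thresholds: centering
    thresholds on the median unregulated level makes each regulatory link
    functional in roughly half the ensemble.
    """
    if n_draws < 10_000:
        raise ValueError("n_draws must be >= 10000 for a stable median")
    rng = np.random.default_rng(seed)
    g = rng.uniform(*ranges.g, n_draws)
    k = rng.uniform(*ranges.k, n_draws)
    if np.all(g == 0):
        raise ValueError("degenerate production-rate range")
    return float(np.median(g / k))


# ---------------------------------------------------------------------------
# topology preprocessing
# ---------------------------------------------------------------------------


class _Topology:
    """Edge arrays of a network, pre-ordered by target gene for fast grouping."""

    def __init__(self, net: GeneNetwork) -> None:
        self.genes = list(net.nodes)
        gi = {g: i for i, g in enumerate(self.genes)}
        src = np.array([gi[e.source] for e in net.edges], dtype=np.intp)
        tgt = np.array([gi[e.target] for e in net.edges], dtype=np.intp)
        sign = np.array([e.sign for e in net.edges], dtype=np.intp)
        order = np.argsort(tgt, kind="stable")
        self.src = src[order]
        self.tgt = tgt[order]
        self.sign = sign[order]
        self.order = order  # original-edge -> sorted position mapping helper
        self.n_genes = len(self.genes)
        self.n_edges = len(src)
        if self.n_edges:
            change = np.flatnonzero(np.diff(self.tgt)) + 1
            self.seg_starts = np.concatenate([[0], change])
            self.genes_with_in = self.tgt[self.seg_starts]
        else:
            self.seg_starts = np.array([], dtype=np.intp)
            self.genes_with_in = np.array([], dtype=np.intp)

    def group_product(self, per_edge: np.ndarray) -> np.ndarray:
        """Product of a per-edge quantity over incoming edges, per gene.

        ``per_edge`` is (n_models, n_edges) in sorted-edge order; genes with no
        incoming edges get 1.
        """
        m = per_edge.shape[0]
        out = np.ones((m, self.n_genes))
        if self.n_edges:
            out[:, self.genes_with_in] = np.multiply.reduceat(
                per_edge, self.seg_starts, axis=1
            )
        return out


# ---------------------------------------------------------------------------
# parameter sampling
# ---------------------------------------------------------------------------


def _sample_stacked(
    topo: _Topology,
    ranges: SamplingRanges,
    n_models: int,
    rng: np.random.Generator,
    median_threshold: float,
) -> dict[str, np.ndarray]:
    g = rng.uniform(*ranges.g, (n_models, topo.n_genes))
    k = rng.uniform(*ranges.k, (n_models, topo.n_genes))
    n = rng.integers(ranges.n[0], ranges.n[1] + 1, (n_models, topo.n_edges))
    lam = rng.uniform(*ranges.lam, (n_models, topo.n_edges))
    lam = np.where(topo.sign > 0, lam, 1.0 / lam)
    lo, hi = ranges.threshold_span
    x0 = rng.uniform(lo * median_threshold, hi * median_threshold, (n_models, topo.n_edges))
    return {"g": g, "k": k, "n": n.astype(float), "lam": lam, "x0": x0}


def sample_parameters(
    net: GeneNetwork,
    ranges: SamplingRanges = SamplingRanges(),
    n_models: int = 10_000,
    seed: int = 0,
) -> list[RacipeParams]:
    """Sample random kinetic parameter sets for a network; reproducible by seed.

    Per model: G ~ U(1,100), k ~ U(0.1,1), integer Hill coefficients uniform on
    1..6, excitatory fold changes ~ U(1,100), inhibitory fold changes the
    reciprocals of U(1,100) draws, thresholds ~ U(0.02 M, 1.98 M) with M the
    median unregulated level.  Edge-aligned arrays follow the network's edge
    order.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    topo = _Topology(net)
    m_thr = ranges.median_threshold
    if m_thr is None:
        m_thr = estimate_median_threshold(ranges, seed=seed)
    rng = np.random.default_rng(seed)
    stacked = _sample_stacked(topo, ranges, n_models, rng, m_thr)
    inv = np.empty_like(topo.order)
    inv[topo.order] = np.arange(topo.n_edges)  # back to original edge order
    return [
        RacipeParams(
            g=stacked["g"][i],
            k=stacked["k"][i],
            n=stacked["n"][i][inv].astype(int),
            lam=stacked["lam"][i][inv],
            x0=stacked["x0"][i][inv],
        )
        for i in range(n_models)
    ]


def _stack_params(topo: _Topology, params: list[RacipeParams]) -> dict[str, np.ndarray]:
    g = np.stack([p.g for p in params])
    k = np.stack([p.k for p in params])
    n = np.stack([p.n for p in params]).astype(float)[:, topo.order]
    lam = np.stack([p.lam for p in params])[:, topo.order]
    x0 = np.stack([p.x0 for p in params])[:, topo.order]
    return {"g": g, "k": k, "n": n, "lam": lam, "x0": x0}


def _init_bounds(topo: _Topology, stacked: dict[str, np.ndarray]):
    """Log-uniform initial-condition bounds per gene and model.

    max = G/k; min = (G/k) * prod(lambda-_in) / prod(lambda+_in).
    """
    base = stacked["g"] / stacked["k"]
    lam = stacked["lam"]
    lam_plus = np.where(topo.sign > 0, lam, 1.0)
    lam_minus = np.where(topo.sign < 0, lam, 1.0)
    prod_plus = topo.group_product(lam_plus)
    prod_minus = topo.group_product(lam_minus)
    ymax = base
    ymin = base * prod_minus / prod_plus
    return ymin, ymax


def _draw_inits(ymin, ymax, rng: np.random.Generator) -> np.ndarray:
    u = rng.uniform(size=ymin.shape)
    return np.exp(np.log(ymin) + u * (np.log(ymax) - np.log(ymin)))


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def _derivative(y, topo: _Topology, stacked, scale):
    x = y[:, topo.src]
    h = stacked["lam"] + (1.0 - stacked["lam"]) / (
        1.0 + (x / stacked["x0"]) ** stacked["n"]
    )
    hprod = topo.group_product(h)
    return stacked["g"] / scale * hprod - stacked["k"] * y


def _integrate_euler(
    y: np.ndarray,
    topo: _Topology,
    stacked: dict[str, np.ndarray],
    dt: float = DT,
    t_max: float = T_MAX,
    tol: float = CONV_TOL,
    check_every: int = 25,
):
    """Fixed-step Euler to a fixed point, freezing converged models.

    Convergence: max_genes |dY/dt| / max(Y, eps) < tol.  Returns (y, converged).
    """
    lam_plus = np.where(topo.sign > 0, stacked["lam"], 1.0)
    scale_full = topo.group_product(lam_plus)
    m = y.shape[0]
    active = np.arange(m)
    converged = np.zeros(m, dtype=bool)
    n_steps = int(round(t_max / dt))
    sub = {key: val[active] for key, val in stacked.items()}
    scale = scale_full[active]
    ya = y[active]
    done_steps = 0
    while done_steps < n_steps and active.size:
        block = min(check_every, n_steps - done_steps)
        for _ in range(block):
            dy = _derivative(ya, topo, sub, scale)
            ya += dt * dy
            np.maximum(ya, 0.0, out=ya)  # levels cannot go negative
        done_steps += block
        dy = _derivative(ya, topo, sub, scale)
        rel = np.max(np.abs(dy) / np.maximum(ya, _EPS), axis=1)
        ok = rel < tol
        y[active] = ya
        if ok.any():
            converged[active[ok]] = True
            keep = ~ok
            active = active[keep]
            ya = ya[keep]
            scale = scale[keep]
            sub = {key: val[keep] for key, val in sub.items()}
    if active.size:
        y[active] = ya
    return y, converged


try:  # compiled kernel; the numpy block integrator is the fallback
    import numba as _numba

    @_numba.njit(cache=True)
    def _euler_kernel(y, g, k, lam, nh, x0, src, tgt, sign, dt, n_steps, tol, check_every, eps):
        m, n_genes = y.shape
        n_edges = src.size
        conv = np.zeros(m, dtype=np.bool_)
        scale = np.ones((m, n_genes))
        for e in range(n_edges):
            if sign[e] > 0:
                for i in range(m):
                    scale[i, tgt[e]] *= lam[i, e]
        prod = np.empty(n_genes)
        dy = np.empty(n_genes)
        for i in range(m):
            yi = y[i]
            step = 0
            while step < n_steps:
                block = min(check_every, n_steps - step)
                for _ in range(block):
                    for j in range(n_genes):
                        prod[j] = 1.0
                    for e in range(n_edges):
                        r = yi[src[e]] / x0[i, e]
                        rn = r
                        for _p in range(nh[i, e] - 1):
                            rn *= r
                        prod[tgt[e]] *= lam[i, e] + (1.0 - lam[i, e]) / (1.0 + rn)
                    for j in range(n_genes):
                        dy[j] = g[i, j] / scale[i, j] * prod[j] - k[i, j] * yi[j]
                        yi[j] += dt * dy[j]
                        if yi[j] < 0.0:
                            yi[j] = 0.0
                step += block
                # convergence: max relative derivative below tol
                for j in range(n_genes):
                    prod[j] = 1.0
                for e in range(n_edges):
                    r = yi[src[e]] / x0[i, e]
                    rn = r
                    for _p in range(nh[i, e] - 1):
                        rn *= r
                    prod[tgt[e]] *= lam[i, e] + (1.0 - lam[i, e]) / (1.0 + rn)
                rel = 0.0
                for j in range(n_genes):
                    d = g[i, j] / scale[i, j] * prod[j] - k[i, j] * yi[j]
                    denom = yi[j] if yi[j] > eps else eps
                    a = abs(d) / denom
                    if a > rel:
                        rel = a
                if rel < tol:
                    conv[i] = True
                    break
        return conv

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False


def _integrate(y, topo, stacked, dt=DT, t_max=T_MAX, tol=CONV_TOL, check_every=25):
    """Dispatch to the compiled kernel when available."""
    if _HAVE_NUMBA and topo.n_edges:
        n_steps = int(round(t_max / dt))
        conv = _euler_kernel(
            y,
            stacked["g"],
            stacked["k"],
            stacked["lam"],
            stacked["n"].astype(np.int64),
            stacked["x0"],
            topo.src.astype(np.int64),
            topo.tgt.astype(np.int64),
            topo.sign.astype(np.int64),
            dt,
            n_steps,
            tol,
            check_every,
            _EPS,
        )
        return y, conv
    return _integrate_euler(y, topo, stacked, dt=dt, t_max=t_max, tol=tol,
                            check_every=check_every)


def simulate_model(
    net: GeneNetwork,
    params: RacipeParams,
    init: np.ndarray | None = None,
    tol: float = CONV_TOL,
    dt: float = DT,
    t_max: float = T_MAX,
    method: str = "euler",
    seed: int = 0,
) -> tuple[np.ndarray, bool]:
    """Integrate one model to steady state; returns (steady state, converged).

    ``method`` may be "euler" (fixed step, the ensemble default) or "rk45"
    (adaptive, via scipy) for cross-checking integrator independence.
    """
    topo = _Topology(net)
    stacked = _stack_params(topo, [params])
    if init is None:
        ymin, ymax = _init_bounds(topo, stacked)
        init = _draw_inits(ymin, ymax, np.random.default_rng(seed))[0]
    y0 = np.asarray(init, float).reshape(1, -1).copy()
    if y0.shape[1] != net.n_nodes:
        raise ValueError("initial condition length must match gene count")
    if method == "euler":
        y, conv = _integrate(y0, topo, stacked, dt=dt, t_max=t_max, tol=tol)
        return y[0], bool(conv[0])
    if method == "rk45":
        from scipy.integrate import solve_ivp

        lam_plus = np.where(topo.sign > 0, stacked["lam"], 1.0)
        scale = topo.group_product(lam_plus)

        def rhs(_t, yv):
            return _derivative(yv.reshape(1, -1), topo, stacked, scale)[0]

        sol = solve_ivp(rhs, (0.0, t_max), y0[0], method="RK45", rtol=1e-8, atol=1e-10)
        y = sol.y[:, -1]
        dy = rhs(0.0, y)
        conv = bool(np.max(np.abs(dy) / np.maximum(y, _EPS)) < tol)
        return y, conv
    raise ValueError(f"unknown method {method!r}")


def simulate_ensemble(
    net: GeneNetwork,
    ranges: SamplingRanges = SamplingRanges(),
    n_models: int = 10_000,
    seed: int = 0,
    dt: float = DT,
    t_max: float = T_MAX,
    tol: float = CONV_TOL,
) -> RacipeEnsemble:
    """Simulate an ensemble of random models of one topology.

    One random initial condition per model; non-converged models are retried
    once from a fresh initial condition, then flagged.  All randomness comes
    from one generator stream seeded by ``seed``, so the ensemble matrix is
    bitwise reproducible.
    """
    topo = _Topology(net)
    m_thr = ranges.median_threshold
    if m_thr is None:
        m_thr = estimate_median_threshold(ranges, seed=seed)
    rng = np.random.default_rng(seed)
    stacked = _sample_stacked(topo, ranges, n_models, rng, m_thr)
    ymin, ymax = _init_bounds(topo, stacked)
    inits = _draw_inits(ymin, ymax, rng)
    y, converged = _integrate(inits.copy(), topo, stacked, dt=dt, t_max=t_max, tol=tol)
    if not converged.all():
        bad = np.flatnonzero(~converged)
        retry_inits = _draw_inits(ymin[bad], ymax[bad], rng)
        sub = {key: val[bad] for key, val in stacked.items()}
        y2, conv2 = _integrate(retry_inits.copy(), topo, sub, dt=dt, t_max=t_max, tol=tol)
        y[bad[conv2]] = y2[conv2]
        inits[bad[conv2]] = retry_inits[conv2]
        converged[bad[conv2]] = True
    rate = float(converged.mean())
    if rate < 1.0:
        log.info("convergence rate %.4f (%d/%d models)", rate, converged.sum(), n_models)
    params = _unstack_params(topo, stacked)
    out = RacipeEnsemble(
        network=net,
        params=params,
        states=y,
        converged=converged,
        seed=seed,
        inits=inits,
    )
    out._stacked = stacked  # reused by knockdown re-simulation
    return out


def _unstack_params(topo: _Topology, stacked: dict[str, np.ndarray]) -> list[RacipeParams]:
    inv = np.empty_like(topo.order)
    inv[topo.order] = np.arange(topo.n_edges)
    n_o = stacked["n"][:, inv].astype(int)
    lam_o = stacked["lam"][:, inv]
    x0_o = stacked["x0"][:, inv]
    return [
        RacipeParams(g=stacked["g"][i], k=stacked["k"][i], n=n_o[i], lam=lam_o[i], x0=x0_o[i])
        for i in range(stacked["g"].shape[0])
    ]


def simulate_knockdown(
    net: GeneNetwork,
    ensemble: RacipeEnsemble,
    genes: Iterable[str],
    kd_factor: float = 0.95,
    dt: float = DT,
    t_max: float = T_MAX,
    tol: float = CONV_TOL,
) -> RacipeEnsemble:
    """Re-simulate every model with the knocked-down genes' production reduced.

    The production rate G of each gene in ``genes`` (1 or 2 of them) is
    multiplied by (1 - kd_factor); all other parameters and each model's
    initial condition are reused, preserving the 1:1 pairing with the
    unperturbed ensemble.  The returned ensemble carries the unperturbed
    log2 mean/sd as its normalization reference.
    """
    genes = list(genes)
    if not 1 <= len(genes) <= 2:
        raise ValueError("knockdown sets have size 1 or 2")
    gi = {g: i for i, g in enumerate(net.nodes)}
    missing = [g for g in genes if g not in gi]
    if missing:
        raise KeyError(f"unknown knockdown gene(s): {missing}")
    if not 0.0 <= kd_factor <= 1.0:
        raise ValueError("kd_factor must be in [0,1]")
    topo = _Topology(net)
    base = getattr(ensemble, "_stacked", None)
    stacked = dict(base) if base is not None else _stack_params(topo, ensemble.params)
    stacked["g"] = stacked["g"].copy()
    for g in genes:
        stacked["g"][:, gi[g]] *= 1.0 - kd_factor
    if ensemble.inits is None:
        raise ValueError("ensemble does not carry initial conditions")
    y, converged = _integrate(
        ensemble.inits.copy(), topo, stacked, dt=dt, t_max=t_max, tol=tol
    )
    ref = getattr(ensemble, "_log2_ref", None)
    if ref is None:
        ref = ensemble.log2_norm_reference()
        ensemble._log2_ref = ref
    out = RacipeEnsemble(
        network=net,
        params=_unstack_params(topo, stacked),
        states=y,
        converged=converged,
        seed=ensemble.seed,
        norm_reference=ref,
        inits=ensemble.inits,
    )
    out._stacked = stacked
    return out


def check_steady_states(ensemble: RacipeEnsemble, tol: float = CONV_TOL) -> np.ndarray:
    """Direct re-evaluation of the ODE right-hand side at the reported states.

    Returns the per-model maximum relative derivative, independent of the
    integrator; converged models should satisfy values < tol.
    """
    topo = _Topology(ensemble.network)
    stacked = _stack_params(topo, ensemble.params)
    lam_plus = np.where(topo.sign > 0, stacked["lam"], 1.0)
    scale = topo.group_product(lam_plus)
    dy = _derivative(ensemble.states, topo, stacked, scale)
    return np.max(np.abs(dy) / np.maximum(ensemble.states, _EPS), axis=1)
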