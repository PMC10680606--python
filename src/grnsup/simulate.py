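"""Steady-state expression simulation on layered regulatory networks.

Each non-MR node obeys ``dx_i/dt = P_i(x) - lambda * x_i`` where the
production rate ``P_i`` sums Hill-function contributions ``|K| * f(x_reg)``
over incoming edges (activating ``f = x^n / (x^n + h^n)``, repressive its
one-complement).  Master regulators have a constant per-condition production
rate.  The half-response ``h`` of a regulator is its noise-free steady-state
level averaged over conditions, computed exactly layer by layer (the network
is a 3-layer DAG).  Stochastic simulation adds a single-step Langevin term
with amplitude ``q * sqrt(P + lambda*x) * sqrt(dt)`` and clips negative
excursions to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConsistencyError, ConvergenceError, ParameterError
from .network import ExpressionMatrix, MRProfileSet, RegulatoryNetwork


@dataclass
class SimulationParams:
    """Dynamics and integration settings.

    decay
        Shared first-order decay rate lambda (> 0) of every transcript.
    noise_amplitude
        Scale q of the multiplicative Langevin noise; 0 gives the
        deterministic fixed point.
    dt, n_steps
        Euler step and nominal number of steps to reach steady state.
    n_conditions_sim
        Number of conditions ("cell types", one cell each) simulated before
        any subsampling.
    tol
        Fixed-point residual tolerance enforced in deterministic mode.
    """

    decay: float = 0.8
    noise_amplitude: float = 1.0
    dt: float = 0.01
    n_steps: int = 2000
    n_conditions_sim: int = 100
    tol: float = 1e-8

    def validate(self) -> None:
        if self.decay <= 0 or self.dt <= 0 or self.n_steps < 1 or self.noise_amplitude < 0:
            raise ParameterError("require decay>0, dt>0, n_steps>=1, noise_amplitude>=0")


def hill_regulation(x, h, n, repressive=False):
    """Hill response in [0, 1] of a regulator at level ``x``.

    Activating: ``x^n / (x^n + h^n)``; repressive: one minus that.  Vectorized
    over ``x``.
    """
    if np.any(np.asarray(h) <= 0):
        raise ParameterError("half-response h must be > 0")
    xn = np.power(x, n)
    act = xn / (xn + np.power(h, n))
    return 1.0 - act if repressive else act


def production_rate(
    target: int,
    levels: dict[int, float],
    net: RegulatoryNetwork,
    h: dict[int, float],
) -> float:
    """Production rate of a TF or gene given its regulators' current levels.

    Sums ``|K| * hill_regulation(x_reg, h_reg, n, repressive=K<0)`` over
    incoming edges.  (MRs use their per-condition basal rate instead; asking
    for an MR's regulated rate is a consistency error.)
    """
    if net.layer_of(target) == "MR":
        raise ConsistencyError("MRs have basal, not regulated, production")
    if not net.parameterized:
        raise ConsistencyError("network edges lack K / Hill assignments")
    total = 0.0
    for (reg, tgt), K, n in zip(net.edges, net.K, net.hill):
        if tgt != target:
            continue
        if reg not in levels:
            raise ConsistencyError(f"missing level for regulator node {reg}")
        if reg not in h:
            raise ConsistencyError(f"missing half-response for regulator node {reg}")
        total += abs(K) * hill_regulation(levels[reg], h[reg], n, repressive=K < 0)
    return total


# --------------------------------------------------------------------- internals
def _edge_arrays(net: RegulatoryNetwork):
    if not net.parameterized:
        raise ConsistencyError("network edges lack K / Hill assignments")
    reg = net.edges[:, 0]
    tgt = net.edges[:, 1]
    return reg, tgt, np.abs(net.K), (net.K < 0), net.hill.astype(float)


def _incidence(tgt, absk, n_nodes):
    """Sparse (n_nodes, n_edges) map from per-edge responses to node production."""
    from scipy import sparse

    E = len(tgt)
    return sparse.csr_matrix((absk, (tgt, np.arange(E))), shape=(n_nodes, E))


def _edge_responses(x, reg, is_rep, hill, hn):
    """Per-edge Hill responses in [0, 1]; shape (n_edges, m)."""
    xn = np.power(x[reg, :], hill[:, None])
    f = xn / (xn + hn)
    f[is_rep, :] = 1.0 - f[is_rep, :]
    return f


def steady_state_layered(
    net: RegulatoryNetwork,
    profiles: MRProfileSet,
    sim: SimulationParams | None = None,
    h: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact noise-free steady state, evaluated layer by layer.

    Returns ``(x, h)`` where ``x`` is ``(n_nodes, m)`` and ``h`` the
    per-node half-response (mean steady level over conditions).  Because the
    network is a 3-layer DAG the fixed point factorizes: MR levels are
    ``rate/decay`` in closed form, TF levels follow from MR levels, gene
    levels from TF levels.  Passing ``h`` freezes the half-responses instead
    of deriving them from mean levels.
    """
    sim = sim or SimulationParams()
    sim.validate()
    if profiles.n_mr != net.n_mr:
        raise ConsistencyError("profile width does not match n_mr")
    lam = sim.decay
    m = profiles.m
    reg, tgt, absk, is_rep, hill = _edge_arrays(net)
    x = np.zeros((net.n_nodes, m))
    x[: net.n_mr, :] = profiles.rates.T / lam

    h_out = np.zeros(net.n_nodes)
    h_out[: net.n_mr] = x[: net.n_mr, :].mean(axis=1)
    if h is not None:
        h_out = np.asarray(h, dtype=float).copy()

    for lo, hi in ((net.tf_slice.start, net.tf_slice.stop), (net.gene_slice.start, net.gene_slice.stop)):
        mask = (tgt >= lo) & (tgt < hi)
        # floor: a regulator whose steady level is identically 0 contributes 0
        h_edge = np.maximum(h_out[reg[mask]], 1e-12)
        hn = np.power(h_edge[:, None], hill[mask][:, None])
        f = _edge_responses(x, reg[mask], is_rep[mask], hill[mask], hn)
        P = _incidence(tgt[mask], absk[mask], net.n_nodes) @ f
        x[lo:hi, :] = P[lo:hi, :] / lam
        if h is None:
            h_out[lo:hi] = x[lo:hi, :].mean(axis=1)
    return x, h_out


def simulate(
    net: RegulatoryNetwork,
    profiles: MRProfileSet,
    sim: SimulationParams | None = None,
    seed: int = 0,
) -> ExpressionMatrix:
    """Simulate one steady-state cell per condition by Euler(-Maruyama) integration.

    Deterministic mode (``noise_amplitude == 0``) integrates until the
    fixed-point residual ``max |P_i - lambda*x_i|`` over non-MR nodes falls
    below ``sim.tol`` (continuing past ``n_steps`` if needed, up to tenfold)
    and raises :class:`ConvergenceError` naming the worst node otherwise.
    Stochastic mode runs exactly ``n_steps`` steps.
    """
    sim = sim or SimulationParams()
    sim.validate()
    if profiles.n_mr != net.n_mr:
        raise ConsistencyError("profile width does not match n_mr")
    rng = np.random.default_rng(seed)
    lam, dt, q = sim.decay, sim.dt, sim.noise_amplitude
    m = profiles.m
    reg, tgt, absk, is_rep, hill = _edge_arrays(net)

    # half-responses from the exact noise-free solution
    _, h = steady_state_layered(net, profiles, sim)
    h_edge = np.maximum(h[reg], 1e-12)

    basal = np.zeros((net.n_nodes, m))
    basal[: net.n_mr, :] = profiles.rates.T
    non_mr = np.zeros(net.n_nodes, dtype=bool)
    non_mr[net.n_mr:] = True

    x = np.zeros((net.n_nodes, m))
    sqdt = np.sqrt(dt)
    hn = np.power(h_edge[:, None], hill[:, None])
    W = _incidence(tgt, absk, net.n_nodes)
    max_steps = sim.n_steps if q > 0 else 10 * sim.n_steps
    for step in range(max_steps):
        P = W @ _edge_responses(x, reg, is_rep, hill, hn) + basal
        drift = P - lam * x
        if q > 0:
            x = x + drift * dt + q * np.sqrt(P + lam * x) * sqdt * rng.standard_normal(x.shape)
        else:
            x = x + drift * dt
            if step >= sim.n_steps - 1:
                resid = np.abs(drift[non_mr, :])
                if resid.max() <= sim.tol:
                    break
        np.maximum(x, 0.0, out=x)
    else:
        if q == 0:
            P = W @ _edge_responses(x, reg, is_rep, hill, hn) + basal
            resid = np.abs((P - lam * x)[non_mr, :])
            if resid.max() > sim.tol:
                worst_flat = int(np.argmax(resid.max(axis=1)))
                worst = net.node_ids[np.flatnonzero(non_mr)[worst_flat]]
                raise ConvergenceError(
                    f"no fixed point after {max_steps} steps; worst node {worst} "
                    f"residual {resid.max():.3g}",
                    worst_node=worst,
                    residual=float(resid.max()),
                )

    return ExpressionMatrix(
        values=x, row_ids=net.node_ids, layers=net.layers,
        condition_ids=[f"c{j}" for j in range(m)],
    )


def subsample_conditions(expr: ExpressionMatrix, m: int, seed: int = 0) -> ExpressionMatrix:
    """Keep ``m`` distinct conditions chosen uniformly without replacement."""
    if m > expr.m:
        raise ParameterError("m exceeds the number of available conditions")
    rng = np.random.default_rng(seed)
    cols = np.sort(rng.choice(expr.m, size=m, replace=False))
    return ExpressionMatrix(
        expr.values[:, cols],
        list(expr.row_ids),
        list(expr.layers),
        [expr.condition_ids[c] for c in cols],
    )


def apply_dropout(expr: ExpressionMatrix, fraction: float, seed: int = 0) -> ExpressionMatrix:
    """Zero exactly ``round(fraction * n_entries)`` entries, chosen uniformly."""
    if not 0.0 <= fraction <= 1.0:
        raise ParameterError("dropout fraction must lie in [0, 1]")
    out = expr.copy()
    n = out.values.size
    k = int(round(fraction * n))
    if k:
        rng = np.random.default_rng(seed)
        flat = rng.choice(n, size=k, replace=False)
        out.values.flat[flat] = 0.0
    return out
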