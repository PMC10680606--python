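"""Random benchmark generation: layered topologies, interaction parameters, MR profiles.

The sampling scheme mirrors the benchmark design used throughout the package:
every TF receives exactly ``d_mr_tf`` master regulators; every target gene
receives an in-degree drawn uniformly from ``d_tf_g_range`` and that many
distinct TF parents chosen uniformly without replacement.  Interaction
strengths are uniform on [1, 5] in magnitude, repressive with probability
0.2, with Hill coefficient 2 (90%) or 1 (10%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .network import ExpressionMatrix, MRProfileSet, RegulatoryNetwork

#: magnitude range for interaction strengths
K_RANGE = (1.0, 5.0)
#: probability that an interaction is repressive (K negated)
REPRESSOR_PROB = 0.2
#: probability that the Hill coefficient is 2 (else 1)
HILL2_PROB = 0.9

#: default low/high MR production-rate ranges; clearly separated regimes
DEFAULT_LOW_RANGE = (0.2, 0.8)
DEFAULT_HIGH_RANGE = (2.0, 4.0)


def derive_seed(master_seed: int, index: int) -> int:
    """Counter-based child-seed derivation, reproducible per index.

    GRN ``k`` of a benchmark can be regenerated in isolation without drawing
    the streams of GRNs ``0..k-1``.
    """
    return int(
        np.random.SeedSequence(master_seed, spawn_key=(index,)).generate_state(1)[0] % (2**31)
    )


@dataclass
class TopologyParams:
    """Size and connectivity parameters of one 3-layer benchmark network."""

    n_mr: int = 5
    n_tf: int = 100
    n_g: int = 100
    d_mr_tf: int = 3
    d_tf_g_range: tuple[int, int] = (3, 7)
    n_grn: int = 1

    def validate(self) -> None:
        lo, hi = self.d_tf_g_range
        if min(self.n_mr, self.n_tf, self.n_g, self.d_mr_tf, self.n_grn, lo) < 1:
            raise ParameterError("all counts and degree bounds must be >= 1")
        if lo > hi:
            raise ParameterError("d_tf_g_range must be a nondecreasing pair")
        if self.d_mr_tf > self.n_mr:
            raise ParameterError("d_mr_tf exceeds the number of MRs")
        if hi > self.n_tf:
            raise ParameterError("upper bound of d_tf_g_range exceeds n_tf")


def sample_topology(params: TopologyParams, seed: int) -> RegulatoryNetwork:
    """Sample a random layered topology (edges without K / Hill assignments)."""
    params.validate()
    rng = np.random.default_rng(seed)
    tf0 = params.n_mr
    g0 = params.n_mr + params.n_tf
    edges = []
    for t in range(params.n_tf):
        for r in rng.choice(params.n_mr, size=params.d_mr_tf, replace=False):
            edges.append((int(r), tf0 + t))
    lo, hi = params.d_tf_g_range
    for g in range(params.n_g):
        k = int(rng.integers(lo, hi + 1))
        for r in rng.choice(params.n_tf, size=k, replace=False):
            edges.append((tf0 + int(r), g0 + g))
    net = RegulatoryNetwork(
        params.n_mr, params.n_tf, params.n_g, np.asarray(edges, dtype=np.int64)
    )
    net.validate()
    return net


def sample_interactions(net: RegulatoryNetwork, seed: int) -> RegulatoryNetwork:
    """Assign signed strengths and Hill coefficients to every edge.

    |K| ~ Uniform[1, 5]; sign negative with probability 0.2; Hill coefficient
    2 with probability 0.9 else 1; all draws independent across edges.
    """
    rng = np.random.default_rng(seed)
    n = net.n_edges
    K = rng.uniform(*K_RANGE, size=n)
    K[rng.random(n) < REPRESSOR_PROB] *= -1.0
    hill = np.where(rng.random(n) < HILL2_PROB, 2, 1).astype(np.int64)
    out = RegulatoryNetwork(net.n_mr, net.n_tf, net.n_g, net.edges, K=K, hill=hill)
    out.validate()
    return out


def sample_mr_profiles(
    net: RegulatoryNetwork,
    m: int,
    low_range: tuple[float, float] = DEFAULT_LOW_RANGE,
    high_range: tuple[float, float] = DEFAULT_HIGH_RANGE,
    seed: int = 0,
) -> MRProfileSet:
    """Draw per-condition MR production rates from a low/high mixture.

    For each (condition, MR) cell the low or high range is chosen with equal
    probability, then the rate is uniform within the chosen range.
    """
    lo1, lo2 = low_range
    hi1, hi2 = high_range
    if lo1 <= 0 or lo1 > lo2 or hi1 > hi2:
        raise ParameterError("ranges must be positive nondecreasing intervals")
    if lo2 > hi1:  # interior overlap; touching (or degenerate) ranges are allowed
        raise ParameterError("low range must not overlap the high range")
    if m < 1:
        raise ParameterError("need at least one condition")
    rng = np.random.default_rng(seed)
    pick_high = rng.random((m, net.n_mr)) < 0.5
    u = rng.random((m, net.n_mr))
    rates = np.where(pick_high, hi1 + u * (hi2 - hi1), lo1 + u * (lo2 - lo1))
    return MRProfileSet(rates=rates, low=low_range, high=high_range)


def generate_benchmark(
    params: TopologyParams | Sequence[TopologyParams],
    m: int,
    sim: "SimulationParams | None" = None,
    seed: int = 0,
    low_range: tuple[float, float] = DEFAULT_LOW_RANGE,
    high_range: tuple[float, float] = DEFAULT_HIGH_RANGE,
    dropout_fraction: float = 0.0,
) -> list[tuple[RegulatoryNetwork, ExpressionMatrix]]:
    """Generate ``n_grn`` independent (network, expression-matrix) pairs.

    Each GRN is sampled, parameterized, simulated at the simulator's native
    number of conditions, and then subsampled to ``m`` columns.  Optional
    dropout corruption is applied after subsampling.  Heterogeneous benchmarks
    are supported by passing a sequence of :class:`TopologyParams`, cycled
    across GRNs; ``n_grn`` is then the total across the cycle of the first
    entry.
    """
    from .simulate import SimulationParams, apply_dropout, simulate, subsample_conditions

    if sim is None:
        sim = SimulationParams()
    plist = [params] if isinstance(params, TopologyParams) else list(params)
    for p in plist:
        p.validate()
    n_grn = plist[0].n_grn
    if m > sim.n_conditions_sim:
        raise ParameterError("m exceeds the number of simulated conditions")
    out = []
    for k in range(n_grn):
        p = plist[k % len(plist)]
        s = derive_seed(seed, k)
        net = sample_topology(replace(p, n_grn=1), derive_seed(s, 0))
        net = sample_interactions(net, derive_seed(s, 1))
        profiles = sample_mr_profiles(
            net, sim.n_conditions_sim, low_range, high_range, seed=derive_seed(s, 2)
        )
        expr = simulate(net, profiles, sim, seed=derive_seed(s, 3))
        if m < sim.n_conditions_sim:
            expr = subsample_conditions(expr, m, seed=derive_seed(s, 4))
        if dropout_fraction > 0:
            expr = apply_dropout(expr, dropout_fraction, seed=derive_seed(s, 5))
        out.append((net, expr))
    return out
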