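"""Self-contained evaluation experiments for the mining method.

Each function runs one study end-to-end from a seed — small-instance
comparison against an exhaustive oracle, planted-pattern recovery under
the reference benchmark, feasibility/ascent verification of the optimizer,
and the detection-rate heaviness sweep — and returns plain numbers.  They
are used by the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from .benchmark import PlantedSpec, default_benchmark, detection_rate, score_recovery
from .miner import (
    MiningConfig,
    mine_all,
    mine_fixed_size,
    norm_f,
    norm_g,
    optimize_memberships,
    pattern_heaviness,
    update_network_memberships,
)
from .network import NetworkTensor

__all__ = [
    "random_uniform_tensor",
    "exhaustive_best_heaviness",
    "oracle_equivalence_rate",
    "planted_recovery_rate",
    "optimizer_diagnostics",
    "detection_rate_by_heaviness",
]


def random_uniform_tensor(n: int, m: int, seed: int) -> NetworkTensor:
    """i.i.d. symmetric U(0, 1) weights with zero diagonal."""
    rng = np.random.default_rng(seed)
    weights = np.empty((m, n, n))
    for k in range(m):
        upper = np.triu(rng.uniform(0.0, 1.0, size=(n, n)), 1)
        weights[k] = upper + upper.T
    return NetworkTensor(
        [f"e{i:03d}" for i in range(n)], [f"n{k:02d}" for k in range(m)], weights
    )


def exhaustive_best_heaviness(
    tensor: NetworkTensor, n_exons: int, n_networks: int
) -> float:
    """Brute force over every exon subset of the given size and every
    network subset: the discrete optimum the relaxation approximates."""
    best = 0.0
    for exons in itertools.combinations(tensor.node_ids, n_exons):
        for nets in itertools.combinations(tensor.network_ids, n_networks):
            best = max(best, pattern_heaviness(tensor, exons, nets))
    return best


def oracle_equivalence_rate(
    n_trials: int = 50,
    n: int = 8,
    m: int = 3,
    n_exons: int = 4,
    n_networks: int = 2,
    ratio: float = 0.95,
    seed: int = 0,
) -> tuple[int, int]:
    """(successes, trials): how often the miner's fixed-size pattern reaches
    the given fraction of the exhaustive-search optimum on random tensors."""
    successes = 0
    for trial in range(n_trials):
        t = random_uniform_tensor(n, m, seed + trial)
        oracle = exhaustive_best_heaviness(t, n_exons, n_networks)
        cfg = MiningConfig(
            seed=seed + trial, min_exons=n_exons, min_networks=n_networks
        )
        mined = mine_fixed_size(t, cfg, n_exons, n_networks)
        if mined.heaviness >= ratio * oracle:
            successes += 1
    return successes, n_trials


def planted_recovery_rate(
    n_seeds: int = 20,
    seed: int = 0,
    exon_cut: float = 0.9,
    net_cut: float = 0.8,
) -> tuple[int, int]:
    """(recovered, seeds): how often the first mined cluster matches the
    planted pattern of the reference benchmark at the Jaccard cutoffs."""
    hits = 0
    for r in range(n_seeds):
        bench = default_benchmark(seed + r)
        cfg = MiningConfig(seed=seed + r, max_patterns=2)
        clusters = mine_all(bench.tensor, cfg)
        report = score_recovery(clusters[:1], bench, exon_cut=exon_cut, net_cut=net_cut)
        hits += int(all(report.detected))
    return hits, n_seeds


@dataclass
class OptimizerDiagnostics:
    max_f_violation: float
    max_g_violation: float
    max_trace_decrease: float
    max_y_suboptimality: float


def optimizer_diagnostics(
    n_tensors: int = 10,
    n_y_instances: int = 100,
    seed: int = 0,
) -> OptimizerDiagnostics:
    """Feasibility, ascent, and network-update-optimality measurements.

    Runs the optimizer on random tensors recording constraint violations
    and the worst per-step objective decrease, and compares the
    closed-form network update against numeric constrained maximization
    (SLSQP) on random score vectors.
    """
    from scipy.optimize import minimize

    cfg = MiningConfig(seed=seed)
    max_f = max_g = max_dec = 0.0
    for r in range(n_tensors):
        t = random_uniform_tensor(12, 4, seed + 77 * r)
        sol = optimize_memberships(t, replace(cfg, seed=seed + r))
        max_f = max(max_f, abs(norm_f(sol.x, cfg.p, cfg.alpha) - 1.0))
        max_g = max(max_g, abs(norm_g(sol.y, cfg.q) - 1.0))
        trace = np.array(sol.objective_trace)
        if trace.size > 1:
            max_dec = max(max_dec, float(np.max(-np.diff(trace), initial=0.0)))

    rng = np.random.default_rng(seed)
    max_subopt = 0.0
    for _ in range(n_y_instances):
        m = int(rng.integers(2, 7))
        t = random_uniform_tensor(6, m, int(rng.integers(0, 2**31 - 1)))
        x = rng.uniform(0.0, 1.0, size=6)
        x = x / norm_f(x, cfg.p, cfg.alpha)
        y = update_network_memberships(t, x, cfg.q)
        scores = 0.5 * np.einsum("kij,i,j->k", t.weights, x, x)
        res = minimize(
            lambda v: -float(scores @ v),
            np.full(m, (1.0 / m) ** (1.0 / cfg.q)),
            method="SLSQP",
            bounds=[(0.0, 1.0)] * m,
            constraints={"type": "eq", "fun": lambda v: float(np.sum(v**cfg.q) - 1.0)},
            options={"maxiter": 500, "ftol": 1e-14},
        )
        y_num = np.maximum(res.x, 0.0)
        y_num = y_num / norm_g(y_num, cfg.q)
        max_subopt = max(max_subopt, float(scores @ y_num - scores @ y))
        max_g = max(max_g, abs(norm_g(y, cfg.q) - 1.0))
    return OptimizerDiagnostics(
        max_f_violation=max_f,
        max_g_violation=max_g,
        max_trace_decrease=max_dec,
        max_y_suboptimality=max_subopt,
    )


def detection_rate_by_heaviness(
    levels: tuple[float, ...] = (0.3, 0.5, 0.7),
    n_seeds: int = 10,
    n: int = 120,
    m: int = 12,
    size: int = 8,
    recurrence: int = 5,
    noise_sd: float = 0.02,
    background_mean: float = 0.1,
    seed: int = 0,
) -> dict[float, float]:
    """Planted-pattern detection rate at each target heaviness level,
    everything else held fixed."""
    return {
        level: detection_rate(
            PlantedSpec(size, recurrence, level, noise_sd),
            n=n,
            m=m,
            background_mean=background_mean,
            seeds=range(seed, seed + n_seeds),
        )
        for level in levels
    }
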