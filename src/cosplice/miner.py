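"""Frequent heavy-subgraph mining across many weighted networks.

A frequent co-splicing cluster (FSC) is a set of exons that forms a heavy
subgraph simultaneously in several networks of a collection.  With the
collection stacked into a tensor ``a[i, j, k]``, an FSC is scored by the
summed weight it captures,

    H_A(x, y) = 1/2 * sum_ijk a_ijk x_i x_j y_k,

where x >= 0 ranks exons and y >= 0 ranks networks.  The discrete problem
(binary x, y of fixed sizes) is NP-hard, so we maximize H_A over the
continuous feasible set f(x) = 1, g(y) = 1 with the mixed norms

    f(x) = alpha * ||x||_p + (1 - alpha) * ||x||_2   (0 < p < 1)
    g(y) = ||y||_q                                    (q > 1).

The L_p term with p < 1 drives exon memberships sparse while the L_2 term
keeps the surviving components smooth; the L_q norm with large q pushes
network memberships toward equal magnitudes so a cluster is credited for
appearing in many networks.  Because f is non-convex, the solver uses
multi-stage convex relaxation: the concave reparameterization of f through
h(x) = x^2 is linearized at the current iterate, giving a weighted
quadratic surrogate constraint sum_i v_i x_i^2; each stage solves the
resulting subproblem by reweighted power iteration alternated with an
exact closed-form network update, then refreshes the weights v so the
surrogate hugs f more tightly around the new iterate.

After optimization, exons and networks are ranked by membership and up to
two representative patterns meeting a heaviness threshold are read off the
ranked prefixes; their edges are masked (zeroed) and the optimization
repeats to find the next cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .network import NetworkTensor

__all__ = [
    "MiningConfig",
    "MembershipSolution",
    "RelaxationState",
    "FrequentCoSplicingCluster",
    "DegenerateSliceError",
    "objective_heaviness",
    "norm_f",
    "norm_g",
    "update_network_memberships",
    "update_exon_memberships",
    "refresh_relaxation_weights",
    "optimize_memberships",
    "pattern_heaviness",
    "extract_representative_patterns",
    "mine_fixed_size",
    "mask_pattern",
    "mine_all",
]

logger = logging.getLogger(__name__)


class DegenerateSliceError(RuntimeError):
    """The exon-membership gradient vanished (no weight left to follow)."""


@dataclass(frozen=True)
class MiningConfig:
    """Parameters of the mining run.

    p, alpha, q parameterize the norm constraints (defaults are the
    combination selected on planted-cluster simulations); the heaviness
    threshold and minimum exon/network counts define which ranked-prefix
    patterns are reported as clusters.
    """

    p: float = 0.8
    alpha: float = 0.2
    q: float = 10.0
    heaviness_threshold: float = 0.4
    min_exons: int = 5
    min_networks: int = 3
    max_patterns: int = 100
    max_stages: int = 20
    max_inner_iters: int = 500
    tol: float = 1e-7
    epsilon_smooth: float = 1e-10
    seed: int = 0
    restarts: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError("p must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.q <= 1:
            raise ValueError("q must exceed 1")
        if not 0 < self.heaviness_threshold <= 1:
            raise ValueError("heaviness_threshold must lie in (0, 1]")
        if self.min_exons < 2:
            raise ValueError("min_exons must be >= 2")
        if self.min_networks < 1:
            raise ValueError("min_networks must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class MembershipSolution:
    """Feasible point of the relaxed problem: exon vector x with f(x)=1,
    network vector y with g(y)=1, and the attained objective H_A(x, y)."""

    x: np.ndarray
    y: np.ndarray
    objective: float
    no_signal: bool = False
    objective_trace: list[float] = field(default_factory=list)
    stages: int = 0


@dataclass
class RelaxationState:
    """Coefficients of the current convex surrogate constraint.

    ``v`` is the gradient of the concave reparameterization of f at the
    current iterate (in u = x^2 coordinates); the surrogate constraint is
    sum_i v_i x_i^2 = const.  The additive dual constant does not affect
    the argmax and is not stored.
    """

    v: np.ndarray
    stage: int = 0
    objective_trace: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class FrequentCoSplicingCluster:
    """An exon set forming a heavy subgraph in a set of networks."""

    exon_ids: frozenset[str]
    network_ids: frozenset[str]
    heaviness: float
    objective: float = 0.0

    @property
    def recurrence(self) -> int:
        return len(self.network_ids)

    def key(self) -> tuple[frozenset[str], frozenset[str]]:
        return (self.exon_ids, self.network_ids)


# ---------------------------------------------------------------------------
# Objective and norms


def _check_nonnegative(vec: np.ndarray, name: str) -> np.ndarray:
    vec = np.asarray(vec, dtype=float)
    if vec.size and vec.min() < 0:
        raise ValueError(f"{name} must be componentwise nonnegative")
    return vec


def objective_heaviness(tensor: NetworkTensor, x: np.ndarray, y: np.ndarray) -> float:
    """H_A(x, y) = 1/2 sum_ijk a_ijk x_i x_j y_k."""
    x = _check_nonnegative(x, "x")
    y = _check_nonnegative(y, "y")
    if x.shape != (tensor.n_nodes,) or y.shape != (tensor.n_networks,):
        raise ValueError(
            f"membership dimensions {x.shape}/{y.shape} do not match tensor "
            f"({tensor.n_nodes} nodes, {tensor.n_networks} networks)"
        )
    W = np.tensordot(y, tensor.weights, axes=(0, 0))
    return 0.5 * float(x @ W @ x)


def norm_f(x: np.ndarray, p: float, alpha: float) -> float:
    """Mixed exon norm alpha*||x||_p + (1-alpha)*||x||_2 (sparse-but-smooth)."""
    x = _check_nonnegative(x, "x")
    lp = float(np.sum(x**p)) ** (1.0 / p)
    l2 = float(np.sqrt(np.sum(x**2)))
    return alpha * lp + (1 - alpha) * l2


def norm_g(y: np.ndarray, q: float) -> float:
    """Network norm ||y||_q; large q rewards many near-equal components."""
    y = _check_nonnegative(y, "y")
    m = float(y.max(initial=0.0))
    if m == 0:
        return 0.0
    return m * float(np.sum((y / m) ** q)) ** (1.0 / q)


# ---------------------------------------------------------------------------
# Block updates


def _network_scores(weights: np.ndarray, x: np.ndarray) -> np.ndarray:
    """w_k = 1/2 x' A_k x for each slice k."""
    return 0.5 * np.einsum("kij,i,j->k", weights, x, x, optimize=True)


def _y_from_scores(w: np.ndarray, q: float) -> np.ndarray:
    """Exact maximizer of sum_k w_k y_k over {y >= 0, ||y||_q = 1}.

    By Hoelder's inequality the optimum is y_k proportional to
    w_k^(1/(q-1)); an all-zero score vector returns the uniform feasible
    point.
    """
    w = np.maximum(w, 0.0)
    if not w.any():
        y = np.ones_like(w)
    else:
        scale = w.max()
        y = (w / scale) ** (1.0 / (q - 1.0))
    return y / norm_g(y, q)


def update_network_memberships(
    tensor: NetworkTensor, x: np.ndarray, q: float
) -> np.ndarray:
    """Closed-form network-membership update given exon memberships."""
    x = _check_nonnegative(x, "x")
    if x.shape != (tensor.n_nodes,):
        raise ValueError("x dimension does not match tensor")
    return _y_from_scores(_network_scores(tensor.weights, x), q)


def refresh_relaxation_weights(
    x: np.ndarray, p: float, alpha: float, epsilon_smooth: float = 1e-10
) -> np.ndarray:
    """Surrogate weights v for the next convex stage.

    v is the gradient at u = x^2 of the concave function
    fbar(u) = alpha*(sum (u_i+eps)^(p/2))^(1/p) + (1-alpha)*(sum u_i + eps)^(1/2),
    the reparameterization of f through h(x) = x^2; the smoothing eps keeps
    every v_i finite at zero components.
    """
    x = _check_nonnegative(x, "x")
    eps = epsilon_smooth
    u = x**2
    sp = np.sum((u + eps) ** (p / 2.0))
    v_lp = alpha * 0.5 * sp ** ((1.0 - p) / p) * (u + eps) ** ((p - 2.0) / 2.0)
    v_l2 = (1 - alpha) * 0.5 * (np.sum(u) + eps) ** -0.5
    return v_lp + v_l2


def _x_power_step(
    W: np.ndarray, x: np.ndarray, v: np.ndarray, p: float, alpha: float
) -> np.ndarray:
    """One reweighted power step under the surrogate constraint, then
    rescaled back onto f(x) = 1 (f is positively homogeneous)."""
    x_new = np.maximum(W @ x, 0.0) / v
    nrm = norm_f(x_new, p, alpha)
    if nrm == 0:
        raise DegenerateSliceError("exon-membership gradient vanished")
    return x_new / nrm


def update_exon_memberships(
    tensor: NetworkTensor,
    x: np.ndarray,
    y: np.ndarray,
    state: RelaxationState,
    cfg: MiningConfig,
) -> np.ndarray:
    """One reweighted power step for the current convex stage.

    With W = sum_k a_ijk y_k, the step is x' = max(0, W x) / v followed by
    rescaling so that f(x') = 1.
    """
    x = _check_nonnegative(x, "x")
    y = _check_nonnegative(y, "y")
    W = np.tensordot(y, tensor.weights, axes=(0, 0))
    return _x_power_step(W, x, state.v, cfg.p, cfg.alpha)


# ---------------------------------------------------------------------------
# Multi-stage optimization


def _feasible_uniform(n: int, p: float, alpha: float) -> np.ndarray:
    x = np.ones(n)
    return x / norm_f(x, p, alpha)


def _optimize_from(
    weights: np.ndarray, cfg: MiningConfig, x0: np.ndarray
) -> MembershipSolution:
    """Run the multi-stage relaxation from one starting point."""
    p, alpha, q = cfg.p, cfg.alpha, cfg.q
    x = x0 / norm_f(x0, p, alpha)
    w = _network_scores(weights, x)
    y = _y_from_scores(w, q)
    obj = float(w @ y)
    trace = [obj]
    stage = 0
    for stage in range(1, cfg.max_stages + 1):
        v = refresh_relaxation_weights(x, p, alpha, cfg.epsilon_smooth)
        stage_start = obj
        W = np.tensordot(y, weights, axes=(0, 0))
        for _ in range(cfg.max_inner_iters):
            # x ascent under fixed y until the quadratic form stalls
            x_new = _x_power_step(W, x, v, p, alpha)
            obj_x = 0.5 * float(x_new @ W @ x_new)
            if obj_x < obj - 1e-12 * max(1.0, abs(obj)):
                break  # safeguard: reject a non-ascending step
            x = x_new
            # exact y update re-couples the networks
            w = _network_scores(weights, x)
            y = _y_from_scores(w, q)
            new_obj = float(w @ y)
            W = np.tensordot(y, weights, axes=(0, 0))
            if new_obj < obj - 1e-12 * max(1.0, abs(obj)):
                break
            improved = new_obj - obj
            obj = new_obj
            trace.append(obj)
            if improved < cfg.tol * max(1.0, abs(obj)):
                break
        if obj - stage_start < cfg.tol * max(1.0, abs(obj)):
            break
    return MembershipSolution(
        x=x, y=y, objective=obj, objective_trace=trace, stages=stage
    )


def optimize_memberships(
    tensor: NetworkTensor, cfg: MiningConfig
) -> MembershipSolution:
    """Maximize H_A over f(x)=1, g(y)=1 by multi-stage convex relaxation.

    The first start is the uniform feasible point; additional seeded random
    restarts (``cfg.restarts`` total) guard against poor local optima, and
    the best objective wins.  An all-zero tensor yields a flagged
    no-signal solution with objective 0.
    """
    n, m = tensor.n_nodes, tensor.n_networks
    if not tensor.weights.any():
        x = _feasible_uniform(n, cfg.p, cfg.alpha)
        y = np.ones(m) / norm_g(np.ones(m), cfg.q)
        return MembershipSolution(x=x, y=y, objective=0.0, no_signal=True)
    rng = np.random.default_rng(cfg.seed)
    best: MembershipSolution | None = None
    for r in range(cfg.restarts):
        x0 = np.ones(n) if r == 0 else rng.uniform(0.1, 1.0, size=n)
        try:
            sol = _optimize_from(tensor.weights, cfg, x0)
        except DegenerateSliceError:
            # restart once from a seeded random point before giving up
            try:
                sol = _optimize_from(tensor.weights, cfg, rng.uniform(0.1, 1.0, size=n))
            except DegenerateSliceError:
                continue
        if best is None or sol.objective > best.objective:
            best = sol
    if best is None:
        x = _feasible_uniform(n, cfg.p, cfg.alpha)
        y = np.ones(m) / norm_g(np.ones(m), cfg.q)
        return MembershipSolution(x=x, y=y, objective=0.0, no_signal=True)
    return best


# ---------------------------------------------------------------------------
# Pattern extraction, masking, and the mining loop


def pattern_heaviness(
    tensor: NetworkTensor,
    exon_ids: Iterable[str],
    network_ids: Iterable[str],
) -> float:
    """Average weight of all intra-pattern edges over the pattern's networks."""
    exon_idx = tensor.node_index(exon_ids)
    net_idx = tensor.network_index(network_ids)
    if len(exon_idx) < 2:
        raise ValueError("pattern heaviness needs at least 2 exons")
    if len(net_idx) < 1:
        raise ValueError("pattern heaviness needs at least 1 network")
    block = tensor.weights[np.ix_(net_idx, exon_idx, exon_idx)]
    s = len(exon_idx)
    n_edges = s * (s - 1) // 2
    # each unordered edge appears twice in the symmetric block
    return float(block.sum() / (2 * n_edges * len(net_idx)))


def _per_network_heaviness(
    weights: np.ndarray, exon_idx: np.ndarray
) -> np.ndarray:
    s = len(exon_idx)
    block = weights[np.ix_(np.arange(weights.shape[0]), exon_idx, exon_idx)]
    return block.sum(axis=(1, 2)) / (s * (s - 1))


def _rank(values: np.ndarray, ids: Sequence[str]) -> list[int]:
    """Indices sorted by descending membership, ties broken by id."""
    return sorted(range(len(ids)), key=lambda i: (-values[i], ids[i]))


def extract_representative_patterns(
    tensor: NetworkTensor, sol: MembershipSolution, cfg: MiningConfig
) -> list[FrequentCoSplicingCluster]:
    """Read up to two clusters off the membership rankings.

    Exons and networks are sorted by decreasing membership (ties by id);
    only strictly positive memberships can enter a pattern.  A pattern
    "occurs" in a network when its exon set's average edge weight in that
    network meets the heaviness threshold.  Two representatives are
    reported: (a) the minimum-size top-exon prefix together with every
    network in which it occurs (most recurrent), and (b) the longest exon
    prefix that still occurs in at least ``min_networks`` networks and
    whose every added exon connects to the previous members with average
    weight above the threshold (largest).  Duplicates collapse to one
    cluster; the list is ordered largest-first.
    """
    if sol.no_signal:
        return []
    theta = cfg.heaviness_threshold
    node_ids, net_ids = tensor.node_ids, tensor.network_ids
    exon_order = [i for i in _rank(sol.x, node_ids) if sol.x[i] > 0]
    if len(exon_order) < cfg.min_exons:
        return []

    def qualifying(exon_idx: np.ndarray) -> np.ndarray:
        h = _per_network_heaviness(tensor.weights, exon_idx)
        return np.flatnonzero(h >= theta)

    base = np.array(exon_order[: cfg.min_exons])
    base_nets = qualifying(base)
    if len(base_nets) < cfg.min_networks:
        return []

    patterns: list[tuple[np.ndarray, np.ndarray]] = [(base, base_nets)]

    exons = list(base)
    nets = base_nets
    for cand in exon_order[cfg.min_exons :]:
        trial = np.array(exons + [cand])
        trial_nets = qualifying(trial)
        if len(trial_nets) < cfg.min_networks:
            break
        # marginal connectivity of the candidate to the current members,
        # averaged over the networks the grown pattern occurs in
        marginal = float(
            tensor.weights[np.ix_(trial_nets, [cand], exons)].mean()
        )
        if marginal < theta:
            break
        exons, nets = list(trial), trial_nets
    patterns.append((np.array(exons), nets))

    out: list[FrequentCoSplicingCluster] = []
    seen = set()
    for exon_idx, net_idx in patterns:
        cluster = FrequentCoSplicingCluster(
            exon_ids=frozenset(node_ids[i] for i in exon_idx),
            network_ids=frozenset(net_ids[k] for k in net_idx),
            heaviness=pattern_heaviness(
                tensor,
                [node_ids[i] for i in exon_idx],
                [net_ids[k] for k in net_idx],
            ),
            objective=sol.objective,
        )
        if cluster.key() not in seen:
            seen.add(cluster.key())
            out.append(cluster)
    out.sort(key=lambda c: (-len(c.exon_ids), -c.heaviness))
    return out


def _block_sum(weights: np.ndarray, exon_idx: np.ndarray, net_idx: np.ndarray) -> float:
    return float(weights[np.ix_(net_idx, exon_idx, exon_idx)].sum())


def _exon_swap_search(
    weights: np.ndarray, exon_idx: np.ndarray, net_idx: np.ndarray
) -> np.ndarray:
    """Best-improvement single-exon swaps at a fixed network set.

    Replaces one member by one non-member whenever that increases the
    weight captured in the selected networks; a swap i -> j changes the
    block sum by 2 * (conn_j - conn_i - w_ij) where conn is summed
    connectivity to the current members.
    """
    n = weights.shape[1]
    exon_idx = np.array(sorted(exon_idx))
    w_sel = weights[net_idx].sum(axis=0)
    for _ in range(500):
        conn = w_sel[:, exon_idx].sum(axis=1)
        score = _block_sum(weights, exon_idx, net_idx)
        outside = np.setdiff1d(np.arange(n), exon_idx)
        if outside.size == 0:
            break
        best_gain, best_swap = 0.0, None
        for i in exon_idx:
            gains = 2.0 * (conn[outside] - conn[i] - w_sel[i, outside])
            j = int(np.argmax(gains))
            if gains[j] > best_gain + 1e-12 * max(1.0, score):
                best_gain, best_swap = gains[j], (i, int(outside[j]))
        if best_swap is None:
            break
        i, j = best_swap
        exon_idx = np.array(sorted([e for e in exon_idx if e != i] + [j]))
    return exon_idx


def _refine_fixed_size(
    weights: np.ndarray,
    exon_idx: np.ndarray,
    net_idx: np.ndarray,
    max_net_enum: int = 60,
) -> tuple[np.ndarray, np.ndarray]:
    """Polish a rounded fixed-size pattern by discrete local search.

    The exon swap search is seeded from every candidate network subset
    when there are at most ``max_net_enum`` of them (the network dimension
    is usually the small combinatorial axis), otherwise from the networks
    in which the rounded exon set is heaviest; each seed then alternates
    exon swaps with exact network re-selection until stable, and the
    heaviest local optimum wins.  Pattern sizes are preserved throughout.
    """
    import itertools
    from math import comb

    m = weights.shape[0]
    k2 = len(net_idx)
    if comb(m, k2) <= max_net_enum:
        net_seeds = [np.array(c) for c in itertools.combinations(range(m), k2)]
    else:
        net_seeds = [np.asarray(net_idx)]
    best_score = -np.inf
    best: tuple[np.ndarray, np.ndarray] | None = None
    for seed_nets in net_seeds:
        ex, nets = np.asarray(exon_idx), seed_nets
        ex = _exon_swap_search(weights, ex, nets)
        for _ in range(20):
            h = _per_network_heaviness(weights, ex)
            new_nets = np.argsort(-h, kind="stable")[:k2]
            if set(new_nets) == set(nets):
                break
            nets = new_nets
            ex = _exon_swap_search(weights, ex, nets)
        score = _block_sum(weights, ex, nets)
        if score > best_score:
            best_score, best = score, (ex, nets)
    assert best is not None
    return best


def mine_fixed_size(
    tensor: NetworkTensor, cfg: MiningConfig, n_exons: int, n_networks: int
) -> FrequentCoSplicingCluster:
    """Continuous relaxation of the fixed-size discrete problem.

    Solves the relaxation (with restarts), rounds each solution to the
    ``n_exons`` top-ranking exons paired with the ``n_networks`` networks
    in which that exon set is heaviest, polishes the rounding by discrete
    local search, and returns the heaviest pattern found.
    """
    if n_exons < 2 or n_exons > tensor.n_nodes:
        raise ValueError("n_exons out of range")
    if n_networks < 1 or n_networks > tensor.n_networks:
        raise ValueError("n_networks out of range")
    rng = np.random.default_rng(cfg.seed)
    n = tensor.n_nodes
    best: FrequentCoSplicingCluster | None = None
    for r in range(cfg.restarts):
        x0 = np.ones(n) if r == 0 else rng.uniform(0.1, 1.0, size=n)
        try:
            sol = _optimize_from(tensor.weights, cfg, x0)
        except DegenerateSliceError:
            continue
        exon_idx = np.array(_rank(sol.x, tensor.node_ids)[:n_exons])
        h = _per_network_heaviness(tensor.weights, exon_idx)
        net_idx = np.argsort(-h, kind="stable")[:n_networks]
        exon_idx, net_idx = _refine_fixed_size(tensor.weights, exon_idx, net_idx)
        exon_ids = [tensor.node_ids[i] for i in exon_idx]
        net_ids = [tensor.network_ids[k] for k in net_idx]
        cluster = FrequentCoSplicingCluster(
            exon_ids=frozenset(exon_ids),
            network_ids=frozenset(net_ids),
            heaviness=pattern_heaviness(tensor, exon_ids, net_ids),
            objective=sol.objective,
        )
        if best is None or cluster.heaviness > best.heaviness:
            best = cluster
    if best is None:
        raise DegenerateSliceError("no restart produced a usable solution")
    return best


def mask_pattern(
    tensor: NetworkTensor, cluster: FrequentCoSplicingCluster
) -> NetworkTensor:
    """Zero the cluster's intra-edges in its networks; everything else is
    untouched, so masking is local and idempotent."""
    exon_idx = tensor.node_index(cluster.exon_ids)
    net_idx = tensor.network_index(cluster.network_ids)
    out = tensor.copy()
    out.weights[np.ix_(net_idx, exon_idx, exon_idx)] = 0.0
    return out


def mine_all(
    tensor: NetworkTensor, cfg: MiningConfig
) -> list[FrequentCoSplicingCluster]:
    """Optimize, extract representatives, mask, repeat.

    Stops when a round yields no pattern meeting the heaviness threshold
    or when ``cfg.max_patterns`` clusters have been reported.  Both
    representatives of a round are masked before re-optimizing so a round
    cannot rediscover itself.
    """
    clusters: list[FrequentCoSplicingCluster] = []
    seen: set = set()
    work = tensor.copy()
    round_no = 0
    while len(clusters) < cfg.max_patterns:
        round_no += 1
        sol = optimize_memberships(work, replace(cfg, seed=cfg.seed + round_no - 1))
        if sol.no_signal:
            break
        found = [
            c for c in extract_representative_patterns(work, sol, cfg)
            if c.key() not in seen
        ]
        if not found:
            break
        logger.info(
            "round %d: objective %.6g, %d pattern(s)", round_no, sol.objective, len(found)
        )
        for cluster in found:
            work = mask_pattern(work, cluster)
            if len(clusters) < cfg.max_patterns:
                seen.add(cluster.key())
                clusters.append(cluster)
    return clusters
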