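"""Signed weighted modularity: the Q* objective and its Louvain-type maximiser.

For a fully connected network with positive and negative weights the
partition quality is scored on the two sign layers separately,

    Q+ = (1/v+) * sum_ij (w+_ij - s+_i s+_j / v+) * delta(M_i, M_j)

and analogously Q- on the magnitudes of the negative weights, where s are
node strengths, v the layer's total weight (ordered-pair convention) and
the sum runs over all ordered node pairs of the same module (the null-model
term includes i = j, as in standard Newman-style modularity).  The combined
objective down-weights the negative layer,

    Q* = Q+ - (v- / (v+ + v-)) * Q-,

so negative weights are auxiliary to positive ones: a high-Q* partition
keeps most positive weight within modules and pushes negative weight
between them.  A symmetric convention weighting both layers by their share
of total weight is available behind a flag.

The maximiser is a Louvain-type greedy scheme operating jointly on both
layers: seeded sweeps of single-node moves accepted when the combined gain
is positive, followed by module agglomeration, repeated until no gain, with
multiple random restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import SignedNetwork

_GAIN_EPS = 1e-12


@dataclass(frozen=True)
class Partition:
    """Module-affiliation vector: one module label per network node."""

    affiliation: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "affiliation", tuple(int(a) for a in self.affiliation)
        )

    @property
    def n_nodes(self) -> int:
        return len(self.affiliation)

    @property
    def n_modules(self) -> int:
        return len(set(self.affiliation))

    def canonical(self) -> "Partition":
        """Relabel modules 1..m by first appearance."""
        mapping: dict[int, int] = {}
        out = []
        for a in self.affiliation:
            if a not in mapping:
                mapping[a] = len(mapping) + 1
            out.append(mapping[a])
        return Partition(tuple(out))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.affiliation, dtype=int)


@dataclass(frozen=True)
class ModularityResult:
    """Best partition found together with its Q* decomposition."""

    partition: Partition
    q_star: float
    q_pos: float
    q_neg: float
    n_restarts: int
    seed: int


def _layer_score(w: np.ndarray, aff: np.ndarray, gamma: float) -> float:
    """Newman modularity of one nonnegative layer (0 if the layer is empty)."""
    v = w.sum()
    if v == 0.0:
        return 0.0
    s = w.sum(axis=1)
    same = aff[:, None] == aff[None, :]
    return float(((w - gamma * np.outer(s, s) / v) * same).sum() / v)


def modularity_score(
    net: SignedNetwork,
    partition: Partition | np.ndarray,
    convention: str = "asymmetric",
    gamma: float = 1.0,
) -> tuple[float, float, float]:
    """Score a partition on a signed network.

    Returns ``(q_star, q_pos, q_neg)``.  With ``convention="asymmetric"``
    (default) the negative layer enters as an auxiliary penalty,
    ``Q* = Q+ - (v-/(v+ + v-)) Q-``; with ``"symmetric"`` both layers are
    weighted by their share of total weight,
    ``Q* = (v+ Q+ - v- Q-)/(v+ + v-)``.  If the network has no negative
    weights, Q* = Q+ exactly under either convention.
    """
    aff = partition.as_array() if isinstance(partition, Partition) else np.asarray(partition)
    if aff.shape[0] != net.n_nodes:
        raise ValueError("partition length does not match network size")
    wp = net.positive_part
    wn = net.negative_part
    vp = wp.sum()
    vn = wn.sum()
    if vp + vn == 0.0:
        raise ValueError("all-zero weight matrix: modularity is undefined")
    q_pos = _layer_score(wp, aff, gamma)
    q_neg = _layer_score(wn, aff, gamma)
    if convention == "asymmetric":
        q_star = q_pos - vn / (vp + vn) * q_neg
    elif convention == "symmetric":
        q_star = (vp * q_pos - vn * q_neg) / (vp + vn)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return float(q_star), q_pos, q_neg


def _layer_coefficients(vp: float, vn: float, convention: str) -> tuple[float, float]:
    """Multipliers (c_pos, c_neg) such that Q* = c_pos*Q+ - c_neg*Q-."""
    if convention == "asymmetric":
        return 1.0, vn / (vp + vn)
    if convention == "symmetric":
        return vp / (vp + vn), vn / (vp + vn)
    raise ValueError(f"unknown convention {convention!r}")


def _local_moves(
    wp: np.ndarray,
    wn: np.ndarray,
    vp: float,
    vn: float,
    c_pos: float,
    c_neg: float,
    gamma: float,
    rng: np.random.Generator,
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """One Louvain phase of greedy single-node moves on the aggregated graph.

    Node moves are accepted when the joint gain across the two sign layers
    is positive; ties break to the first maximal candidate in label order.
    Self-loop weights (internal weight of aggregated nodes) never change
    module, so they cancel from every gain.
    """
    n = wp.shape[0]
    comm = np.arange(n) if init is None else init.copy()
    sp = wp.sum(axis=1)
    sn = wn.sum(axis=1)
    comm_sp = np.bincount(comm, weights=sp, minlength=n)
    comm_sn = np.bincount(comm, weights=sn, minlength=n)
    improved = False
    moved = True
    while moved:
        moved = False
        for i in rng.permutation(n):
            a = comm[i]
            comm_sp[a] -= sp[i]
            comm_sn[a] -= sn[i]
            # weight from i to each community, excluding the self-loop
            row_p = wp[i].copy()
            row_n = wn[i].copy()
            row_p[i] = 0.0
            row_n[i] = 0.0
            kp = np.bincount(comm, weights=row_p, minlength=n)
            kn = np.bincount(comm, weights=row_n, minlength=n)
            gain = np.zeros(n)
            if vp > 0.0:
                gain += c_pos * (2.0 / vp) * (kp - gamma * sp[i] * comm_sp / vp)
            if vn > 0.0:
                gain -= c_neg * (2.0 / vn) * (kn - gamma * sn[i] * comm_sn / vn)
            best = int(np.argmax(gain))
            if gain[best] > gain[a] + _GAIN_EPS:
                comm[i] = best
                moved = True
                improved = True
            else:
                comm[i] = a
            comm_sp[comm[i]] += sp[i]
            comm_sn[comm[i]] += sn[i]
    return comm, improved


def _aggregate(w: np.ndarray, comm: np.ndarray, n_comm: int) -> np.ndarray:
    """Collapse nodes by community; internal weight becomes self-loops."""
    ind = np.zeros((n_comm, w.shape[0]))
    ind[comm, np.arange(w.shape[0])] = 1.0
    return ind @ w @ ind.T


def _louvain_once(
    wp: np.ndarray,
    wn: np.ndarray,
    convention: str,
    gamma: float,
    rng: np.random.Generator,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """One full greedy run: node sweeps, agglomeration, and a refinement
    loop of single-node moves on the original graph (nodes fused into an
    aggregate can otherwise never leave a badly chosen module)."""
    vp = wp.sum()
    vn = wn.sum()
    c_pos, c_neg = _layer_coefficients(vp, vn, convention)
    n = wp.shape[0]
    # original node -> current community
    aff = np.arange(n) if init is None else np.unique(init, return_inverse=True)[1]
    while True:
        # single-node moves on the original graph from the current partition
        comm, improved_nodes = _local_moves(
            wp, wn, vp, vn, c_pos, c_neg, gamma, rng, init=aff
        )
        _, aff = np.unique(comm, return_inverse=True)
        # agglomeration ascent
        improved_agg = False
        n_comm = aff.max() + 1
        cur_p = _aggregate(wp, aff, n_comm)
        cur_n = _aggregate(wn, aff, n_comm)
        while True:
            comm, improved = _local_moves(cur_p, cur_n, vp, vn, c_pos, c_neg, gamma, rng)
            if not improved:
                break
            improved_agg = True
            _, comm = np.unique(comm, return_inverse=True)
            aff = comm[aff]
            n_comm = comm.max() + 1
            if n_comm == cur_p.shape[0]:
                break
            cur_p = _aggregate(cur_p, comm, n_comm)
            cur_n = _aggregate(cur_n, comm, n_comm)
        if not (improved_nodes or improved_agg):
            return aff


def maximize_modularity(
    net: SignedNetwork,
    n_restarts: int = 100,
    seed: int = 0,
    convention: str = "asymmetric",
    gamma: float = 1.0,
) -> ModularityResult:
    """Maximise Q* by the Louvain-type scheme with seeded random restarts.

    Each restart runs the greedy optimisation with an independent random
    node-sweep order; the first restart starts from singleton modules and
    later restarts from random initial partitions with a random module
    count, which lets the greedy scheme reach optima whose basin excludes
    the singleton start.  The best-scoring partition (in canonical form)
    is returned, with its score recomputed by :func:`modularity_score`.
    """
    if net.n_nodes < 2:
        raise ValueError("network must have at least 2 nodes")
    if n_restarts < 1:
        raise ValueError("n_restarts must be at least 1")
    wp = net.positive_part
    wn = net.negative_part
    if wp.sum() + wn.sum() == 0.0:
        raise ValueError("all-zero weight matrix: modularity is undefined")
    master = np.random.default_rng(seed)
    best_aff: np.ndarray | None = None
    best_q = -np.inf
    n = net.n_nodes
    for restart in range(n_restarts):
        rng = np.random.default_rng(master.integers(2**31))
        if restart == 0:
            init = None
        else:
            k = int(rng.integers(1, n + 1))
            init = rng.integers(0, k, size=n)
        aff = _louvain_once(wp, wn, convention, gamma, rng, init=init)
        q, _, _ = modularity_score(net, aff, convention=convention, gamma=gamma)
        if q > best_q + _GAIN_EPS:
            best_q = q
            best_aff = aff
    assert best_aff is not None
    partition = Partition(tuple(best_aff + 1)).canonical()
    q_star, q_pos, q_neg = modularity_score(
        net, partition, convention=convention, gamma=gamma
    )
    return ModularityResult(
        partition=partition,
        q_star=q_star,
        q_pos=q_pos,
        q_neg=q_neg,
        n_restarts=n_restarts,
        seed=seed,
    )


def coassignment_matrix(partitions: list[Partition]) -> np.ndarray:
    """Fraction of runs in which each node pair shares a module."""
    if not partitions:
        raise ValueError("no partitions supplied")
    n = partitions[0].n_nodes
    d = np.zeros((n, n))
    for p in partitions:
        aff = p.as_array()
        if aff.shape[0] != n:
            raise ValueError("partitions have unequal length")
        d += aff[:, None] == aff[None, :]
    return d / len(partitions)


def consensus_partition(
    partitions: list[Partition],
    threshold: float = 0.5,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 20,
) -> Partition:
    """Consensus of repeated stochastic partitions via co-assignment clustering.

    The co-assignment matrix across runs is thresholded (entries below
    ``threshold`` zeroed) and re-clustered with the modularity maximiser;
    the procedure repeats until all runs agree.  Unanimous input is
    returned unchanged (canonical form).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    if not partitions:
        raise ValueError("no partitions supplied")
    current = [p.canonical() for p in partitions]
    for it in range(max_iter):
        if all(p == current[0] for p in current):
            return current[0]
        d = coassignment_matrix(current)
        d = np.where(d >= threshold, d, 0.0)
        np.fill_diagonal(d, 0.0)
        if d.sum() == 0.0:
            # nothing survives thresholding: every node its own module
            return Partition(tuple(range(1, current[0].n_nodes + 1)))
        net = SignedNetwork(weights=d)
        current = [
            maximize_modularity(net, n_restarts=n_restarts, seed=seed + it * 997 + r).partition
            for r in range(len(current))
        ]
    return current[0]
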