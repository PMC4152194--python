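"""Reproducibility of modular organization: MI/VoI, null networks, group splits.

Partition similarity is measured by normalized mutual information
(2 I(P;Q) / (H(P) + H(Q)), in [0, 1], 1 iff identical up to relabelling)
and distance by the variation of information
(H(P) + H(Q) - 2 I(P;Q), normalized by log N so it lies in [0, 1]).
Chance baselines come from null networks in which the multiset of edge
weights is preserved but their placement is randomly permuted, destroying
community structure while conserving the global weight distribution (and
hence the totals v+ and v- exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np

from .connectivity import FCMatrix, mean_fc, split_into_groups
from .modularity import Partition, maximize_modularity
from .network import SignedNetwork, network_from_fc


# --------------------------------------------------------------------------
# partition information measures


def _contingency(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    _, pi = np.unique(p, return_inverse=True)
    _, qi = np.unique(q, return_inverse=True)
    table = np.zeros((pi.max() + 1, qi.max() + 1))
    np.add.at(table, (pi, qi), 1.0)
    return table


def _entropy(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _mutual_information(table: np.ndarray) -> float:
    n = table.sum()
    pij = table / n
    outer = np.outer(table.sum(axis=1), table.sum(axis=0)) / n**2
    mask = pij > 0
    return float((pij[mask] * np.log(pij[mask] / outer[mask])).sum())


def _as_arrays(p, q) -> tuple[np.ndarray, np.ndarray]:
    pa = p.as_array() if isinstance(p, Partition) else np.asarray(p)
    qa = q.as_array() if isinstance(q, Partition) else np.asarray(q)
    if pa.shape[0] != qa.shape[0]:
        raise ValueError("partitions have unequal length")
    return pa, qa


def partition_mi(p, q, normalization: str = "sum") -> float:
    """Normalized mutual information between two partitions.

    ``"sum"`` (default): 2 I / (H(P) + H(Q)); ``"none"``: raw I in nats.
    If either partition has zero entropy (single module) the normalized
    value is 0 by the 0/0 := 0 convention.
    """
    pa, qa = _as_arrays(p, q)
    table = _contingency(pa, qa)
    i = _mutual_information(table)
    if normalization == "none":
        return i
    if normalization != "sum":
        raise ValueError(f"unknown normalization {normalization!r}")
    denom = _entropy(table.sum(axis=1)) + _entropy(table.sum(axis=0))
    if denom == 0.0:
        return 0.0
    return float(np.clip(2.0 * i / denom, 0.0, 1.0))


def partition_voi(p, q, normalization: str = "logN") -> float:
    """Variation of information between two partitions.

    ``"logN"`` (default) divides by log N, bounding the value to [0, 1]
    (0 iff identical up to relabelling, 1 for singletons vs one module);
    ``"none"`` returns the metric in nats.
    """
    pa, qa = _as_arrays(p, q)
    table = _contingency(pa, qa)
    voi = _entropy(table.sum(axis=1)) + _entropy(table.sum(axis=0)) - 2.0 * _mutual_information(table)
    voi = max(voi, 0.0)
    if normalization == "none":
        return float(voi)
    if normalization != "logN":
        raise ValueError(f"unknown normalization {normalization!r}")
    n = pa.shape[0]
    if n < 2:
        return 0.0
    return float(np.clip(voi / np.log(n), 0.0, 1.0))


# --------------------------------------------------------------------------
# null networks


def null_network(net: SignedNetwork, seed: int, method: str = "permute") -> SignedNetwork:
    """Surrogate network with community structure destroyed.

    ``"permute"`` (default): uniform permutation of the upper-triangular
    weights, mirrored to symmetry — the exact multiset of weights (hence
    v+ and v-) is preserved.  ``"sign_preserving"``: positive weights are
    permuted among positive edge positions and negative among negative
    ones, additionally preserving each node's positive/negative degree.
    """
    rng = np.random.default_rng(seed)
    n = net.n_nodes
    iu = np.triu_indices(n, k=1)
    w = net.weights[iu]
    out = np.zeros((n, n))
    if method == "permute":
        out[iu] = rng.permutation(w)
    elif method == "sign_preserving":
        shuffled = w.copy()
        for mask in (w > 0, w < 0):
            vals = w[mask]
            shuffled[mask] = rng.permutation(vals)
        out[iu] = shuffled
    else:
        raise ValueError(f"unknown null method {method!r}")
    out = out + out.T
    return SignedNetwork(weights=out, roi_labels=net.roi_labels)


# --------------------------------------------------------------------------
# reports


@dataclass
class ReproducibilityReport:
    """Mean +/- SD of pairwise MI and VoI for observed and null partitions."""

    level: str
    mi_mean: float
    mi_sd: float
    voi_mean: float
    voi_sd: float
    null_mi_mean: float
    null_mi_sd: float
    null_voi_mean: float
    null_voi_sd: float
    n_partitions: int
    n_randomizations: int
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def _pairwise_stats(partitions: list[Partition]) -> tuple[np.ndarray, np.ndarray]:
    mi = []
    voi = []
    for p, q in combinations(partitions, 2):
        mi.append(partition_mi(p, q))
        voi.append(partition_voi(p, q))
    return np.asarray(mi), np.asarray(voi)


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    if x.size == 0:
        return float("nan"), float("nan")
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return float(x.mean()), sd


def _best_partition(net: SignedNetwork, n_restarts: int, seed: int) -> Partition:
    return maximize_modularity(net, n_restarts=n_restarts, seed=seed).partition


def subject_level_report(
    nets: list[SignedNetwork],
    n_restarts: int = 100,
    seed: int = 0,
    null_method: str = "permute",
) -> ReproducibilityReport:
    """Between-subject reproducibility of modular organization.

    Each subject's network is partitioned independently; MI and VoI are
    pooled over all unordered subject pairs.  The same computation runs on
    one null network per subject as the chance baseline.
    """
    if len(nets) < 2:
        raise ValueError("need at least 2 networks")
    root = np.random.SeedSequence(seed)
    opt_seeds, null_seeds = root.spawn(2)
    opt_seeds = opt_seeds.spawn(len(nets))
    null_seeds = null_seeds.spawn(len(nets))
    observed = [
        _best_partition(net, n_restarts, int(s.generate_state(1)[0] % 2**31))
        for net, s in zip(nets, opt_seeds)
    ]
    nulls = []
    for net, s in zip(nets, null_seeds):
        s1, s2 = (int(v % 2**31) for v in s.generate_state(2))
        nulls.append(_best_partition(null_network(net, s1, null_method), n_restarts, s2))
    mi, voi = _pairwise_stats(observed)
    nmi, nvoi = _pairwise_stats(nulls)
    return ReproducibilityReport(
        level="subject",
        mi_mean=_mean_sd(mi)[0],
        mi_sd=_mean_sd(mi)[1],
        voi_mean=_mean_sd(voi)[0],
        voi_sd=_mean_sd(voi)[1],
        null_mi_mean=_mean_sd(nmi)[0],
        null_mi_sd=_mean_sd(nmi)[1],
        null_voi_mean=_mean_sd(nvoi)[0],
        null_voi_sd=_mean_sd(nvoi)[1],
        n_partitions=len(nets),
        n_randomizations=1,
        seed=seed,
    )


def group_randomization_report(
    matrices: list[FCMatrix],
    n_groups: int = 4,
    n_randomizations: int = 1000,
    n_restarts: int = 100,
    seed: int = 0,
    null_method: str = "permute",
) -> ReproducibilityReport:
    """Group-level reproducibility over repeated random subject groupings.

    Each randomization splits the cohort into ``n_groups`` near-equal
    groups, averages FC within groups, partitions each group-mean network,
    and records MI/VoI over all group pairs; statistics are pooled over
    group pairs and randomizations.  A parallel branch does the same on
    null networks derived from the group-mean matrices.
    """
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be at least 1")
    if n_groups < 2:
        raise ValueError("n_groups must be at least 2")
    if n_groups > len(matrices):
        raise ValueError("more groups than subjects")
    mi_all, voi_all, nmi_all, nvoi_all = [], [], [], []
    root = np.random.SeedSequence(seed)
    for rand_seq in root.spawn(n_randomizations):
        split_s, opt_s, null_s = rand_seq.spawn(3)
        rng = np.random.default_rng(split_s)
        groups = split_into_groups(len(matrices), n_groups, rng)
        group_nets = [
            network_from_fc(mean_fc([matrices[i] for i in g])[0]) for g in groups
        ]
        opt_seeds = opt_s.spawn(n_groups)
        observed = [
            _best_partition(net, n_restarts, int(s.generate_state(1)[0] % 2**31))
            for net, s in zip(group_nets, opt_seeds)
        ]
        nulls = []
        for net, s in zip(group_nets, null_s.spawn(n_groups)):
            s1, s2 = (int(v % 2**31) for v in s.generate_state(2))
            nulls.append(
                _best_partition(null_network(net, s1, null_method), n_restarts, s2)
            )
        mi, voi = _pairwise_stats(observed)
        nmi, nvoi = _pairwise_stats(nulls)
        mi_all.append(mi)
        voi_all.append(voi)
        nmi_all.append(nmi)
        nvoi_all.append(nvoi)
    mi = np.concatenate(mi_all)
    voi = np.concatenate(voi_all)
    nmi = np.concatenate(nmi_all)
    nvoi = np.concatenate(nvoi_all)
    return ReproducibilityReport(
        level="group",
        mi_mean=_mean_sd(mi)[0],
        mi_sd=_mean_sd(mi)[1],
        voi_mean=_mean_sd(voi)[0],
        voi_sd=_mean_sd(voi)[1],
        null_mi_mean=_mean_sd(nmi)[0],
        null_mi_sd=_mean_sd(nmi)[1],
        null_voi_mean=_mean_sd(nvoi)[0],
        null_voi_sd=_mean_sd(nvoi)[1],
        n_partitions=n_groups,
        n_randomizations=n_randomizations,
        seed=seed,
    )
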