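"""Node centrality on signed networks: generalized strength, diversity, hubs.

Generalized strength combines the two sign layers asymmetrically,

    s*_i = s+_i - (s-_i / (s+_i + s-_i)) * s-_i,

so the negative strength is rescaled by the node's negative share and
positive connections dominate.  Diversity is the normalized entropy of a
node's strength distribution across the modules of a partition, computed
per sign layer and combined with the same negative-share factor,

    h*_i = h+_i - (s-_i / (s+_i + s-_i)) * h-_i.

A node is a hub when both s* and h* exceed their across-node means
(strictly).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .modularity import Partition
from .network import SignedNetwork


def signed_strengths(net: SignedNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Per-node positive and |negative| strengths."""
    return net.strength_pos, net.strength_neg


def _negative_share(
    s_pos: np.ndarray, s_neg: np.ndarray, net: SignedNetwork | None, scaling: str
) -> np.ndarray:
    """Rescaling factor applied to the negative layer.

    ``"node"`` (default): each node's own negative share s-/(s+ + s-).
    ``"global"``: the network-wide share v-/(v+ + v-), identical for all
    nodes.
    """
    if scaling == "node":
        tot = s_pos + s_neg
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(tot > 0, s_neg / np.where(tot > 0, tot, 1.0), 0.0)
        return share
    if scaling == "global":
        if net is None:
            raise ValueError("global scaling requires the network")
        vtot = net.total_weight_pos + net.total_weight_neg
        share = net.total_weight_neg / vtot if vtot > 0 else 0.0
        return np.full_like(s_pos, share)
    raise ValueError(f"unknown scaling {scaling!r}")


def generalized_strength(
    s_pos: np.ndarray,
    s_neg: np.ndarray,
    net: SignedNetwork | None = None,
    scaling: str = "node",
) -> np.ndarray:
    """Combine sign-layer strengths into the generalized strength s*."""
    s_pos = np.asarray(s_pos, dtype=float)
    s_neg = np.asarray(s_neg, dtype=float)
    return s_pos - _negative_share(s_pos, s_neg, net, scaling) * s_neg


def _layer_diversity(w: np.ndarray, aff: np.ndarray, n_modules: int) -> np.ndarray:
    """Normalized entropy of each node's strength across modules (one layer)."""
    n = w.shape[0]
    if n_modules <= 1:
        return np.zeros(n)
    # per-node within-module strengths s_i(u)
    module_strength = np.zeros((n, n_modules))
    for u in range(1, n_modules + 1):
        module_strength[:, u - 1] = w[:, aff == u].sum(axis=1)
    s = module_strength.sum(axis=1)
    h = np.zeros(n)
    active = s > 0
    p = module_strength[active] / s[active, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h[active] = -plogp.sum(axis=1) / np.log(n_modules)
    return h


def diversity(
    net: SignedNetwork,
    partition: Partition,
    scaling: str = "node",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-node diversity (h+, h-, h*) with respect to a module partition.

    For each sign layer the module-strength fractions p_i(u) = s_i(u)/s_i
    enter a Shannon entropy normalized by log m, so h lies in [0, 1]: 0 if
    a node's strength is confined to one module, 1 if spread uniformly over
    all m.  Nodes with zero strength in a layer, and single-module
    partitions, get h = 0.
    """
    aff = partition.as_array()
    if aff.shape[0] != net.n_nodes:
        raise ValueError("partition length does not match network size")
    m = partition.n_modules
    # relabel to 1..m in case the partition is not canonical
    aff = Partition(tuple(aff)).canonical().as_array()
    h_pos = _layer_diversity(net.positive_part, aff, m)
    h_neg = _layer_diversity(net.negative_part, aff, m)
    s_pos, s_neg = signed_strengths(net)
    h_star = h_pos - _negative_share(s_pos, s_neg, net, scaling) * h_neg
    return h_pos, h_neg, h_star


def classify_hubs(s_star: np.ndarray, h_star: np.ndarray) -> np.ndarray:
    """Hub flags: strictly above-mean generalized strength AND diversity."""
    s_star = np.asarray(s_star, dtype=float)
    h_star = np.asarray(h_star, dtype=float)
    if s_star.shape[0] < 2:
        raise ValueError("hub classification needs at least 2 nodes")
    return (s_star > s_star.mean()) & (h_star > h_star.mean())


def centrality_profile(
    net: SignedNetwork,
    partition: Partition,
    scaling: str = "node",
) -> pd.DataFrame:
    """Full per-node centrality table, sorted by descending s*.

    Columns: s_pos, s_neg, s_star, h_pos, h_neg, h_star, is_hub; the index
    holds ROI labels when the network carries them.
    """
    s_pos, s_neg = signed_strengths(net)
    s_star = generalized_strength(s_pos, s_neg, net, scaling)
    h_pos, h_neg, h_star = diversity(net, partition, scaling)
    labels = net.roi_labels or [f"node{i + 1}" for i in range(net.n_nodes)]
    df = pd.DataFrame(
        {
            "s_pos": s_pos,
            "s_neg": s_neg,
            "s_star": s_star,
            "h_pos": h_pos,
            "h_neg": h_neg,
            "h_star": h_star,
            "is_hub": classify_hubs(s_star, h_star),
        },
        index=pd.Index(labels, name="roi"),
    )
    return df.sort_values("s_star", ascending=False)
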