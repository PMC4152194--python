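"""Signed weighted network container and elementary graph properties.

All sums follow the ordered-pair (double-counting) convention standard for
undirected weighted graphs: the total positive weight ``v_pos`` is the sum
of the positive part of the full weight matrix, i.e. twice the sum over the
unique (upper-triangular) edges, and node strengths are plain row sums of
each sign layer.  Negative quantities are reported as magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SignedNetwork:
    """Fully connected undirected network with signed real edge weights.

    ``weights`` is a symmetric N x N matrix with zero diagonal; positive
    entries are correlated ("positive") connections, negative entries
    anti-correlated ones.
    """

    weights: np.ndarray
    roi_labels: list[str] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.all(np.isfinite(w)):
            raise ValueError("weight matrix contains non-finite entries")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weight matrix must be symmetric")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if self.roi_labels is not None and len(self.roi_labels) != w.shape[0]:
            raise ValueError("number of ROI labels must match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        """Unique node pairs of the fully connected undirected graph."""
        n = self.n_nodes
        return n * (n - 1) // 2

    @property
    def positive_part(self) -> np.ndarray:
        """Matrix of positive weights (zeros elsewhere)."""
        return np.clip(self.weights, 0.0, None)

    @property
    def negative_part(self) -> np.ndarray:
        """Matrix of |negative weights| (zeros elsewhere)."""
        return np.clip(-self.weights, 0.0, None)

    # -- elementary per-node properties ------------------------------------

    @property
    def degree_pos(self) -> np.ndarray:
        """Number of positive connections of each node."""
        return (self.weights > 0).sum(axis=1)

    @property
    def degree_neg(self) -> np.ndarray:
        """Number of negative connections of each node."""
        return (self.weights < 0).sum(axis=1)

    @property
    def strength_pos(self) -> np.ndarray:
        """Sum of positive connection weights of each node."""
        return self.positive_part.sum(axis=1)

    @property
    def strength_neg(self) -> np.ndarray:
        """Sum of |negative| connection weights of each node."""
        return self.negative_part.sum(axis=1)

    # -- totals (ordered-pair convention) ----------------------------------

    @property
    def total_weight_pos(self) -> float:
        """Sum of all positive weights over ordered pairs (= sum of strength_pos)."""
        return float(self.positive_part.sum())

    @property
    def total_weight_neg(self) -> float:
        """Sum of all |negative| weights over ordered pairs."""
        return float(self.negative_part.sum())


def network_from_fc(fc) -> SignedNetwork:
    """Build a :class:`SignedNetwork` from an FC matrix object."""
    return SignedNetwork(weights=fc.z.copy(), roi_labels=list(fc.roi_labels))
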