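"""Signed functional-connectivity matrices from ROI time series.

Per-subject networks are built by partial correlation — the correlation of
each pair of regional signals after regressing out all other regions — so
matrix entries approximate *direct* functional coupling.  Coefficients are
Fisher z-transformed (arctanh) before any averaging, and group or cohort
networks are element-wise means on the z scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_FISHER_CLIP = 1.0 - 1e-7

#: Condition number above which plain inversion of the sample correlation
#: matrix is refused (enable shrinkage instead).
MAX_CONDITION_NUMBER = 1e10


@dataclass
class ROITimeSeries:
    """One subject's T x N matrix of ROI-mean signals.

    ``values[t, k]`` is the signal of region ``roi_labels[k]`` at timepoint
    ``t``.  Columns must be ordered consistently across subjects.
    """

    values: np.ndarray
    roi_labels: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (timepoints x regions) array")
        if self.values.shape[1] != len(self.roi_labels):
            raise ValueError("number of ROI labels must match number of columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class FCMatrix:
    """Symmetric N x N signed matrix of Fisher-z partial correlations.

    The matrix is the weighted adjacency of the fully connected functional
    network; the diagonal is fixed at zero (self-connections are never
    used).
    """

    z: np.ndarray
    roi_labels: list[str]
    subject_id: str = ""
    n_subjects_averaged: int = 1

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = self.z.shape[0]
        if self.z.ndim != 2 or self.z.shape[1] != n:
            raise ValueError("FC matrix must be square")
        if len(self.roi_labels) != n:
            raise ValueError("number of ROI labels must match matrix size")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("FC matrix contains non-finite values")
        if not np.allclose(self.z, self.z.T, atol=1e-10):
            raise ValueError("FC matrix must be symmetric")
        self.z = (self.z + self.z.T) / 2.0
        np.fill_diagonal(self.z, 0.0)

    @property
    def n_rois(self) -> int:
        return self.z.shape[0]


def partial_correlation(
    ts: ROITimeSeries | np.ndarray, shrinkage: bool = False
) -> np.ndarray:
    """Partial-correlation matrix of the columns of a time-series matrix.

    Computed from the precision matrix of the sample *correlation* matrix
    (scale-invariant across regions):  ``pcorr(i, j) = -P_ij / sqrt(P_ii P_jj)``
    where ``P`` is the inverse correlation matrix.  The diagonal is set to
    zero.

    Parameters
    ----------
    ts : ROITimeSeries or (T, N) array
    shrinkage : bool
        Apply Ledoit-Wolf shrinkage to the covariance before inversion.
        Required when the sample correlation matrix is singular or
        near-singular (e.g. T <= N).
    """
    x = ts.values if isinstance(ts, ROITimeSeries) else np.asarray(ts, dtype=float)
    t, n = x.shape
    if shrinkage:
        from sklearn.covariance import LedoitWolf

        # standardise columns so the shrunk covariance is a correlation-like
        # matrix and shrinkage acts toward the identity
        xs = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
        corr = LedoitWolf(assume_centered=True).fit(xs).covariance_
    else:
        if t <= n:
            raise ValueError(
                f"T={t} <= N={n}: sample correlation matrix is singular; "
                "enable shrinkage"
            )
        corr = np.corrcoef(x, rowvar=False)
        cond = np.linalg.cond(corr)
        if cond > MAX_CONDITION_NUMBER:
            raise ValueError(
                f"sample correlation matrix is ill-conditioned (condition "
                f"number {cond:.3e}); enable shrinkage"
            )
    prec = np.linalg.inv(corr)
    d = np.sqrt(np.diag(prec))
    p = -prec / np.outer(d, d)
    p = (p + p.T) / 2.0
    np.fill_diagonal(p, 0.0)
    return np.clip(p, -1.0, 1.0)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z-transform arctanh(r), with |r| clipped just below 1."""
    return np.arctanh(np.clip(r, -_FISHER_CLIP, _FISHER_CLIP))


def subject_fc(ts: ROITimeSeries, shrinkage: bool = False) -> FCMatrix:
    """Fisher-z partial-correlation network of one subject."""
    z = np.asarray(fisher_z(partial_correlation(ts, shrinkage=shrinkage)))
    np.fill_diagonal(z, 0.0)
    return FCMatrix(z=z, roi_labels=list(ts.roi_labels), subject_id=ts.subject_id)


def _check_labels(matrices: list[FCMatrix]) -> list[str]:
    labels = matrices[0].roi_labels
    for m in matrices[1:]:
        if m.roi_labels != labels:
            raise ValueError("FC matrices have mismatching ROI labels")
    return labels


def mean_fc(matrices: list[FCMatrix]) -> tuple[FCMatrix, np.ndarray]:
    """Element-wise mean and sample SD of a list of z-matrices.

    Returns the mean network as an :class:`FCMatrix` (with
    ``n_subjects_averaged`` set) and the SD matrix (ddof=1; zeros for a
    single subject).
    """
    if not matrices:
        raise ValueError("mean_fc requires at least one matrix")
    labels = _check_labels(matrices)
    stack = np.stack([m.z for m in matrices])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(matrices) > 1 else np.zeros_like(mean)
    out = FCMatrix(
        z=mean,
        roi_labels=list(labels),
        subject_id="mean",
        n_subjects_averaged=len(matrices),
    )
    return out, sd


def split_into_groups(
    n_subjects: int, n_groups: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Seeded random split of subject indices into groups of near-equal size.

    Group sizes differ by at most one when ``n_subjects`` is not divisible
    by ``n_groups``.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be at least 2")
    if n_groups > n_subjects:
        raise ValueError(
            f"cannot split {n_subjects} subjects into {n_groups} groups"
        )
    perm = rng.permutation(n_subjects)
    return [np.sort(g) for g in np.array_split(perm, n_groups)]


def upper_triangle(z: np.ndarray) -> np.ndarray:
    """Vectorised strict upper triangle (the network's unique edge weights)."""
    iu = np.triu_indices(z.shape[0], k=1)
    return z[iu]


def group_split_fc_correlation(
    matrices: list[FCMatrix], n_groups: int, seed: int
) -> dict:
    """Between-group reproducibility of the FC values themselves.

    Subjects are randomly split into ``n_groups`` groups, FC matrices
    averaged within each group, and the Pearson correlation computed
    between every pair of groups across the vectorised upper-triangular
    connection weights.

    Returns a dict with the ``n_groups x n_groups`` correlation table
    (NaN below the diagonal, 1 on it), the list of per-group upper-triangle
    weight vectors (for distribution plots), and the group memberships.
    """
    if not matrices:
        raise ValueError("no FC matrices supplied")
    _check_labels(matrices)
    rng = np.random.default_rng(seed)
    groups = split_into_groups(len(matrices), n_groups, rng)
    group_edges = []
    for g in groups:
        gm, _ = mean_fc([matrices[i] for i in g])
        group_edges.append(upper_triangle(gm.z))
    r = np.full((n_groups, n_groups), np.nan)
    np.fill_diagonal(r, 1.0)
    for a in range(n_groups):
        for b in range(a + 1, n_groups):
            r[a, b] = np.corrcoef(group_edges[a], group_edges[b])[0, 1]
    return {
        "r": r,
        "group_edge_weights": group_edges,
        "groups": [g.tolist() for g in groups],
        "seed": seed,
    }
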