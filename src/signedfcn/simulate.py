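"""Synthetic multi-subject ROI time series with a planted signed modular covariance.

The generator emulates a sedated-rodent resting-state cohort at the level that
matters for network analysis: each subject is a T x N matrix of ROI signals
drawn from a multivariate normal whose correlation matrix carries a known
block (planted-partition) structure -- strong positive correlation within
modules, weak positive correlation between most module pairs, and negative
correlation between a configurable minority of module pairs.  Every
downstream stage (partial correlation, signed modularity, hub detection,
reproducibility statistics) can therefore be tested against known ground
truth without any acquired data.

Samples are temporally i.i.d.: the downstream statistics use only zero-lag
partial correlation, so temporal autocorrelation would not change any of
them.  An AR(1) switch is available for users who want serially correlated
signals; it defaults off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import ROITimeSeries

#: Maximum amount by which the positive-definiteness repair may change any
#: correlation entry before the configuration is declared infeasible.
PD_REPAIR_TOLERANCE = 0.05

#: Eigenvalue floor used when repairing an indefinite block correlation matrix.
PD_EIGENVALUE_FLOOR = 1e-4


@dataclass(frozen=True)
class PlantedPartitionSpec:
    """Parameters of the planted signed modular covariance and the cohort.

    Defaults mirror the study conditions the package targets: 40 subjects,
    165 timepoints, 36 regions organised into six unequally sized modules,
    with anti-correlated coupling between the two frontal/somatomotor-like
    blocks and the thalamic/midbrain-like block.

    Parameters
    ----------
    n_nodes : int
        Number of regions of interest (network nodes).
    module_sizes : tuple of int
        Size of each planted module; must sum to ``n_nodes``.
    within_corr : float
        Correlation between nodes of the same module, in (0, 1).
    between_corr : float
        Baseline correlation between nodes of different modules.
    anti_pairs : tuple of (int, int)
        1-based module-index pairs whose between-module correlation is set
        to ``anti_corr`` instead of ``between_corr``.
    anti_corr : float
        Negative correlation assigned to ``anti_pairs``.
    n_timepoints : int
        Samples per subject; must exceed ``n_nodes`` so the per-subject
        sample correlation matrix is invertible.
    n_subjects : int
        Cohort size.
    subject_sd : float
        Standard deviation of the per-subject jitter added independently to
        every off-diagonal correlation before sampling.
    ar_coeff : float
        AR(1) coefficient for optional temporal autocorrelation; 0 disables.
    seed : int
        Master seed; all subject-level randomness derives from it.
    """

    n_nodes: int = 36
    module_sizes: tuple[int, ...] = (5, 4, 8, 8, 3, 8)
    within_corr: float = 0.6
    between_corr: float = 0.05
    anti_pairs: tuple[tuple[int, int], ...] = ((1, 6), (2, 6))
    anti_corr: float = -0.2
    n_timepoints: int = 165
    n_subjects: int = 40
    subject_sd: float = 0.05
    ar_coeff: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.module_sizes)
        object.__setattr__(self, "module_sizes", sizes)
        object.__setattr__(
            self, "anti_pairs", tuple((int(a), int(b)) for a, b in self.anti_pairs)
        )
        self.validate()

    def validate(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be positive")
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if sum(self.module_sizes) != self.n_nodes:
            raise ValueError(
                f"module_sizes sum to {sum(self.module_sizes)}, expected {self.n_nodes}"
            )
        for name in ("within_corr", "between_corr", "anti_corr"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (-1, 1)")
        m = len(self.module_sizes)
        for a, b in self.anti_pairs:
            if not (1 <= a <= m and 1 <= b <= m) or a == b:
                raise ValueError(f"anti_pair ({a}, {b}) is not a valid module pair")
        if self.n_timepoints <= self.n_nodes:
            raise ValueError(
                "n_timepoints must exceed n_nodes for a well-conditioned "
                f"sample covariance (got T={self.n_timepoints}, N={self.n_nodes})"
            )
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be nonnegative")
        if not 0.0 <= abs(self.ar_coeff) < 1.0:
            raise ValueError("ar_coeff must lie in (-1, 1)")

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)


def true_partition(spec: PlantedPartitionSpec) -> np.ndarray:
    """Module-affiliation vector implied by ``module_sizes`` (labels 1..m)."""
    return np.repeat(np.arange(1, spec.n_modules + 1), spec.module_sizes)


def _nearest_pd_correlation(c: np.ndarray, floor: float = PD_EIGENVALUE_FLOOR) -> np.ndarray:
    """Floor the eigenvalues of a symmetric matrix and rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh(c)
    if vals[0] > floor:
        return c
    repaired = (vecs * np.maximum(vals, floor)) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def build_block_covariance(spec: PlantedPartitionSpec) -> np.ndarray:
    """Construct the planted n x n block correlation matrix.

    Entry (i, j) is ``within_corr`` for same-module pairs and
    ``between_corr`` (or ``anti_corr`` for configured module pairs)
    otherwise.  If the raw block matrix is indefinite it is repaired by
    eigenvalue flooring and diagonal rescaling; a repair that moves any
    entry by more than :data:`PD_REPAIR_TOLERANCE` raises, signalling an
    infeasible correlation configuration.
    """
    spec.validate()
    labels = true_partition(spec)
    same = labels[:, None] == labels[None, :]
    c = np.where(same, spec.within_corr, spec.between_corr)
    for a, b in spec.anti_pairs:
        mask_a = labels == a
        mask_b = labels == b
        c[np.ix_(mask_a, mask_b)] = spec.anti_corr
        c[np.ix_(mask_b, mask_a)] = spec.anti_corr
    np.fill_diagonal(c, 1.0)

    repaired = _nearest_pd_correlation(c)
    shift = np.abs(repaired - c).max()
    if shift > PD_REPAIR_TOLERANCE:
        raise ValueError(
            "positive-definiteness repair would perturb the block correlation "
            f"matrix by {shift:.4f} > {PD_REPAIR_TOLERANCE}; the requested "
            "correlation configuration is infeasible"
        )
    return repaired


#: Subject covariances are kept at least this well conditioned, as a
#: fraction of the planted matrix's smallest eigenvalue.  Partial
#: correlations are the inverse-covariance off-diagonals, so a
#: near-singular subject matrix would turn the jitter into arbitrarily
#: large partial-correlation perturbations and the "variability" into pure
#: inversion noise.
SUBJECT_CONDITIONING_FRACTION = 0.75


def _jitter_covariance(base: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Add symmetric N(0, sd^2) jitter to every off-diagonal entry, re-repair to PD.

    The repair shrinks the jittered matrix toward the base matrix just far
    enough that its smallest eigenvalue stays at or above
    :data:`SUBJECT_CONDITIONING_FRACTION` times the base matrix's smallest
    eigenvalue.  Every entry therefore stays between its jittered and its
    planted value: the jitter is attenuated when it threatens conditioning,
    never amplified.
    """
    n = base.shape[0]
    noise = rng.normal(0.0, sd, size=(n, n))
    noise = (noise + noise.T) / np.sqrt(2.0)  # keep marginal sd after symmetrisation
    np.fill_diagonal(noise, 0.0)
    c = np.clip(base + noise, -0.99, 0.99)
    np.fill_diagonal(c, 1.0)
    floor = SUBJECT_CONDITIONING_FRACTION * np.linalg.eigvalsh(base)[0]
    if np.linalg.eigvalsh(c)[0] >= floor:
        return c
    lo, hi = 0.0, 1.0  # bisect the smallest blend weight restoring conditioning
    for _ in range(40):
        t = (lo + hi) / 2.0
        if np.linalg.eigvalsh((1.0 - t) * c + t * base)[0] >= floor:
            hi = t
        else:
            lo = t
    return (1.0 - hi) * c + hi * base


def _sample_timeseries(
    cov: np.ndarray, n_timepoints: int, ar: float, rng: np.random.Generator
) -> np.ndarray:
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n_timepoints, cov.shape[0]))
    x = z @ chol.T
    if ar != 0.0:
        # AR(1) filter along time; stationary variance restored by rescaling.
        for t in range(1, n_timepoints):
            x[t] = ar * x[t - 1] + np.sqrt(1.0 - ar**2) * x[t]
    return x


def subject_seeds(spec: PlantedPartitionSpec) -> list[np.random.SeedSequence]:
    """Deterministic per-subject seed sequences spawned from the master seed."""
    return np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)


def generate_cohort(spec: PlantedPartitionSpec) -> list[ROITimeSeries]:
    """Draw the synthetic cohort: one T x N time-series matrix per subject.

    Each subject receives an individually jittered copy of the planted
    correlation matrix (between-subject variability) and ``n_timepoints``
    multivariate-normal samples from it.  Fully reproducible from
    ``spec.seed``.
    """
    spec.validate()
    base = build_block_covariance(spec)
    labels = [f"ROI{i + 1:02d}" for i in range(spec.n_nodes)]
    cohort = []
    for s, seq in enumerate(subject_seeds(spec)):
        rng = np.random.default_rng(seq)
        cov = _jitter_covariance(base, spec.subject_sd, rng) if spec.subject_sd > 0 else base
        x = _sample_timeseries(cov, spec.n_timepoints, spec.ar_coeff, rng)
        cohort.append(
            ROITimeSeries(values=x, roi_labels=list(labels), subject_id=f"sub-{s + 1:02d}")
        )
    return cohort
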