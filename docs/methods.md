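# Methods

This note documents the models, conventions, and numerical choices behind
`signedfcn`, and what the synthetic validation does and does not
demonstrate.

## Network construction

Per subject, the T×N matrix of ROI signals is reduced to an N×N matrix of
partial correlations computed from the precision matrix of the sample
*correlation* matrix (not covariance): partial correlations are identical
either way, but working on the correlation scale is invariant to ROI
signal amplitude and keeps conditioning uniform. Plain inversion requires
T > N and a condition number below 1e10; otherwise the `shrinkage` flag
applies Ledoit–Wolf shrinkage toward the identity (via scikit-learn) on
the standardized signals. Regularisation is off by default since the
target study design (T = 165 > N = 36) does not need it.

Coefficients are clipped to |r| ≤ 1 − 1e−7 before `arctanh`, the diagonal
is fixed at 0 everywhere (self-connections are never used), and all
averaging and statistics happen on the z scale.

## Signed modularity Q*

Totals follow the ordered-pair convention: `v± = Σ_ij w±_ij` is twice the
upper-triangular sum, and node strengths are row sums of each sign layer.
Each layer is scored as Newman modularity,
`Q± = (1/v±) Σ_ij (w±_ij − s±_i s±_j / v±) δ(M_i, M_j)`, with the sum over
all ordered pairs including i = j in the null-model term (the weight term
is unaffected because the diagonal is zero). This is the convention under
which a one-module partition of an all-positive network scores exactly 0.

The combined objective is asymmetric, `Q* = Q⁺ − (v⁻/(v⁺+v⁻))·Q⁻`: the
negative layer contributes as a penalty scaled by the network's negative
weight share, making negative weights auxiliary to positive ones. If
v⁻ = 0, Q* = Q⁺ exactly; if v⁺ = 0, Q* = −Q⁻. A symmetric variant that
weights both layers by their share, `Q* = (v⁺Q⁺ − v⁻Q⁻)/(v⁺+v⁻)`, is
available via `convention="symmetric"`. The resolution parameter `gamma`
defaults to 1 and is exposed for sensitivity analysis.

### Maximisation

The optimiser is a Louvain-type greedy scheme run jointly on the two
layers: sweeps of single-node moves (accepted when the combined ΔQ* > 0,
ties broken to the first maximal candidate in label order, node order
randomised per sweep), agglomeration of modules into super-nodes with
self-loops, and — after each agglomeration ascent — a refinement loop of
single-node moves on the *original* graph, because nodes fused into an
aggregate could otherwise never individually leave a badly chosen module.

Restart 0 starts from singleton modules; subsequent restarts start from
uniformly random partitions with a random module count. Random starts
matter: on random signed instances there exist global optima whose basin
of attraction excludes the singleton start entirely, and with them the
optimiser matches exhaustive enumeration over all set partitions on every
small-network test instance (N ≤ 8, where enumeration is feasible). The
gain tolerance for accepting a move is 1e−12, which both breaks float ties
deterministically and prevents cycling.

`consensus_partition` stabilises repeated stochastic runs by thresholding
the co-assignment matrix and re-clustering it until all runs agree; if
nothing survives the threshold the nodes are returned as singletons.

## Centrality

Both generalized measures rescale the negative layer by the node-level
negative share `s⁻_i/(s⁺_i+s⁻_i)` (so positive connections dominate, and a
node with no negative connections reduces exactly to its positive
measure); the global share `v⁻/(v⁺+v⁻)` is available via
`scaling="global"`. Diversity uses the natural-log Shannon entropy of the
within-module strength fractions normalized by log m (any base cancels);
conventions: 0·log 0 = 0, zero-strength layers and single-module
partitions give h = 0. Hubs require *strictly* above-mean s* and h*, so a
degenerate profile with all nodes identical has no hubs.

## Reproducibility statistics

MI is normalized as `2I/(H(P)+H(Q))` with 0/0 := 0 (a single-module
partition carries no information and scores 0 against anything, including
itself); VoI is normalized by log N. Neither normalization is canonical in
the literature, so both are switchable (`normalization="none"` returns
nats). Null networks permute the upper-triangular weight multiset
uniformly (the complete-graph topology is trivially preserved, v± exactly
conserved); a `sign_preserving` variant permutes magnitudes within the
positive and within the negative edge positions, preserving each node's
signed degrees. One null realisation per network per run.

Subject-level reports partition each subject's network independently and
pool MI/VoI over all unordered pairs. Group-level reports repeat a seeded
random split into near-equal groups (sizes differ by at most 1 when the
cohort is not divisible), average FC within groups on the z scale,
partition each group-mean network, and pool over group pairs and
randomizations. The default is 1000 randomizations; the acceptance script
uses 50 with 10 optimiser restarts per partition, problem sizes at which
the report statistics are already stable to two decimals.

## Synthetic cohort generator

The generator emulates a sedated-rodent resting-state cohort: 40 subjects,
165 timepoints, 36 ROIs in six modules of sizes (5, 4, 8, 8, 3, 8),
within-module correlation 0.6, between-module baseline 0.05, and
correlation −0.2 between the two frontal/somatomotor-like blocks (modules
1 and 2) and the thalamic-like block (module 6) — anti-correlations exist
but are fewer than positive correlations, matching resting-state
phenomenology. Per-subject variability adds N(0, 0.05²) jitter to every
off-diagonal correlation. Samples are temporally i.i.d. Gaussian: every
downstream statistic uses only zero-lag partial correlation, so temporal
autocorrelation would change nothing; an AR(1) switch exists for users who
want serially correlated signals and defaults off.

Two positive-definiteness repairs are used, deliberately different:

* The *planted* block matrix is repaired by eigenvalue flooring (at 1e−4)
  plus rescaling to unit diagonal, and the construction fails if the
  repair would move any entry by more than 0.05 — a large repair means the
  requested correlation configuration was infeasible, and silently
  returning something else would falsify the planted structure. At the
  defaults no repair is needed (smallest eigenvalue 0.4).
* The *subject-jittered* matrices are repaired by shrinking toward the
  planted matrix just enough that the smallest eigenvalue stays at or
  above 0.75× the planted matrix's smallest eigenvalue. Flooring is the
  wrong tool here: entry-wise jitter of sd 0.05 on a 36×36 matrix has
  spectral norm ~0.6, so floored matrices become near-singular, and
  because partial correlation inverts the matrix, the "variability" then
  explodes into inversion noise that swamps the planted signal entirely.
  The blend repair keeps every entry between its jittered and planted
  value — jitter is attenuated when it threatens conditioning, never
  amplified — and keeps subject matrices about as well-conditioned as the
  planted one.

Seeding: per-subject generators are spawned from the master seed via
`numpy.random.SeedSequence`, so cohorts are bit-reproducible and adding
subjects does not perturb existing ones.

### What the synthetic validation shows — and does not

Passing tests demonstrate that the estimator chain (partial correlation →
z → averaging → Q* maximisation → centrality → MI/VoI) recovers a known
modular structure under Gaussian sampling noise and between-subject
covariance jitter, and that the reproducibility statistics separate
structure from permutation-null chance in the right direction at both
subject and group level. The generator does not model hemodynamics,
scanner noise spectra, motion or physiological confounds, and its planted
structure is deliberately strong: on this cohort every subject recovers
the planted partition exactly (subject-level MI = 1.0), which is cleaner
than typical in-vivo data, where subject-level agreement is substantial
but imperfect. Directional conclusions (observed MI above null, VoI below
null, group-level agreement at least subject-level) transfer; absolute
MI/VoI magnitudes do not.

A related desk-scale note: with T = 165 and N = 36 the sampling error of a
single partial correlation is ≈ 0.09, comparable to the planted
partial-correlation signal spread (sd ≈ 0.06 across edges), so the
between-group Pearson correlation of FC values over 630 edges plateaus
around 0.80 for groups of 10 regardless of how small the between-subject
jitter is; the tests assert this qualitative high-reproducibility anchor
with a stochastic tolerance.

## Parameter defaults

| parameter | default | meaning / rationale |
|---|---|---|
| `within_corr` | 0.6 | planted same-module correlation |
| `between_corr` | 0.05 | weak positive background coupling |
| `anti_corr` | −0.2 | coupling of the configured anti-correlated module pairs |
| `subject_sd` | 0.05 | sd of per-subject correlation jitter |
| `n_restarts` | 100 | optimiser restarts; 36-node networks converge well below this |
| `gamma` | 1.0 | modularity resolution |
| `n_groups` | 4 | group-split size of 10 mirrors a typical study design |
| `n_randomizations` | 1000 | grouping randomizations (50 in the acceptance script) |
| consensus `threshold` | 0.5 | co-assignment fraction required to survive |

## Known limitations

* Q* maximisation is a heuristic; global optimality is verified only where
  enumeration is feasible (N ≤ 8). For larger networks, restarts plus the
  refinement pass give reproducible, high-quality local optima.
* The Gaussian generator cannot probe robustness to heavy-tailed noise,
  temporal confounds, or mis-specified parcellations.
* Statistical testing of MI/VoI differences (beyond descriptive
  mean ± SD against nulls) is out of scope, as is overlapping or
  hierarchical community structure.
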