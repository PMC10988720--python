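# Methods

This note records the models, numerical choices and limitations behind
`plomcon`, in the order the pipeline runs.

## Feature quantities

A *feature* is a (protein, compartment) pair; its quantity at one time
point is the median, over all cells pooled across retained fields, of
the mean fluorescence of that protein's channel inside that
compartment.  The median (even counts: mean of the two central values)
is robust to the heavy right tail of per-cell intensities.  Fields
enter the pool only when their confluency — the fraction of the field
covered by segmented cells — lies in [0.20, 0.65], boundaries
inclusive; sparse fields segment unreliably and crowded fields merge
cells.  A feature missing at any time point is excluded from the table
(the network stage needs a complete K × T matrix) with a warning.

The five supported compartments are nucleus, nuclear membrane,
cytoplasm, plasma membrane, and the derived nucleus/cytoplasm ratio of
mean intensities, emitted only when both means are positive.  The ratio
is a translocation readout: it rises when a protein moves into the
nucleus even if total abundance is constant.

## Image analysis

Each channel arrives as a z-stack; analysis runs on the maximum
intensity projection.  Nuclei are detected on the smoothed nuclear
marker channel (Gaussian σ = 1 px, Otsu threshold, connected
components, regions < `min_area` = 40 px removed).  The light default
smoothing reflects that realistic inputs are already optically blurred;
heavier smoothing systematically dilates masks.  Cells are obtained by
marker-controlled watershed on the inverted smoothed cytoplasmic marker
channel, seeded by the nuclei and restricted to an Otsu foreground mask
(union the seeds).  Seeds propagate their label ids, so cell and
nucleus maps share ids and each cell contains exactly one nucleus by
construction; cells that nevertheless pair with zero or multiple nuclei
are dropped with a warning.  Compartments: cytoplasm = cell ∖ nucleus;
plasma-membrane ring = cell ∖ erosion(cell, w); nuclear-membrane ring =
(dilation(nucleus, w) ∖ erosion(nucleus, w)) ∩ cell, with ring width
w = `membrane_width` = 2 px (no width is standard; 2 px on 20×
confocal data spans the optical edge).  Cells touching the image border
are kept.  All label-map invariants (nucleus ⊆ cell, cytoplasm
disjoint from nucleus, rings inside the cell) are validated on every
output.

## Covariance and the graphical lasso

Feature trajectories are z-scored over time by default, making S the
correlation matrix: fluorescence units are arbitrary per antibody, and
an unstandardized covariance would be dominated by bright stains.  The
penalty weights in common use (0.9, 0.95) are only meaningful on the
correlation scale, which is why standardization is the default; a
zero-variance feature cannot be z-scored and is dropped with a
warning.  With T = 9 time points and K in the hundreds, S is singular
and only the penalized problem is well posed.

The estimator maximizes `log det Λ − tr(SΛ) − ρ‖Λ‖₁` with the penalty
on **all** entries.  The solver is block coordinate descent on the dual
covariance estimate W: cold start W = S + ρI (penalized-diagonal
stationarity fixes W_ii = S_ii + ρ exactly), then one row/column at a
time, each solved by coordinate-descent lasso (numba-compiled inner
loop).  Convergence is declared when the mean absolute update of Λ per
sweep falls below `tol` = 1e−5, with `max_iter` = 200 sweeps;
non-convergence raises, carrying the objective trace.  The per-sweep
primal objective is recorded; each column update solves its dual block
problem exactly and the recorded trace is nondecreasing on all tested
instances.  Zeros are exact (soft thresholding), so the sparsity
pattern is the conditional-independence graph; entries below 1e−8 are
treated as zero downstream.  The off-diagonal-only penalty variant is
available behind `penalize_diagonal=False` and cross-checks against
scikit-learn's estimator, which implements only that variant.

Two properties worth knowing: (i) when ρ exceeds every off-diagonal
|S_ij|, the estimate is exactly diagonal (KKT); (ii) as ρ → 0 with S
invertible, Λ → S⁻¹, but the optimum at a finite ρ is biased away from
S⁻¹ by O(ρ‖S⁻¹‖²) — inversion-oracle comparisons are meaningful only on
well-conditioned instances.

## Blockwise protein adjacency

Partial correlations P_ij = −Λ_ij/√(Λ_ii Λ_jj) (diagonal 1) are reduced
to proteins by scanning each between-protein block of P for its extreme
entry.  Default is the largest **absolute** value with sign retained —
a strong negative partial correlation is still covariation; the
largest-signed-value reading is available as `block_mode="signed"`.
Ties break to the lexicographically smallest (compartment_i,
compartment_j) pair, making the reduction deterministic.
Within-protein blocks are ignored; the compartment pair attaining each
maximum annotates the edge.

## Overlapping clustering and dense modules

Clustering runs on unweighted topology (an edge either survived the
penalty or did not).  Seeds are maximal cliques (enumeration budget
10⁵, beyond which edge seeds are used).  The cluster system's
modularity is the sum over clusters C of
(1/2m) Σ_{i≠j∈C} (A_ij − k_i k_j / 2m); pairs shared by several
clusters contribute once per cluster, which is what lets clusters
overlap.  Fusion is greedy on modularity gain with deterministic
lexicographic tie-breaking, and a cluster that becomes a subset of a
fused cluster is absorbed, with its removed contribution charged to the
gain — without this, nested seed classes double-count and the trace
would not be exact.  Merging stops when no fusion strictly increases
modularity; decomposing a clique into its edges leaves modularity
unchanged, so edge seeding can terminate at the same modularity with
finer clusters.  Dense modules are clusters whose induced-subgraph mean
degree strictly exceeds the network's mean degree.

## Two-condition differencing

Each condition is estimated from its own time course alone.  At one ρ,
edges partition into lost (control only), gained, retained.  Across a
ρ grid, a protein pair is *lost* when it carries an edge in at least
one control network and in no treated network; per-pair multiplicities
(count of per-ρ edges on each side) are reported.  No significance is
attached to a difference — that would need replicate time courses.

## Synthetic data

The generator defines the study conditions the tests run under:
36 proteins, compartment subsets cycling through sizes 2–5 per protein
(K = 126 features), 9 time points at 0.5–8 h, two conditions, baseline
100 intensity units, 8 shared latent factors (3–6 member features,
loadings 15–30 either sign), one condition-specific factor (loading 40
on two nuclear features) planting the control-only edge, and Gaussian
noise σ = 4 truncated at zero.  Factor trajectories are standardized
random cubics over the time grid — covariation over a 9-point course
needs low-frequency structure, which white noise lacks.  Trajectories
depend on the seed but not the condition, so a seed's two tables share
their common structure; noise draws are per condition.  Planted
loadings sit well above noise because the planted contrast is the
qualitative ground truth the differencing stage is judged against.

Scenes are flat-disk cells (radius 14 px, nucleus 6 px) with
min-separation rejection sampling, rendered to ≥ 2 z-planes with
plane-dependent attenuation, Gaussian blur σ = 2 px and Poisson noise;
ground-truth masks and pixel-counted confluency come for free.  Scene
defaults use tens of cells per field — full-well scale is an
acquisition choice, not a property of the algorithms.  Expression
matrices are per-gene lognormal baselines with multiplicative
treated-group shifts of 2^log2FC and lognormal noise (σ_log = 0.1).

What the generator does **not** emulate: uneven illumination, antibody
cross-reactivity, out-of-focus light, cell-cycle heterogeneity,
segmentation-error correlation between channels, and array detection
dropouts.  Passing tests show the algorithms recover what was planted
under these idealized conditions, not that a particular biological
network is correct.

## Expression prefilter

Each sample is rescaled so the median of its detected signals is
exactly 25 (idempotent; zero median raises).  Group summary is the
arithmetic mean of normalized signals (3 vs 3 samples; mean vs median
is immaterial at n = 3 and mean is the documented choice); a gene is up
when mean_treated/mean_control ≥ 1.5 and down when ≤ 1/1.5, both
inclusive.  Genes with zero control mean are excluded and reported.
Detection flags default to all-detected for synthetic data.

## Problem sizes and determinism

Test and acceptance runs use: 100 random correlation instances (K ≤ 6)
for solver oracles, 2 × 10⁵ brute-force candidates at K = 2, 3, 50
simulated two-condition experiments at full study scale for the
planted-edge loss rate, and 100 scenes of 8 cells at 256² for
segmentation fidelity — sizes at which every check is exercised at full
fidelity while the whole suite stays interactive.  All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; no
global random state is touched, and same-seed reruns are bit-identical
up to filesystem timestamps.

## Known limitations

- One network per condition; no joint or time-lagged estimation, no
  model selection for ρ, no edge confidence intervals.
- Segmentation is 2D on projections; overlapping cells in z are not
  separable.
- The OCG variant's seeds and stopping rule are documented choices;
  other variants (centered cliques, target class counts) would give
  different, equally defensible clusterings.
- The blockwise reduction keeps only the extreme entry per protein
  pair; multi-compartment covariation between the same pair is visible
  only through the per-ρ multiplicity counts.
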