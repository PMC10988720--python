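# plomcon

Protein covariation networks from time-course immunofluorescence
features.

High-content imaging of a panel of immunostained proteins yields, for
each protein, a mean fluorescence intensity in each subcellular
compartment (nucleus, nuclear membrane, cytoplasm, plasma membrane,
and the nucleus/cytoplasm ratio) at each time point after a
perturbation.  When two proteins respond to the same signalling events,
their feature quantities co-vary over the time course.  `plomcon` turns
such per-compartment feature trajectories into a sparse
partial-correlation network over proteins — a covariation network —
and reports how that network changes between two conditions (e.g.
vehicle control vs drug treatment), which is a way to read a compound's
mechanism of action off imaging data.

The package covers the whole chain for anyone doing this kind of
analysis: a ground-truthed synthetic microscopy generator, image
feature extraction (projection, segmentation, compartment features,
medians), network estimation, overlapping graph clustering, network
differencing, and the companion microarray prefilter (global median
normalization and a fold-change gate).

## The model

Let x ∈ R^K collect the per-timepoint median feature quantities of K
(protein, compartment) features, observed at T time points.  With
S the sample covariance of the (by default z-scored) trajectories, the
precision matrix Λ = Σ⁻¹ is estimated by the graphical lasso:

    max_Λ  log det Λ − trace(SΛ) − ρ‖Λ‖₁

with the L1 penalty over all entries of Λ (diagonal included).  The
penalty weight ρ sets network sparsity.  Partial correlations follow as

    P_ij = −Λ_ij / √(Λ_ii Λ_jj),

so P_ij ≠ 0 exactly where the two features remain dependent given all
others.  P is then reduced to a protein-level adjacency: for each
protein pair, the feature-level block of P is scanned and the entry of
largest absolute value (sign retained) becomes the edge weight,
annotated with the compartment pair that attained it.  Networks are
clustered with an Overlapping-Cluster-Generator-style algorithm
(maximal-clique seeds, greedy modularity-gain fusion; nodes may belong
to several clusters), and clusters whose within-cluster mean degree
2|E_C|/|C| exceeds the network's mean degree 2|E|/|V| are reported as
dense modules.  Two conditions are compared by classifying each protein
pair as lost, gained, or retained.

## Worked example

```python
from plomcon import CovariationModel, default_study_spec, generate_timecourse_features

spec = default_study_spec()                       # 36 proteins, 9 time points, planted structure
control = generate_timecourse_features(spec, "control", seed=1)
res = CovariationModel(control).fit(rho=0.9)
print(res.summary())
```

```
Covariation Network Results
==============================================
condition                              control
features (K)                               126
proteins (M)                                36
time points (T)                              9
penalty rho                                0.9
standardized                              True
sweeps to converge                           3
penalized log-likelihood               -206.79
protein edges                               75
network mean degree                      4.167
==============================================
strongest edges (|partial correlation|):
  P17[cytoplasm] -- P23[nuclear_membrane]  +0.044
  P01[nucleus] -- P02[nucleus]  +0.043
  ...
```

K = 126 features over 36 proteins were estimated from 9 time points at
ρ = 0.9; 75 protein pairs keep a nonzero partial correlation, each
annotated with the compartments that carried it.  The generator planted
a control-only latent factor linking the nuclear features of P01 and
P02 — visible above among the strongest edges.  Comparing against the
treated condition reports exactly that edge as lost:

```python
treated = CovariationModel(generate_timecourse_features(spec, "treated", seed=1)).fit(rho=0.9)
diff = res.compare(treated)
("P01", "P02") in diff.lost        # True
```

The same stages are available as a CLI (`plomcon simulate | segment |
features | network | cluster | compare | normalize | defilter |
run-all`); `plomcon run-all --outdir out` writes feature tables,
per-rho precision/partial-correlation matrices, GraphML networks,
cluster JSON, the difference report, and a provenance record with
checksums.

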