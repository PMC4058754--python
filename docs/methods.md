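# Methods

This note documents the model implemented by `agdist`, the defaults and
why they were chosen, the synthetic validation design, and known limits.

## Network construction

A subject's network is built from the in-mask voxel time series alone.
Voxel activity is mean squared amplitude, P(T) = (1/n) Σ tᵢ²; since the
intended inputs are bandpass-filtered (hence near zero-mean), this is
effectively the series variance and no demeaning is applied before the
power computation. Powers are min–max normalized to [0, 1] per subject;
a constant power map degenerates to all zeros by convention.

Percentile selection uses the nearest-rank rule: the top
⌈(1 − p/100)·n⌉ voxels are kept and every voxel tied with the cutoff
value is kept with them (so a fully tied input selects everything).
Whether normalization happens before or after ranking is immaterial — the
transform is monotone — but normalization comes first for definiteness.
The default percentile is 98.

Nodes are ROI clusters of selected voxels: ROI identity, not spatial
contiguity, defines the cluster. A node's power is the mean of its
members' *normalized* powers, which keeps node power in [0, 1] and
consistent with the [0, 1] normalization of the distance components. ROIs
with no selected voxel are simply absent, so node counts vary across
subjects — the distance below is designed for that. With the per-ROI
selection variant (used by the fixed-length baseline features), every ROI
containing at least one in-mask voxel yields a node, fixing node counts
across subjects.

Edges are positive Pearson correlations of node mean series at or above
corrTh; negative and absolute-value variants are out of scope. A
zero-variance mean series has an undefined correlation; it is defined as
0 with a warning, which guarantees such a pair never crosses any
practical threshold. Nodes left edgeless by the threshold are kept: their
power and position still inform the matching.

## Graph distance

The distance between two graphs is the minimum total cost of injectively
assigning the smaller graph's nodes to the larger one's, solved exactly
with the Hungarian algorithm at the ~60-node scale this pipeline
produces. Node-pair costs weight five [0, 1] components with
W = (0.2, 0.1, 0.2, 0.1, 0.4): spatial mismatch carries the largest
weight so anatomically distant nodes rarely match; own-node degree and
power gaps weigh twice their neighbor-profile counterparts.

Degree and power gaps are normalized by the maximum weighted degree and
maximum node power over all nodes of all *training* graphs; test-set
values beyond those maxima are clamped so components stay ≤ 1. A
degenerate all-zero maximum is guarded by substituting 1. Normalization
constants are computed per training cohort (per site), matching the
per-site protocol. Neighbor profiles are compared positionally after
descending sort and zero padding; the denominator uses the *padded*
length, which keeps the component in [0, 1] for any pair of profiles.

The spatial component is the sigmoid d₅ = 1/(1 + 300·e^(−δ/4)) of the
Euclidean gap δ in world mm: ≈ 1/301 at δ = 0, 0.5 at δ = 4·ln 300
≈ 22.8 mm, → 1 far apart — strictly increasing, so coincident nodes are
maximally matchable and distant ones are penalized. A variant with the
opposite exponent sign (which *decreases* with distance) exists behind
`SpatialConfig(printed_variant=True)` for comparison only; it contradicts
the measure's intent and is never used by the pipeline. The constants 300
and 4 have no sensitivity analysis behind them and are config-exposed.

Because even a perfect self-matching pays the 1/301 sigmoid floor per
node, the raw self-distance of an N-node graph is N·0.4/301 rather than
zero. The pairwise matrix therefore forces its diagonal to 0 — a metric
embedding needs zero self-dissimilarity — and logs the raw value. The
total assignment cost is used un-normalized as the distance; a
per-node-count normalization exists but is off by default. Ties among
equally optimal assignments are broken arbitrarily: only the total cost
is consumed downstream, and it is unique.

## Embedding and classification

MDS minimizes the metric stress
√(Σ_{i<j}(D_ij − ‖xᵢ−xⱼ‖)² / Σ_{i<j}D²_ij) by SMACOF majorization from
the classical (Torgerson) initialization; stress is provably
non-increasing per iteration, and iteration stops at a relative stress
change below 1e-8 or at the 100 000-iteration cap. Two dimensions are the
default working space. The embedding never sees labels, so computing it
once per cohort before leave-one-out classification leaks nothing;
per-fold re-embedding would only add noise and cost.

Classification uses a polynomial-kernel SVM, (x·y + 1)³ with C = 1, on
standardized embedding coordinates — the kernel form, degree and unit box
constraint mirror the defaults of the classic MATLAB implementation this
protocol descends from, including its autoscaling. Class imbalance is
deliberately left unweighted. Test cohorts enter through a joint
transductive embedding of the train+test distance matrix (train-only SVM
supervision); an out-of-sample interpolation was considered and left
unimplemented since the protocol gives no mechanism for it.

The evaluation protocol sweeps corrTh over {0.30, …, 0.90} in steps of
0.10, scores each (site × group) training cell by LOOCV, discards
degenerate cells (specificity or sensitivity exactly 0 — the classifier
collapsed onto one class), carries the best surviving threshold to the
test split, and pools sex-stratified rates subject-weighted, the same
weighting used for cross-site averages. Groups with fewer than 4 subjects
(or fewer than 2 per class) are skipped with a warning.

## Baseline features

Degree, m-step generalized topological overlap (default m = 5, per-node
value = row mean of the pairwise overlap matrix — the per-node reduction
is this package's choice), clustering coefficient, local efficiency and
the rich-club curve φ(k) for k = 0..K (K = the maximum training degree)
are computed on binarized graphs, the baseline form of the standard
toolbox measures; weighted variants are out of scope. The rich club uses
the strict form — nodes of degree > k — and encodes φ as 0 when fewer
than 2 nodes qualify. Global per-subject features (density, global
efficiency, rich club at a single k, fraction of nodes with power >
powTH = 0.85) support correlation of features with embedding axes.

## Synthetic cohorts

The generator emulates what the pipeline assumes about its inputs, not
BOLD biophysics. On a 12×12×12 grid (4 mm voxels) a spherical mask of
~840 voxels contains 8 compact ROI blobs of 20 voxels each plus an
unlabeled margin. Latent per-ROI series are zero-mean draws from a
group-dependent correlation matrix — two blocks with within-block
correlation 0.35 and cross-block 0.05, the case group's four paired
cross-block entries shifted up by `effect_size` — optionally AR(1)
smoothed (coefficient 0.3) to mimic the temporal smoothness of filtered
BOLD while preserving the marginal covariance. Positive definiteness is
checked and a too-large shift fails with advice to lower the effect.

Two percent of mask voxels (matching the 98th-percentile selection),
spread round-robin across ROIs, carry their ROI latent at amplitude 3
plus N(0, 0.5²) voxel noise; all other in-mask voxels are pure noise.
The ~36:1 power ratio makes the selection step near-deterministic, which
is intentional: it isolates the downstream machinery from selection
noise. Defaults are 20 subjects per group and 120 timepoints. Sexes
alternate within groups and carry no effect unless the `sex_effect` knob
is turned, which exists to exercise the stratified protocol.

What passing synthetic tests shows: the pipeline recovers planted
connectivity differences (mean LOOCV detection ≥ 85% at effect 0.6 over
five seeds at these sizes) and stays at chance on null cohorts. What it
does not show: performance on real rs-fMRI, where ROI boundaries are
imperfect, noise is structured (motion, physiology), effects are far
smaller, and site heterogeneity dominates — the real-data accuracies this
protocol reports live in the 60–75% range, not the ~100% the clean
synthetic construction allows.

## Numerical choices and degenerate inputs

- Percentile rank uses a 1e-9-cushioned ceiling so exact fractions are
  not inflated by floating-point error.
- Pearson correlations are clipped to [−1, 1]; zero-variance series give
  0 with a warning.
- All-zero dissimilarity matrices are rejected by the embedding (stress
  is undefined there).
- A collapsed classical MDS initialization is replaced by tiny seeded
  jitter; all randomness elsewhere flows through explicit seeds, and
  reruns are bit-identical.
- Profile distances clamp at 1 to absorb test-set values beyond training
  maxima.

## Problem sizes

Validation runs use cohorts of 12–40 subjects, 8 ROIs, 80–120 timepoints
and up to five seeds per claim — large enough for the binomial noise
bounds asserted in the tests, small enough that the whole suite and the
acceptance script each complete in well under a minute on one CPU.

## Known limitations

- No out-of-sample embedding: scoring new subjects requires recomputing
  the joint embedding.
- The node-signature weights, sigmoid constants and SVM hyperparameters
  are fixed conventions, not fitted quantities; no tuning interface is
  provided beyond the config dataclasses.
- The distance is not guaranteed to satisfy the triangle inequality;
  metric-stress MDS tolerates this but classical interpretation of the
  axes should be cautious.
- Multi-class (subtype) labels, negative-correlation networks and
  weighted baseline features are out of scope.
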