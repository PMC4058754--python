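# agdist

Attributed-graph distances for resting-state fMRI functional connectivity
networks, with the full embedding-and-classification pipeline built on top.

## The problem

Resting-state fMRI gives one BOLD time series per voxel. A common way to
compare subjects — for example ADHD patients against typically developing
controls — is to summarize each brain as a functional connectivity network
and look for topological differences between groups. Most approaches reduce
each network to a vector of graph statistics; this package instead compares
the networks *directly*, through a distance defined between attributed
graphs, and only then maps subjects into a low-dimensional space for
classification. It is aimed at researchers who have preprocessed
(motion-corrected, registered, bandpass-filtered) 4D volumes, a brain mask
and an ROI parcellation, and want subject-level predictions rather than
group-level statistics.

## The method

For each subject:

1. **Voxel selection.** Each in-mask voxel's activity is its time-series
   power P(T) = (1/n) Σᵢ tᵢ²; powers are min–max normalized to [0, 1] and
   the voxels at or above the 98th percentile are kept.
2. **Nodes.** Selected voxels are clustered by the ROI label they fall in;
   each ROI with at least one selected voxel becomes a node carrying the
   mean member time series, mean world coordinate and mean normalized
   power. Node counts therefore vary across subjects.
3. **Edges.** Node pairs whose mean-series Pearson correlation is positive
   and ≥ corrTh are connected, with the correlation as the edge weight.
4. **Signatures.** Every node n gets the descriptor
   ⟨deg(n), deg(ngh(n)), pow(n), pow(ngh(n)), coord(n)⟩ — weighted degree,
   descending-sorted neighbor degrees, power, descending-sorted neighbor
   powers, coordinate.

Two graphs are compared by the minimum-cost assignment (Hungarian
algorithm) of the smaller graph's nodes onto the larger one, where a node
pair costs

    dist(v₁, v₂) = W · [d₁, d₂, d₃, d₄, d₅]ᵀ,   W = [0.2, 0.1, 0.2, 0.1, 0.4]

with d₁/d₃ the degree/power gaps normalized by the training-set maxima,
d₂/d₄ positional L1 gaps of the zero-padded neighbor profiles, and
d₅ = 1/(1 + 300·e^(−‖c₁−c₂‖/4)) a sigmoid of the inter-node distance in mm
that discourages matching nodes from different brain regions. The total
assignment cost is the inter-subject distance.

The symmetric distance matrix is embedded in 2D by metric-stress MDS
(SMACOF, classical initialization), and subjects are classified in the
projected plane with a polynomial-kernel SVM: leave-one-out
cross-validation on training cohorts, and a joint (transductive) embedding
with train-only supervision for test cohorts. Networks are rebuilt over
corrTh ∈ {0.30, …, 0.90}; the best non-degenerate training threshold is
carried to the test split. Standard graph features (degree, m-step
topological overlap, clustering coefficient, local efficiency, rich-club
curve) are included as baselines, together with the global features used
to interpret the embedding axes.

A synthetic-cohort generator (`agdist.synthetic`) produces volumes, masks,
atlases and phenotype tables with planted group-dependent ROI correlation
structure, so the whole pipeline can be exercised and validated without
any imaging download.

## Worked example

```python
from agdist import (SyntheticCohortConfig, make_atlas, simulate_cohort,
                    extract_voxel_series, build_graph, NetworkConfig,
                    GraphClassificationModel)

cfg = SyntheticCohortConfig(n_per_group=10, effect_size=0.6, seed=3)
atlas, mask = make_atlas(cfg)
graphs, labels = [], []
for vol, rec in simulate_cohort(cfg):
    vs = extract_voxel_series(vol, mask, atlas)
    graphs.append(build_graph(vs, cfg=NetworkConfig(corr_threshold=0.5),
                              subject_id=rec.subject_id))
    labels.append(rec.label)

model = GraphClassificationModel.from_graphs(graphs, labels)
print(model.fit(method="loocv").summary())
```

prints

```
Graph classification results
==============================================
protocol            loocv
subjects scored     20
embedding dims      2
embedding stress    0.077508
detection rate      90.00%  (95% CI 69.90-97.21)
specificity         90.00%
sensitivity         90.00%
degenerate          False
==============================================
```

Twenty simulated subjects (10 controls, 10 cases with a 0.6 shift planted
on cross-block ROI correlations) are built into attributed graphs, matched
pairwise, embedded, and scored by leave-one-out cross-validation: 18 of 20
subjects are labeled correctly, with the same accuracy on both groups; the
stress value says the 2D embedding reproduces the graph distances to
within about 8%.

The same pipeline is scriptable from the shell: `agdist simulate`,
`agdist build`, `agdist embed`, `agdist classify` and `agdist sweep`
(see `agdist --help`).

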