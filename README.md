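# idgcn — invertible dynamic graph convolutional networks for brain connectivity

`idgcn` classifies subjects from functional brain-connectivity features while
staying fully *reconstructible*: the network's pre-classifier output can be
inverted exactly back to its input features, so the evidence the classifier
uses can be mapped onto specific connectivity edges. It is aimed at
neuroimaging researchers who want a connectome classifier whose decisions can
be interrogated edge-by-edge and node-by-node, and at methodologists who need
a compact, fully testable reference implementation of invertible spectral
graph networks.

## The model

Each subject is a graph over N atlas ROIs. From the ROI time series the
package computes the static Pearson correlation matrix `X` (row i = node i's
feature vector) and a dynamic auxiliary feature `F_t`: the per-edge standard
deviation of correlations over sliding windows. Per ROI, a random forest
pre-screens the `N-1` static features down to `M` and the dynamic features
down to `J`, giving an `N x (M+J)` input.

Two k-nearest graphs carry the convolution: a *functional* graph (strongest
|correlation| neighbours) and a *spatial* graph (nearest centroids, edges
weighted by |correlation|). On a graph with adjacency `A`, features are
filtered with Chebyshev polynomials of the rescaled normalized Laplacian

    L  = I − D^{−1/2} A D^{−1/2},   L~ = (2/λ_max) L − I,
    X_out = σ( Σ_{k=0}^{K−1} T_k(L~) · X_in · W_k ),   T_k = 2 L~ T_{k−1} − T_{k−2}.

Spatial-graph and functional-graph convolutions (φ and ω) are coupled inside
additive invertible blocks:

    y1 = x1 + φ(x2),  y2 = x2 + ω(y1),  z1 = ½(y1+y2),  z2 = ½(y2−y1),

which invert exactly for *any* φ, ω. Three blocks are stacked (the first
receives the same features on both lanes); a fully connected softmax layer
with a one-hot acquisition-site covariate produces class probabilities, and
training minimises mean cross-entropy. Because everything before the FC layer
is invertible, masking all but the most class-discriminative output units and
inverting the stack reconstructs exactly the input features that carry the
decision — the basis of the edge-importance report. A complementary lesion
analysis removes one ROI at a time (features zeroed, node isolated in both
graphs, models retrained per fold) and scores it by the cross-validated
accuracy drop.

Evaluation uses stratified 5-fold cross-validation with accuracy, AUC,
precision, recall and F1 from the confusion counts; the supervised screening
is refit inside every training fold.

## Worked example

```python
from idgcn import CohortSpec, generate_cohort, cross_validate, TrainConfig

cohort = generate_cohort(CohortSpec(
    n_subjects_per_class=40, n_rois=20,
    informative_edges=[(0, 1), (2, 3), (4, 5)],
    static_effect=0.6, seed=7,
))
cv = cross_validate(
    cohort,
    TrainConfig(epochs=300, learning_rate=0.01, weight_decay=1.0),
    M=8, J=4, k=3, K=3, folds=5, seed=0, rf_trees=150,
)
print(f"accuracy {cv.mean['accuracy']:.4f} +- {cv.sd['accuracy']:.4f}")
print(f"auc      {cv.mean['auc']:.4f}")
```

prints

```
accuracy 0.9875 +- 0.0250
auc      0.9875
```

— a cohort with a planted correlation shift of 0.6 on three edges is almost
perfectly separable, while the same pipeline on a null cohort (no planted
effect) stays at chance level (accuracy ≈ 0.5). The fold models, screening
selections and per-fold metrics in `cv` feed directly into
`reconstruction_edge_importance` and `lesion_node_importance`, which return
ranked edge lists and per-ROI accuracy drops.

The same pipeline runs from the shell:

```bash
idgcn simulate --out cohort/ --subjects-per-class 30 --edges 0-1,2-3 --static-effect 0.6
idgcn run --manifest cohort/manifest.tsv --data-dir cohort/timeseries \
          --coords cohort/coords.tsv --out results/ --m 8 --j 4
```

writing `metrics.tsv`, `selection.tsv`, `checkpoint.npz`,
`importance_edges.tsv` and `run.log`, each stamped with the config hash and
seed.

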