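# Methods

## Model and assumptions

The classifier operates on per-subject functional connectivity. Its central
design constraint is *exact invertibility up to the final linear layer*:
every transformation between the screened input features and the flattened
pre-classifier output is an additive coupling block

    y1 = x1 + φ(x2),  y2 = x2 + ω(y1),  z1 = ½(y1 + y2),  z2 = ½(y2 − y1),

whose inverse (y1 = z1 − z2, y2 = z1 + z2, x2 = y2 − ω(y1), x1 = y1 − φ(x2))
is algebraic and holds for arbitrary φ and ω — no invertibility condition on
the inner functions is needed, and ReLU activations inside φ/ω are fine. φ is
a Chebyshev graph convolution on the spatial k-nearest graph, ω on the
functional k-nearest graph; both preserve the feature dimension, as the
additive coupling requires. Three blocks are chained, block b > 1 consuming
the (z1, z2) of block b − 1. This wiring keeps the whole pre-FC network
invertible; note that the ½(y1 ± y2) lane mixing is *not* idempotent, so with
zero-weight blocks the stack is not the identity (three zero blocks map x to
(0, −x/2)) — only the round trip is exact, which is the property the
interpretation relies on.

Assumptions worth stating explicitly:

- Connectivity is Pearson correlation; nodes are exchangeable given the
  graphs, and group differences are expressed as correlation shifts on edges.
- Graph weights are |r|. The normalized Laplacian needs non-negative degrees,
  and magnitudes keep strong anti-correlations in the graph. Functional
  neighbour selection therefore also ranks by |r|.
- The site covariate enters only the FC layer, as a one-hot column appended
  to the flattened block output; with a single site it degenerates to a
  constant column.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `M` | static features kept per ROI | 48 (`RunConfig`) | reference setting for a 110-ROI atlas; must be ≤ N−1, so desk-scale cohorts (N = 20) use 4–8 |
| `J` | dynamic features kept per ROI | 10 | reference setting; ablation arm sets 0 |
| `k` | neighbours per node in both graphs | 3 | reference setting; sparsifies to the most reliable connections |
| `K` | Chebyshev order | 3 | reference setting; receptive field of 2 hops |
| `window_length`, `stride` | sliding-window sampling (time points) | 30, 10 | common dynamic-connectivity practice; unconstrained otherwise, so both are exposed in the config |
| `rf_trees` | trees per screening forest | 500 | stable impurity importances; reduced in large seed-sweep experiments where stability is averaged anyway |
| `TrainConfig` | optimizer, lr, epochs, weight decay | adam, 1e-3, 100, 0 | conservative defaults; the experiment configs below override them |

Temporal variation is summarised as the *population* (divide-by-n) standard
deviation of windowed correlations per edge; variance or a coefficient of
variation would also be defensible, but only the ranking of features matters
downstream.

λ_max is computed exactly per graph by an eigensolver rather than the common
λ_max ≈ 2 shortcut, since the rescaling definition uses the true maximum;
an edgeless graph (L = I) takes the conventional λ_max := 2, making L~ = 0.

## Training regimes

All gradients are analytic (the layer, block and stack backward passes are
hand-derived and verified against central differences to < 1e-4 relative
error). Weight decay is *decoupled* from the adaptive moments (AdamW-style);
fed through Adam's normalizer, L2 loses most of its effect.

Two regimes are used deliberately, and the difference is a real property of
reconstruction-based interpretation, not a tuning accident:

- **Classification regime** (`CLASSIFIER_CONFIG`: Adam, lr 0.01, 300 epochs,
  decay 1.0): best held-out accuracy, including on weak nonstationary
  signals. Adam solutions, however, spread the class-discriminative FC weight
  over many correlated output units.
- **Interpretable regime** (`INTERPRET_CONFIG`: plain gradient descent,
  lr 0.5, 800 epochs, decay 0.2): gradient descent with L2 converges to the
  regularized optimum, which concentrates FC weight on the genuinely
  informative units and keeps block weights small, so the masked-inverse
  reconstruction localizes on the true edges. The L2-regularized convex
  reference (logistic regression on the same screened features) shows the
  same localization, which is what motivates this regime.

Masked reconstruction ranks pre-FC units by |w₁ − w₀| of their FC rows,
keeps the top fraction (default 10%), zeroes the rest, inverts the stack and
averages absolute reconstructed magnitudes per (ROI, slot); slot scores are
scattered to edges through the screening map and symmetrised by max. With
top fraction 1 this provably returns the mean |input| per slot (the
invertibility limit), so the importance signal comes entirely from the
masking. Gradient-based saliency would be a reasonable alternative scoring.

The lesion analysis zeroes the lesioned ROI's feature row *and* any selected
feature slot sourced from that ROI (those slots are correlations with the
excluded node), isolates the node in both graphs, rebuilds the Laplacians,
retrains the fold models on the baseline fold splits and selections, and
scores the ROI by the drop in mean cross-validated accuracy.

## Synthetic data: what it emulates and what it does not

The generator plants group differences on a known sparse edge set. Each
informative edge (i, j) with target correlation ρ gives both ROIs a shared
standard-normal latent with loading √ρ plus independent noise scaled to unit
variance, so the population correlation is exactly ρ; class 1 shifts ρ by
`static_effect`. A `dynamic_effect` d > 0 multiplies the class-1 latent by a
slow sinusoid 1 + d·sin(2πt/P + phase), normalised so E[w²] = 1 — the
full-length correlation is unchanged and only the *windowed* correlations
fluctuate, which is exactly the signal the dynamic features summarise.
Sites are assigned round-robin with a small constant offset added to the
series (0.1·noise_sd per site step); a time-constant offset is invisible to
correlation, so it exercises the site-covariate plumbing without confounding
the features. ROI centroids are uniform in a 140×170×140 mm box; only
relative distances matter for the spatial graph.

Not emulated: hemodynamic response shapes, autocorrelated scanner noise,
head motion, site-specific covariance structure, negative planted
correlations (the shared-latent construction is non-negative), or realistic
small-world topology. Passing tests therefore demonstrate that the pipeline
recovers the *kind* of structure it assumes — planted correlation shifts and
planted nonstationarity under Gaussian noise — not that it would achieve any
particular accuracy on real multi-site data.

## Validation experiments (problem sizes)

`idgcn.experiments` freezes the reference designs; the test suite and
`scripts/acceptance.py` both run them.

- *Invertibility*: 100 random 3-block parameterizations at N = 20, F = 58;
  worst round-trip error must be ≤ 1e-9 (double precision).
- *Spectral equivalence*: ≥ 50 random graphs, N ≤ 12, K ≤ 6; polynomial
  layer vs eigendecomposition oracle ≤ 1e-8.
- *Screening recovery*: 3 planted edges, shift 0.5, 100 subjects/class,
  M = 5, 20 seeds; all planted columns recovered in ≥ 90% of seeds. Null
  control: 200 null cohorts (10 ROIs, 30/class); selected positions tested
  for uniformity by chi-square at α = 0.01.
- *Learnability*: shift 0.6 on 3 edges, 40/class, M = 8, J = 4 → mean 5-fold
  CV accuracy ≥ 0.85; matched null cohort stays inside the binomial 95% band
  around 0.5.
- *Dynamic ablation*: no static shift, modulation amplitude 1.0, series
  length 200, 100/class; J = 10 must beat J = 0 by more than one CV SD.
  (Shorter series make the SD-over-windows estimator too noisy for a stable
  margin; 18 windows at length 30/stride 10 suffice.)
- *Edge recovery*: 20 runs, shift 0.6, 30/class, M = 6, interpretable
  regime; all three planted edges inside the reconstructed top-10% list in
  ≥ 80% of runs.
- *Lesion contrast*: a single planted edge (12 ROIs, 30/class) so that
  excluding either planted ROI removes the whole class signal; the median
  accuracy drop of planted ROIs must exceed that of null ROIs.

## Numerical choices and degenerate inputs

- Reconstruction paths run in float64 end to end.
- Zero-variance ROIs: correlation row/column set to 0 (diagonal included)
  with a warning, keeping shapes stable across subjects.
- k-NN ties break toward the lower ROI index; symmetrization is by union, so
  every node keeps at least k neighbours.
- Isolated nodes use D^{−1/2} = 0, leaving L_ii = 1.
- Cross-entropy probabilities are clipped to [1e-12, 1 − 1e-12].
- AUC is the normalized Mann–Whitney statistic of the class-1 scores;
  single-class folds report AUC as NaN (excluded from aggregates).
- Training aborts with a diagnostic on non-finite loss.

## Known limitations

- The numpy implementation is desk-scale: full-batch training over a few
  hundred subjects with N ≲ 50 ROIs is comfortable; a 110-ROI, 867-subject
  study is feasible but slow, and no GPU path exists.
- Interpretation quality depends on the training regime (above); a model
  trained purely for accuracy may spread its evidence across units, in which
  case the reconstructed edge ranking is diffuse. This is inherent to
  post-hoc inversion of overparameterized models.
- The lesion analysis retrains N × folds models and is the most expensive
  step; it reuses the baseline screening selections rather than refitting
  them under the lesion.
- Negative target correlations and effects that reduce |r| are outside the
  generator's current construction.
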