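# Methods

## Model

`wakesleep` implements a layered Helmholtz machine whose units are
multicompartment neuron models.  A network has a stimulus layer `r^(0) = s`
(flattened image, pixels in [0, 1]) and hidden layers `r^(1) .. r^(L)` with
widths ascending from the sensory side (default `[32, 16, 6]`).  Every unit
carries two sets of dendritic branches:

* **basal (recognition)**: the bottom-up drive of unit *i* in layer *l* is

  `h_i = phi( sum_n w_in * phi_d(W_in r^(l-1) + c_in) + b_i )`

* **apical (generative)**: the top-down drive is the mirror image,

  `mu_i = phi( sum_n m_in * phi_d(M_in r^(l+1) + d_in) + a_i )`

`phi_d` is tanh followed by batch normalization with a learnable per-branch
affine; `phi` is tanh followed by batch normalization constrained to zero
mean and unit variance across the batch with no affine, which pins the
scale of unit activity and prevents a scale indeterminacy between the two
pathways.  Branch conductances `w, m` are kept strictly positive by storing
an unconstrained pre-parameter and mapping it through softplus; updates act
on the pre-parameter through the chain rule, so positivity survives any
additive update without clipping.

One exception to the no-affine soma rule: the generative compartment that
reconstructs the stimulus layer (`gen/0`) has a learnable per-pixel scale
and shift after its normalization.  Its target is fixed pixel data — with
many near-constant background pixels — not normalized unit activity, and a
hard zero-mean/unit-variance output would leave a large irreducible
reconstruction error that contaminates every plasticity measurement at zero
dose.  The hidden-layer indeterminacy argument does not apply there because
the stimulus itself is not free to rescale.

Conditional distributions: `r^(l) ~ N(h(r^(l-1)), sigma_b^2 I)` bottom-up,
`r^(l) ~ N(mu(r^(l+1)), sigma_p^2 I)` top-down, a standard-normal prior on
`r^(L)`, and a learned diagonal variance `diag(h2(r^(L-1)))` for the
top-layer inference distribution, with `h2` a multicompartment map whose
soma nonlinearity is a bare exponential (positivity).

Defaults: `sigma_b = sigma_p = 0.1`, three branches per compartment,
normalization momentum 0.1.  These are deliberate, configurable choices —
the noise scales set the floor of all variability statistics and the branch
count sets compartmental expressiveness (a single branch with identity
affine recovers a one-compartment control model).

## Wake-Sleep training

Training alternates two phases per step on a stimulus batch (default 512):

* **Wake (alpha = 0)**: sample activity bottom-up from a data batch and
  update every *generative* parameter with the local delta rule
  `d_theta = (1 - alpha) * eta * (r_i - mu_i) / sigma_p^2 * d mu_i/d theta`.
* **Sleep (alpha = 1)**: sample ancestrally from the generative model and
  update every *recognition* parameter with
  `d_theta = alpha * eta * (r_i - h_i) / sigma_b^2 * d h_i/d theta`.

The drive derivatives are computed analytically per parameter type (soma
nonlinearity derivative x branch conductance x branch nonlinearity
derivative x presynaptic rate); normalization statistics are treated as
constants within a step, keeping every update a function of quantities
local to the synapse, its branch, and its soma.  The top layer's mean path
divides by the learned variance `h2` instead of `sigma_b^2`, and `h2`
itself follows the Gaussian log-likelihood gradient
`((r - h)^2 / h2 - 1) / 2` with respect to its pre-exponential soma input.
All updates are verified against central-difference gradients of the
corresponding Gaussian log-likelihoods (relative error < 1e-4 in the test
suite; measured ~1e-7).

Updates averaged over the batch feed an Adam optimizer (default, lr 2e-3
in the experiment configurations) or a plain gradient step.  A
reconstruction proxy — mean squared error between the stimulus and its
generative reconstruction `mu(r^(1))` from a Wake sample — is logged per
epoch, and training can stop when the proxy has not improved by 2% for 25
consecutive epochs ("plateau stopping").  Plateau stopping matters: well
past the plateau, small-network Adam training can destabilize and the
reconstruction degrades, which inflates zero-dose apical plasticity (see
Limitations).  After training, normalization sites are frozen to their
running statistics so that single-stimulus simulation is well defined.

## Hallucination dynamics

Intermediate doses `0 < alpha < 1` make activity depend on both neighbors
simultaneously, so activity is simulated as a stochastic dynamical system:

    r_t = (1 - gamma) r_{t-1} + gamma * f(h(r_{t-1}), mu(r_{t-1}), alpha)
          + f(sigma_b, sigma_p, alpha) * sqrt(gamma (2 - gamma)) * eta_t

with update fraction `gamma = 0.1`, 800 steps, and the soft-max
interpolation

    f(a, b, alpha) = kappa * log[(1-alpha) exp(a/kappa) + alpha exp(b/kappa)]

computed in log-sum-exp form with exact endpoint short-circuits.
`kappa = 0.35` biases the mixture toward registering positive drive from
either pathway, so hallucinated strokes are added on top of the stimulus
rather than fading it.  Numerical conventions chosen where the dynamics
admit more than one discretization:

* The noise prefactor `sqrt(gamma (2 - gamma))` makes the stationary
  variance of the noise component exactly `f(sigma_b, sigma_p, alpha)^2`
  for every `gamma`, and reduces to the one-shot training sampler at
  `gamma = 1` (Wake at alpha=0, Sleep at alpha=1).  A bare `sqrt(gamma)`
  prefactor would shrink the noise floor by `1/(2-gamma)` and, compounded
  across layers, collapse dream-state variance.
* The stimulus layer obeys the same update with its "bottom-up drive" given
  by the external image (closed-eye condition: an all-zeros image), so at
  alpha=0 it relaxes to the image plus noise and at higher doses top-down
  content mixes in through `f`.
* The top layer's top-down drive is its prior mean (0) and its noise s.d.
  interpolates `f(sqrt(h2), 1, alpha)` elementwise, preserving both
  training-limit samplers.
* Traces start from a Wake sample of the stimulus, making alpha=0
  trajectories stationary from the first step; downstream statistics
  discard a 200-step burn-in.

Two manipulations: `apical_stim_layer` zeroes the top-down drive into the
stimulus layer before interpolation; `deepest_layer` clamps `r^(L)` to zero
at every step.  The noise-based control protocol drops the apical
contribution entirely and injects noise of s.d. `sigma_b + alpha`
(uniformly across layers), so that variability grows with dose without any
increase in top-down influence.

## Analyses

All analyses consume the simulator's own traces; key conventions:

* **Alignment**: Pearson correlation across stimuli between a neuron's
  basal and apical drives under Wake responses, against a random-pair
  baseline (derangement within layer); layers 1..L-1 pooled.
* **Plasticity (relative change)**: for each test image the dynamics are
  simulated and the delta-rule updates accumulated at every post-burn-in
  step ("gated" applies the alpha/(1-alpha) gates; "ungated" lets both
  pathways learn).  The net change per parameter is summarized as
  `|d_theta| / (|theta| + 1e-2)`, averaged within the apical and basal
  groups (stored parameters, i.e. conductance pre-parameters).  An optional
  update stride accumulates every k-th step scaled by k — an unbiased
  thinning used by the full-scale reproduction script.
* **Plasticity alignment**: cosine similarity between concatenated update
  vectors per group.
* **Variability**: per-neuron variance across post-burn-in frames at fixed
  stimulus, with an across-stimulus reference (variance across stimuli of
  time-averaged activity).
* **Decoding**: a separate 256-unit tanh perceptron trained by Adam on
  cross-entropy over Wake activity of layer 2, evaluated on final-step
  trace activity; logit variance is the across-ensemble variance per logit
  dimension, averaged.
* **Correlation similarity**: Pearson correlation between the off-diagonal
  entries of the neuron x neuron correlation matrices (final-step activity
  across the stimulus ensemble) of two trace sets.  The unit diagonal is
  excluded because it is constant and would inflate similarity.
* **PC spectra**: explained-variance proportions of final-step activity;
  effective dimensionality as the participation ratio `1 / sum p_i^2`.
* **Variance ratio**: per stimulus-layer neuron,
  `(Var_inact + 1e-3) / (Var + 1e-3)` with variances across the stimulus
  ensemble at the final step, so equal variances give exactly 1.

The layer used for correlation/variability analyses is an explicit argument
everywhere (`layer_index`), defaulting to the first hidden layer, because
reasonable conventions differ; reports carry the layer label.

## Synthetic stimuli

The glyph generator renders ten fixed digit-like polyline templates as
Gaussian-profile strokes (s.d. 1.1 px) on a 28x28 canvas with random
rotation (±12°), translation (±2 px), scale (±12%) and additive clipped
noise (s.d. 0.03), emulating what the analyses need from handwritten
digits: sparse bright strokes on a dark background and ten learnable
classes (a 256-unit perceptron exceeds 80% held-out accuracy on raw
pixels).  It does not emulate stroke-style diversity, class-conditional
multimodality, or pixel-intensity statistics of real handwriting, so
passing tests demonstrate the mechanism of the model, not performance on
real image data.  Real MNIST can be substituted through the IDX reader.

## Problem sizes

The reproduction script (`scripts/acceptance.py`) uses the default
[32, 16, 6] network on 2,000 glyphs (1,800 train / 200 held out), a
coarse-then-fine Adam schedule (160 epochs at 2e-3, 60 at 5e-4), 800-step
dynamics on 128 held-out images, three training seeds, and update stride 4.
The test suite runs trace statistics at a reduced scale (14x14 glyphs,
[16, 8, 4] networks, 400-step simulations); the dose-grid plasticity check
runs the full-scale pipeline at a single training seed, because the
plasticity dose curve only takes its characteristic shape in networks with
a small enough held-out reconstruction residual.

## Limitations

* The dynamics low-pass each layer's drive fluctuations (an AR(1) with the
  same relaxation time as its input), so dream-state variance at full dose
  is several-fold below ancestral Sleep samples for a 3-layer cascade at
  `gamma = 0.1`.  Dream *content* (template-structured states) is
  unaffected; quantitative variance comparisons against ancestral samples
  should account for this compression.
* The dose of maximal ungated plasticity is a property of a *well-trained*
  network: under-trained or destabilized networks have their plasticity
  dominated by the zero-dose reconstruction residual of the stimulus-layer
  generative synapses, which moves the grid argmax to 0.  Even at
  convergence, the residual generalization gap of a 1,800-image ensemble
  keeps the zero-dose term substantial, and the peak's grid location
  varies between the lowest intermediate doses (0.25 vs 0.5) across
  training seeds; with far larger training sets the zero-dose term shrinks
  and the peak sharpens toward the middle of the dose range.
* An untrained network's hallucinations are unstructured but not white at
  the pixel level: the random low-rank top-down drive induces correlated
  fluctuations that dominate `sigma_p = 0.1` noise.  Whiteness holds for
  the noise-based control protocol.
* Updates through normalization treat batch statistics as constants
  (frozen-statistics derivatives), matching the local delta-rule form; this
  is exact for frozen norms and an approximation during training.
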