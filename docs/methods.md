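# Methods

## Data model

A sample is a matrix of S sensor channels × T time points in
dimensionless conductivity-ratio units; the canonical in-memory
orientation is sensors × time (matching the network's channels × length
input), while the on-disk format is time-major (T rows × S columns under a
header of sensor names) for readability — readers transpose. A dataset is
an ordered list of samples sharing S, T and sensor names, with a fixed
class vocabulary.

Before modeling, every sensor row is zero-centered per sample:
x′ = (x − mean) / (max − min), with the statistics taken over that
sensor's own T points. This makes each row mean-zero with range exactly 1,
removing per-sensor offset and scale while keeping curve shape. A constant
row has no discriminative content, so the zero-range case maps to zeros
rather than dividing by zero. Normalization is strictly per sample, so
applying it before a train/test split leaks nothing across the split.

## The encoder–decoder

The encoder is conv(7 channels, kernel 5) → ReLU → maxpool 2 →
conv(12, kernel 3) → ReLU → maxpool 2 → flatten → fully-connected → softmax
over K classes; with the default 10×120 input the temporal lengths are
120 → 116 → 58 → 56 → 28 and the flatten width is 12·28 = 336. The length
arithmetic must be exact (each conv output divisible by the pool width);
construction fails otherwise, naming the offending stage. The decoder
mirrors the stack: fully-connected K → 336, index-based max-unpooling
using the paired encoder pool indices, transposed convolutions back to
7 then 10 channels, ReLU after each stage except the final output layer,
which is linear because zero-centered targets are signed. Index-based
unpooling (rather than nearest-neighbour upsampling) preserves the sharp
localized "feature stamps" that make decoded responses interpretable.

Training minimizes CE + λ·MSE with λ = 1 by default. The constrained view
— classify correctly subject to reconstructing the input — is implemented
as this weighted relaxation, the standard device when no multiplier
schedule is specified; λ is exposed in `TrainConfig`. The decoder consumes
the encoder's softmax output, so gradients flow through the bottleneck
from both loss terms; an optional teacher-forcing mode feeds the one-hot
label instead (default off). Optimization is mini-batch Adam (lr 1e-3,
batch 32, 200 epochs) — conventional defaults for a network this size; all
exposed. Training history records per-epoch mean total/CE/MSE losses and
training accuracy. Two fits with identical data, config and seed are
bit-identical on a fixed platform (pure numpy, single RNG stream).

The layers themselves (valid 1-D convolution, width-2 max-pooling with
recorded argmax indices, max-unpooling, stride-1 transposed convolution,
fully-connected, softmax/cross-entropy, Adam) are implemented in numpy
with explicit backward passes; every backward pass is verified against
central-difference numeric gradients in the test suite. Ties in
max-pooling resolve to the earlier position; prediction ties resolve to
the lowest class index.

## Synthetic study generator

The generator emulates the morphology of headspace measurements of plant
material with a 10-sensor metal-oxide array sampled at 1 Hz for 120 s,
seven odor classes with 100 samples each. Sensor s of a sample from class
c follows

    b[s] + g · A_c[s] · (1 − exp(−t/τ)) + d_c[s] · k + ε(t)

a saturating-exponential rise to plateau (τ = 15 s), a signed linear
baseline drift (slope uniform in ±0.002 per step — upward drift mimics
slow volatilization, downward drift chamber overflow), a per-sample
lognormal gain g (σ = 0.08) shared across sensors that stands in for
heterogeneous within-class material sources, and iid Gaussian noise
(σ = 0.02). Class amplitude vectors are drawn uniformly and re-drawn until
all pairwise Euclidean distances exceed 0.5 × `class_separation`, so
classes are distinct by construction. The noise/drift/gain magnitudes are
calibration choices (no instrument values are available to copy); the
calibration anchor is a separability floor — a plain LDA on the default
configuration scores ≥ 0.90 mean holdout accuracy — placing the synthetic
task in the same difficulty regime as real plant-material studies, at the
easy end. Seeding is hierarchical: one root seed, per-sample seeds derived
from (root, class, counter), so generation is a pure function of the
configuration and independent of generation order.

What the simulator does **not** reproduce: temperature/humidity
dependence, day-scale sensor drift, cross-sensitivity correlations between
sensors, non-exponential transients, or class-conditional noise. In
practice the default synthetic task is close to linearly separable — all
strong classifiers (OLCE, LDA, CNN–SVM, PCA–LDA, MLP) sit at or near 1.0
accuracy — so passing the accuracy-floor tests shows the pipeline is
wired correctly and the model trains, not that the encoder–decoder would
beat linear baselines on noisy instrument data.

## Evaluation

Metrics are computed from the K×K confusion matrix (rows true, columns
predicted): accuracy = trace/n; unweighted macro precision/recall/F1
(per-class values with zero denominators count as 0 — macro equals
weighted averaging under the balanced design); Hamming loss = 1 − accuracy
for single-label problems; Cohen's kappa = (Po − Pe)/(1 − Pe) with
Po = trace/n and Pe = Σ aᵢbᵢ/n² from the marginals, undefined (raised)
when both marginals concentrate on one class.

The comparison harness runs R repetitions (default 10); each repetition
re-splits the data (stratified 75/25, seed base+r) **and** re-initializes
the model (seed base+r) — both sources of run-to-run variation in a
repeated-holdout protocol. The 75/25 split is chosen so the test set is
175 of 700 samples. The accuracy column is summarized as Max/Min/Ave/Var;
Var is the population variance (divisor n), with sample variance exposed
as an option.

## Baselines

All five comparators sit behind one fit/predict interface and consume
flattened 1200-dimensional zero-centered samples, except the CNN–SVM,
which keeps the S×T matrix. Underlying estimators are scikit-learn.
Unstated details are fixed as follows and exposed as hyperparameters: MLP
hidden widths 256-128-64-32 (a conventional funnel from 1200 inputs to 7
outputs; only depth 4 and ReLU are structural); PCA–LDA grid
{2, 5, 10, 20, 30, 40, 49, 60, 80, 100} scored by 5-fold CV accuracy on
the training split (folds capped so every class keeps ≥ 1 member per
fold); CNN–SVM with conv kernels 5 and 3, channels 8 and 16, pool 2, a
64-unit fully-connected feature layer trained for 30 epochs under a
temporary softmax head then frozen, features classified by an RBF SVM
(C = 1, the common default kernel; linear exposed).

## Problem sizes used by the shipped runs

The test suite trains the full model on small synthetic configurations
(10-sample memorization toy; 3 runs at 50 samples/class for the
accuracy-floor check). `scripts/acceptance.py` uses the full default
700-sample study with 3 harness repetitions per model; these sizes are the
package's own desk-scale defaults and can be raised via `--n-runs` or the
CLI configuration.

## Known limitations

- The synthetic study is easier than instrument data; comparative rankings
  on it are not evidence about real-world rankings.
- Stride-1, padding-0 convolutions only; pooling width fixed at 2; input
  lengths must satisfy the exact-arithmetic constraint.
- Single-label bottleneck only (no multi-label/binary-code variant).
- Training is CPU numpy; fine at 10×120 scale, not meant for large inputs.
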