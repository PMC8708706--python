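# Methods

This note documents the models implemented in `artflow`, the choices made
where the design was genuinely open, and what the test suite does and does
not establish.

## Ego-motion flow simulator (`artflow.flow`)

Self-motion through a rigid scene is simulated with a pinhole camera
(512×512 px, 90° field of view, so the focal length is 256 px; 30 fps) in
a camera-centered frame with x right, y up, z forward. Image coordinates
are relative to the principal point with y up; pixel-grid coordinates
(top-left origin) are used only at I/O boundaries. Heading is given as
azimuth (right-positive) and elevation (up-positive); rotation rates are
(pitch, yaw, roll) about the camera (x, y, z) axes under the right-hand
rule, in deg/s.

Each sample is 10 frames (0.33 s) of motion under a constant instantaneous
twist (T, ω): translation speed 3 m/s along the heading, and — in the
translation+rotation environment — a rotation magnitude drawn
Uniform(1, 10) °/s about an independent uniformly random 3D axis, recorded
as its pitch/yaw/roll components. Headings are Uniform(−45°, 45°) in both
angles. Dataset sizes default to 500 train / 250 test for the two
translation-only environments and 1000 / 500 for translation+rotation.

Scenes contain 2000 dots. Cloud scenes draw dots uniformly over the view
frustum cross-section at each depth with depth Uniform(1, 50) m (uniform in
image position and in depth — chosen over uniform-in-volume so that image
coverage is depth-independent). Ground scenes place dots on a plane 1.61 m
below the camera, sampled uniformly over the image-plane footprint of the
visible patch whose viewing ray meets the plane within the depth range
(rejection sampling; this avoids the extreme far-field thinning a uniform
world-plane sample would produce). Between frames the dots are rigidly
transformed (`P' = R(ω dt)ᵀ(P − T dt)`, dt = 1/30 s); dots leaving the
frustum or depth range are replaced by fresh draws from the scene's
generating distribution, so the count is exactly 2000 on every frame. The
supporting plane of ground scenes is tracked through the transforms so
respawned dots land on the current plane. Flow is evaluated at the start
of each frame from the instantaneous first-order equations; exactly
stationary dots are dropped (their direction is undefined). Flow speed is
converted px/frame → °/s with the uniform small-angle scale
(90/512 °/px × 30 fps), keeping the mapping invertible; the small-angle
approximation overestimates angular speed toward the image corners, a
deliberate simplification shared by the MT speed-preference units.

## MT population (`artflow.mt`)

5000 model neurons with 15 px circular receptive fields (RFs) at uniform
random image positions. Direction tuning is von Mises,
`d = exp(σθ(cos(θ−θpref)−1))` with σθ = 3 (≈90° full width at half
maximum), preferred directions uniform on [0, 2π). Speed tuning is
log-normal, `s = exp(−log²((ν+s0)/(νpref+s0))/(2σν²))`, with per-neuron
bandwidth σν ~ N(1.16, 0.5) resampled until positive (a non-positive
bandwidth is meaningless), offset s0 ~ Exponential(rate 0.25 /s, mean
4 °/s) interpreted as a rate — the distribution's usual λ notation — and
νpref drawn by choosing one of five octave-spaced bins
(0.5–2, 2–4.3, 4.3–7.6, 7.6–12.7, 12.7–32 °/s) uniformly and then
uniformly within it.

The net input of a neuron on a frame is the *mean* of d·s over flow
vectors inside its RF (zero for an empty RF; neurons whose RF crosses the
image border simply see fewer vectors). Each neuron integrates
`dn/dt = −A·n + (B−n)·I` with A = 0.1 /s, B = 2.5, from n(0) = 0 for every
sequence (responses must be sequence-specific). The input is recomputed at
frame boundaries and held for the frame's ten Euler substeps of 0.1 frame
(1/300 s). Time is in physical seconds: with the frame taken as the time
unit instead, integrated membrane values saturate the output sigmoid
(median activation > 0.999) and the encoding collapses. Because the input
is constant within a frame, the ten substeps form a linear recurrence that
is collapsed to its exact power form — identical values to the explicit
loop (asserted in tests), one vectorized step per frame. RF lookup uses a
k-d tree over RF centers with a sparse within-radius pair query per frame.

The output is `m = n²/(n² + γ²)` with γ = 0.007, held fixed across
datasets so the encoding is dataset-independent. The constant is of the
order of the median membrane value on cloud translation-only data
(measured ≈0.02 here), placing typical activations in the sigmoid's
sensitive range while keeping every component strictly inside [0, 1) as
complement coding requires.

## Fuzzy ART hierarchy (`artflow.fuzzy_art`, `artflow.network`)

Each module clusters vectors in [0,1]^M after complement coding
x = (m, 1−m), which fixes ‖x‖₁ = M and prevents weight collapse. Weights
start as a 2M×Cmax matrix of ones (Cmax = 512; exhausting it raises an
error rather than silently skipping learning). Committed cells compete via
choice-by-difference `T_j = ‖x∧w_j‖₁ + (1−α)(M−‖w_j‖₁)`, α = 0.01. The
search walks cells in descending T_j (ties to the earliest-committed cell
— the rule is deterministic and the choice is otherwise arbitrary), checks
each at most once, and recodes the first cell whose match
Γ = ‖x∧w‖₁/‖x‖₁ reaches the vigilance ρ with β = 0.1; if none matches, a
new cell fast-commits (β = 1, so its weights equal the input). There is no
match tracking or vigilance raising (plain fuzzy ART, unsupervised).

The network is a grid of such modules per layer: by default an 8×8 layer
(ρ₁ = 0.65, softmax output) whose 64 modules partition the MT population
by RF-center sector, fanning in to a single output module (ρ₂ = 0.85,
raw-T output) whose weight columns are the learned templates. The fan-in
machinery is generic (any grid sequence with even divisibility), but two
layers suffice for these simulations. Layers train sequentially — one pass
each by default — with lower layers frozen before the next trains, since a
module's input dimension is the (data-dependent) committed-cell count of
its sources. Concatenation is row-major over (row, col) with module-local
cells in commit order, fixed so serialization and decoding are stable. If
an MT draw leaves a sector empty (probability ~e⁻⁷⁸ at the defaults, but
real for small test populations), the population is redrawn with the next
seed. Sample presentation order is generation order, governed by the
dataset seed.

## Decoders (`artflow.decoders`)

Both decoders minimize mean-squared error with Adam on z-scored features
and labels (ε-guarded for zero-variance columns; predictions are returned
in original units, asserted reversible to 1e−10). Early stopping watches a
seeded 20% validation split with patience 5. The MLP has one hidden layer
of 250 ReLU units, mini-batches of 32, at most 500 epochs
(scikit-learn's `MLPRegressor`). The linear decoder is an affine map
trained full-batch; because it takes one gradient step per epoch versus
the MLP's ~n/32, it uses a 0.01 step size and a 2000-epoch budget to reach
the least-squares solution before the patience rule fires. Heading error
pools absolute errors over azimuth and elevation; rotation errors are
per-axis. Angular labels are treated as plain reals (ranges ≤ ±45° never
wrap).

## Hebbian baseline (`artflow.hebbian`)

The comparison network keeps the grid, the MT partition and the
feed-forward wiring, but each module runs Sanger's generalized Hebbian
rule `ΔW = η(y xᵀ − LT(y yᵀ)W)`, η = 0.01, whose rows converge to the
leading principal components (verified against an eigendecomposition
oracle at |cos| ≥ 0.99). Module width is C_mean, the rounded mean
committed-cell count of the matching fuzzy ART layer. Weights initialize
Uniform(−0.01, 0.01); epochs repeat until successive weight matrices
differ by < 0.01 in Frobenius norm (cap 200 epochs, warning on
non-convergence). Each module's own update consumes its raw linear
outputs, but the signal passed between layers is logistic-transformed
(f(x) = 1/(1+e⁻ˣ)) during training as at prediction: the rule is stable
only for η below 1/λmax of the input covariance, and raw linear
inter-layer signals have unbounded variance, which makes the fixed rate
diverge in the second layer.

A consequence worth stating plainly: with this numerically stable wiring,
the PCA baseline decodes heading from the cloud translation-only data
about as well as the fuzzy ART network (sometimes better with the MLP
readout), while needing many epochs where fuzzy ART needs one. The
head-to-head harness therefore asserts that both networks decode far below
chance and that the Hebbian modules genuinely require iterative epochs —
not a strict accuracy ordering.

## Generative pass (`artflow.generative`)

The backward pass is this package's own minimal-assumption inverse of each
forward stage. A weight column is mapped back to feature space by the
midpoint of its fuzzy box, `defuzz(w) = (w[:M] + 1 − w[M:])/2`, which
inverts complement coding exactly for freshly committed cells. Template
activations (normalized to sum 1) convexly weight the defuzzed template
columns to estimate the layer-1 activation vector; within each module the
renormalized cell activations weight the defuzzed layer-1 columns to
estimate MT activations. The MT sigmoid is not inverted — the decode below
is invariant to monotone reweighting of a neuron's contribution direction.
Flow is then read out per spatial bin (default 16×16) by population
vector: direction from the activation-weighted circular mean of preferred
directions, speed as the activation-weighted geometric mean of preferred
speeds (matching the log-normal tuning); bins with no neurons, no mass, or
a circular resultant under 0.1 emit no vector. When reconstructing from
raw output-layer activations, `ARTFLOWResults.reconstruct` first applies a
softmax: choice-by-difference values carry a large common baseline, so
convex weighting of the raw values blends all templates nearly uniformly;
the softmax mirrors the forward normalization of non-output layers.
Reconstruction quality is quantified by mean absolute angular difference
and relative speed error against the nearest true flow vectors, and the
round-trip test requires the best-fit FoE of a reconstruction to land in
the true heading's image quadrant for a clear majority of off-axis
samples — with ~10–20 templates, heading is quantized too coarsely for
every sample to resolve.

## Stability semantics

Multi-epoch runs are independent trainings from the same data and order.
Layer-1 committed-cell totals are non-decreasing in the epoch budget
(a longer run extends the shorter one's deterministic trajectory on fixed
inputs). Output-layer templates are compared across budgets after aligning
features per layer-1 module on the shared commit-order prefix (extra
epochs can grow the top module's input dimension) and defuzzing; template
*counts* can fluctuate slightly across budgets because the layer-2 inputs
themselves shift. Stability is asserted as: aligned drift between
consecutive budgets stays below half the mean between-template contrast
and decays as budgets grow. With β_recode = 0, drift is exactly zero.

## Problem sizes

The acceptance script and end-to-end tests run the two translation-only
environments at their full 500/250 study size and translation+rotation at
its half-size 500/250 replicate, each with the full 5000-neuron MT
population; a complete three-environment acceptance run takes about two
minutes on one CPU. Unit and property tests use smaller replicates
(tens of sequences, ~1–2k MT neurons) chosen so every grid sector stays
populated.

## What the synthetic data does and does not show

The generator produces exact first-order flow of rigid dot scenes: no
occlusion beyond frustum clipping, no flow-estimation noise, no
independently moving objects, no photometric effects. Passing accuracy
tests therefore demonstrates the encoding/learning/decoding chain under
the stated geometry, not robustness to estimator noise or scene clutter;
with camera-derived flow (supplied as `.flo`), errors several times larger
are to be expected. Decoded rotation labels use the package's axis
conventions; comparisons against data with other conventions need a sign
mapping. Known limitations: the backward pass is a declared stand-in
design rather than a transcription of a published procedure; vigilance
must be retuned for feature statistics far from [0,1)-normalized MT
activations; and wall-clock comparisons between the learners are logged
but never asserted, since they are implementation- and machine-dependent.
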