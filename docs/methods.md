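# Methods

This package studies how well routinely collected clinical evaluations of
elderly adults can predict laboratory measures of balance control during
gait, using a small feed-forward neural network as the mapping. Because no
subject-level data are distributed with it, the package also contains a
synthetic-cohort generator and a gait-trial synthesizer that together stand
in for the clinical study population and the motion-capture laboratory.
This note documents the models, their assumptions, the defaults, and what
the synthetic experiments can and cannot show.

## Balance-control measures

Balance during walking is summarized by the interaction of the body's
center of mass (CoM) with the base of support (BoS), evaluated at
heel-strike events:

* **CoM–BoS distance** (cm): the minimum horizontal distance from the CoM
  ground projection to the BoS boundary — a static balance-control measure.
* **CoMv–BoS displacement** (cm): the distance from the CoM projection to
  the BoS boundary measured along the instantaneous horizontal CoM velocity
  direction — a dynamic balance-control measure. For a CoM inside the BoS
  this is always defined and never smaller than the CoM–BoS distance; for a
  CoM outside the BoS it is defined only if the velocity ray re-enters the
  support region, and is otherwise flagged with a reason code.
* **BoS area** (cm²): the area of the support polygon.

The BoS is modeled as the in-contact foot outline during single support and
the convex hull of both in-contact outlines during double support, with
contact given by boolean flags rather than force plates. Whether the
original support-region definition included the inter-foot region exactly
as a convex hull is not documented; the hull convention is declared here,
not inferred. Likewise no sign convention is imposed when the CoM falls
outside the BoS: the distance is reported unsigned with `inside=False`.

All geometry lives in the ground plane; the vertical CoM coordinate is
ignored for distances (the BoS is a ground-plane construct). Internally
everything is in metres; the reporting boundary converts to cm and cm².
Trajectories are conditioned with a fourth-order low-pass Butterworth
filter at 8 Hz before evaluation, applied forward–backward (zero phase), as
is standard for 60 Hz motion-capture data; the forward–backward pass
squares the magnitude response, and a single-pass option is provided. CoM
velocity, when not supplied, is obtained by central differences of the
filtered positions (one-sided at the ends).

Degenerate inputs are rejected rather than silently absorbed:
self-intersecting polygons, frames with no foot in contact, sampling rates
at or below twice the cutoff, speeds below 1e-4 m/s (the CoMv measure is
then undefined).

## The network and its trainer

The mapping is a three-layer feed-forward regression network,

    y = W2 · tanh(W1 · x + b1) + b2,

with one tangent-sigmoid hidden layer (grid sizes 5, 10, 20, 30) and a
linear output layer for the three balance measures. Inputs and targets are
min-max normalized per column to [−1, 1]; the training mean squared error
and its stopping goals (0.1, 0.01, 0.001) are defined on the normalized
targets — goals of that magnitude are only meaningful on a bounded scale,
so the normalized interpretation is adopted as a declared assumption.
Whether min–max or z-score scaling was used in the original environment is
not documented; min–max onto [−1, 1] is the convention of the toolbox that
environment is associated with, and is what the serialized model stores.

Training is Levenberg–Marquardt: per epoch the full-parameter update
`(JᵀJ + μI)δ = Jᵀe` is solved with the analytic backpropagation Jacobian of
the residuals; a step is accepted only if the MSE decreases (then μ/=10),
otherwise μ*=10 and the step is retried; training stops at the error goal,
at 500 epochs, or when μ exceeds 1e10. The damping schedule
(μ₀ = 1e-3, ×10/÷10, μ_max = 1e10) is standard LM practice. When the
parameter count exceeds the residual count — routine here, since a
30-hidden, 16-input network has 603 parameters against 42×3 = 126 training
residuals — the update is solved in the algebraically identical dual form
`δ = Jᵀ(JJᵀ + μI)⁻¹e`, which is much cheaper. Accepted-step MSE is
monotone non-increasing by construction, and the whole procedure is
deterministic given the seed.

Weights are initialized Nguyen–Widrow style (random hidden directions
scaled to 0.7·H^(1/I) with spread biases), seeded, with a plain-uniform
fallback; the original study does not state its initialization and this
matches the default of the environment it names. No validation split or
early stopping beyond the goal/cap is used. Pre-activations are clamped to
±40 before tanh to keep derivatives finite. Input importance is summarized
as the per-input sum of absolute hidden-layer weights, with ties broken
stably by column index.

## The grid experiment

Fifty-six subjects rotate through 4 folds of 14 test / 42 training
subjects (a seeded random partition, so every subject is tested exactly
once; an independent-draws mode exists behind a flag because the original
wording is ambiguous between a rotation and four independent splits). Six
input groupings — the five clinical functional domains (subject
characteristics: age, sex, BMI; clinical examination: fall history,
medications, vision, hearing; clinical balance: BBS, TUG, ABC; cognitive
performance: TMT B−A, GDS, SLUMS; muscle strength: ankle plantarflexors,
knee extensors, hip abductors) plus their 16-feature union — crossed with
four hidden sizes and three goals give 72 configurations.

Within each fold the normalizers are fitted on the 42 training rows only;
an audit on the normalizer's fit count enforces that test rows never leak
into fitting. Test predictions are denormalized and scored per outcome by
Pearson correlation and mean absolute error in real units. Correlations
that are undefined (constant predictions) are recorded as missing with a
reason and excluded from fold means, with a count kept. A master seed
expands deterministically into per-configuration and per-fold training
seeds. The best configuration per grouping is chosen by argmax of the mean
fold R averaged over the three outcomes — how the original "selected
combinations" were chosen is not fully documented, so argmax is declared.
Inferential statistics on the grid factors (the original three-way ANOVA)
are deliberately out of scope; descriptive mean (SD) tables replace them.

## The synthetic cohort

The generator emulates a community-dwelling elderly cohort whose marginal
means and SDs match published descriptives of such a study population
(age 76.1 (6.5) y, 22/56 male, BMI 27.4 (6.1), …, CoM–BoS 3.8 (1.1) cm,
CoMv–BoS 19.3 (3.5) cm, BoS area 436 (88) cm²). Only marginals are
published; the dependence structure is a declared three-latent-factor
Gaussian model (global balance ability, lower-limb strength, cognition).
Each feature loads on the latents with a fixed default loading vector and
carries independent unique variance; the outcomes are monotone functions
of their own latent combinations — by default a variance-normalized
`tanh` link, so the clinical-to-balance mapping is genuinely nonlinear but
learnable — plus independent noise.

Two calibration details matter:

* **Censored/rounded moment matching.** Instruments are bounded and often
  integer-valued (BBS ≤ 56, SLUMS ≤ 30, GDS ≤ 15, ABC ≤ 100, counts ≥ 0).
  Published descriptives are of the recorded values, i.e. after bounds and
  rounding. Naive clip-and-round would bias both moments (the BBS ceiling
  sits only ~0.7 SD above the target mean), so for each variable the
  generator solves for the underlying Gaussian (μ, σ) whose censored — and,
  for integer instruments, integer-rounded — distribution reproduces the
  target mean and SD exactly; the solve matches closed-form censored-normal
  moments for continuous variables and exact probability sums over the
  integer support for discrete ones. At n = 10⁵ every marginal mean lands
  within 1% and every SD within 2% of its target.
* **Outcome noise fraction.** `outcome_noise_frac` (default 0.15) is the
  fraction of standardized outcome variance unexplainable from the
  latents. The default was chosen so that cross-validated correlations
  achievable by models trained on a few dozen subjects fall in the 0.3–0.9
  range typical of clinical-to-biomechanical mappings, with the all-inputs
  grouping clearly dominating single domains. Binary traits (sex, hearing)
  use a probit threshold on their latent score, so their prevalences (22/56
  and 14/56) hold exactly under any loading.

The latent loadings are a stand-in, not an estimate of any real
population's correlation structure; they encode only the qualitative prior
that balance instruments track a balance factor, strength measures a
strength factor, and cognitive screens a cognitive factor, with the
outcomes drawing on all three.

## The gait-trial synthesizer

Trials are built by inverse design so that the geometry module, applied to
the synthetic trial, recovers a requested outcome triple. Alternating
left/right footprints (rectangle with a rounded toe; foot length
0.152 × body height, a standard anthropometric ratio; body height default
1.65 m) are laid out with the step length solved by bisection so the
double-support hull at heel strike has the requested area. At initial
contact the leading foot is in heel-only contact — its outline during the
double-support window is the rear 45% of the template — which is what
brings double-support areas into the physiological few-hundred-cm² range;
the trailing foot keeps its full outline (a simplification of late-stance
forefoot contact). Small areas scale the footprint and stance down
proportionally (smaller subjects); deep CoM placements widen the stance.

The event pose is then solved on the prototype hull: the CoM point is
sought on the boundary of the hull eroded by the requested CoM–BoS
distance (for a convex hull every such point is exactly that distance from
the boundary), and the heading is found by bisecting the continuous
angle-to-ray-distance map until the ray-cast distance equals the requested
CoMv–BoS displacement, preferring rear points and forward headings so the
pose resembles gait. The CoM is threaded through the per-event poses on a
cubic Hermite spline (60 Hz, 0.55 s steps, six heel strikes by default).
Because the evaluated heading comes from central differences of the
*filtered* trajectory, which deviates slightly from the spline's knot
tangent, the knot velocities are iteratively rotated until the measured
heading matches the solved pose heading. A band-limited (<1.5 Hz) random
wander of 1 mm SD is added afterwards as path noise.

Requested outcomes that are geometrically impossible — a CoM–BoS distance
deeper than the eroded hull allows, a CoMv–BoS displacement shorter than
the CoM–BoS distance or longer than any chord, an area below the two-foot
minimum at the smallest plausible foot scale — raise a generation error
with a diagnostic rather than producing a distorted trial.

Round-trip accuracy over outcomes drawn from the cohort distribution:
median worst-measure relative error ~2%, maximum ~10%, with the area
component exact to the bisection tolerance.

## What the synthetic experiments show — and what they do not

Passing tests establish that the geometry is correct against brute-force
oracles, that the trainer is a faithful Levenberg–Marquardt implementation
(it attains the least-squares optimum on linear data, its Jacobian matches
finite differences, its accepted-step error is monotone), and that the
full experimental design reproduces the qualitative training phenomena:
5-hidden networks routinely exhaust the 500-epoch cap at the 0.001 goal
while 20/30-hidden networks converge in tens of epochs or less, and the
all-inputs grouping outperforms every single clinical domain. They do not
certify the original study's numerical correlations (obtained on 56 real
subjects whose data are unavailable), nor realistic inter-feature
correlation magnitudes, marker-based CoM estimation, force-plate contact
detection, or gait-event detection — events are inputs here, and the
synthesizer's gait is deliberately stylized (periodic, symmetric, noise
only in the CoM path).

## Problem sizes and numerical choices

The default experiment sizes are those of the study design: 56 subjects,
4×14 rotation, 72 configurations, 500-epoch cap — the full grid runs in
well under a minute on one core. Calibration checks use n = 10⁵ draws;
geometry oracle comparisons use ≥10³ random convex polygons with
dense-boundary (10⁵ samples) and ray-marching (10⁻⁵ m step) oracles at a
10⁻³ cm agreement tolerance; trial round-trips use 100 outcomes. Floats
serialize via `repr` (shortest round-trip representation), so model JSON
and cohort CSV round-trip bit-exactly; CSV parsing uses round-trip float
precision. Hull/area computations, point-in-polygon tests and ray
intersections are delegated to `shapely`; filtering to `scipy.signal`; the
LM trainer, Jacobian, normalization, generators and experiment logic are
implemented here.
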