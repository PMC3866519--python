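# Methods

## The model

`covisim` simulates category learning by two interacting memory systems
and asks, by global analysis of the parameter space, which interaction
architectures allow the procedural system to learn at all.

**Explicit system.** A deliberately minimal stand-in for rule-based,
declarative learning: the best one-dimensional criterion rule for the
category structure, applied deterministically from the first trial
(criterial noise σ²_E = 0), so the system has no free parameters.  Its
discriminant on stimulus **x** is h_E = ±(x_d − C_d) with C_d the
criterion on dimension d; the response is A when h_E < 0, otherwise B,
and |h_E| — the distance from the stimulus to the rule bound, measured
in the 25-unit grid coordinates shared with the procedural network — is
the system's confidence.  For follow-up experiments the responder can
instead be pinned to a fixed accuracy (correct with probability p,
independently per trial) while keeping the rule's confidences.

**Procedural system.** A two-layer cortical–striatal network.  625
sensory units tile the stimulus space on a 25×25 grid; unit K responds
to a stimulus at grid position **g** with the radial basis function

    I_K = exp(−d(K, g)² / σ_R),

d being Euclidean distance in grid units.  Two striatal units (one per
response) integrate the sensory layer linearly, S_J = Σ_K w_KJ I_K; the
response is A iff S_A > S_B (ties → B) and |h_P| = |S_A − S_B| is the
procedural confidence.  Synapses obey a three-factor reinforcement rule
gated by presynaptic activation, postsynaptic activation relative to the
NMDA/AMPA receptor thresholds, and phasic dopamine relative to baseline:

    Δw_K = α I_K [S_J − θ_NMDA]⁺ [D − D_base]⁺ (w_max − w_K)
         − β I_K [S_J − θ_NMDA]⁺ [D_base − D]⁺ w_K
         − γ I_K [θ_NMDA − S_J]⁺ [S_J − θ_AMPA]⁺ w_K .

A strong lateral-inhibition simplification restricts each trial's update
to the column of the striatal unit that carried the (post-injection)
procedural response.  Dopamine follows the reward-prediction error:
obtained reward R ∈ {+1, −1} (0 if feedback is withheld), predicted
reward tracks it by the single-operator rule P ← P + α_pr (R − P), and
release is piecewise linear in RPE = R − P with floor 0, baseline 0.2
at RPE = 0, and ceiling 1 (slope 0.8 between RPE = −0.25 and 1).

**Arbitration.** Trust θ_E in the explicit system (θ_P = 1 − θ_E)
starts at 0.99 and is updated every trial from the explicit *suggestion*'s
correctness: θ_E ← θ_E + Δ_OC (1 − θ_E) on correct suggestions,
θ_E ← θ_E − Δ_OE θ_E on errors.  Under soft switching the explicit
system emits the response iff θ_E |h_E| ≥ θ_P |h_P| (ties to the
rule-preferring explicit side); the hard-never-switch regime lets the
explicit system emit every response, the worst case for procedural
learning.  Feedback is routed either independently (the procedural
learner is rewarded for its own suggestion every trial) or as a single
signal (rewarded according to the emitted response).  The five
architectures are 2FB-SS, 1FB-HS, 1FB-SS and the bootstrapped 1FB-HS-B
and 1FB-SS-B.

**Bootstrapping.** On explicit-controlled trials (only), |h_E| is added
to the striatal unit matching the explicit response before feedback.
This biases the weight update toward the explicit choice without
overwriting a procedural preference that is already stronger, letting
the procedural system learn from — and eventually out-perform — the
suboptimal rule that trains it.

## Per-trial schedule

1. sensory activations I and striatal activations S_A, S_B;
2. explicit and procedural suggestions with confidences;
3. controller selection (soft) or explicit control (hard);
4. bootstrap injection if enabled and the explicit system controls;
5. emitted response; feedback; reward routed per architecture;
6. RPE and dopamine from the current predicted reward;
7. weight update on the column of the unit maximal *after* injection,
   using its post-injection activation;
8. predicted-reward and trust updates (P uses the previous trial's
   reward by construction; the trust update keys on the explicit
   suggestion's correctness regardless of controller, including in the
   hard regime, where it is recorded but behaviorally inert).

A training run is followed by a frozen-weight test pass over every
stimulus once — the asymptotic procedural accuracy used everywhere as
the outcome measure.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| σ_R | RBF width (grid units²) | 4.5 | fixed in all studies |
| θ_AMPA, θ_NMDA | receptor activation thresholds | 0.01, 0.1 | fixed; θ_NMDA > θ_AMPA |
| α, β | strengthening/weakening rates | 0.03 | search range [0.001, 1], log-spaced |
| γ | AMPA-band weakening rate | 0 | inert at these thresholds; term retained |
| α_pr | predicted-reward convergence rate | 0.07 | search range [0.005, 1] |
| D_base | baseline dopamine | 0.2 | value of D at RPE = 0 |
| w_max | weight ceiling | 1 | natural ceiling given D ∈ [0, 1] |
| θ_E(1) | initial explicit trust | 0.99 | rule-first prior |
| Δ_OC, Δ_OE | trust growth/decay rates | 0.01 | search range [0.001, 0.2] (soft-switch single-feedback space only) |
| initial weights | uniform [0.001, 0.2] | — | keeps S above θ_NMDA from trial 1, far from w_max |
| P₁ | initial predicted reward | 0 | first-trial RPE equals first reward |

Defaults for the searched rates are the geometric midpoints of their
ranges.  The initial-weight distribution is the package's choice (only
"random initial weights" is prescribed by the protocol).

## Synthetic category structures

* **II**: 300 stimuli per category from bivariate normals with means
  (40, 60) and (60, 40), common variance 167.59 and covariance 151.26,
  on a [0, 100]² space; draws falling outside the space are resampled
  (not clipped) to preserve the distribution shape.  The optimal bound
  is the main diagonal; the best 1D rule reaches ≈ 78% — the gap that
  makes the structure diagnostic of procedural learning.
* **RB**: the same distributions rotated 45° counter-clockwise about
  (50, 50), making the optimal bound the vertical line x = 50 (a
  verbalizable rule); candidates outside the space before or after
  rotation are resampled.
* **Hybrid**: 300 uniform samples per category from each side of a
  piecewise bound — vertical x = 50 on the upper half (y ≥ 50), the
  diagonal y = x on the lower half — with category A the left/upper
  region.  This structure is known only from a pictorial depiction, so
  the geometry is a reconstruction; under the uniform measure on the
  square its best 1D
  rule scores 0.875 (the regions have unequal area, so the same rule
  scores 0.90 on a balanced per-category sample).  Every sampled
  stimulus lies strictly off the bound.

The generators emulate the stimulus *coordinates* only.  No perceptual
or criterial noise, no psychophysical scaling of the underlying disk
stimuli, no response times, and no trial-by-trial human lapses are
modeled — passing tests therefore speak to the learnability structure of
the architectures, not to quantitative fits of human data.

## Training length

The protocol prescribes training "on the sample stimuli" without a
trial count, while the test phase is explicitly the *asymptotic*
procedural accuracy.  We therefore trained to asymptote: accuracy at the
slowest corners of the search ranges (α = β = 0.001) was tracked as a
function of passes through the 600-stimulus sample, on both the II and
hybrid structures.  Eight passes suffice for II; the hybrid corner is
slower (0.76 after 8 passes, 0.90 by 32, plateauing ≈ 0.93 by 64).  The
default is **32 passes (19 200 training trials)** for every study and
structure.  One pass is enough for mid-range parameters; the long tail
exists only at the learning-rate floor.

## Parameter-space partitioning

A parameter point's *data pattern* is the decile of its procedural test
accuracy (left-closed, right-open, top decile closed; the never-switch
model's 60s decile is split into 60–64/65–69 for resolution), averaged
over a fixed bank of 19 stimulus orderings + weight initializations so
that the map is deterministic.  The primary search is an exhaustive
log-spaced lattice — 8 points/axis on the three-axis spaces (512
points), 5 points/axis on the five-axis soft-switch space (3125 points,
evaluated on a 7-seed subset of the bank) — with a pattern's volume
estimated as its fraction of lattice points (equal cell weights in log
space).  A light region-growing Monte-Carlo search is provided as a
cross-check; its volume estimates (sample fractions) are cruder, and
the lattice is the canonical path.  The originally reported volumes
came from an MCMC partitioning whose internals are not public, so
volume figures should be compared at grid-surrogate, not printed,
precision.

Each pattern's **representative** is its member point closest to the
pattern's log-space centroid — a geometric notion of typicality.  (The
member with median accuracy is often a corner of the hypercube, where
takeover and learning decouple in ways a chain-based search would not
report.)  The robustness stage re-runs each representative on 200 fresh
random orderings/initializations; the accuracy-takeover correlation is
the Pearson r between representative mean accuracy and mean number of
procedural-controlled responses, computed on the partition's own
stimulus sample for both seed banks.

## Numerical choices and degenerate inputs

* Ties: S_A = S_B responds B; θ_E|h_E| = θ_P|h_P| gives control to the
  explicit system; rule fitting breaks ties toward dimension x, positive
  polarity, smallest criterion.
* Weights are clamped to [0, w_max] after each update as a safety net
  against overshoot at the extremes of the rate ranges (the rule's own
  gain terms bound the fixed points but not a single large step).
* All randomness in a run (weights, ordering, degraded-responder error
  trials) derives from one run seed through independent spawned
  streams; batches over a seed bank reproduce the corresponding single
  runs bit-for-bit.  The trial loop exists twice — a numba kernel for
  the ~10⁵-run partitions and a vectorized numpy fallback — and both are
  cross-checked against the readable reference loop in the test suite.
* Weight-ratio maps guard denominators below 10⁻³ (cells flagged rather
  than infinite), keeping outputs serializable where a unit's weights
  are driven to zero.
* Degenerate configurations fail loudly: non-positive-definite category
  covariances, empty stimulus sets, rates outside (0, 1], the
  independent-feedback/hard-switch combination, and zero-variance
  correlation inputs all raise errors.

## Known limitations

* The explicit system never selects or switches rules; results are a
  best case for explicit performance and say nothing about hypothesis
  testing.
* Grid-surrogate volumes and pattern representatives differ from a
  chain-based partitioning; the accuracy–takeover correlations are the
  quantity most sensitive to that choice.
* The soft-switch single-feedback model's takeover dynamics produce a
  genuine mid-session accuracy drop when trust decays before the
  procedural system has learned; only bootstrapped and
  independent-feedback runs are claimed to be discontinuity-free.
* The hybrid-bound geometry is a reconstruction from a verbal
  description; quantities tied to its exact areas (e.g., the 1D-rule
  ceiling) carry that approximation.
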