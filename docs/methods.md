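# Methods

## The problem

In a two-alternative perceptual discrimination around a neutral point — here,
judging whether a grating is tilted clockwise or counterclockwise of a
cardinal orientation — an observer's tendency to favor one response can have
two distinct origins. A *sensory* bias is a shift in the internal stimulus
representation: the orientation that looks neutral is not the physical
neutral. A *decisional* bias is a shift of the decision criterion: the
evidence is mapped to responses asymmetrically. With a single
stimulus-response mapping the two are indistinguishable — the psychometric
function's location confounds them.

The method exploits a mapping manipulation: the observer performs the same
discrimination under two mirrored response mappings (a reference imagined on
the right versus the left, or top versus bottom). A sensory bias moves both
psychometric curves the same way; a criterion shift moves them in opposite
directions, because the criterion is defined relative to the response
mapping. Fitting the two curves jointly therefore separates the biases.

## Models

### Symmetric-task SDT family

The probability of a clockwise-consistent response to orientation θ (degrees,
positive = clockwise) is a cumulative normal:

- primary mapping: `P = Φ((θ − (δD − δS)) / σ1)`
- mirrored mapping: `P = Φ((θ − (−δD − δS)) / σ2)`

with sensory bias δS, decisional bias δD (degrees), and slope σ (degrees of
internal noise). This is the stimulus-space form of a standard
signal-detection model with linear transduction: an evidence-space intercept,
criterion and gain reduce to δS, δD and σ, which is why only the
stimulus-space parameters are represented.

Lapses deform the asymptotes: `P → λ1 + (1 − λ1 − λ2)·Φ` per mapping, with
independent (λ1′, λ2′) for the mirrored mapping when the four-lapse structure
is active. The diagnostic key-preference lapse λ* sits on *opposite*
asymptotes of the two mappings (upper asymptote of the primary, lower of the
mirrored): a stimulus-independent preference for one physical response key
presses the two curves in opposite directions, which is also the signature of
a criterion shift — hence the diagnostic. λ* is only statistically
identified on top of the two-lapse structure (one shared lapse per mapping);
with four free asymptote parameters it enters only through sums with them and
the likelihood-ratio test would be vacuous. The λ* test therefore uses the
two-lapse base.

### Asymmetric-task interval family

For the "aligned or not?" task the observer responds *aligned* when the
internal estimate falls inside a criterion interval:

`P = Φ((θ − (m − h)) / σ) − Φ((θ − (m + h)) / σ)`

with center `m = δS + δD` (primary) or `δS − δD` (mirrored) and half-width
`h` per mapping. The sensory bias moves both bell-shaped curves together; an
antisymmetric decisional bias δD moves them apart; a symmetric decisional
bias (different interval widths across mappings) changes their height/width
without moving the peaks. This parameterization was designed to reproduce the
observed qualitative patterns; no canonical closed form for this task was
available, so it is this package's own construction.

### Indecision family

A high-threshold alternative: evidence below τ1 yields one response, above τ2
the other, and inside the uncertainty interval the observer guesses the
clockwise-consistent key with probability ξ (primary mapping) or 1 − ξ
(mirrored). In stimulus space, with z = θ − δS:

`P = Φ((z − τ2)/σ) + g·[Φ((τ2 − z)/σ) − Φ((τ1 − z)/σ)]`, g ∈ {ξ, 1 − ξ}.

Note the joint likelihood depends on δS only through δS + τ1 and δS + τ2, so
the nominal five parameters contain one flat direction; the AIC nevertheless
uses the nominal count (the model *is* specified with five parameters), which
matches the convention that it has two parameters more than the SDT model.
The reduced variant forces symmetric bounds (τ1 = −τ2 around the shifted
percept), leaving four parameters.

## Fitting

Trials aggregate exactly into binomial cells (k of n at each level × mapping;
levels matched after rounding at 1e−6 deg, appropriate for constant-stimuli
designs). The log-likelihood is the sum of binomial log-densities, binomial
coefficients included, with success probabilities from the model. Fitting is
bounded Nelder–Mead from 8 deterministic multi-starts: bias starts from the
empirical 50%-crossings of the two mappings (their half-sum and
half-difference estimate −δS and δD), σ from the empirical 25–75% spread,
lapses from 0.01; the remaining starts are seeded jitters of that point. The
best start is polished by simplex restarts until formal convergence.
Parameter boxes: biases ±10 deg, σ and half-widths in [0.05, 10] deg, lapses
in [0, 0.45], ξ in [0, 1] — all far outside the ±2 deg stimulus range.
Probabilities are clipped to [1e−10, 1 − 1e−10] inside likelihoods only,
never in the model functions. Inside the model-selection ladder, each nested
fit is warm-started from the neighbouring model's optimum (projected by
parameter name) plus 4 jittered starts; this preserves the nesting
monotonicity of maximized likelihoods, which is additionally guarded — if a
reduced optimum ever beats its fuller model, the fuller model is refit from
the embedded reduced optimum, and a residual deficit beyond 1e−6 nats raises
an error rather than producing a negative test statistic.

## Model selection and classification

Starting from the fullest symmetric spec (two slopes, four lapses, both
biases free), consecutive likelihood-ratio tests at α = 0.05 (χ² reference,
df = parameter-count difference) reduce: lapses four → two → one → none,
then slopes two → one. Lapse structure is resolved before slopes because
asymptote misfit distorts slope estimates more than vice versa; any fixed
order is defensible and this one is frozen. When a lapse-free model is
compared against lapsed ones its lapses are pinned at 0.01 rather than 0,
which describes real observers better. The survivor always keeps δS, δD and
σ free.

From the survivor, the reductions δD = 0, δS = 0 and δS = δD = 0 are tested.
A reduction "fits better" when the test fails to reject it: labels are
*sensory* (δD droppable, δS not), *decisional* (the reverse),
*sensory_plus_decisional* (neither droppable), *no_bias* (both droppable and
the joint reduction not rejected). If both single reductions are acceptable
but the joint one is rejected, the reduction with the lower AIC wins.
Reported δS and δD come from the structure-selected fit in which both are
free. χ² reference distributions are used even for boundary parameters
(lapses, λ*, ξ); the resulting conservatism is documented, not corrected —
the λ* test's realized false-positive rate is ≈1–3% at nominal α = 5%.

The SDT-versus-indecision comparison is by AIC between the *bare* models:
3-parameter SDT versus the 5-parameter indecision model and its 4-parameter
symmetric-bounds variant. Comparing bare against bare keeps the contest
about the bias mechanism; a structure-selected SDT spec can carry a
boundary-stuck lapse parameter (λ̂ = 0 retained only because of the 0.01 pin
on the null side) whose AIC penalty would decide the comparison for reasons
unrelated to either mechanism. AIC values within 1e−6 are ties, resolved
toward fewer parameters and then toward SDT.

## Synthetic data

The generator emulates the constant-stimuli design the analysis assumes: 9
levels from −2 to 2 deg in 0.5-deg steps, 30 trials per level per mapping
(the per-cell count of a 6-blocks-of-360-trials session spread over 8
intermixed conditions), both mappings, Bernoulli responses under any model in
the family, trial order shuffled deterministically by seed. A blocked-session
preset (4 × 270 trials, one task, 60 per cell) is also provided. Population
draws use δS ~ U(−1.5, 1.5), δD ~ U(−0.5, 0.5), σ ~ U(0.3, 1.0) deg — the
magnitudes a typical observer sample spans, with sensory biases about three
times the decisional ones; these ranges are package choices for simulation
studies, not measured values.

Not simulated: trial-order and history effects (the models are history-free),
reaction times, block-order effects, and evidence-space trajectories.
Passing tests therefore show that the pipeline is correct and calibrated
*for data generated by its own model family under this design*; they do not
certify behavior under serial dependencies, drifting criteria, or non-normal
evidence distributions.

## Validation studies and problem sizes

The studies the test suite and `scripts/acceptance.py` run, with the sizes
chosen for them: parameter recovery (100 groups; median absolute error of
both biases ≈ 0.03 deg, well under the 0.15-deg tolerance), classification
specificity (150 null groups; false-assignment rates checked against the
exact binomial 99% interval around α), sensitivity (100 groups each for a
1-deg sensory and a 0.5-deg decisional bias; ≥ 95% correct labels),
SDT-versus-indecision AIC wins on criterion-shift data (50 groups), and the
λ* false-positive rate on criterion-shift data (100 groups).

## Known limitations

- The 0.01 lapse pin interacts with *lapse-free* data: when many cells are
  saturated, the free-lapse model "significantly" beats the pinned model by
  escaping to λ̂ = 0, so clean low-σ groups often retain a boundary-stuck
  lapse parameter. On real data, where small lapses are ubiquitous, the
  convention helps; on synthetic clean data it inflates selected structures
  (bias labels are unaffected).
- λ* is directional: it encodes a preference for the key that is
  clockwise-consistent under the mirrored mapping. A preference for the
  opposite key would need the mirror-image model; on null data the test is
  symmetric, so calibration results are unaffected.
- The indecision model's flat likelihood direction (δS confounded with the
  interval bounds) is harmless to the simplex optimizer but means its
  reported δS is not interpretable in isolation.
- Group-level summaries pool a participant's two orientation bands as
  independent observations (matching the conventional degrees of freedom for
  this design) although they share a participant.
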