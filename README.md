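# choicebias

Decoupling **sensory** from **decisional** choice biases in two-alternative
perceptual decisions.

When an observer judges whether a grating is tilted clockwise or
counterclockwise of vertical, a tendency to answer "clockwise" too often can
mean two very different things: the orientation that *looks* vertical is
itself tilted (a sensory bias, δS), or the decision criterion favors one
response (a decisional bias, δD). With a single stimulus–response mapping the
psychometric function's location confounds them — it estimates only δD − δS.

The method implemented here separates the two by fitting the two mirrored
response mappings of the same discrimination **jointly**. The probability of
a clockwise-consistent response is

- primary mapping: P(θ) = Φ((θ − (δD − δS)) / σ₁)
- mirrored mapping: P(θ) = Φ((θ − (−δD − δS)) / σ₂)

so a sensory bias shifts both curves together while a criterion shift moves
them apart, and δS and δD become separately identifiable. On top of this
core the package provides:

- slope and lapse extensions (two slopes; one, two or four lapse rates; the
  diagnostic key-preference lapse λ*), with a consecutive
  likelihood-ratio-test ladder (α = 0.05) that selects the simplest adequate
  structure per group;
- a four-way bias classification per group (*no bias*, *sensory*,
  *decisional*, *sensory + decisional*) from LRTs of the bias reductions;
- an AIC comparison of the SDT account against a high-threshold
  **indecision** model (guessing inside an uncertainty interval), in full and
  symmetric-bounds variants;
- an interval-judgment model for the asymmetric ("aligned or not?") task;
- a constant-stimuli simulator (9 levels from −2° to 2°, 30 trials per level
  per mapping by default) and population generator with ground-truth tables;
- a dataset pipeline (screening of non-modulated/inverted groups, per-group
  classification, group-level summaries) and a small CLI.

Estimators follow scikit-learn conventions (`PsychometricModel`,
`BiasClassifier` with `fit`, `predict_proba`, `get_params`); module-level
functions (`fit_mle`, `select_structure`, `classify_bias`, ...) are thin
wrappers over the same core.

## Worked example

```python
import choicebias as cb

design = cb.DesignSpec()  # 9 levels x 30 trials x 2 reference mappings
params = cb.SymmetricParams(delta_s=0.8, delta_d=-0.3, sigma_primary=0.6)
trials = cb.simulate_group(design, "symmetric_sdt", params, seed=7)

cls = cb.classify_bias(trials, seed=3)
print(f"label      : {cls.label}")
print(f"delta_s_hat: {cls.delta_s_hat:+.3f} deg (true +0.800)")
print(f"delta_d_hat: {cls.delta_d_hat:+.3f} deg (true -0.300)")

comp = cb.compare_indecision(trials, seed=3)
print(f"AIC  SDT {comp.aic_sdt:.1f} | indecision {comp.aic_indecision:.1f} | "
      f"symmetric-bounds {comp.aic_indecision_symmetric:.1f}"
      f" -> winner {comp.winner}")
```

prints

```
label      : sensory_plus_decisional
delta_s_hat: +0.808 deg (true +0.800)
delta_d_hat: -0.306 deg (true -0.300)
AIC  SDT 41.7 | indecision 45.7 | symmetric-bounds 43.7 -> winner sdt
```

Both generating biases are recovered to within a few hundredths of a degree
and classified correctly, and the signal-detection account beats both
indecision variants by AIC, as it should on data it generated.

The same analysis runs from the shell: `choicebias simulate` /
`fit` / `classify` / `compare-indecision` / `report` (see
`choicebias --help`).

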