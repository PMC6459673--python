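"""Model selection: the LRT reduction ladder, bias classification and the
SDT-versus-indecision comparison.

The fullest symmetric-task model (two slopes, four lapses, both biases free)
is reduced by *consecutive* likelihood-ratio tests at alpha = 0.05, lapse
structure first (four → two → one → none), then slopes (two → one); the
survivor always keeps ``delta_s``, ``delta_d`` and ``sigma`` free.  When a
lapse-free model is compared against lapsed ones its lapses are pinned at
0.01 rather than 0, which fits real observers better.

From the surviving structure the three bias reductions (``delta_d = 0``,
``delta_s = 0``, both zero) classify the group as *sensory*, *decisional*,
*no_bias* or *sensory_plus_decisional*: a reduction "fits better" when the
LRT fails to reject it.

Two diagnostics accompany classification: the lambda-star LRT asks whether an
extra stimulus-independent key-preference lapse (placed on opposite
asymptotes of the two mappings) explains the data as well as a criterion
shift would, and :func:`compare_indecision` pits the selected SDT model
against the high-threshold indecision model by AIC.

Boundary caveat: lapse-type parameters sit at 0 under their null, where the
chi-squared reference distribution is conservative; following the source
procedure the plain chi-squared tail is used regardless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .data import Cells
from .fitting import FitResult, _Layout, _coerce_cells, fit_mle
from .models import ModelSpec

__all__ = [
    "OptimizerFailureError", "LadderStep", "StructureSelection",
    "BiasClassification", "IndecisionComparison",
    "likelihood_ratio_test", "select_structure", "classify_bias",
    "lambda_star_check", "compare_indecision", "BiasClassifier",
]

#: lapse value used for lapse-free models inside comparisons
COMPARISON_FIXED_LAPSE = 0.01

#: heuristic multi-starts used for each fit inside the ladder, on top of the
#: warm start projected from the neighbouring model in the nesting chain
LADDER_STARTS = 4


class OptimizerFailureError(RuntimeError):
    """A nested fit beat its fuller model beyond numerical tolerance."""


@dataclass
class LadderStep:
    """One likelihood-ratio test between nested specs."""

    full_spec: ModelSpec
    reduced_spec: ModelSpec
    lr_statistic: float
    df: int
    p_value: float
    kept: str  # "full" | "reduced"
    full_fit: FitResult | None = field(default=None, repr=False)
    reduced_fit: FitResult | None = field(default=None, repr=False)


@dataclass
class StructureSelection:
    """Surviving fit of the structure ladder plus the test trail."""

    fit: FitResult
    steps: list[LadderStep]


@dataclass
class BiasClassification:
    """Four-way bias label with its supporting test trail.

    ``delta_s_hat`` / ``delta_d_hat`` come from the structure-selected fit in
    which both biases are free; ``selected_spec`` is the accepted reduction.
    """

    label: str
    selected_spec: ModelSpec
    delta_s_hat: float
    delta_d_hat: float
    trail: list[LadderStep]
    selected_fit: FitResult | None = field(default=None, repr=False)
    structure_fit: FitResult | None = field(default=None, repr=False)


@dataclass
class IndecisionComparison:
    """AIC comparison of the selected SDT fit against the indecision model."""

    aic_sdt: float
    aic_indecision: float
    aic_indecision_symmetric: float
    winner: str
    sdt_fit: FitResult = field(repr=False, default=None)
    indecision_fit: FitResult = field(repr=False, default=None)
    indecision_symmetric_fit: FitResult = field(repr=False, default=None)


_LAPSE_ORDER = {"none": 0, "one": 1, "two": 2, "four": 3}


def _is_nested(full: ModelSpec, reduced: ModelSpec) -> bool:
    if full.family != reduced.family:
        return False
    if _LAPSE_ORDER[reduced.lapse_structure] > _LAPSE_ORDER[full.lapse_structure]:
        return False
    if reduced.n_sigmas > full.n_sigmas:
        return False
    if reduced.with_lambda_star and not full.with_lambda_star:
        return False
    if full.symmetric_bounds and not reduced.symmetric_bounds:
        return False
    bias_sets = {"full": {"delta_s", "delta_d"}, "sensory_only": {"delta_s"},
                 "decisional_only": {"delta_d"}, "none": set()}
    if not bias_sets[reduced.bias_structure] <= bias_sets[full.bias_structure]:
        return False
    return reduced.n_parameters < full.n_parameters


def likelihood_ratio_test(full: FitResult, reduced: FitResult,
                          alpha: float = 0.05) -> LadderStep:
    """Chi-squared LRT of a reduced spec against the fuller spec.

    ``kept`` is the full spec iff p < alpha.  A likelihood deficit of the
    fuller model beyond 1e-6 nats raises :class:`OptimizerFailureError`.
    """
    if not _is_nested(full.spec, reduced.spec):
        raise ValueError("reduced spec is not nested in the full spec")
    df = full.n_parameters - reduced.n_parameters
    stat = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    if stat < -1e-6:
        raise OptimizerFailureError(
            f"reduced model beats full model by {-stat / 2:.3g} nats; "
            "the optimizer failed on the fuller spec")
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, df))
    return LadderStep(full.spec, reduced.spec, float(stat), int(df), p,
                      "full" if p < alpha else "reduced",
                      full_fit=full, reduced_fit=reduced)


def _warm_fit(cells: Cells, spec: ModelSpec, seed: int,
              parent: FitResult | None, n_starts: int) -> FitResult:
    extra = None
    if parent is not None:
        extra = [_Layout(spec).vector(parent.params)]
    return fit_mle(cells, spec, seed=seed, n_starts=n_starts,
                   extra_starts=extra)


def _guarded_step(cells: Cells, full_fit: FitResult, reduced_fit: FitResult,
                  alpha: float, seed: int) -> tuple[LadderStep, FitResult]:
    """LRT with a monotonicity guard: if the reduced optimum beats the full
    one, refit the fuller spec from the reduced optimum (which embeds in the
    full space) before testing."""
    if reduced_fit.log_likelihood > full_fit.log_likelihood + 1e-9:
        refit = _warm_fit(cells, full_fit.spec, seed, reduced_fit, 1)
        if refit.log_likelihood > full_fit.log_likelihood:
            full_fit = refit
    return likelihood_ratio_test(full_fit, reduced_fit, alpha), full_fit


def select_structure(table, family: str = "symmetric_sdt", seed: int = 0,
                     alpha: float = 0.05, n_starts: int = 8) -> StructureSelection:
    """Reduce the fullest spec by consecutive LRTs; biases stay free.

    Ladder order: lapses four → two → one → none (fixed at 0.01), then two
    slopes → one.  Each reduced fit is warm-started from the survivor.
    """
    cells = _coerce_cells(table)
    full_spec = ModelSpec(family=family, n_sigmas=2, lapse_structure="four",
                          bias_structure="full",
                          fixed_lapse=COMPARISON_FIXED_LAPSE)
    current = fit_mle(cells, full_spec, seed=seed, n_starts=n_starts)
    if not current.converged:
        raise OptimizerFailureError(f"fit did not converge for {full_spec}")
    steps: list[LadderStep] = []

    for lapse in ("two", "one", "none"):
        reduced_spec = current.spec.reduced(lapse_structure=lapse)
        reduced = _warm_fit(cells, reduced_spec, seed, current, LADDER_STARTS)
        if not reduced.converged:
            raise OptimizerFailureError(f"fit did not converge for {reduced_spec}")
        step, current = _guarded_step(cells, current, reduced, alpha, seed)
        steps.append(step)
        if step.kept == "full":
            break
        current = reduced

    if current.spec.n_sigmas == 2:
        reduced_spec = current.spec.reduced(n_sigmas=1)
        reduced = _warm_fit(cells, reduced_spec, seed, current, LADDER_STARTS)
        if not reduced.converged:
            raise OptimizerFailureError(f"fit did not converge for {reduced_spec}")
        step, current = _guarded_step(cells, current, reduced, alpha, seed)
        steps.append(step)
        if step.kept == "reduced":
            current = reduced

    return StructureSelection(fit=current, steps=steps)


def classify_bias(table, family: str = "symmetric_sdt", alpha: float = 0.05,
                  seed: int = 0, n_starts: int = 8) -> BiasClassification:
    """Classify a group's bias by LRTs against the selected structure.

    A reduction "provides a better fit" when the LRT fails to reject it
    (p >= alpha).  When both single-bias reductions are individually
    acceptable but the both-zero reduction is rejected, the reduction with
    the lower AIC wins.
    """
    cells = _coerce_cells(table)
    sel = select_structure(cells, family=family, seed=seed, alpha=alpha,
                           n_starts=n_starts)
    base = sel.fit
    trail = list(sel.steps)

    fit_d0 = _warm_fit(cells, base.spec.reduced(bias_structure="sensory_only"),
                       seed, base, LADDER_STARTS)
    step_d, base = _guarded_step(cells, base, fit_d0, alpha, seed)
    fit_s0 = _warm_fit(cells, base.spec.reduced(bias_structure="decisional_only"),
                       seed, base, LADDER_STARTS)
    step_s, base = _guarded_step(cells, base, fit_s0, alpha, seed)
    trail += [step_d, step_s]

    ds_hat = float(getattr(base.params, "delta_s", 0.0))
    dd_hat = float(getattr(base.params, "delta_d", 0.0))

    d_ok = step_d.kept == "reduced"   # delta_d = 0 acceptable
    s_ok = step_s.kept == "reduced"   # delta_s = 0 acceptable

    if not d_ok and not s_ok:
        return BiasClassification("sensory_plus_decisional", base.spec,
                                  ds_hat, dd_hat, trail,
                                  selected_fit=base, structure_fit=base)
    if d_ok and not s_ok:
        return BiasClassification("sensory", fit_d0.spec, ds_hat, dd_hat,
                                  trail, selected_fit=fit_d0, structure_fit=base)
    if s_ok and not d_ok:
        return BiasClassification("decisional", fit_s0.spec, ds_hat, dd_hat,
                                  trail, selected_fit=fit_s0, structure_fit=base)

    fit_00 = _warm_fit(cells, base.spec.reduced(bias_structure="none"),
                       seed, base, LADDER_STARTS)
    step_0, base = _guarded_step(cells, base, fit_00, alpha, seed)
    trail.append(step_0)
    if step_0.kept == "reduced":
        return BiasClassification("no_bias", fit_00.spec, ds_hat, dd_hat,
                                  trail, selected_fit=fit_00, structure_fit=base)
    # both single reductions acceptable, joint rejected: lower AIC wins
    if fit_d0.aic <= fit_s0.aic:
        return BiasClassification("sensory", fit_d0.spec, ds_hat, dd_hat,
                                  trail, selected_fit=fit_d0, structure_fit=base)
    return BiasClassification("decisional", fit_s0.spec, ds_hat, dd_hat,
                              trail, selected_fit=fit_s0, structure_fit=base)


def lambda_star_check(table, seed: int = 0, alpha: float = 0.05,
                      n_sigmas: int = 1) -> LadderStep:
    """LRT for the key-preference lapse lambda-star (diagnostic only).

    The base model carries one shared lapse per reference mapping (the
    "two"-lapse structure); lambda-star is added as one extra parameter
    sitting on opposite asymptotes of the two mappings — the signature of a
    stimulus-independent preference for one response key.  This is the only
    lapse structure on which lambda-star is identified: with four free
    asymptotes it is redundant (it enters only through sums with them).

    Under a pure criterion shift the test should not reject, which is what
    separates decisional biases from key-preference lapses.
    """
    cells = _coerce_cells(table)
    base_spec = ModelSpec(family="symmetric_sdt", n_sigmas=n_sigmas,
                          lapse_structure="two", bias_structure="full")
    base = fit_mle(cells, base_spec, seed=seed, n_starts=8)
    star_spec = base_spec.reduced(with_lambda_star=True)
    star_fit = _warm_fit(cells, star_spec, seed, base, LADDER_STARTS)
    step, _ = _guarded_step(cells, star_fit, base, alpha, seed)
    return step


def compare_indecision(table, seed: int = 0) -> IndecisionComparison:
    """Fit the SDT model and both indecision variants; lowest AIC wins.

    The contest is between bias *mechanisms*, so it pits the bare models
    against each other: the three-parameter SDT model (delta_s, delta_d,
    sigma) versus the indecision model, which replaces the criterion by the
    two uncertainty-interval bounds and introduces the guess probability (two
    parameters more), and versus the reduced variant with symmetric bounds
    ``c1 = -c2``.  With equal AIC the model with fewer parameters wins, and
    SDT wins remaining ties.
    """
    cells = _coerce_cells(table)
    sdt = fit_mle(cells, ModelSpec(family="symmetric_sdt"), seed=seed,
                  n_starts=8)
    ind_full = fit_mle(cells, ModelSpec(family="indecision"), seed=seed,
                       n_starts=8)
    ind_sym = _warm_fit(cells, ModelSpec(family="indecision",
                                         symmetric_bounds=True),
                        seed, ind_full, LADDER_STARTS)
    cand = [("sdt", sdt), ("indecision", ind_full),
            ("indecision_symmetric", ind_sym)]
    order = {"sdt": 0, "indecision_symmetric": 1, "indecision": 2}
    # AICs within numerical round-off are ties: fewer parameters wins,
    # then the SDT model
    best_aic = min(f.aic for _, f in cand)
    tied = [(nm, f) for nm, f in cand if f.aic <= best_aic + 1e-6]
    winner = min(tied, key=lambda kv: (kv[1].n_parameters, order[kv[0]]))[0]
    return IndecisionComparison(
        aic_sdt=sdt.aic, aic_indecision=ind_full.aic,
        aic_indecision_symmetric=ind_sym.aic, winner=winner,
        sdt_fit=sdt, indecision_fit=ind_full, indecision_symmetric_fit=ind_sym)


class BiasClassifier:
    """Scikit-learn-style wrapper around :func:`classify_bias`.

    ``X`` as in :class:`~choicebias.fitting.PsychometricModel`; after
    :meth:`fit` the four-way label is in ``label_`` and the bias estimates in
    ``delta_s_`` / ``delta_d_``.
    """

    def __init__(self, family="symmetric_sdt", alpha=0.05, n_starts=8,
                 random_state=0):
        self.family = family
        self.alpha = alpha
        self.n_starts = n_starts
        self.random_state = random_state

    _param_names = ("family", "alpha", "n_starts", "random_state")

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        from .data import cells_from_arrays
        from .fitting import PsychometricModel
        theta, side = PsychometricModel._coerce_X(X)
        cells = cells_from_arrays(theta, side, np.asarray(y, dtype=float))
        self.classification_ = classify_bias(
            cells, family=self.family, alpha=self.alpha,
            seed=self.random_state, n_starts=self.n_starts)
        self.label_ = self.classification_.label
        self.delta_s_ = self.classification_.delta_s_hat
        self.delta_d_ = self.classification_.delta_d_hat
        self.selected_spec_ = self.classification_.selected_spec
        self.trail_ = self.classification_.trail
        return self
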