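"""Tests for the joint binomial likelihood and maximum-likelihood fitting."""

import numpy as np
import pandas as pd
import pytest

import choicebias as cb
from choicebias.data import aggregate_cells, cells_from_arrays
from choicebias.fitting import _Layout, _neg_ll_factory
from tests.conftest import make_symmetric_group


class TestLogLikelihood:
    def test_single_bernoulli_reduction(self):
        """One cell with n = 1, k = 1 gives exactly log p."""
        table = pd.DataFrame([
            {"participant": "p", "task": "symmetric",
             "orientation_band": "horizontal", "reference": "primary",
             "orientation_deg": 0.5, "response": 1}])
        params = cb.SymmetricParams(delta_s=0.2, delta_d=0.1,
                                    sigma_primary=0.7)
        p = cb.p_choice_symmetric(0.5, params, "primary")
        ll = cb.log_likelihood(table, cb.ModelSpec(), params)
        assert ll == pytest.approx(np.log(p), abs=1e-12)

    def test_matches_factorial_oracle_on_toy_table(self, toy_table,
                                                   binom_logpmf):
        """The joint likelihood equals the sum of explicitly enumerated
        binomial log-pmfs over the 4 cells."""
        params = cb.SymmetricParams(delta_s=0.3, delta_d=-0.2,
                                    sigma_primary=0.8)
        expected = 0.0
        for ref, theta, k in [("primary", -1.0, 2), ("primary", 1.0, 9),
                              ("mirrored", -1.0, 3), ("mirrored", 1.0, 7)]:
            p = cb.p_choice_symmetric(theta, params, ref)
            expected += binom_logpmf(k, 10, p)
        ll = cb.log_likelihood(toy_table, cb.ModelSpec(), params)
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_single_reference_degeneracy(self, symmetric_group):
        """With primary-only data the likelihood depends on the biases only
        through delta_d - delta_s: translating both leaves it unchanged."""
        table = symmetric_group(delta_s=0.5, delta_d=0.25, seed=11)
        table = table[table["reference"] == "primary"]
        cells = aggregate_cells(table)
        spec = cb.ModelSpec()
        base = cb.log_likelihood(cells, spec, cb.SymmetricParams(
            delta_s=0.5, delta_d=0.25, sigma_primary=0.6))
        for t in (-1.0, -0.1, 0.1, 1.0, 3.0):
            shifted = cb.log_likelihood(cells, spec, cb.SymmetricParams(
                delta_s=0.5 + t, delta_d=0.25 + t, sigma_primary=0.6))
            assert abs(shifted - base) <= 1e-12

    def test_empty_table_raises(self):
        with pytest.raises(Exception):
            cb.log_likelihood(pd.DataFrame(columns=["orientation_deg",
                                                    "reference", "response"]),
                              cb.ModelSpec(),
                              cb.SymmetricParams(sigma_primary=1.0))

    @pytest.mark.parametrize("spec", [
        cb.ModelSpec(n_sigmas=2, lapse_structure="four"),
        cb.ModelSpec(lapse_structure="four_plus_star"),
        cb.ModelSpec(family="indecision"),
        cb.ModelSpec(family="indecision", symmetric_bounds=True),
    ])
    def test_optimizer_objective_agrees_with_public_likelihood(self, spec):
        """The specialized optimizer objective and the public model-function
        path compute the same likelihood."""
        if spec.family == "indecision":
            params = cb.IndecisionParams(delta_s=0.1, tau1=-0.4, tau2=0.6,
                                         xi=0.3, sigma=0.5)
            table = cb.simulate_group(cb.DesignSpec(), "indecision", params,
                                      seed=4)
        else:
            table = make_symmetric_group(delta_s=0.4, delta_d=-0.2, seed=4,
                                         lam1=0.05, lam2p=0.08)
        cells = aggregate_cells(table)
        layout = _Layout(spec)
        neg_ll = _neg_ll_factory(layout, cells)
        rng = np.random.default_rng(0)
        from choicebias.models import InvalidParameterError
        for _ in range(6):
            x = layout.clip(np.array([rng.uniform(lo, hi)
                                      for lo, hi in layout.bounds]))
            try:
                params = layout.build(x)
            except InvalidParameterError:
                # constraint-violating points get the penalty value
                assert neg_ll(x) == 1e12
                continue
            assert -neg_ll(x) == pytest.approx(
                cb.log_likelihood(cells, spec, params), abs=1e-9)


class TestFitMLE:
    def test_recovers_generating_parameters(self, symmetric_group):
        table = symmetric_group(delta_s=0.8, delta_d=-0.3, sigma=0.6, seed=7)
        fit = cb.fit_mle(table, cb.ModelSpec(), seed=1)
        assert fit.converged
        assert fit.estimates["delta_s"] == pytest.approx(0.8, abs=0.2)
        assert fit.estimates["delta_d"] == pytest.approx(-0.3, abs=0.2)
        assert fit.estimates["sigma_primary"] == pytest.approx(0.6, abs=0.2)

    def test_noise_free_self_consistency(self):
        """At saturating n the estimates match the generating values."""
        table = make_symmetric_group(delta_s=0.0, delta_d=0.0, sigma=0.5,
                                     seed=3, n_per_level=400)
        fit = cb.fit_mle(table, cb.ModelSpec(), seed=2)
        assert fit.estimates["delta_s"] == pytest.approx(0.0, abs=0.06)
        assert fit.estimates["delta_d"] == pytest.approx(0.0, abs=0.06)
        assert fit.estimates["sigma_primary"] == pytest.approx(0.5, abs=0.06)

    def test_deterministic_refit(self, symmetric_group):
        """Same table, spec and seed give a bit-identical result."""
        table = symmetric_group(delta_s=0.4, delta_d=0.1, seed=9)
        a = cb.fit_mle(table, cb.ModelSpec(lapse_structure="one"), seed=5)
        b = cb.fit_mle(table, cb.ModelSpec(lapse_structure="one"), seed=5)
        assert a.log_likelihood == b.log_likelihood
        assert a.estimates == b.estimates
        assert a.start_log_likelihoods == b.start_log_likelihoods

    def test_aic_consistency(self, symmetric_group):
        table = symmetric_group(seed=13)
        fit = cb.fit_mle(table, cb.ModelSpec(), seed=0)
        assert fit.aic == pytest.approx(
            2 * fit.n_parameters - 2 * fit.log_likelihood, abs=1e-12)
        assert fit.log_likelihood == pytest.approx(
            cb.log_likelihood(table, fit.spec, fit.params), abs=1e-8)

    def test_fit_beats_generating_parameters(self, symmetric_group):
        """The optimum cannot be worse than the true generating point."""
        truth = cb.SymmetricParams(delta_s=0.8, delta_d=-0.3,
                                   sigma_primary=0.6)
        table = symmetric_group(delta_s=0.8, delta_d=-0.3, sigma=0.6, seed=21)
        fit = cb.fit_mle(table, cb.ModelSpec(), seed=3)
        assert fit.log_likelihood >= cb.log_likelihood(
            table, cb.ModelSpec(), truth) - 1e-6

    def test_nesting_monotonicity(self, symmetric_group):
        """A fuller spec's optimum is at least as good as a nested spec's."""
        table = symmetric_group(delta_s=0.5, delta_d=0.2, seed=17)
        cells = aggregate_cells(table)
        lls = {}
        for name, spec in [
                ("basic", cb.ModelSpec()),
                ("one", cb.ModelSpec(lapse_structure="one")),
                ("four", cb.ModelSpec(lapse_structure="four")),
                ("full", cb.ModelSpec(lapse_structure="four", n_sigmas=2))]:
            lls[name] = cb.fit_mle(cells, spec, seed=1).log_likelihood
        assert lls["one"] >= lls["basic"] - 1e-6
        assert lls["four"] >= lls["one"] - 1e-6
        assert lls["full"] >= lls["four"] - 1e-6

    def test_row_order_invariance(self, symmetric_group):
        table = symmetric_group(delta_s=0.3, seed=19)
        shuffled = table.sample(frac=1.0, random_state=42).reset_index(drop=True)
        a = cb.fit_mle(table, cb.ModelSpec(), seed=4)
        b = cb.fit_mle(shuffled, cb.ModelSpec(), seed=4)
        assert a.log_likelihood == b.log_likelihood
        assert a.estimates == b.estimates

    def test_single_reference_warns(self, symmetric_group):
        table = symmetric_group(seed=23)
        table = table[table["reference"] == "primary"]
        with pytest.warns(UserWarning, match="one reference"):
            cb.fit_mle(table, cb.ModelSpec(), seed=0)


class TestPsychometricModelEstimator:
    def test_fit_predict_roundtrip(self, symmetric_group):
        table = symmetric_group(delta_s=0.6, delta_d=-0.2, seed=31)
        X = table[["orientation_deg", "reference"]]
        y = table["response"].to_numpy()
        est = cb.PsychometricModel(random_state=1).fit(X, y)
        assert est.converged_
        proba = est.predict_proba(X)
        assert proba.shape == (len(table), 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert est.score(X, y) > np.log(0.5) - 0.5  # beats coin flip zone

    def test_get_set_params_roundtrip(self):
        est = cb.PsychometricModel()
        est.set_params(lapse_structure="one", n_starts=3)
        assert est.get_params()["lapse_structure"] == "one"
        with pytest.raises(ValueError):
            est.set_params(bogus=1)

    def test_sklearn_clone_compatible(self):
        sklearn = pytest.importorskip("sklearn.base")
        est = cb.PsychometricModel(lapse_structure="two", random_state=7)
        clone = sklearn.clone(est)
        assert clone.get_params() == est.get_params()


def test_cells_round_trip_counts(symmetric_group):
    table = symmetric_group(seed=37)
    cells = aggregate_cells(table)
    assert cells.n_trials == len(table)
    assert cells.theta.size == 18  # 9 levels x 2 references
    direct = cells_from_arrays(
        table["orientation_deg"], (table["reference"] == "mirrored").astype(int),
        table["response"])
    np.testing.assert_array_equal(direct.k, cells.k)
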