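"""Joint maximum-likelihood fitting of a model spec to one group's trials.

One *group* is one participant × one orientation band × one task.  Its trials
collapse into binomial cells (successes k of n at each orientation level ×
reference mapping); the log-likelihood of a parameter vector is the sum of
binomial log-probabilities with the success probability supplied by the
spec's model function, binomial coefficients included.

Fitting both reference mappings jointly is what identifies the sensory and
decisional biases: with a single mapping the likelihood depends on the biases
only through ``delta_d - delta_s`` and the profile along
``(delta_s + t, delta_d + t)`` is exactly flat.

The optimizer is a bounded Nelder-Mead simplex run from several deterministic
starts (locations from empirical 50%-crossings, scale from the empirical
25-75% spread, lapses from 0.01), with the best start polished by a restart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .data import Cells, aggregate_cells
from .models import (
    AsymmetricParams,
    IndecisionParams,
    InvalidParameterError,
    ModelSpec,
    ReferenceSide,
    SymmetricParams,
    p_aligned_asymmetric,
    p_choice_indecision,
    p_choice_symmetric,
)

__all__ = ["FitResult", "log_likelihood", "fit_mle", "PsychometricModel",
           "BOUNDS", "LIKELIHOOD_EPS"]

#: probability clipping applied inside likelihoods only
LIKELIHOOD_EPS = 1e-10

#: parameter boxes; these comfortably exceed the +/-2 deg stimulus range
BOUNDS = {
    "bias": (-10.0, 10.0),
    "sigma": (0.05, 10.0),
    "half_width": (0.05, 10.0),
    "lapse": (0.0, 0.45),
    "xi": (0.0, 1.0),
    "tau_center": (-10.0, 10.0),
    "tau_half": (0.0, 10.0),
}

_MODEL_FN = {
    "symmetric_sdt": p_choice_symmetric,
    "asymmetric_interval": p_aligned_asymmetric,
    "indecision": p_choice_indecision,
}

_LAPSE_NAMES = {
    "none": (),
    "one": ("lam",),
    "two": ("lam_p", "lam_m"),
    "four": ("lam1", "lam2", "lam1p", "lam2p"),
}


class _Layout:
    """Mapping between a spec's free-parameter vector and a params object."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        names: list[str] = []
        bounds: list[tuple[float, float]] = []

        def add(name, box):
            names.append(name)
            bounds.append(BOUNDS[box])

        if spec.bias_structure in ("full", "sensory_only"):
            add("delta_s", "bias")
        if spec.family != "indecision" and spec.bias_structure in ("full", "decisional_only"):
            add("delta_d", "bias")
        if spec.family == "symmetric_sdt":
            add("sigma_primary", "sigma")
            if spec.n_sigmas == 2:
                add("sigma_mirrored", "sigma")
        elif spec.family == "asymmetric_interval":
            add("sigma", "sigma")
            add("half_width_primary", "half_width")
            if spec.n_sigmas == 2:
                add("half_width_mirrored", "half_width")
        else:  # indecision
            add("sigma", "sigma")
            add("xi", "xi")
            if not spec.symmetric_bounds:
                add("tau_center", "tau_center")
            add("tau_half", "tau_half")
        if spec.family != "indecision":
            for nm in _LAPSE_NAMES[spec.lapse_structure]:
                add(nm, "lapse")
        if spec.with_lambda_star:
            add("lam_star", "lapse")

        self.names = tuple(names)
        self.bounds = tuple(bounds)
        assert len(names) == spec.n_parameters

    def build(self, x: Sequence[float]):
        """Construct a validated params object from a free vector."""
        spec = self.spec
        v = dict(zip(self.names, np.asarray(x, dtype=float)))
        ds = v.get("delta_s", 0.0)
        dd = v.get("delta_d", 0.0)
        if spec.family == "indecision":
            w = v["tau_half"]
            c = 0.0 if spec.symmetric_bounds else v["tau_center"]
            return IndecisionParams(
                delta_s=ds, tau1=c - w, tau2=c + w, xi=v["xi"],
                sigma=v["sigma"], symmetric_bounds=spec.symmetric_bounds)
        ls = spec.lapse_structure
        if ls == "none":
            l1 = l2 = l1p = l2p = spec.fixed_lapse
        elif ls == "one":
            l1 = l2 = l1p = l2p = v["lam"]
        elif ls == "two":
            l1 = l2 = v["lam_p"]
            l1p = l2p = v["lam_m"]
        else:
            l1, l2, l1p, l2p = v["lam1"], v["lam2"], v["lam1p"], v["lam2p"]
        if spec.family == "symmetric_sdt":
            s1 = v["sigma_primary"]
            s2 = v["sigma_mirrored"] if spec.n_sigmas == 2 else s1
            return SymmetricParams(
                delta_s=ds, delta_d=dd, sigma_primary=s1, sigma_mirrored=s2,
                lam1=l1, lam2=l2, lam1p=l1p, lam2p=l2p,
                lam_star=v.get("lam_star", 0.0))
        h1 = v["half_width_primary"]
        h2 = v["half_width_mirrored"] if spec.n_sigmas == 2 else h1
        return AsymmetricParams(
            delta_s=ds, delta_d=dd, half_width_primary=h1,
            half_width_mirrored=h2, sigma=v["sigma"],
            lam1=l1, lam2=l2, lam1p=l1p, lam2p=l2p)

    def vector(self, params) -> np.ndarray:
        """Project a params object (possibly of a nested/fuller spec) onto
        this layout's free vector, used for warm starts."""
        out = []
        for nm in self.names:
            if nm == "lam":
                out.append(getattr(params, "lam1", 0.01))
            elif nm == "lam_p":
                out.append(getattr(params, "lam1", 0.01))
            elif nm == "lam_m":
                out.append(getattr(params, "lam1p", 0.01))
            elif nm == "sigma" and not hasattr(params, "sigma"):
                out.append(getattr(params, "sigma_primary"))
            elif nm == "sigma_primary" and not hasattr(params, "sigma_primary"):
                out.append(getattr(params, "sigma"))
            elif nm == "sigma_mirrored":
                out.append(getattr(params, "sigma_mirrored",
                                   getattr(params, "sigma", 1.0)))
            elif nm == "half_width_mirrored":
                out.append(getattr(params, "half_width_mirrored",
                                   getattr(params, "half_width_primary")))
            elif nm == "tau_center":
                out.append(0.5 * (params.tau1 + params.tau2))
            elif nm == "tau_half":
                out.append(0.5 * (params.tau2 - params.tau1))
            else:
                out.append(getattr(params, nm, 0.0))
        x = np.asarray(out, dtype=float)
        return self.clip(x)

    def clip(self, x: np.ndarray, margin: float = 1e-9) -> np.ndarray:
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return np.clip(x, lo + margin, hi - margin)


def _cell_probs(spec: ModelSpec, params, cells: Cells) -> np.ndarray:
    fn = _MODEL_FN[spec.family]
    p = np.empty_like(cells.theta)
    prim = cells.side == 0
    if prim.any():
        p[prim] = fn(cells.theta[prim], params, ReferenceSide.PRIMARY)
    if (~prim).any():
        p[~prim] = fn(cells.theta[~prim], params, ReferenceSide.MIRRORED)
    return p


def _coerce_cells(table) -> Cells:
    if isinstance(table, Cells):
        return table
    return aggregate_cells(table)


def _coerce_params(spec: ModelSpec, params):
    if isinstance(params, (SymmetricParams, AsymmetricParams, IndecisionParams)):
        return params
    if isinstance(params, Mapping):
        cls = {"symmetric_sdt": SymmetricParams,
               "asymmetric_interval": AsymmetricParams,
               "indecision": IndecisionParams}[spec.family]
        return cls(**params)
    raise InvalidParameterError(f"cannot interpret parameters {params!r}")


def log_likelihood(table, spec: ModelSpec, params) -> float:
    """Joint two-reference binomial log-likelihood (nats).

    ``table`` may be a one-group trial DataFrame or a pre-aggregated
    :class:`~choicebias.data.Cells`.  Includes the binomial coefficient
    terms, so the value is the log of the full binomial density.
    Probabilities are clipped to ``[1e-10, 1 - 1e-10]`` here only.
    """
    cells = _coerce_cells(table)
    params = _coerce_params(spec, params)
    p = np.clip(_cell_probs(spec, params, cells), LIKELIHOOD_EPS, 1.0 - LIKELIHOOD_EPS)
    return float(cells.log_binom
                 + np.sum(cells.k * np.log(p) + (cells.n - cells.k) * np.log1p(-p)))


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    spec: ModelSpec
    params: object
    estimates: dict
    log_likelihood: float
    n_parameters: int
    aic: float
    converged: bool
    n_restarts_used: int
    x: np.ndarray = field(repr=False, default=None)
    start_log_likelihoods: tuple = field(repr=False, default=())
    start_estimates: tuple = field(repr=False, default=())


def _side_stats(cells: Cells, side_code: int):
    """Empirical (50%-crossing, 25-75% spread based sigma) for one side."""
    m = cells.side == side_code
    if not m.any():
        return 0.0, 1.0
    th = cells.theta[m]
    prop = cells.k[m] / cells.n[m]
    order = np.argsort(th)
    th, prop = th[order], prop[order]

    def crossing(level):
        above = prop >= level
        if above.all():
            return th[0]
        if not above.any():
            return th[-1]
        i = int(np.argmax(above))  # first index at/above level
        if i == 0:
            return th[0]
        p0, p1 = prop[i - 1], prop[i]
        if p1 == p0:
            return 0.5 * (th[i - 1] + th[i])
        return th[i - 1] + (level - p0) * (th[i] - th[i - 1]) / (p1 - p0)

    pse = crossing(0.5)
    spread = crossing(0.75) - crossing(0.25)
    sigma = spread / 1.349 if spread > 0 else 0.5 * (th[-1] - th[0]) / 1.349
    sigma = float(np.clip(sigma, BOUNDS["sigma"][0] * 2, BOUNDS["sigma"][1] / 2))
    return float(pse), sigma


def _peak_stats(cells: Cells, side_code: int):
    """Empirical (peak location, half-width) for one side of interval data."""
    m = cells.side == side_code
    if not m.any():
        return 0.0, 1.0
    th = cells.theta[m]
    prop = cells.k[m] / cells.n[m]
    peak = float(th[np.argmax(prop)])
    half = prop >= 0.5 * prop.max() if prop.max() > 0 else np.ones_like(prop, bool)
    width = float(th[half].max() - th[half].min()) if half.any() else 1.0
    return peak, max(0.5 * width, 0.2)


def _heuristic_start(layout: _Layout, cells: Cells) -> np.ndarray:
    spec = layout.spec
    if spec.family == "asymmetric_interval":
        m_p, h_p = _peak_stats(cells, 0)
        m_m, h_m = _peak_stats(cells, 1)
        ds, dd = 0.5 * (m_p + m_m), 0.5 * (m_p - m_m)
        base = {"delta_s": ds, "delta_d": dd, "sigma": 0.5,
                "half_width_primary": h_p, "half_width_mirrored": h_m}
    else:
        pse_p, sig_p = _side_stats(cells, 0)
        pse_m, sig_m = _side_stats(cells, 1)
        # primary crossing = delta_d - delta_s, mirrored = -delta_d - delta_s
        ds, dd = -0.5 * (pse_p + pse_m), 0.5 * (pse_p - pse_m)
        base = {"delta_s": ds, "delta_d": dd,
                "sigma_primary": sig_p, "sigma_mirrored": sig_m,
                "sigma": 0.5 * (sig_p + sig_m),
                "tau_center": dd, "tau_half": max(abs(dd), 0.3), "xi": 0.5}
    x = []
    for nm in layout.names:
        if nm in base:
            x.append(base[nm])
        elif nm.startswith("lam"):
            x.append(0.01)
        else:
            x.append(0.0)
    return layout.clip(np.asarray(x, dtype=float))


def _make_starts(layout: _Layout, cells: Cells, n_starts: int,
                 rng: np.random.Generator) -> list[np.ndarray]:
    x0 = _heuristic_start(layout, cells)
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        x = x0.copy()
        for j, nm in enumerate(layout.names):
            if nm in ("delta_s", "delta_d", "tau_center"):
                x[j] += rng.normal(0.0, 0.5)
            elif nm.startswith("sigma") or nm.startswith("half_width"):
                x[j] *= float(np.exp(rng.normal(0.0, 0.4)))
            elif nm == "xi":
                x[j] = rng.uniform(0.1, 0.9)
            elif nm == "tau_half":
                x[j] = rng.uniform(0.05, 1.5)
            else:  # lapses
                x[j] = rng.uniform(0.0, 0.08)
        starts.append(layout.clip(x))
    return starts


def _neg_ll_factory(layout: _Layout, cells: Cells):
    """Build a fast negative-log-likelihood closure for the optimizer.

    Specialized per family to avoid per-evaluation object construction; it
    computes exactly the same quantity as :func:`log_likelihood` at the
    parameters :meth:`_Layout.build` would produce (asserted in the test
    suite).
    """
    from scipy.special import ndtr

    spec = layout.spec
    prim = cells.side == 0
    th_p, th_m = cells.theta[prim], cells.theta[~prim]
    k_p, n_p = cells.k[prim], cells.n[prim]
    k_m, n_m = cells.k[~prim], cells.n[~prim]
    lb = cells.log_binom
    eps = LIKELIHOOD_EPS
    idx = {nm: i for i, nm in enumerate(layout.names)}

    def get(x, nm, default=0.0):
        i = idx.get(nm)
        return x[i] if i is not None else default

    def binom_ll(p_p, p_m):
        p_p = np.clip(p_p, eps, 1.0 - eps)
        p_m = np.clip(p_m, eps, 1.0 - eps)
        return (lb
                + float(np.sum(k_p * np.log(p_p) + (n_p - k_p) * np.log1p(-p_p)))
                + float(np.sum(k_m * np.log(p_m) + (n_m - k_m) * np.log1p(-p_m))))

    def lapses(x):
        ls = spec.lapse_structure
        if ls == "none":
            f = spec.fixed_lapse
            return f, f, f, f
        if ls == "one":
            l = x[idx["lam"]]
            return l, l, l, l
        if ls == "two":
            lp, lm = x[idx["lam_p"]], x[idx["lam_m"]]
            return lp, lp, lm, lm
        return (x[idx["lam1"]], x[idx["lam2"]],
                x[idx["lam1p"]], x[idx["lam2p"]])

    if spec.family == "symmetric_sdt":
        def neg_ll(x):
            ds, dd = get(x, "delta_s"), get(x, "delta_d")
            s1 = x[idx["sigma_primary"]]
            s2 = x[idx["sigma_mirrored"]] if spec.n_sigmas == 2 else s1
            l1, l2, l1p, l2p = lapses(x)
            star = get(x, "lam_star")
            if l1 + l2 + star >= 1.0 or l1p + l2p + star >= 1.0:
                return 1e12
            p_p = l1 + (1.0 - l1 - l2 - star) * ndtr((th_p - (dd - ds)) / s1)
            p_m = (l1p + star
                   + (1.0 - l1p - l2p - star) * ndtr((th_m - (-dd - ds)) / s2))
            return -binom_ll(p_p, p_m)
    elif spec.family == "asymmetric_interval":
        def neg_ll(x):
            ds, dd = get(x, "delta_s"), get(x, "delta_d")
            sg = x[idx["sigma"]]
            h1 = x[idx["half_width_primary"]]
            h2 = (x[idx["half_width_mirrored"]] if spec.n_sigmas == 2 else h1)
            l1, l2, l1p, l2p = lapses(x)
            if l1 + l2 >= 1.0 or l1p + l2p >= 1.0:
                return 1e12
            m_p, m_m = ds + dd, ds - dd
            core_p = ndtr((th_p - (m_p - h1)) / sg) - ndtr((th_p - (m_p + h1)) / sg)
            core_m = ndtr((th_m - (m_m - h2)) / sg) - ndtr((th_m - (m_m + h2)) / sg)
            return -binom_ll(l1 + (1.0 - l1 - l2) * core_p,
                             l1p + (1.0 - l1p - l2p) * core_m)
    else:  # indecision
        def neg_ll(x):
            ds = get(x, "delta_s")
            sg, xi = x[idx["sigma"]], x[idx["xi"]]
            w = x[idx["tau_half"]]
            c = get(x, "tau_center")
            t1, t2 = c - w, c + w
            z_p, z_m = th_p - ds, th_m - ds
            in_p = ndtr((t2 - z_p) / sg) - ndtr((t1 - z_p) / sg)
            in_m = ndtr((t2 - z_m) / sg) - ndtr((t1 - z_m) / sg)
            return -binom_ll(ndtr((z_p - t2) / sg) + xi * in_p,
                             ndtr((z_m - t2) / sg) + (1.0 - xi) * in_m)

    return neg_ll


def fit_mle(table, spec: ModelSpec, seed: int = 0, n_starts: int = 8,
            extra_starts: Sequence[np.ndarray] | None = None,
            max_fev: int = 2000) -> FitResult:
    """Maximize the joint log-likelihood of ``spec`` over one group.

    Runs a bounded Nelder-Mead search from ``n_starts`` deterministic
    seed-derived starts (plus any ``extra_starts``, e.g. warm starts from a
    nested model), polishes the best optimum with a simplex restart, and
    returns the best converged solution.
    """
    import warnings

    cells = _coerce_cells(table)
    if spec.family != "asymmetric_interval" and spec.bias_structure == "full" \
            and not (cells.has_side(0) and cells.has_side(1)):
        # joint bias identification requires both mappings; fitting proceeds
        # but the caller should know the biases are only weakly identified
        warnings.warn("only one reference mapping present: delta_s and "
                      "delta_d are identified only through their difference")
    for code, name in ((0, "primary"), (1, "mirrored")):
        m = cells.side == code
        if m.any():
            k, n = cells.k[m].sum(), cells.n[m].sum()
            if k == 0 or k == n:
                warnings.warn(f"all responses identical on the {name} "
                              "mapping: its bias is weakly identified")
    if np.unique(cells.theta).size < 2:
        raise InvalidParameterError("need at least 2 distinct orientations")
    layout = _Layout(spec)
    rng = np.random.default_rng(seed)
    starts = _make_starts(layout, cells, n_starts, rng)
    if extra_starts is not None:
        starts = [layout.clip(np.asarray(s, dtype=float)) for s in extra_starts] + starts
    neg_ll = _neg_ll_factory(layout, cells)

    if len(layout.names) == 0:
        x_best = np.empty(0)
        ll = -neg_ll(x_best)
        params = layout.build(x_best)
        return FitResult(spec, params, {}, ll, 0, -2.0 * ll, True, 0,
                         x=x_best, start_log_likelihoods=(), start_estimates=())

    results = []
    for x0 in starts:
        f0 = neg_ll(x0)
        opts = dict(maxfev=max_fev, xatol=1e-7,
                    fatol=1e-9 * max(1.0, abs(f0)))
        res = minimize(neg_ll, x0, method="Nelder-Mead",
                       bounds=layout.bounds, options=opts)
        results.append(res)
    best = min(results, key=lambda r: r.fun)
    # polish: simplex restarts from the best optimum until formal convergence
    # (high-dimensional specs can exhaust one start's evaluation budget)
    polished_ok = False
    for _ in range(4):
        res2 = minimize(neg_ll, best.x, method="Nelder-Mead",
                        bounds=layout.bounds,
                        options=dict(maxfev=max_fev, xatol=1e-8,
                                     fatol=1e-10 * max(1.0, abs(best.fun))))
        if res2.fun <= best.fun:
            best = res2
        if res2.success:
            polished_ok = True
            break
    params = layout.build(best.x)
    ll = -float(best.fun)
    k = spec.n_parameters
    estimates = dict(zip(layout.names, (float(v) for v in best.x)))
    return FitResult(
        spec=spec, params=params, estimates=estimates, log_likelihood=ll,
        n_parameters=k, aic=2.0 * k - 2.0 * ll,
        converged=bool(polished_ok or any(r.success for r in results)),
        n_restarts_used=len(starts),
        x=np.asarray(best.x, dtype=float),
        start_log_likelihoods=tuple(-float(r.fun) for r in results),
        start_estimates=tuple(tuple(float(v) for v in r.x) for r in results),
    )


class PsychometricModel:
    """Scikit-learn-style estimator for one model spec.

    ``X`` is array-like of shape (n_trials, 2) with columns
    ``[orientation_deg, reference]`` (reference coded 0/'primary' or
    1/'mirrored'), or a DataFrame with those columns; ``y`` is the binary
    response.  After :meth:`fit`, estimates live in ``params_``,
    ``log_likelihood_``, ``aic_`` and ``result_``.
    """

    def __init__(self, family="symmetric_sdt", n_sigmas=1,
                 lapse_structure="none", bias_structure="full",
                 symmetric_bounds=False, with_lambda_star=False,
                 fixed_lapse=0.0, n_starts=8, random_state=0):
        self.family = family
        self.n_sigmas = n_sigmas
        self.lapse_structure = lapse_structure
        self.bias_structure = bias_structure
        self.symmetric_bounds = symmetric_bounds
        self.with_lambda_star = with_lambda_star
        self.fixed_lapse = fixed_lapse
        self.n_starts = n_starts
        self.random_state = random_state

    _param_names = ("family", "n_sigmas", "lapse_structure", "bias_structure",
                    "symmetric_bounds", "with_lambda_star", "fixed_lapse",
                    "n_starts", "random_state")

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            family=self.family, n_sigmas=self.n_sigmas,
            lapse_structure=self.lapse_structure,
            bias_structure=self.bias_structure,
            symmetric_bounds=self.symmetric_bounds,
            with_lambda_star=self.with_lambda_star,
            fixed_lapse=self.fixed_lapse)

    @staticmethod
    def _coerce_X(X):
        if isinstance(X, pd.DataFrame):
            theta = X["orientation_deg"].to_numpy(float)
            ref = X["reference"].to_numpy()
        else:
            X = np.asarray(X)
            if X.ndim != 2 or X.shape[1] != 2:
                raise ValueError("X must have two columns: "
                                 "orientation_deg, reference")
            theta = X[:, 0].astype(float)
            ref = X[:, 1]
        if ref.dtype.kind in "OUS":
            side = np.array([1 if str(r) == "mirrored" else 0 for r in ref])
        else:
            side = np.asarray(ref, dtype=float).astype(int)
        return theta, side

    def fit(self, X, y):
        from .data import cells_from_arrays
        theta, side = self._coerce_X(X)
        y = np.asarray(y, dtype=float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("y must be binary")
        cells = cells_from_arrays(theta, side, y)
        self.result_ = fit_mle(cells, self._spec(), seed=self.random_state,
                               n_starts=self.n_starts)
        self.params_ = self.result_.params
        self.log_likelihood_ = self.result_.log_likelihood
        self.aic_ = self.result_.aic
        self.n_parameters_ = self.result_.n_parameters
        self.converged_ = self.result_.converged
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 2
        return self

    def predict_proba(self, X):
        if not hasattr(self, "result_"):
            raise RuntimeError("call fit before predict_proba")
        theta, side = self._coerce_X(X)
        fn = _MODEL_FN[self.result_.spec.family]
        p1 = np.empty_like(theta)
        for code, s in ((0, ReferenceSide.PRIMARY), (1, ReferenceSide.MIRRORED)):
            m = side == code
            if m.any():
                p1[m] = fn(theta[m], self.params_, s)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)

    def score(self, X, y):
        """Mean per-trial log-likelihood (nats)."""
        p = np.clip(self.predict_proba(X)[:, 1], LIKELIHOOD_EPS, 1 - LIKELIHOOD_EPS)
        y = np.asarray(y, dtype=float)
        return float(np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))
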