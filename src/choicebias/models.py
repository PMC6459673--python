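"""Probability models for two-alternative orientation judgments.

Three model families map a signed stimulus orientation (degrees, positive =
clockwise of the neutral cardinal orientation) and a reference mapping to the
probability of the clockwise-consistent (or "aligned") response:

* the signal-detection (SDT) psychometric family for the symmetric task, a
  cumulative normal whose location is ``delta_d - delta_s`` for the primary
  reference mapping and ``-delta_d - delta_s`` for the mirrored one, optionally
  deformed by lapse rates;
* an interval-judgment family for the asymmetric ("aligned or not?") task;
* a high-threshold *indecision* family in which evidence falling inside an
  uncertainty interval triggers a stimulus-independent guess.

The sensory bias ``delta_s`` shifts both reference mappings identically; the
decisional bias ``delta_d`` (a criterion shift) moves them in opposite
directions — this sign flip is what makes the two biases separable when the
two mappings are fitted jointly.

All functions here are pure and perform no probability clipping; numerical
guards live in the likelihood code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy.special import ndtr

__all__ = [
    "InvalidParameterError",
    "ReferenceSide",
    "SymmetricParams",
    "AsymmetricParams",
    "IndecisionParams",
    "ModelSpec",
    "p_choice_symmetric",
    "p_choice_indecision",
    "p_aligned_asymmetric",
]


class InvalidParameterError(ValueError):
    """A parameter vector violates a model constraint."""


class ReferenceSide(str, Enum):
    """Reference mapping of a trial.

    ``PRIMARY`` is the mapping for which the "down"-type key means clockwise
    (reference imagined right for horizontal gratings, top for vertical);
    ``MIRRORED`` is the opposite mapping (left / bottom).
    """

    PRIMARY = "primary"
    MIRRORED = "mirrored"


def _as_side(side: "ReferenceSide | str") -> ReferenceSide:
    if isinstance(side, ReferenceSide):
        return side
    return ReferenceSide(str(side))


def _check(cond: bool, message: str) -> None:
    if not cond:
        raise InvalidParameterError(message)


@dataclass
class SymmetricParams:
    """Parameters of the symmetric-task SDT psychometric family.

    ``delta_s`` and ``delta_d`` are the sensory and decisional biases in
    degrees; ``sigma_primary`` / ``sigma_mirrored`` are the psychometric
    slopes (noise SDs) for the two reference mappings; ``lam1``/``lam2`` and
    ``lam1p``/``lam2p`` are the lower/upper asymptote lapse rates for the
    primary and mirrored mappings; ``lam_star`` is the extra
    key-preference lapse placed on the upper asymptote of the primary mapping
    and the lower asymptote of the mirrored one.
    """

    delta_s: float = 0.0
    delta_d: float = 0.0
    sigma_primary: float = 1.0
    sigma_mirrored: float | None = None
    lam1: float = 0.0
    lam2: float = 0.0
    lam1p: float = 0.0
    lam2p: float = 0.0
    lam_star: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_mirrored is None:
            self.sigma_mirrored = self.sigma_primary
        _check(self.sigma_primary > 0, "sigma_primary must be > 0")
        _check(self.sigma_mirrored > 0, "sigma_mirrored must be > 0")
        for name in ("lam1", "lam2", "lam1p", "lam2p", "lam_star"):
            v = getattr(self, name)
            _check(0.0 <= v < 0.5, f"{name} must lie in [0, 0.5)")
        _check(self.lam1 + self.lam2 + self.lam_star < 1.0,
               "lam1 + lam2 + lam_star must be < 1")
        _check(self.lam1p + self.lam2p + self.lam_star < 1.0,
               "lam1p + lam2p + lam_star must be < 1")


@dataclass
class AsymmetricParams:
    """Parameters of the interval-judgment model for the asymmetric task.

    The observer responds "aligned" when the internal orientation estimate
    falls inside a criterion interval.  ``delta_s`` shifts the estimate,
    ``delta_d`` shifts the interval center with a sign that flips across
    reference mappings, and unequal half-widths across mappings encode a
    symmetric decisional bias.
    """

    delta_s: float = 0.0
    delta_d: float = 0.0
    half_width_primary: float = 1.0
    half_width_mirrored: float | None = None
    sigma: float = 1.0
    lam1: float = 0.0
    lam2: float = 0.0
    lam1p: float = 0.0
    lam2p: float = 0.0

    def __post_init__(self) -> None:
        if self.half_width_mirrored is None:
            self.half_width_mirrored = self.half_width_primary
        _check(self.half_width_primary > 0, "half_width_primary must be > 0")
        _check(self.half_width_mirrored > 0, "half_width_mirrored must be > 0")
        _check(self.sigma > 0, "sigma must be > 0")
        for name in ("lam1", "lam2", "lam1p", "lam2p"):
            v = getattr(self, name)
            _check(0.0 <= v < 0.5, f"{name} must lie in [0, 0.5)")
        _check(self.lam1 + self.lam2 < 1.0, "lam1 + lam2 must be < 1")
        _check(self.lam1p + self.lam2p < 1.0, "lam1p + lam2p must be < 1")


@dataclass
class IndecisionParams:
    """Parameters of the high-threshold indecision model.

    ``tau1 <= tau2`` bound the uncertainty interval in stimulus space; inside
    it the observer guesses the clockwise-consistent key with probability
    ``xi`` under the primary mapping (``1 - xi`` under the mirrored one).
    """

    delta_s: float = 0.0
    tau1: float = 0.0
    tau2: float = 0.0
    xi: float = 0.5
    sigma: float = 1.0
    symmetric_bounds: bool = False

    def __post_init__(self) -> None:
        _check(self.sigma > 0, "sigma must be > 0")
        _check(self.tau1 <= self.tau2, "tau1 must be <= tau2")
        _check(0.0 <= self.xi <= 1.0, "xi must lie in [0, 1]")
        if self.symmetric_bounds:
            _check(np.isclose(self.tau1, -self.tau2),
                   "symmetric_bounds requires tau1 == -tau2")


_LAPSE_STRUCTURES = ("none", "one", "two", "four")
_BIAS_STRUCTURES = ("full", "sensory_only", "decisional_only", "none")
_FAMILIES = ("symmetric_sdt", "asymmetric_interval", "indecision")

_N_LAPSE = {"none": 0, "one": 1, "two": 2, "four": 4}
_N_BIAS = {"full": 2, "sensory_only": 1, "decisional_only": 1, "none": 0}


@dataclass(frozen=True)
class ModelSpec:
    """Which model family and parameter-sharing structure is being fitted.

    ``lapse_structure='four_plus_star'`` is accepted and normalized to
    ``'four'`` with ``with_lambda_star=True``.  For the asymmetric family
    ``n_sigmas=2`` means side-specific interval half-widths (the sigma itself
    is always shared).  ``fixed_lapse`` is the value at which all lapse rates
    are pinned when ``lapse_structure='none'`` (0.01 during comparisons
    against lapsed models, 0 otherwise).
    """

    family: str = "symmetric_sdt"
    n_sigmas: int = 1
    lapse_structure: str = "none"
    bias_structure: str = "full"
    symmetric_bounds: bool = False
    with_lambda_star: bool = False
    fixed_lapse: float = 0.0

    def __post_init__(self) -> None:
        if self.lapse_structure == "four_plus_star":
            object.__setattr__(self, "lapse_structure", "four")
            object.__setattr__(self, "with_lambda_star", True)
        if self.family not in _FAMILIES:
            raise InvalidParameterError(f"unknown family {self.family!r}")
        if self.lapse_structure not in _LAPSE_STRUCTURES:
            raise InvalidParameterError(
                f"unknown lapse_structure {self.lapse_structure!r}")
        if self.bias_structure not in _BIAS_STRUCTURES:
            raise InvalidParameterError(
                f"unknown bias_structure {self.bias_structure!r}")
        if self.n_sigmas not in (1, 2):
            raise InvalidParameterError("n_sigmas must be 1 or 2")
        if self.with_lambda_star and self.family != "symmetric_sdt":
            raise InvalidParameterError(
                "lambda_star is only defined for the symmetric family")
        if self.family == "indecision":
            if self.n_sigmas != 1 or self.lapse_structure != "none":
                raise InvalidParameterError(
                    "indecision family has one sigma and no lapses")
        if not (0.0 <= self.fixed_lapse < 0.5):
            raise InvalidParameterError("fixed_lapse must lie in [0, 0.5)")

    @property
    def n_parameters(self) -> int:
        """Number of free parameters implied by the structure fields."""
        if self.family == "indecision":
            n = 2  # sigma, xi
            n += 1 if self.bias_structure in ("full", "sensory_only") else 0
            n += 1 if self.symmetric_bounds else 2
            return n
        n = _N_BIAS[self.bias_structure] + _N_LAPSE[self.lapse_structure]
        if self.family == "symmetric_sdt":
            n += self.n_sigmas
            n += 1 if self.with_lambda_star else 0
        else:  # asymmetric_interval: shared sigma + 1 or 2 half-widths
            n += 1 + self.n_sigmas
        return n

    def reduced(self, **changes) -> "ModelSpec":
        """Return a copy with the given structure fields changed."""
        return replace(self, **changes)


def p_choice_symmetric(theta, params: SymmetricParams, side) -> np.ndarray | float:
    """P(clockwise-consistent choice) under the symmetric-task SDT model.

    The core is ``Phi((theta - (delta_d - delta_s)) / sigma1)`` for the
    primary mapping and ``Phi((theta - (-delta_d - delta_s)) / sigma2)`` for
    the mirrored one; the side's lapse transform is then applied, with the
    key-preference lapse ``lam_star`` lowering the upper asymptote of the
    primary mapping and raising the lower asymptote of the mirrored one.
    """
    side = _as_side(side)
    th = np.asarray(theta, dtype=float)
    if side is ReferenceSide.PRIMARY:
        core = ndtr((th - (params.delta_d - params.delta_s)) / params.sigma_primary)
        p = params.lam1 + (1.0 - params.lam1 - params.lam2 - params.lam_star) * core
    else:
        core = ndtr((th - (-params.delta_d - params.delta_s)) / params.sigma_mirrored)
        p = (params.lam1p + params.lam_star
             + (1.0 - params.lam1p - params.lam2p - params.lam_star) * core)
    return p if np.ndim(theta) else float(p)


def p_choice_indecision(theta, params: IndecisionParams, side) -> np.ndarray | float:
    """P(clockwise-consistent choice) under the indecision model.

    With ``z = theta - delta_s``: ``Phi((z - tau2)/sigma) +
    g * [Phi((tau2 - z)/sigma) - Phi((tau1 - z)/sigma)]`` where the guess
    probability ``g`` is ``xi`` for the primary mapping and ``1 - xi`` for the
    mirrored one.
    """
    side = _as_side(side)
    z = np.asarray(theta, dtype=float) - params.delta_s
    g = params.xi if side is ReferenceSide.PRIMARY else 1.0 - params.xi
    upper = ndtr((z - params.tau2) / params.sigma)
    inside = ndtr((params.tau2 - z) / params.sigma) - ndtr((params.tau1 - z) / params.sigma)
    p = upper + g * inside
    return p if np.ndim(theta) else float(p)


def p_aligned_asymmetric(theta, params: AsymmetricParams, side) -> np.ndarray | float:
    """P("aligned" response) under the asymmetric-task interval model.

    The criterion interval is centered on ``delta_s + delta_d`` for the
    primary mapping and ``delta_s - delta_d`` for the mirrored one, with the
    side's half-width; before lapses the curve peaks at the center with height
    ``2*Phi(h/sigma) - 1``.
    """
    side = _as_side(side)
    th = np.asarray(theta, dtype=float)
    if side is ReferenceSide.PRIMARY:
        m = params.delta_s + params.delta_d
        h = params.half_width_primary
        lo, hi = params.lam1, params.lam2
    else:
        m = params.delta_s - params.delta_d
        h = params.half_width_mirrored
        lo, hi = params.lam1p, params.lam2p
    core = ndtr((th - (m - h)) / params.sigma) - ndtr((th - (m + h)) / params.sigma)
    p = lo + (1.0 - lo - hi) * core
    return p if np.ndim(theta) else float(p)
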