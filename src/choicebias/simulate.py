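"""Constant-stimuli simulation of trial-level choice data.

Emulates the study design the analysis assumes: per group, 9 orientation
levels from -2 to 2 deg in 0.5 deg steps, ~30 trials per level per reference
mapping, two mirrored reference mappings, responses Bernoulli under a chosen
generating model.  Populations draw generating parameters per group and emit
a ground-truth table for recovery studies.

No trial-order or history effects are simulated: the models are history-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import validate_trial_table
from .fitting import _MODEL_FN
from .models import (
    AsymmetricParams,
    IndecisionParams,
    InvalidParameterError,
    ReferenceSide,
    SymmetricParams,
)

__all__ = ["DesignSpec", "PopulationSpec", "simulate_group",
           "simulate_population", "experiment2_design", "DEFAULT_LEVELS"]

#: the constant-stimuli grid: -2 to 2 deg in 0.5 deg steps
DEFAULT_LEVELS = tuple(np.round(np.arange(-2.0, 2.01, 0.5), 6))


@dataclass(frozen=True)
class DesignSpec:
    """A constant-stimuli session layout for one group.

    The default 30 trials per level per reference is the per-cell count of a
    6-blocks-of-360-trials session spread over 8 intermixed conditions.
    """

    levels: tuple = DEFAULT_LEVELS
    n_per_level_per_reference: int = 30
    references: tuple = (ReferenceSide.PRIMARY, ReferenceSide.MIRRORED)
    task: str = "symmetric"
    orientation_band: str = "horizontal"

    def __post_init__(self):
        lv = np.asarray(self.levels, dtype=float)
        if lv.size == 0 or not np.all(np.diff(lv) > 0):
            raise ValueError("levels must be non-empty and strictly increasing")
        if self.n_per_level_per_reference <= 0:
            raise ValueError("n_per_level_per_reference must be positive")


def experiment2_design() -> DesignSpec:
    """Blocked-session preset: 4 blocks of 270 trials, one task, two
    references around the vertical orientation (60 trials per cell)."""
    return DesignSpec(n_per_level_per_reference=60, orientation_band="vertical")


@dataclass(frozen=True)
class PopulationSpec:
    """Between-group spread of generating parameters.

    Default ranges span the bias magnitudes a typical observer sample shows
    (sensory biases up to ~1.5 deg, decisional biases smaller); a range with
    equal endpoints pins the parameter.  ``seed`` is mandatory.
    """

    n_groups: int
    seed: int
    delta_s_range: tuple = (-1.5, 1.5)
    delta_d_range: tuple = (-0.5, 0.5)
    sigma_range: tuple = (0.3, 1.0)
    lapse_structure_probs: dict = field(default_factory=lambda: {"none": 1.0})
    lapse_range: tuple = (0.01, 0.08)
    family: str = "symmetric_sdt"

    def __post_init__(self):
        if self.n_groups < 0:
            raise ValueError("n_groups must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for nm in ("delta_s_range", "delta_d_range"):
            lo, hi = getattr(self, nm)
            if not (-10 <= lo <= hi <= 10):
                raise ValueError(f"{nm} must lie within [-10, 10]")
        lo, hi = self.sigma_range
        if not (0.05 <= lo <= hi <= 10):
            raise ValueError("sigma_range must lie within [0.05, 10]")
        total = sum(self.lapse_structure_probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError("lapse_structure_probs must sum to 1")


def _task_for_family(family: str) -> str:
    return "asymmetric" if family == "asymmetric_interval" else "symmetric"


def simulate_group(design: DesignSpec, family: str, params, seed: int,
                   participant: str = "sim001") -> pd.DataFrame:
    """Simulate one group's trials under a generating model.

    Each (level, reference) cell receives ``n`` Bernoulli draws with the
    model's response probability; the trial order is then shuffled
    deterministically by ``seed``.
    """
    if family not in _MODEL_FN:
        raise InvalidParameterError(f"unknown family {family!r}")
    fn = _MODEL_FN[family]
    task = _task_for_family(family)
    if design.task != task:
        raise ValueError(f"design.task={design.task!r} does not match "
                         f"family {family!r}")
    rng = np.random.default_rng(seed)
    n = design.n_per_level_per_reference
    rows_theta, rows_side, rows_resp = [], [], []
    for ref in design.references:
        ref = ReferenceSide(ref)
        for theta in design.levels:
            p = float(fn(float(theta), params, ref))
            resp = (rng.random(n) < p).astype(int)
            rows_theta.append(np.full(n, float(theta)))
            rows_side.append(np.full(n, ref.value, dtype=object))
            rows_resp.append(resp)
    table = pd.DataFrame({
        "participant": participant,
        "task": task,
        "orientation_band": design.orientation_band,
        "reference": np.concatenate([np.asarray(s) for s in rows_side]),
        "orientation_deg": np.concatenate(rows_theta),
        "response": np.concatenate(rows_resp),
    })
    table = table.iloc[rng.permutation(len(table))].reset_index(drop=True)
    return validate_trial_table(table)


def _true_label(delta_s: float, delta_d: float) -> str:
    s, d = delta_s != 0.0, delta_d != 0.0
    if s and d:
        return "sensory_plus_decisional"
    if s:
        return "sensory"
    if d:
        return "decisional"
    return "no_bias"


def _draw_params(pop: PopulationSpec, rng: np.random.Generator):
    ds = float(rng.uniform(*pop.delta_s_range))
    dd = float(rng.uniform(*pop.delta_d_range))
    sigma = float(rng.uniform(*pop.sigma_range))
    structures = sorted(pop.lapse_structure_probs)
    probs = [pop.lapse_structure_probs[s] for s in structures]
    structure = structures[int(rng.choice(len(structures), p=probs))]
    lam = {"lam1": 0.0, "lam2": 0.0, "lam1p": 0.0, "lam2p": 0.0}
    if structure == "one":
        lam = dict.fromkeys(lam, float(rng.uniform(*pop.lapse_range)))
    elif structure == "two":
        lp = float(rng.uniform(*pop.lapse_range))
        lm = float(rng.uniform(*pop.lapse_range))
        lam.update(lam1=lp, lam2=lp, lam1p=lm, lam2p=lm)
    elif structure == "four":
        lam = {k: float(rng.uniform(*pop.lapse_range)) for k in lam}
    if pop.family == "symmetric_sdt":
        params = SymmetricParams(delta_s=ds, delta_d=dd, sigma_primary=sigma,
                                 **lam)
    elif pop.family == "asymmetric_interval":
        params = AsymmetricParams(delta_s=ds, delta_d=dd, sigma=sigma,
                                  half_width_primary=1.0, **lam)
    else:
        params = IndecisionParams(delta_s=ds, tau1=-abs(dd), tau2=abs(dd),
                                  xi=0.5, sigma=sigma)
    return params, structure, ds, dd, sigma


def simulate_population(pop: PopulationSpec, design: DesignSpec
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ``pop.n_groups`` groups; returns (trials, truth) tables.

    The truth table records the generating family, parameters and the
    implied bias label per group.
    """
    rng = np.random.default_rng(pop.seed)
    group_seeds = rng.integers(0, 2**31 - 1, size=max(pop.n_groups, 1))
    trials, truth = [], []
    task = _task_for_family(pop.family)
    for i in range(pop.n_groups):
        params, structure, ds, dd, sigma = _draw_params(pop, rng)
        pid = f"sim{i + 1:03d}"
        trials.append(simulate_group(design, pop.family, params,
                                     seed=int(group_seeds[i]),
                                     participant=pid))
        truth.append({
            "participant": pid,
            "orientation_band": design.orientation_band,
            "task": task,
            "family": pop.family,
            "delta_s": ds, "delta_d": dd, "sigma": sigma,
            "lapse_structure": structure,
            "true_label": _true_label(ds, dd),
        })
    truth_cols = ["participant", "orientation_band", "task", "family",
                  "delta_s", "delta_d", "sigma", "lapse_structure",
                  "true_label"]
    if pop.n_groups == 0:
        from .data import REQUIRED_COLUMNS
        return (pd.DataFrame(columns=list(REQUIRED_COLUMNS)),
                pd.DataFrame(columns=truth_cols))
    return (pd.concat(trials, ignore_index=True),
            pd.DataFrame(truth, columns=truth_cols))
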