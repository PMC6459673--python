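"""End-to-end orchestration: per-group fitting and classification over a
whole dataset, exclusion screening, and group-level bias summaries.

Groups whose responses are not modulated by orientation (the basic
psychometric fit does not beat a flat, intercept-only binomial model, or the
fitted slope parameter escapes to its upper bound) are excluded, as are
groups whose response proportions decrease with orientation on both mappings
(inverted response coding); exclusions are recorded with reasons, never
fatal.

Summaries mirror the standard group-level readouts: mean and 95% t-interval
of |delta_s| and |delta_d|, a paired t-test between them, and Pearson
correlations of the sensory bias across tasks and across orientation bands.
Groups from the two orientation bands of one participant are pooled as
independent observations in those tests (flagged: they share a participant).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2, pearsonr, spearmanr, t as t_dist, ttest_rel

from .data import aggregate_cells, iter_groups, validate_trial_table
from .fitting import _MODEL_FN, fit_mle
from .models import ModelSpec, ReferenceSide
from .selection import (
    classify_bias,
    compare_indecision,
    lambda_star_check,
)

__all__ = ["RunConfig", "RunResult", "BiasSummary", "run_dataset",
           "summarize_biases", "single_reference_bias", "crossing_orientation"]

_FAMILY_FOR_TASK = {"symmetric": "symmetric_sdt",
                    "asymmetric": "asymmetric_interval"}


@dataclass(frozen=True)
class RunConfig:
    """Options for a whole-dataset run."""

    alpha: float = 0.05
    seed: int = 0
    n_starts: int = 8
    run_indecision: bool = True
    run_lambda_star: bool = False
    exclusion_alpha: float = 0.05


@dataclass
class RunResult:
    """Per-group classifications, indecision comparisons and group status."""

    classifications: pd.DataFrame
    status: pd.DataFrame
    indecision: pd.DataFrame
    details: dict = field(repr=False, default_factory=dict)


def _flat_log_likelihood(cells) -> float:
    """Intercept-only binomial model: one shared success probability."""
    p = float(np.clip(cells.k.sum() / cells.n.sum(), 1e-10, 1 - 1e-10))
    return float(cells.log_binom
                 + np.sum(cells.k * np.log(p) + (cells.n - cells.k) * np.log1p(-p)))


def screen_group(table, family: str, seed: int = 0, alpha: float = 0.05):
    """Exclusion screen; returns (ok, reason, basic_fit).

    "not modulated": the basic model (biases + one slope, no lapses) does not
    beat the flat model at ``alpha``, or its slope-type parameter hits the
    upper bound.  "inverted" (symmetric task only): empirical response
    proportions decrease with orientation on both mappings.
    """
    from dataclasses import replace

    cells = aggregate_cells(table)
    ll_flat = _flat_log_likelihood(cells)

    def modulated(c):
        fit = fit_mle(c, ModelSpec(family=family), seed=seed, n_starts=4)
        df = fit.n_parameters - 1
        stat = max(0.0, 2.0 * (fit.log_likelihood - ll_flat))
        p = float(chi2.sf(stat, df))
        scale_name = "sigma_primary" if family == "symmetric_sdt" else "sigma"
        scale = fit.estimates.get(scale_name, 0.0)
        return (p < alpha and scale < 10.0 - 1e-3), fit

    ok, basic = modulated(cells)
    if ok:
        return True, "analyzed", basic
    # an increasing probit cannot track decreasing proportions, so inverted
    # response coding also presents as "not modulated"; disambiguate by the
    # Spearman trend sign plus a refit on flipped responses
    if family == "symmetric_sdt":
        rhos = []
        for code in (0, 1):
            m = cells.side == code
            if m.sum() >= 3:
                rho = spearmanr(cells.theta[m], cells.k[m] / cells.n[m]).statistic
                if np.isfinite(rho):
                    rhos.append(rho)
        if rhos and all(r < 0 for r in rhos):
            flipped = replace(cells, k=cells.n - cells.k)
            if modulated(flipped)[0]:
                return False, "inverted", basic
    return False, "not modulated", basic


def run_dataset(trials: pd.DataFrame, config: RunConfig | None = None) -> RunResult:
    """Screen, fit and classify every group of a trial table.

    Per-group failures are recorded in the status table and skipped.  For
    symmetric-task groups whose label includes a decisional bias the
    SDT-versus-indecision AIC comparison is run as well.
    """
    config = config or RunConfig()
    validate_trial_table(trials)
    class_rows, status_rows, ind_rows = [], [], []
    details: dict = {}
    if len(trials) == 0:
        return RunResult(pd.DataFrame(), pd.DataFrame(), pd.DataFrame(), details)
    groups = list(iter_groups(trials))
    seeds = np.random.default_rng(config.seed).integers(0, 2**31 - 1,
                                                        size=len(groups))
    for (key, sub), gseed in zip(groups, seeds):
        participant, band, task = key
        family = _FAMILY_FOR_TASK[str(task)]
        record = dict(participant=participant, orientation_band=band, task=task)
        try:
            ok, reason, _ = screen_group(sub, family, seed=int(gseed),
                                         alpha=config.exclusion_alpha)
            status_rows.append({**record, "status": reason})
            if not ok:
                continue
            cls = classify_bias(sub, family=family, alpha=config.alpha,
                                seed=int(gseed), n_starts=config.n_starts)
            spec = cls.structure_fit.spec
            trail_p = ";".join(f"{s.p_value:.4g}" for s in cls.trail)
            class_rows.append({
                **record,
                "label": cls.label,
                "delta_s": cls.delta_s_hat,
                "delta_d": cls.delta_d_hat,
                "sigma_primary": cls.structure_fit.estimates.get(
                    "sigma_primary", cls.structure_fit.estimates.get("sigma")),
                "sigma_mirrored": cls.structure_fit.estimates.get(
                    "sigma_mirrored"),
                "n_sigmas": spec.n_sigmas,
                "lapse_structure": spec.lapse_structure,
                "log_likelihood": cls.structure_fit.log_likelihood,
                "aic": cls.structure_fit.aic,
                "p_values": trail_p,
            })
            details[key] = cls
            if config.run_lambda_star and family == "symmetric_sdt":
                details[key, "lambda_star"] = lambda_star_check(
                    sub, seed=int(gseed), alpha=config.alpha)
            if (config.run_indecision and family == "symmetric_sdt"
                    and cls.label in ("decisional", "sensory_plus_decisional")):
                comp = compare_indecision(sub, seed=int(gseed))
                ind_rows.append({
                    **record,
                    "aic_sdt": comp.aic_sdt,
                    "aic_indecision": comp.aic_indecision,
                    "aic_indecision_symmetric": comp.aic_indecision_symmetric,
                    "winner": comp.winner,
                })
                details[key, "indecision"] = comp
        except Exception as exc:  # per-group failures are not fatal
            status_rows.append({**record, "status": f"failed: {exc}"})
    return RunResult(
        classifications=pd.DataFrame(class_rows),
        status=pd.DataFrame(status_rows),
        indecision=pd.DataFrame(ind_rows),
        details=details,
    )


def _t_ci(values: np.ndarray, level: float = 0.95):
    values = np.asarray(values, dtype=float)
    m = float(values.mean())
    if len(values) < 2 or np.allclose(values, values[0]):
        return m, (m, m)
    se = float(values.std(ddof=1) / np.sqrt(len(values)))
    h = float(t_dist.ppf(0.5 + level / 2, len(values) - 1)) * se
    return m, (m - h, m + h)


@dataclass
class BiasSummary:
    """Group-level aggregates of the per-group bias estimates."""

    per_group: pd.DataFrame
    mean_abs_delta_s: float | None = None
    ci_abs_delta_s: tuple | None = None
    mean_abs_delta_d: float | None = None
    ci_abs_delta_d: tuple | None = None
    paired_t: float | None = None
    paired_t_df: int | None = None
    paired_t_p: float | None = None
    cross_task_r: float | None = None
    cross_task_df: int | None = None
    cross_task_p: float | None = None
    cross_band_r: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "mean_abs_delta_s", "ci_abs_delta_s", "mean_abs_delta_d",
            "ci_abs_delta_d", "paired_t", "paired_t_df", "paired_t_p",
            "cross_task_r", "cross_task_df", "cross_task_p")}
        d["cross_band_r"] = self.cross_band_r
        d["n_groups"] = int(len(self.per_group))
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)


def summarize_biases(classifications: pd.DataFrame) -> BiasSummary:
    """Aggregate per-group bias estimates.

    Needs >= 2 groups for the aggregates; with fewer, only the per-group
    rows are populated.  Cross-task and cross-band Pearson correlations are
    computed where both members of a pair exist.
    """
    per_group = classifications.copy()
    out = BiasSummary(per_group=per_group)
    if len(per_group) < 2:
        return out
    abs_s = per_group["delta_s"].abs().to_numpy(float)
    abs_d = per_group["delta_d"].abs().to_numpy(float)
    out.mean_abs_delta_s, out.ci_abs_delta_s = _t_ci(abs_s)
    out.mean_abs_delta_d, out.ci_abs_delta_d = _t_ci(abs_d)
    tt = ttest_rel(abs_s, abs_d)
    out.paired_t = float(tt.statistic)
    out.paired_t_df = len(abs_s) - 1
    out.paired_t_p = float(tt.pvalue)

    if per_group["task"].nunique() == 2:
        wide = per_group.pivot_table(index=["participant", "orientation_band"],
                                     columns="task", values="delta_s").dropna()
        if len(wide) >= 3:
            r = pearsonr(wide["symmetric"], wide["asymmetric"])
            out.cross_task_r = float(r.statistic)
            out.cross_task_df = len(wide) - 2
            out.cross_task_p = float(r.pvalue)

    for task, sub in per_group.groupby("task"):
        if sub["orientation_band"].nunique() == 2:
            wide = sub.pivot_table(index="participant",
                                   columns="orientation_band",
                                   values="delta_s").dropna()
            if len(wide) >= 3:
                r = pearsonr(wide["horizontal"], wide["vertical"])
                out.cross_band_r[str(task)] = {
                    "r": float(r.statistic), "df": len(wide) - 2,
                    "p": float(r.pvalue)}
    return out


def crossing_orientation(fit_params, side, family: str = "symmetric_sdt",
                         lo: float = -10.0, hi: float = 10.0) -> float:
    """Orientation at which P(clockwise-consistent) = 0.5 for one mapping.

    For the lapse-free one-slope SDT model this is analytically
    ``delta_d - delta_s`` (primary) or ``-delta_d - delta_s`` (mirrored);
    computed numerically so it applies to any fitted parameter vector.
    """
    fn = _MODEL_FN[family]

    def g(th):
        return float(fn(th, fit_params, side)) - 0.5

    return float(brentq(g, lo, hi))


def single_reference_bias(table, side=ReferenceSide.MIRRORED, seed: int = 0
                          ) -> float:
    """Bias estimate from a single reference mapping.

    For the symmetric task: the orientation at which the fitted single-curve
    probability of a clockwise-consistent response is 50%.  For the
    asymmetric task: the orientation at which the fitted "aligned"
    probability peaks.  Single-mapping data cannot split the bias into
    sensory and decisional parts; this is the conflated estimate.
    """
    side = ReferenceSide(side)
    table = table[table["reference"].astype(str) == side.value]
    task = str(table["task"].iloc[0])
    family = _FAMILY_FOR_TASK[task]
    cells = aggregate_cells(table)
    fit = fit_mle(cells, ModelSpec(family=family,
                                   bias_structure="sensory_only"),
                  seed=seed, n_starts=4)
    if family == "symmetric_sdt":
        return crossing_orientation(fit.params, side, family)
    m = fit.params.delta_s  # interval center; delta_d is pinned at 0
    return float(m)
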