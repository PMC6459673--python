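"""Trial tables and their binomial-cell aggregation.

A trial table is a tidy :class:`pandas.DataFrame` with one row per trial and
columns ``participant``, ``task`` (symmetric / asymmetric),
``orientation_band`` (horizontal / vertical), ``reference`` (primary /
mirrored, after recoding right→primary, left→mirrored etc.),
``orientation_deg`` (signed degrees) and ``response`` (0/1; 1 =
clockwise-consistent for the symmetric task, "aligned" for the asymmetric
one).  An optional ``block`` column is carried through untouched.

Constant-stimuli designs repeat exact orientation levels, so a group's trials
aggregate without information loss into binomial cells (k successes of n at
each level × reference); the likelihood code works on that representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .models import ReferenceSide

REQUIRED_COLUMNS = (
    "participant", "task", "orientation_band", "reference",
    "orientation_deg", "response",
)
GROUP_KEY = ("participant", "orientation_band", "task")

TASKS = ("symmetric", "asymmetric")
BANDS = ("horizontal", "vertical")

#: orientations are matched exactly after rounding at this resolution (deg)
LEVEL_RESOLUTION = 1e-6


class TrialTableError(ValueError):
    """A trial table violates the schema."""


def validate_trial_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate schema and value domains; returns the table unchanged."""
    if not isinstance(table, pd.DataFrame):
        raise TrialTableError("trial table must be a pandas DataFrame")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise TrialTableError(f"missing columns: {missing}")
    if len(table):
        if not np.isfinite(table["orientation_deg"].to_numpy(float)).all():
            raise TrialTableError("orientation_deg must be finite")
        resp = table["response"].to_numpy()
        if not np.isin(resp, (0, 1)).all():
            raise TrialTableError("response must be strictly binary (0/1)")
        bad_ref = set(table["reference"].astype(str)) - {s.value for s in ReferenceSide}
        if bad_ref:
            raise TrialTableError(f"unknown reference values: {sorted(bad_ref)}")
        bad_task = set(table["task"].astype(str)) - set(TASKS)
        if bad_task:
            raise TrialTableError(f"unknown task values: {sorted(bad_task)}")
    return table


def read_trials(path) -> pd.DataFrame:
    """Read a trial table from comma-separated text (header row, UTF-8)."""
    return validate_trial_table(pd.read_csv(path))


def write_trials(table: pd.DataFrame, path) -> None:
    """Write a trial table as comma-separated text."""
    table.to_csv(path, index=False)


def iter_groups(table: pd.DataFrame):
    """Yield ``(key, subtable)`` per (participant, orientation_band, task)."""
    for key, sub in table.groupby(list(GROUP_KEY), sort=True):
        yield key, sub


@dataclass
class Cells:
    """Binomial-cell view of one group's trials.

    ``theta``, ``n``, ``k`` are per-cell arrays; ``side`` is 0 for the
    primary reference and 1 for the mirrored one.  ``log_binom`` caches the
    sum of log binomial coefficients, a data-only constant of the likelihood.
    """

    theta: np.ndarray
    n: np.ndarray
    k: np.ndarray
    side: np.ndarray
    log_binom: float

    @property
    def n_trials(self) -> int:
        return int(self.n.sum())

    def has_side(self, side_code: int) -> bool:
        return bool((self.side == side_code).any())


def cells_from_arrays(theta, side, response) -> Cells:
    """Build binomial cells from per-trial arrays (side coded 0/1).

    Orientation values are rounded to :data:`LEVEL_RESOLUTION` before exact
    matching, as constant-stimuli designs repeat exact levels.  Cells are
    ordered by (side, theta), so the result is invariant to trial order.
    """
    theta = np.round(np.asarray(theta, dtype=float) / LEVEL_RESOLUTION) \
        * LEVEL_RESOLUTION
    side = np.asarray(side, dtype=int)
    response = np.asarray(response, dtype=float)
    if len(theta) == 0:
        raise TrialTableError("empty trial table")
    pairs = np.column_stack([side.astype(float), theta])
    uniq, inv = np.unique(pairs, axis=0, return_inverse=True)
    n = np.bincount(inv).astype(float)
    k = np.bincount(inv, weights=response)
    log_binom = float(np.sum(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)))
    return Cells(theta=uniq[:, 1], n=n, k=k, side=uniq[:, 0].astype(int),
                 log_binom=log_binom)


def aggregate_cells(table: pd.DataFrame) -> Cells:
    """Collapse one group's trials into (level × reference) binomial cells."""
    if len(table) == 0:
        raise TrialTableError("empty trial table")
    side = (table["reference"].astype(str)
            == ReferenceSide.MIRRORED.value).to_numpy().astype(int)
    return cells_from_arrays(table["orientation_deg"].to_numpy(float),
                             side, table["response"].to_numpy(float))
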