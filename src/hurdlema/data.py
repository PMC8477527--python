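"""Long-format EMA data handling for semicontinuous dietary outcomes.

The container and pre-processing steps here implement the standard pipeline
for signal-contingent EMA designs in which an event-contingent record of
intake (timestamp + kcal) is aggregated into the time-interval following each
prompt: matching intake events to prompt windows, person-mean centering of
momentary (Level-1) covariates, and descriptives for a semicontinuous outcome
(share of exact zeros, mean of the positive part).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default CSV column names for long-format EMA files
#: (subject ID, prompt number, study day, clock time, kcal, plus covariates).
DEFAULT_SCHEMA = {
    "participant_id": "ID",
    "prompt_index": "alarm",
    "day": "day",
    "clock_time": "time",
    "outcome": "energy_intake",
}

CORE_COLUMNS = ("participant_id", "prompt_index", "day", "clock_time", "outcome")


class SchemaError(ValueError):
    """A required column is missing from the input file."""


class ValidationError(ValueError):
    """Row-level data violates an invariant (e.g. negative outcome)."""


@dataclass
class LoadReport:
    n_rows_read: int = 0
    n_rows_kept: int = 0
    n_dropped_missing_outcome: int = 0


@dataclass
class EmaDataset:
    """Long-format repeated-measures table, one row per (participant, prompt).

    ``table`` holds the standardised columns ``participant_id``,
    ``prompt_index``, ``day``, ``clock_time``, ``outcome`` plus any covariate
    columns.  ``outcome`` is energy intake in kcal within the interval
    following the prompt: exactly 0 when no eating occurred, a right-skewed
    positive value otherwise (a semicontinuous variable).

    Parameters
    ----------
    table
        The long-format data frame.
    level1_covariates
        Names of covariates that vary within a participant across prompts
        (e.g. person-mean-centered momentary energetic arousal).
    level2_covariates
        Names of covariates constant within a participant
        (e.g. gender coded 0 = male, 1 = female).
    """

    table: pd.DataFrame
    level1_covariates: list[str] = field(default_factory=list)
    level2_covariates: list[str] = field(default_factory=list)
    load_report: LoadReport | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- basic protocol -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_participants(self) -> int:
        return self.table["participant_id"].nunique()

    @property
    def outcome(self) -> np.ndarray:
        return self.table["outcome"].to_numpy(dtype=float)

    def participant_codes(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer codes 0..J-1 per row plus the ordered participant labels."""
        codes, labels = pd.factorize(self.table["participant_id"], sort=True)
        return codes, np.asarray(labels)

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        t = self.table
        missing = [c for c in CORE_COLUMNS if c not in t.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        y = t["outcome"].to_numpy(dtype=float)
        if not np.all(np.isfinite(y)):
            bad = int(np.flatnonzero(~np.isfinite(y))[0])
            raise ValidationError(f"non-finite outcome at row {bad}")
        if np.any(y < 0):
            bad = int(np.flatnonzero(y < 0)[0])
            raise ValidationError(f"negative outcome at row {bad}: {y[bad]}")
        dup = t.duplicated(subset=["participant_id", "prompt_index"])
        if dup.any():
            raise ValidationError(
                "duplicate (participant_id, prompt_index) pairs: "
                f"{t.loc[dup, ['participant_id', 'prompt_index']].iloc[0].tolist()}"
            )
        for cov in self.level2_covariates:
            if t.groupby("participant_id", observed=True)[cov].nunique().gt(1).any():
                raise ValidationError(
                    f"level-2 covariate {cov!r} varies within a participant"
                )


def load_ema_dataset(
    path,
    schema: dict[str, str] | None = None,
    level1_covariates: list[str] | None = None,
    level2_covariates: list[str] | None = None,
    delimiter: str = ",",
) -> EmaDataset:
    """Read a long-format EMA CSV into an :class:`EmaDataset`.

    ``schema`` maps standard field names to the file's column names; the
    default expects the conventional columns ``ID, alarm, day, time,
    energy_intake`` with covariates such as ``gender`` and ``EA`` alongside.
    Rows with a missing outcome are dropped and counted in the load report.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    raw = pd.read_csv(path, delimiter=delimiter)
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise SchemaError(f"mapped column(s) not found in {path}: {missing}")

    df = raw.rename(columns={v: k for k, v in colmap.items()})
    report = LoadReport(n_rows_read=len(df))
    keep = df["outcome"].notna()
    report.n_dropped_missing_outcome = int((~keep).sum())
    df = df.loc[keep].reset_index(drop=True)
    report.n_rows_kept = len(df)
    df["outcome"] = df["outcome"].astype(float)
    for col in ("prompt_index", "day"):
        df[col] = df[col].astype(int)
    df["clock_time"] = df["clock_time"].astype(float)

    if level1_covariates is None and level2_covariates is None:
        # infer: any extra column constant within participant is Level 2
        extras = [c for c in df.columns if c not in CORE_COLUMNS]
        nun = df.groupby("participant_id")[extras].nunique() if extras else None
        level2_covariates = [c for c in extras if nun[c].le(1).all()]
        level1_covariates = [c for c in extras if c not in level2_covariates]
    logger.info(
        "loaded %s: %d rows read, %d kept, %d dropped (missing outcome), %d participants",
        path, report.n_rows_read, report.n_rows_kept,
        report.n_dropped_missing_outcome, df["participant_id"].nunique(),
    )
    return EmaDataset(
        df,
        level1_covariates=list(level1_covariates or []),
        level2_covariates=list(level2_covariates or []),
        load_report=report,
    )


@dataclass(frozen=True)
class IntakeEvent:
    """A single event-contingent intake record within a study day."""

    timestamp: float  # decimal hours, e.g. 8.5 = 8:30
    amount: float  # kcal, strictly positive

    def __post_init__(self) -> None:
        if not np.isfinite(self.timestamp):
            raise ValidationError("event timestamp must be finite")
        if not (np.isfinite(self.amount) and self.amount > 0):
            raise ValidationError(f"event amount must be > 0, got {self.amount}")


def match_intake_to_prompts(
    prompt_times: np.ndarray,
    events: list[IntakeEvent],
    cap_hours: float = 2.0,
) -> np.ndarray:
    """Aggregate intake events into the interval following each prompt.

    For a prompt at time ``t`` the matched outcome is the summed kcal of
    events with timestamp in the half-open window ``(t, t_end]`` where
    ``t_end = min(next prompt, t + cap_hours)``; for the last prompt of the
    day ``t_end = t + cap_hours``.  The cap handles long gaps from missed
    prompts.  Prompts with no matched events receive exactly 0.  An event at
    exactly a prompt time belongs to the *preceding* window (half-open
    convention), so no event is ever counted twice.
    """
    t = np.asarray(prompt_times, dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise ValueError("prompt_times must be a non-empty 1-d sequence")
    if cap_hours <= 0:
        raise ValueError("cap_hours must be > 0")
    if np.any(np.diff(t) <= 0):
        raise ValueError("prompt_times must be strictly increasing")
    events = [e if isinstance(e, IntakeEvent) else IntakeEvent(*e) for e in events]

    ends = np.empty_like(t)
    ends[:-1] = np.minimum(t[1:], t[:-1] + cap_hours)
    ends[-1] = t[-1] + cap_hours
    out = np.zeros_like(t)
    for ev in events:
        in_win = (ev.timestamp > t) & (ev.timestamp <= ends)
        idx = np.flatnonzero(in_win)
        if idx.size:
            out[idx[0]] += ev.amount  # windows are disjoint; idx is unique
    return out


def person_mean_center(values, grouping) -> np.ndarray:
    """Center a Level-1 covariate on each participant's own mean.

    Missing values are ignored when computing the mean and returned missing.
    The resulting variable has per-participant mean 0, so its regression
    coefficient captures within-person fluctuation only.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(np.asarray(grouping))
    counts = s.notna().groupby(g).sum()
    empty = counts[counts == 0]
    if len(empty):
        raise ValidationError(
            f"participant {empty.index[0]!r} has no non-missing values to center"
        )
    centered = s - s.groupby(g).transform("mean")
    return centered.to_numpy()


def describe_semicontinuous(outcome) -> dict:
    """Descriptives of a semicontinuous outcome: zeros and the positive part.

    Returns ``n_total``, ``n_zero``, ``prop_zero`` and ``mean_nonzero`` (NaN
    when no positive values exist).
    """
    y = np.asarray(outcome, dtype=float)
    if y.size == 0:
        raise ValueError("empty outcome")
    if np.any(y < 0) or not np.all(np.isfinite(y)):
        raise ValidationError("outcomes must be finite and >= 0")
    n_zero = int(np.sum(y == 0))
    pos = y[y > 0]
    return {
        "n_total": int(y.size),
        "n_zero": n_zero,
        "prop_zero": n_zero / y.size,
        "mean_nonzero": float(pos.mean()) if pos.size else float("nan"),
    }
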