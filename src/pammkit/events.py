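"""Recurrent event histories on the age timescale.

A subject's follow-up is a window ``(entry_time, exit_time]`` in days since
birth.  Episodes of disease are recorded as exact days.  Two recorded events
closer together than the episode gap (default 14 days) are read as the same
clinical episode: only events occurring *more than* ``gap_days`` after the
previously retained event open a new episode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyWindow",
    "SubjectHistory",
    "canonicalize_episodes",
    "read_histories",
    "write_histories",
]


@dataclass(frozen=True)
class StudyWindow:
    """Observation window and episode-gap rule.

    Parameters
    ----------
    t_min, t_max : float
        Start and end of the observation window in days (default 0 to 728,
        i.e. the first two years of life).
    gap_days : float
        Minimum separation between distinct episodes; events within
        ``gap_days`` of the previously retained event are merged.
    """

    t_min: float = 0.0
    t_max: float = 728.0
    gap_days: float = 14.0

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValueError(f"t_min ({self.t_min}) must be < t_max ({self.t_max})")
        if self.gap_days < 0:
            raise ValueError("gap_days must be >= 0")


def canonicalize_episodes(raw_event_days: Sequence[float], gap_days: float) -> list[float]:
    """Collapse recorded events into distinct episodes by the gap rule.

    Sequential scan: the first event is always retained; a subsequent event
    is retained only if it falls more than ``gap_days`` after the previously
    *retained* event.  Idempotent.

    Raises
    ------
    ValueError
        If ``raw_event_days`` is not sorted ascending.
    """
    days = list(raw_event_days)
    if any(b < a for a, b in zip(days, days[1:])):
        raise ValueError("raw_event_days must be sorted ascending")
    kept: list[float] = []
    for d in days:
        if not kept or d - kept[-1] > gap_days:
            kept.append(d)
    return kept


@dataclass
class SubjectHistory:
    """One subject's canonical recurrent-event history.

    ``episode_times`` are strictly increasing days in
    ``(entry_time, exit_time]`` separated by more than the gap used at
    canonicalization.  ``covariates`` maps covariate names to fixed values
    (binary risk factors coded 0/1).  ``birth_day_of_year`` (1-365) anchors
    the calendar for seasonal terms.
    """

    subject_id: str
    entry_time: float
    exit_time: float
    episode_times: list[float] = field(default_factory=list)
    covariates: dict[str, float] = field(default_factory=dict)
    birth_day_of_year: int | None = None

    def __post_init__(self) -> None:
        if not self.entry_time < self.exit_time:
            raise ValueError(
                f"subject {self.subject_id!r}: entry_time {self.entry_time} "
                f"must be < exit_time {self.exit_time}"
            )
        t = list(self.episode_times)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError(f"subject {self.subject_id!r}: episode_times must be strictly increasing")
        for d in t:
            if not (self.entry_time < d <= self.exit_time):
                raise ValueError(
                    f"subject {self.subject_id!r}: episode at day {d} outside "
                    f"({self.entry_time}, {self.exit_time}]"
                )
        if self.birth_day_of_year is not None and not (1 <= self.birth_day_of_year <= 365):
            raise ValueError("birth_day_of_year must be in 1..365")

    @property
    def n_episodes(self) -> int:
        return len(self.episode_times)

    @property
    def at_risk_time(self) -> float:
        return self.exit_time - self.entry_time


def read_histories(
    table: pd.DataFrame,
    window: StudyWindow | None = None,
    *,
    id_col: str = "id",
    entry_col: str | None = "entry",
    exit_col: str = "exit",
    event_col: str = "event_day",
    birth_doy_col: str | None = "birth_doy",
    covariate_cols: Iterable[str] | None = None,
    canonicalize: bool = True,
) -> list[SubjectHistory]:
    """Read subject histories from a long-format table.

    One row per recorded event; subjects without events contribute a single
    row with a missing ``event_day``.  Entry defaults to the window start
    when the entry column is absent.  Covariates must be constant within
    subject.  Events are canonicalized with the window's gap rule unless
    ``canonicalize=False``.
    """
    window = window or StudyWindow()
    for col in (id_col, exit_col):
        if col not in table.columns:
            raise ValueError(f"missing required column {col!r}")
    has_event = event_col in table.columns
    if not has_event and len(table):
        raise ValueError(f"missing event column {event_col!r}")

    if covariate_cols is None:
        reserved = {id_col, entry_col, exit_col, event_col, birth_doy_col}
        covariate_cols = [c for c in table.columns if c not in reserved]
    covariate_cols = list(covariate_cols)

    for col in [exit_col] + ([entry_col] if entry_col in table.columns else []):
        if not pd.api.types.is_numeric_dtype(table[col]):
            raise ValueError(f"column {col!r} must be numeric")
    if has_event and not pd.api.types.is_numeric_dtype(table[event_col]):
        raise ValueError(f"column {event_col!r} must be numeric")

    ev = table.dropna(subset=[event_col]) if has_event else table.iloc[:0]
    dup = ev.duplicated(subset=[id_col, event_col])
    if dup.any():
        bad = ev.loc[dup, [id_col, event_col]].iloc[0]
        raise ValueError(f"duplicated (subject, event day) row: {tuple(bad)}")

    histories: list[SubjectHistory] = []
    for sid, grp in table.groupby(id_col, sort=False):
        entry = float(grp[entry_col].iloc[0]) if entry_col in grp.columns else window.t_min
        exit_ = float(grp[exit_col].iloc[0])
        if exit_ <= entry:
            raise ValueError(f"subject {sid!r}: exit ({exit_}) <= entry ({entry})")
        if exit_ > window.t_max:
            raise ValueError(f"subject {sid!r}: exit {exit_} beyond window end {window.t_max}")
        days = sorted(float(d) for d in grp[event_col].dropna()) if has_event else []
        for d in days:
            if not (entry < d <= exit_):
                raise ValueError(f"subject {sid!r}: event day {d} outside ({entry}, {exit_}]")
        if canonicalize:
            days = canonicalize_episodes(days, window.gap_days)
        covs = {c: float(grp[c].iloc[0]) for c in covariate_cols}
        bdoy = None
        if birth_doy_col and birth_doy_col in grp.columns and pd.notna(grp[birth_doy_col].iloc[0]):
            bdoy = int(grp[birth_doy_col].iloc[0])
        histories.append(
            SubjectHistory(
                subject_id=str(sid),
                entry_time=entry,
                exit_time=exit_,
                episode_times=days,
                covariates=covs,
                birth_day_of_year=bdoy,
            )
        )
    return histories


def write_histories(histories: Sequence[SubjectHistory]) -> pd.DataFrame:
    """Serialize histories to the canonical long format read by
    :func:`read_histories` (lossless round trip)."""
    cov_names: list[str] = []
    for h in histories:
        for c in h.covariates:
            if c not in cov_names:
                cov_names.append(c)
    rows = []
    for h in histories:
        base: dict[str, object] = {
            "id": h.subject_id,
            "entry": h.entry_time,
            "exit": h.exit_time,
            "birth_doy": h.birth_day_of_year if h.birth_day_of_year is not None else np.nan,
        }
        base.update({c: h.covariates.get(c, np.nan) for c in cov_names})
        if h.episode_times:
            for d in h.episode_times:
                rows.append({**base, "event_day": d})
        else:
            rows.append({**base, "event_day": np.nan})
    return pd.DataFrame(rows, columns=["id", "entry", "exit", "event_day", "birth_doy", *cov_names])
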