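"""Piece-wise exponential data (PED): interval-split pseudo-observations.

The window is partitioned by cutpoints 0 = tau_0 < tau_1 < ... < tau_J =
t_max, intervals half-open (tau_{j-1}, tau_j], with representative time
t_j = tau_j (the right endpoint).  Each subject contributes one row per
interval overlapping each of their at-risk spells; ``offset`` is the log of
the exact time spent at risk in the row, so a Poisson fit on ``event`` with
this offset is the piece-wise exponential likelihood up to a constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .events import StudyWindow, SubjectHistory

__all__ = ["CutpointGrid", "build_cutpoints", "split_to_ped", "attach_current_season"]

PED_COLUMNS = ["id", "j", "tstart", "tend", "t_j", "exposure", "offset", "event"]


@dataclass(frozen=True)
class CutpointGrid:
    """Ordered interval cutpoints tau_0 < ... < tau_J over the window."""

    cutpoints: np.ndarray

    def __post_init__(self) -> None:
        cp = np.asarray(self.cutpoints, dtype=float)
        object.__setattr__(self, "cutpoints", cp)
        if cp.ndim != 1 or len(cp) < 2:
            raise ValueError("need at least two cutpoints")
        if np.any(np.diff(cp) <= 0):
            raise ValueError("cutpoints must be strictly increasing")

    @property
    def n_intervals(self) -> int:
        return len(self.cutpoints) - 1

    @property
    def t_j(self) -> np.ndarray:
        """Representative times: the right endpoint of each interval."""
        return self.cutpoints[1:]

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.cutpoints)

    def interval_of(self, t: np.ndarray) -> np.ndarray:
        """0-based interval index of times in (tau_0, tau_J]."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.cutpoints, t, side="left") - 1
        if np.any((t <= self.cutpoints[0]) | (t > self.cutpoints[-1])):
            raise ValueError("times outside (tau_0, tau_J]")
        return idx


def build_cutpoints(
    histories: Sequence[SubjectHistory],
    window: StudyWindow | None = None,
) -> CutpointGrid:
    """Default grid: window start, the ordered unique episode times, and the
    window end (duplicates and an episode coinciding with t_max collapse)."""
    if not histories:
        raise ValueError("need at least one history")
    window = window or StudyWindow()
    times = sorted({d for h in histories for d in h.episode_times})
    cp = [window.t_min] + [t for t in times if window.t_min < t < window.t_max] + [window.t_max]
    return CutpointGrid(np.asarray(cp))


def _risk_spells(h: SubjectHistory, gap_days: float, blank_gap: bool) -> list[tuple[float, float, float | None]]:
    """Spells (a, b] of continuous risk, each optionally ending in an episode.

    Returns (start, end, episode) triples; episode is the event terminating
    the spell or None for the final censored spell.  With ``blank_gap`` the
    ``gap_days`` after each episode carry no exposure.
    """
    spells = []
    start = h.entry_time
    for e in h.episode_times:
        if e <= start:
            raise ValueError(
                f"subject {h.subject_id!r}: episode at {e} falls outside the at-risk "
                f"spell starting at {start} (gap blanking inconsistent with episodes?)"
            )
        spells.append((start, e, e))
        start = e + gap_days if blank_gap else e
    if start < h.exit_time:
        spells.append((start, h.exit_time, None))
    return spells


def split_to_ped(
    histories: Sequence[SubjectHistory],
    grid: CutpointGrid,
    window: StudyWindow | None = None,
    *,
    blank_gap: bool = False,
) -> pd.DataFrame:
    """Split histories into the PED table (counting-process layout on age).

    One row per subject x risk spell x overlapping interval; ``exposure`` is
    the overlap length, ``event`` is 1 on the row containing the spell's
    terminating episode.  Zero-exposure rows are never emitted.  Covariate
    columns are carried through unchanged.
    """
    window = window or StudyWindow()
    cp = grid.cutpoints
    cov_names: list[str] = []
    for h in histories:
        for c in h.covariates:
            if c not in cov_names:
                cov_names.append(c)

    recs: list[dict] = []
    for h in histories:
        for a, b, episode in _risk_spells(h, window.gap_days, blank_gap):
            # first interval (cp[j-1], cp[j]] with cp[j] > a
            j_first = max(int(np.searchsorted(cp, a, side="right")), 1)
            for j in range(j_first, grid.n_intervals + 1):
                lo, hi = cp[j - 1], cp[j]
                s, t = max(a, lo), min(b, hi)
                if t <= s:
                    if lo >= b:
                        break
                    continue
                ev = 1 if (episode is not None and s < episode <= t) else 0
                rec = {
                    "id": h.subject_id,
                    "j": j,
                    "tstart": s,
                    "tend": t,
                    "t_j": cp[j],
                    "exposure": t - s,
                    "offset": np.log(t - s),
                    "event": ev,
                }
                for c in cov_names:
                    rec[c] = h.covariates.get(c, np.nan)
                recs.append(rec)
            if episode is not None and not (a < episode <= min(b, cp[-1])):
                raise ValueError(f"subject {h.subject_id!r}: episode {episode} outside grid")
    ped = pd.DataFrame(recs, columns=PED_COLUMNS + cov_names)
    # sanity: per-spell events must all have landed in some row
    n_events = sum(h.n_episodes for h in histories)
    if len(ped) and int(ped["event"].sum()) != n_events:
        raise ValueError("internal inconsistency: episodes lost during interval split")
    return ped


def attach_current_season(ped: pd.DataFrame, histories: Sequence[SubjectHistory]) -> pd.DataFrame:
    """Add ``current_doy``: day-of-year at each row's risk-span start.

    current_doy = ((birth_day_of_year - 1 + floor(tstart)) mod 365) + 1,
    periodic with period 365.
    """
    bdoy = {}
    for h in histories:
        if h.birth_day_of_year is None:
            raise ValueError(f"subject {h.subject_id!r} has no birth_day_of_year; seasonality needs it")
        bdoy[h.subject_id] = h.birth_day_of_year
    out = ped.copy()
    birth = out["id"].map(bdoy).to_numpy(dtype=float)
    out["current_doy"] = ((birth - 1 + np.floor(out["tstart"].to_numpy())) % 365) + 1
    return out
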