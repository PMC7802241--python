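"""File-based pipeline steps: split, fit-and-select, simulate.

Thin wrappers over the library that read/write the package's CSV and JSON
dialects, for reproducible batch runs.  Each step is deterministic given
its inputs (and seed) and records counts and conservation checks in a JSON
sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .effects import cumulative_incidence, hazard_curve, hazard_ratio_curve, select_final_model
from .events import StudyWindow, SubjectHistory, read_histories, write_histories
from .model import ModelSpec, fit
from .ped import CutpointGrid, attach_current_season, build_cutpoints, split_to_ped
from .simulate import SimulationScenario, simulate_cohort, truth_curves

__all__ = ["split_to_files", "fit_covariate_to_files", "simulate_to_files"]


def _conservation(ped: pd.DataFrame, histories: Sequence[SubjectHistory]) -> dict:
    by_id = ped.groupby("id")
    exposure = by_id["exposure"].sum()
    events = by_id["event"].sum()
    risk = {h.subject_id: h.at_risk_time for h in histories}
    eps = {h.subject_id: h.n_episodes for h in histories}
    max_err = max(
        (abs(exposure.get(sid, 0.0) - rt) for sid, rt in risk.items()),
        default=0.0,
    )
    ev_ok = all(int(events.get(sid, 0)) == k for sid, k in eps.items())
    return {"max_exposure_error": float(max_err), "events_conserved": bool(ev_ok)}


def split_to_files(
    input_csv: str | Path,
    outdir: str | Path,
    *,
    window: StudyWindow | None = None,
    cutpoints: Sequence[float] | None = None,
    blank_gap: bool = False,
    seasonality: bool = False,
) -> Path:
    """Read a long-format event table, write the PED CSV plus a JSON
    sidecar (cutpoints, counts, total exposure, conservation checks).

    Raises on empty or invalid input.  Returns the PED path.
    """
    window = window or StudyWindow()
    table = pd.read_csv(input_csv)
    if len(table) == 0:
        raise ValueError(f"input file {input_csv} is empty")
    histories = read_histories(table, window)
    grid = CutpointGrid(np.asarray(cutpoints)) if cutpoints is not None else build_cutpoints(histories, window)
    ped = split_to_ped(histories, grid, window, blank_gap=blank_gap)
    if seasonality:
        ped = attach_current_season(ped, histories)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ped_path = outdir / "ped.csv"
    ped.to_csv(ped_path, index=False)
    sidecar = {
        "package_version": __version__,
        "n_subjects": int(ped["id"].nunique()),
        "n_rows": int(len(ped)),
        "n_events": int(ped["event"].sum()),
        "total_exposure_days": float(ped["exposure"].sum()),
        "cutpoints": [float(c) for c in grid.cutpoints],
        "blank_gap": blank_gap,
        "conservation": _conservation(ped, histories),
    }
    (outdir / "ped.json").write_text(json.dumps(sidecar, indent=2))
    return ped_path


def fit_covariate_to_files(
    ped_csv: str | Path,
    covariate: str,
    outdir: str | Path,
    *,
    alpha: float = 0.05,
    baseline_k: int = 10,
    frailty: bool = True,
) -> dict:
    """Fit model 1 and model 2 for one covariate, apply the selection rule,
    write a summary JSON and tidy effect-curve CSVs; returns the report."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    ped = pd.read_csv(ped_csv)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m1 = fit(ped, ModelSpec(covariate=covariate, baseline_k=baseline_k, frailty=frailty))
    m2 = fit(ped, ModelSpec(covariate=covariate, time_varying=True, baseline_k=baseline_k, frailty=frailty))
    report = select_final_model(m1, m2, alpha)
    final = report["fits"][report["chosen"]]

    hazard_curve(final, {covariate: 0.0}, "incidence_per_child_year").to_frame().to_csv(
        outdir / f"incidence_{covariate}0.csv", index=False
    )
    hazard_curve(final, {covariate: 1.0}, "incidence_per_child_year").to_frame().to_csv(
        outdir / f"incidence_{covariate}1.csv", index=False
    )
    hazard_ratio_curve(final, covariate).to_frame().to_csv(outdir / f"hr_{covariate}.csv", index=False)
    cumulative_incidence(final, {covariate: 0.0}).to_frame().to_csv(
        outdir / f"cif_{covariate}0.csv", index=False
    )
    summary = {
        "package_version": __version__,
        "covariate": covariate,
        "alpha": alpha,
        "chosen": report["chosen"],
        "f1_p": report["f1_p"],
        "f1_edf": report["f1_edf"],
        "model1": report["model1"],
        "model2": report["model2"],
        "sigma_frailty": final.sigma_frailty,
    }
    (outdir / f"summary_{covariate}.json").write_text(json.dumps(summary, indent=2))
    return report


def simulate_to_files(scenario: SimulationScenario, outdir: str | Path) -> Path:
    """Simulate a cohort, write the event CSV and a truth JSON (seed and
    truth curves on a daily grid); returns the cohort path."""
    histories, _ = simulate_cohort(scenario)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort_path = outdir / "cohort.csv"
    write_histories(histories).to_csv(cohort_path, index=False)
    grid = np.arange(1.0, scenario.t_max + 1e-9, 7.0)
    tc = truth_curves(scenario, grid)
    truth = {
        "package_version": __version__,
        "seed": scenario.seed,
        "n_subjects": scenario.n_subjects,
        "frailty_sd": scenario.frailty_sd,
        "grid": grid.tolist(),
        **{k: np.asarray(v).tolist() for k, v in tc.items()},
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return cohort_path
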