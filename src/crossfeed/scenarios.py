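"""Simulation experiments: consortium runs, knockouts, time alignment.

These wrap the kinetic core into the workflows used to interrogate the
calibrated model: running the full consortium and summarizing composition,
simulating bacteriostatic knockouts (a species keeps its inoculum but all
growth channels are silenced), and linearly mapping the time axis of a
fast-growing run onto a reference grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    ConsortiumModel,
    InteractionMatrix,
    QpcrCalibration,
    SpeciesParams,
    Trajectory,
    percent_abundance,
    simulate,
)
from .reference import reference_calibrations
from .synthetic_data import CultureDesign, design_model

__all__ = [
    "ScenarioError",
    "AlignmentError",
    "KnockoutSpec",
    "ConsortiumRun",
    "KnockoutResult",
    "run_consortium",
    "apply_knockout",
    "knockout",
    "align_time",
]


class ScenarioError(ValueError):
    """A scenario is inconsistent with the provided model."""


class AlignmentError(ValueError):
    """Time alignment has too few or degenerate anchors."""


@dataclass(frozen=True)
class KnockoutSpec:
    """Bacteriostatic knockout of one species: growth silenced, decay kept."""

    target: str
    mode: str = "bacteriostatic"

    def __post_init__(self):
        if self.mode != "bacteriostatic":
            raise ScenarioError(f"unsupported knockout mode {self.mode!r}")


@dataclass(frozen=True)
class ConsortiumRun:
    trajectory: Trajectory
    percent: pd.DataFrame
    concentrations: pd.DataFrame


@dataclass(frozen=True)
class KnockoutResult:
    trajectory: Trajectory
    percent: pd.DataFrame
    ranking: tuple

    @property
    def dominant(self) -> str:
        return self.ranking[0]


def run_consortium(params: Mapping[str, SpeciesParams],
                   interactions: InteractionMatrix | None,
                   design: CultureDesign,
                   calibrations: Mapping[str, QpcrCalibration] | None = None,
                   rtol: float = 1e-8, atol: float = 1e-10) -> ConsortiumRun:
    """Simulate a multi-species design and summarize composition and pools."""
    if len(design.members) > 1:
        if interactions is None:
            raise ScenarioError("multi-species run requires an interaction matrix")
        missing = [m for m in design.members if m not in interactions.species]
        if missing:
            raise ScenarioError(f"interaction matrix lacks species: {missing}")
    model = design_model(design, params, interactions)
    calibrations = calibrations or reference_calibrations()
    traj = simulate(model, design.times, rtol=rtol, atol=atol)
    percent = percent_abundance(traj, calibrations)
    conc = pd.DataFrame({"time_h": traj.times, "S": traj.S,
                         "A": traj.A, "L": traj.L})
    return ConsortiumRun(trajectory=traj, percent=percent, concentrations=conc)


def apply_knockout(model: ConsortiumModel, spec: KnockoutSpec) -> ConsortiumModel:
    """Model with the target's growth channels silenced (k_d retained)."""
    if spec.target not in model.names:
        raise ScenarioError(f"unknown knockout target {spec.target!r}")
    target = next(p for p in model.species if p.name == spec.target)
    silenced = target.with_values(mu_max=0.0, mu_maxA=0.0, mu_maxL=0.0)
    return model.replace_species(spec.target, silenced)


def knockout(model: ConsortiumModel, spec: KnockoutSpec,
             t_grid: Sequence[float] | None = None,
             calibrations: Mapping[str, QpcrCalibration] | None = None,
             rtol: float = 1e-8, atol: float = 1e-10) -> KnockoutResult:
    """Simulate a bacteriostatic knockout and rank species by final share."""
    ko_model = apply_knockout(model, spec)
    if t_grid is None:
        t_grid = np.linspace(0.0, 72.0, 145)
    calibrations = calibrations or reference_calibrations()
    traj = simulate(ko_model, t_grid, rtol=rtol, atol=atol)
    percent = percent_abundance(traj, calibrations)
    final = percent.iloc[-1].drop("time_h")
    ranking = tuple(final.sort_values(ascending=False).index)
    return KnockoutResult(trajectory=traj, percent=percent, ranking=ranking)


def align_time(reference_times: Sequence[float],
               fast_times: Sequence[float]) -> tuple:
    """Least-squares linear map ``fast ~ scale * reference + offset``.

    Needs at least two anchor points with distinct reference times; returns
    ``(scale, offset)``, the identity ``(1, 0)`` for equal grids.
    """
    ref = np.asarray(reference_times, dtype=float)
    fast = np.asarray(fast_times, dtype=float)
    if ref.shape != fast.shape or ref.ndim != 1 or ref.size < 2:
        raise AlignmentError("need >= 2 paired anchor points")
    if np.ptp(ref) == 0:
        raise AlignmentError("degenerate anchors: reference times are all equal")
    scale, offset = np.polyfit(ref, fast, 1)
    return float(scale), float(offset)
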