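"""Synthetic observed datasets with the structure of the wet-lab designs.

A :class:`CultureDesign` describes one batch culture (vessel, members,
substrate load, sampling grid, replicates, inocula). :func:`generate_dataset`
samples a noiseless simulation on the design grid and adds strictly
observational noise: multiplicative mean-corrected lognormal scatter on qPCR
copy counts and additive truncated-at-zero Gaussian scatter on
concentrations. Noise never feeds back into the dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    ConsortiumModel,
    DomainError,
    InteractionMatrix,
    ParameterError,
    QpcrCalibration,
    SpeciesParams,
    biomass_to_copies,
    simulate,
)
from .reference import (
    SPECIES_ORDER,
    reference_calibrations,
    reference_inoculum,
    reference_interactions,
    reference_species,
)

__all__ = [
    "MICROPLATE_TIMES",
    "BIOREACTOR_TIMES",
    "CultureDesign",
    "NoiseModel",
    "ObservedDataset",
    "design_model",
    "generate_dataset",
    "scenario_catalog",
]

#: microplate sampling grid: every 12 h for 72 h
MICROPLATE_TIMES = tuple(float(t) for t in range(0, 73, 12))
#: bioreactor sampling grid: every 2 h for 24 h
BIOREACTOR_TIMES = tuple(float(t) for t in range(0, 25, 2))


@dataclass(frozen=True)
class CultureDesign:
    """One batch-culture experimental design."""

    name: str
    members: tuple
    vessel: str = "microplate"
    S0: float = 10.0
    times: tuple = MICROPLATE_TIMES
    replicates: int = 2
    inoculum: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "members", tuple(self.members))
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "inoculum", dict(self.inoculum))
        if self.vessel not in ("microplate", "bioreactor"):
            raise ParameterError(f"unknown vessel {self.vessel!r}")
        if not self.members:
            raise ParameterError("design needs at least one member")
        if len(self.times) < 2 or any(
                b <= a for a, b in zip(self.times, self.times[1:])):
            raise ParameterError("sampling times must be strictly increasing")
        if int(self.replicates) < 1:
            raise ParameterError("replicates must be >= 1")
        if self.S0 < 0:
            raise DomainError("S0 must be >= 0")

    def inoculum_of(self, name: str) -> float:
        return float(self.inoculum.get(name, 0.01))

    def to_dict(self) -> dict:
        return {"name": self.name, "members": list(self.members),
                "vessel": self.vessel, "S0": self.S0,
                "times": list(self.times), "replicates": int(self.replicates),
                "inoculum": dict(self.inoculum)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "CultureDesign":
        return cls(name=str(d["name"]), members=tuple(d["members"]),
                   vessel=str(d.get("vessel", "microplate")),
                   S0=float(d.get("S0", 10.0)),
                   times=tuple(d.get("times", MICROPLATE_TIMES)),
                   replicates=int(d.get("replicates", 2)),
                   inoculum=dict(d.get("inoculum", {})))


@dataclass(frozen=True)
class NoiseModel:
    """Observational noise settings; identical seed implies identical data."""

    qpcr_cv: float = 0.20
    conc_sd: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.qpcr_cv < 0 or self.conc_sd < 0:
            raise ParameterError("noise magnitudes must be >= 0")

    def to_dict(self) -> dict:
        return {"qpcr_cv": self.qpcr_cv, "conc_sd": self.conc_sd,
                "seed": int(self.seed)}


@dataclass(frozen=True)
class ObservedDataset:
    """Replicated noisy measurements tied to a culture design.

    ``records`` is a wide table with one row per (time, replicate):
    columns ``time_h``, ``replicate``, ``S``, ``A``, ``L`` (g/L) and
    ``X_<name>`` (genome copies/mL) per member.
    """

    design: CultureDesign
    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.records
        required = {"time_h", "replicate", "S", "A", "L"}
        missing = required - set(df.columns)
        if missing:
            raise ParameterError(f"records missing columns: {sorted(missing)}")
        grid = set(self.design.times)
        if not set(df["time_h"].tolist()) <= grid:
            raise ParameterError("record times must belong to the design grid")
        values = df[self.value_columns()].to_numpy(dtype=float)
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise DomainError("measured values must be finite and >= 0")

    def species_columns(self) -> list:
        return [f"X_{m}" for m in self.design.members]

    def value_columns(self) -> list:
        return self.species_columns() + ["S", "A", "L"]

    def to_tidy(self) -> pd.DataFrame:
        """Long form: one row per time x replicate x measurement."""
        return self.records.melt(
            id_vars=["time_h", "replicate"], value_vars=self.value_columns(),
            var_name="observable", value_name="value")

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame, design: CultureDesign,
                  provenance: dict | None = None) -> "ObservedDataset":
        wide = tidy.pivot_table(index=["time_h", "replicate"],
                                columns="observable", values="value").reset_index()
        wide.columns.name = None
        cols = ["time_h", "replicate"] + [f"X_{m}" for m in design.members] + ["S", "A", "L"]
        return cls(design=design, records=wide[cols], provenance=provenance or {})


def design_model(design: CultureDesign,
                 library: Mapping[str, SpeciesParams] | None = None,
                 interactions: InteractionMatrix | None = None) -> ConsortiumModel:
    """Assemble the consortium model matching a culture design."""
    library = library if library is not None else reference_species()
    missing = [m for m in design.members if m not in library]
    if missing:
        raise ParameterError(f"library lacks species: {missing}")
    species = tuple(library[m] for m in design.members)
    if interactions is not None and len(design.members) > 1:
        interactions = interactions.submatrix(design.members)
    else:
        interactions = None
    x0 = tuple(design.inoculum_of(m) for m in design.members)
    return ConsortiumModel(species=species, interactions=interactions,
                           S0=design.S0, X0=x0)


def generate_dataset(model: ConsortiumModel, design: CultureDesign,
                     noise: NoiseModel,
                     calibrations: Mapping[str, QpcrCalibration] | None = None,
                     rtol: float = 1e-8, atol: float = 1e-10) -> ObservedDataset:
    """Simulate the design and emit a noisy replicated dataset.

    With zero noise the dataset equals the simulation sampled at the design
    times. Lognormal factors are mean-corrected so the expectation of each
    copy-count observable equals the noiseless value.
    """
    if not set(design.members) <= set(model.names):
        raise ParameterError("model species must cover design members")
    calibrations = calibrations or reference_calibrations()
    traj = simulate(model, design.times, rtol=rtol, atol=atol)
    rng = np.random.default_rng(noise.seed)

    sigma = math.sqrt(math.log1p(noise.qpcr_cv ** 2))
    rows = []
    for rep in range(1, design.replicates + 1):
        for k, tk in enumerate(design.times):
            row = {"time_h": tk, "replicate": rep}
            for m in design.members:
                copies = float(biomass_to_copies(traj.Xm(m)[k], calibrations[m]))
                if sigma > 0:
                    copies *= math.exp(rng.normal(0.0, sigma) - 0.5 * sigma ** 2)
                row[f"X_{m}"] = copies
            for col, val in (("S", traj.S[k]), ("A", traj.A[k]), ("L", traj.L[k])):
                v = float(val)
                if noise.conc_sd > 0:
                    v = max(v + rng.normal(0.0, noise.conc_sd), 0.0)
                row[col] = v
            rows.append(row)
    records = pd.DataFrame(rows)
    provenance = {"model": model.to_dict(), "noise": noise.to_dict(),
                  "calibrations": {m: calibrations[m].to_dict() for m in design.members}}
    return ObservedDataset(design=design, records=records, provenance=provenance)


def scenario_catalog(S0: float = 10.0) -> dict[str, CultureDesign]:
    """Catalog of the 12 experimental designs: 4 mono-cultures, 6 paired
    co-cultures, the four-species microplate run and the four-species
    bioreactor run.

    Inocula encode the reported initial asymmetries: Ec starts five-fold
    higher and Bv five-fold lower than the 0.01 g/L default.
    """
    inocula = {m: reference_inoculum(m) for m in SPECIES_ORDER}
    designs: dict[str, CultureDesign] = {}
    for m in SPECIES_ORDER:
        designs[f"mono-{m}"] = CultureDesign(
            name=f"mono-{m}", members=(m,), S0=S0,
            inoculum={m: inocula[m]})
    for i, a in enumerate(SPECIES_ORDER):
        for b in SPECIES_ORDER[i + 1:]:
            designs[f"pair-{a}{b}"] = CultureDesign(
                name=f"pair-{a}{b}", members=(a, b), S0=S0,
                inoculum={a: inocula[a], b: inocula[b]})
    designs["all-microplate"] = CultureDesign(
        name="all-microplate", members=SPECIES_ORDER, S0=S0, inoculum=inocula)
    designs["all-bioreactor"] = CultureDesign(
        name="all-bioreactor", members=SPECIES_ORDER, vessel="bioreactor",
        S0=S0, times=BIOREACTOR_TIMES, replicates=4, inoculum=inocula)
    return designs
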