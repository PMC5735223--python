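"""Packaged reference parameter library for the four-species consortium.

The library bundles the pairwise interaction estimates with documented
default kinetic slots, inoculum presets (higher initial Ec, much lower
initial Bv) and per-species qPCR calibrations, so every scenario in the
package can run out of the box.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

from .model_core import (
    ConsortiumModel,
    InteractionMatrix,
    QpcrCalibration,
    SpeciesParams,
)

__all__ = [
    "SPECIES_ORDER",
    "reference_library",
    "reference_species",
    "reference_interactions",
    "reference_calibrations",
    "reference_inoculum",
    "reference_model",
]

SPECIES_ORDER = ("Bi", "Bv", "Ec", "La")


@lru_cache(maxsize=1)
def _raw() -> dict:
    path = resources.files("crossfeed").joinpath("data/reference_params.json")
    return json.loads(path.read_text())


def reference_library() -> dict:
    """Full raw library document (species, interactions, inocula, calibrations)."""
    return json.loads(json.dumps(_raw()))  # defensive copy


def reference_species() -> dict[str, SpeciesParams]:
    return {name: SpeciesParams.from_dict(d)
            for name, d in _raw()["species"].items()}


def reference_interactions() -> InteractionMatrix:
    return InteractionMatrix.from_dict(_raw()["interactions"])


def reference_calibrations() -> dict[str, QpcrCalibration]:
    return {name: QpcrCalibration.from_dict(d)
            for name, d in _raw()["calibrations"].items()}


def reference_inoculum(name: str) -> float:
    inoc = _raw()["inoculum_g_per_l"]
    return float(inoc["overrides"].get(name, inoc["default"]))


def reference_model(members=SPECIES_ORDER, S0: float = 10.0,
                    inoculum: dict | None = None) -> ConsortiumModel:
    """Build a :class:`ConsortiumModel` for a subset of the reference species.

    ``inoculum`` overrides the preset per-species initial biomass (g/L).
    Mono-cultures carry no interaction matrix; larger models carry the
    reference submatrix restricted to the members.
    """
    members = tuple(members)
    lib = reference_species()
    unknown = [m for m in members if m not in lib]
    if unknown:
        raise KeyError(f"unknown species: {unknown}")
    species = tuple(lib[m] for m in members)
    inter = reference_interactions().submatrix(members) if len(members) > 1 else None
    x0 = tuple((inoculum or {}).get(m, reference_inoculum(m)) for m in members)
    return ConsortiumModel(species=species, interactions=inter, S0=S0, X0=x0)
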