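"""Kinetic core of the consortium model.

The model describes batch growth of up to N bacterial species on a single
primary carbohydrate substrate S, with two fermentation acids (acetate A and
lactate L) acting simultaneously as inhibitory products, cross-feeding
substrates, and carriers of pairwise interaction effects.

State vector layout (dimension ``3 + 2N``)::

    [S, A, L, X_1, X_1m, ..., X_N, X_Nm]

where ``X_i`` is live biomass and ``X_im`` is the measured (cumulative)
biomass of species i, all in g/L. Measured biomass integrates gross growth
only, so it never decreases: DNA from dead cells is still detected by qPCR.

Growth law (per species i)::

    mu_i = mu_max * S/(K_s+S) * I_a/(I_a+A) * I_l/(I_l+L)
           * prod_j clamp(1 - X_j/ef_ji, 0, cap)        for t >= t_lag
    mu_i = 0                                            for t <  t_lag

Secondary (acid) uptake channels are plain Monod terms repressed by the
primary substrate through ``K_rep/(K_rep + S)``, so acids are consumed only
once the preferred carbon source runs low.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "AVOGADRO",
    "BP_GRAMS_PER_MOL",
    "PARAM_SLOTS",
    "DEFAULT_EF_LIMIT",
    "DEFAULT_EF_MIN",
    "INTERACTION_CAP",
    "DomainError",
    "ParameterError",
    "SimulationError",
    "Capabilities",
    "SpeciesParams",
    "InteractionMatrix",
    "ConsortiumModel",
    "Trajectory",
    "QpcrCalibration",
    "specific_growth_rate",
    "interaction_multiplier",
    "build_rhs",
    "simulate",
    "qpcr_copies_per_ml",
    "biomass_to_copies",
    "copies_to_biomass",
    "percent_abundance",
]

AVOGADRO = 6.02214076e23
#: average molar mass of one DNA base pair (g/mol), standard qPCR conversion
BP_GRAMS_PER_MOL = 660.0

#: canonical, documented order of the 17 numeric kinetic slots
PARAM_SLOTS = (
    "mu_max", "K_s", "Y_sx", "Y_a", "Y_l", "I_a", "I_l", "k_d", "t_lag",
    "mu_maxA", "K_sA", "Y_sxA", "mu_maxL", "K_sL", "Y_sxL", "K_rep", "m_s",
)

DEFAULT_EF_LIMIT = 100.0
DEFAULT_EF_MIN = 0.01
#: upper clamp of the interaction multiplier; prevents unbounded mutualism
INTERACTION_CAP = 2.0


class DomainError(ValueError):
    """A physical quantity (concentration, time) is outside its domain."""


class ParameterError(ValueError):
    """A model parameter violates its invariant."""


class SimulationError(RuntimeError):
    """Integration failed; ``last_time`` is the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last valid time: {last_time:g} h)")
        self.last_time = last_time


@dataclass(frozen=True)
class Capabilities:
    """Metabolic capability flags of one species."""

    produces_acetate: bool = False
    produces_lactate: bool = False
    consumes_acetate: bool = False
    consumes_lactate: bool = False

    def to_dict(self) -> dict:
        return {
            "produces_acetate": self.produces_acetate,
            "produces_lactate": self.produces_lactate,
            "consumes_acetate": self.consumes_acetate,
            "consumes_lactate": self.consumes_lactate,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Capabilities":
        return cls(**{k: bool(d.get(k, False)) for k in (
            "produces_acetate", "produces_lactate",
            "consumes_acetate", "consumes_lactate")})


@dataclass(frozen=True)
class SpeciesParams:
    """The 17-slot kinetic parameter vector of one organism.

    Slots whose capability flag is off are forced to zero on construction,
    so a parameter vector is always consistent with its capabilities.
    """

    name: str
    mu_max: float
    K_s: float
    Y_sx: float
    Y_a: float = 0.0
    Y_l: float = 0.0
    I_a: float = 10.0
    I_l: float = 10.0
    k_d: float = 0.0
    t_lag: float = 0.0
    mu_maxA: float = 0.0
    K_sA: float = 0.5
    Y_sxA: float = 0.0
    mu_maxL: float = 0.0
    K_sL: float = 0.5
    Y_sxL: float = 0.0
    K_rep: float = 0.05
    m_s: float = 0.0
    capabilities: Capabilities = field(default_factory=Capabilities)

    def __post_init__(self):
        caps = self.capabilities
        if not caps.produces_acetate:
            object.__setattr__(self, "Y_a", 0.0)
        if not caps.produces_lactate:
            object.__setattr__(self, "Y_l", 0.0)
        if not caps.consumes_acetate:
            object.__setattr__(self, "mu_maxA", 0.0)
            object.__setattr__(self, "Y_sxA", 0.0)
        if not caps.consumes_lactate:
            object.__setattr__(self, "mu_maxL", 0.0)
            object.__setattr__(self, "Y_sxL", 0.0)
        self._validate()

    def _validate(self):
        for slot in PARAM_SLOTS:
            v = getattr(self, slot)
            if not math.isfinite(v) or v < 0:
                raise ParameterError(f"{self.name}: {slot}={v!r} must be finite and >= 0")
        for slot in ("K_s", "I_a", "I_l", "K_rep", "K_sA", "K_sL"):
            if getattr(self, slot) <= 0:
                raise ParameterError(f"{self.name}: {slot} must be > 0")
        if not (0.0 < self.Y_sx <= 1.0):
            raise ParameterError(f"{self.name}: Y_sx must be in (0, 1]")
        if self.Y_a + self.Y_l > 1.0 + 1e-12:
            raise ParameterError(
                f"{self.name}: Y_a + Y_l = {self.Y_a + self.Y_l:g} exceeds 1 "
                "(product mass cannot exceed substrate consumed)")
        caps = self.capabilities
        if caps.consumes_acetate and self.Y_sxA <= 0:
            raise ParameterError(f"{self.name}: consumes_acetate requires Y_sxA > 0")
        if caps.consumes_lactate and self.Y_sxL <= 0:
            raise ParameterError(f"{self.name}: consumes_lactate requires Y_sxL > 0")
        if self.Y_sxA > 1.0 or self.Y_sxL > 1.0:
            raise ParameterError(f"{self.name}: secondary biomass yields must be <= 1")

    # -- serialization -----------------------------------------------------

    def to_vector(self) -> np.ndarray:
        """The 17 numeric slots in :data:`PARAM_SLOTS` order."""
        return np.array([getattr(self, s) for s in PARAM_SLOTS], dtype=float)

    @classmethod
    def from_vector(cls, name: str, vec: Sequence[float],
                    capabilities: Capabilities) -> "SpeciesParams":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(PARAM_SLOTS),):
            raise ParameterError(f"expected {len(PARAM_SLOTS)} slots, got {vec.shape}")
        return cls(name=name, capabilities=capabilities,
                   **dict(zip(PARAM_SLOTS, vec.tolist())))

    def to_dict(self) -> dict:
        d = {"name": self.name}
        d.update({s: getattr(self, s) for s in PARAM_SLOTS})
        d["capabilities"] = self.capabilities.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SpeciesParams":
        caps = Capabilities.from_dict(d.get("capabilities", {}))
        kwargs = {s: float(d[s]) for s in PARAM_SLOTS if s in d}
        return cls(name=str(d["name"]), capabilities=caps, **kwargs)

    def with_values(self, **kwargs) -> "SpeciesParams":
        """Copy with some slots replaced (capability flags re-applied)."""
        return replace(self, **kwargs)


class InteractionMatrix:
    """Pairwise interaction parameters ``ef_ji``.

    ``ef[i, j]`` is the effect of column-organism *j* on row-organism *i*'s
    growth rate, in biomass (g/L) units. Negative values promote growth,
    positive values inhibit it; magnitudes near zero are strong effects and
    magnitudes at the bound are effectively null. The diagonal is undefined
    (stored as NaN) and zero is illegal anywhere (it divides a biomass).
    """

    def __init__(self, species: Sequence[str], ef,
                 ef_limit: float = DEFAULT_EF_LIMIT,
                 ef_min: float = DEFAULT_EF_MIN):
        self.species = tuple(str(s) for s in species)
        n = len(self.species)
        if n < 2:
            raise ParameterError("interaction matrix needs at least 2 species")
        if ef_min <= 0 or ef_limit <= ef_min:
            raise ParameterError("require 0 < ef_min < ef_limit")
        self.ef_limit = float(ef_limit)
        self.ef_min = float(ef_min)
        mat = np.array(ef, dtype=float)
        if mat.shape != (n, n):
            raise ParameterError(f"ef must be {n}x{n}, got {mat.shape}")
        np.fill_diagonal(mat, np.nan)
        off = mat[~np.eye(n, dtype=bool)]
        if not np.all(np.isfinite(off)):
            raise ParameterError("off-diagonal ef entries must be finite")
        mag = np.abs(off)
        if np.any(mag <= self.ef_min * (1 - 1e-12)) or np.any(mag > self.ef_limit * (1 + 1e-12)):
            raise ParameterError(
                f"|ef| must lie in ({self.ef_min:g}, {self.ef_limit:g}]")
        self.ef = mat

    def get(self, affected: str, affecting: str) -> float:
        i = self.species.index(affected)
        j = self.species.index(affecting)
        if i == j:
            raise ParameterError("diagonal interaction is undefined")
        return float(self.ef[i, j])

    def with_entry(self, affected: str, affecting: str, value: float) -> "InteractionMatrix":
        i = self.species.index(affected)
        j = self.species.index(affecting)
        mat = self.ef.copy()
        mat[i, j] = value
        return InteractionMatrix(self.species, mat, self.ef_limit, self.ef_min)

    def submatrix(self, members: Sequence[str]) -> "InteractionMatrix":
        idx = [self.species.index(m) for m in members]
        return InteractionMatrix([self.species[i] for i in idx],
                                 self.ef[np.ix_(idx, idx)],
                                 self.ef_limit, self.ef_min)

    def to_dict(self) -> dict:
        mat = [[None if i == j else float(self.ef[i, j])
                for j in range(len(self.species))] for i in range(len(self.species))]
        return {"order": list(self.species), "ef": mat,
                "ef_limit": self.ef_limit, "ef_min": self.ef_min}

    @classmethod
    def from_dict(cls, d: Mapping) -> "InteractionMatrix":
        order = list(d["order"])
        mat = np.array([[np.nan if v is None else float(v) for v in row]
                        for row in d["ef"]])
        return cls(order, mat, float(d.get("ef_limit", DEFAULT_EF_LIMIT)),
                   float(d.get("ef_min", DEFAULT_EF_MIN)))

    def __eq__(self, other):
        return (isinstance(other, InteractionMatrix)
                and self.species == other.species
                and np.allclose(self.ef, other.ef, equal_nan=True)
                and self.ef_limit == other.ef_limit
                and self.ef_min == other.ef_min)

    def __repr__(self):
        return f"InteractionMatrix(species={self.species}, ef={self.ef!r})"


@dataclass(frozen=True)
class ConsortiumModel:
    """Species, interactions and initial environment of one batch culture."""

    species: tuple
    S0: float
    interactions: InteractionMatrix | None = None
    A0: float = 0.0
    L0: float = 0.0
    X0: tuple = ()
    X0m: tuple | None = None

    def __post_init__(self):
        sp = tuple(self.species)
        object.__setattr__(self, "species", sp)
        if not sp:
            raise ParameterError("model needs at least one species")
        names = [p.name for p in sp]
        if len(set(names)) != len(names):
            raise ParameterError("duplicate species names")
        x0 = tuple(float(v) for v in (self.X0 or (0.0,) * len(sp)))
        if len(x0) != len(sp):
            raise ParameterError("X0 length must match species")
        object.__setattr__(self, "X0", x0)
        x0m = self.X0m if self.X0m is not None else x0
        x0m = tuple(float(v) for v in x0m)
        if len(x0m) != len(sp):
            raise ParameterError("X0m length must match species")
        object.__setattr__(self, "X0m", x0m)
        for v in (self.S0, self.A0, self.L0, *x0, *x0m):
            if not math.isfinite(v) or v < 0:
                raise DomainError("initial values must be finite and >= 0")
        if self.interactions is not None:
            if tuple(self.interactions.species) != tuple(names):
                raise ParameterError(
                    "interaction matrix order must match model species order")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def state_dim(self) -> int:
        return 3 + 2 * self.n_species

    @property
    def names(self) -> tuple:
        return tuple(p.name for p in self.species)

    def initial_state(self) -> np.ndarray:
        y0 = np.empty(self.state_dim)
        y0[:3] = (self.S0, self.A0, self.L0)
        for i in range(self.n_species):
            y0[3 + 2 * i] = self.X0[i]
            y0[4 + 2 * i] = self.X0m[i]
        return y0

    def state_names(self) -> tuple:
        out = ["S", "A", "L"]
        for p in self.species:
            out += [f"X_{p.name}", f"Xm_{p.name}"]
        return tuple(out)

    def replace_species(self, name: str, params: SpeciesParams) -> "ConsortiumModel":
        if params.name != name:
            raise ParameterError("replacement must keep the species name")
        sp = tuple(params if p.name == name else p for p in self.species)
        if name not in [p.name for p in self.species]:
            raise ParameterError(f"unknown species {name!r}")
        return replace(self, species=sp)

    def to_dict(self) -> dict:
        return {
            "species": [p.to_dict() for p in self.species],
            "interactions": None if self.interactions is None else self.interactions.to_dict(),
            "S0": self.S0, "A0": self.A0, "L0": self.L0,
            "X0": list(self.X0), "X0m": list(self.X0m),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ConsortiumModel":
        inter = d.get("interactions")
        return cls(
            species=tuple(SpeciesParams.from_dict(s) for s in d["species"]),
            interactions=None if inter is None else InteractionMatrix.from_dict(inter),
            S0=float(d["S0"]), A0=float(d.get("A0", 0.0)), L0=float(d.get("L0", 0.0)),
            X0=tuple(d.get("X0", ())), X0m=tuple(d["X0m"]) if d.get("X0m") else None,
        )


@dataclass(frozen=True)
class Trajectory:
    """Solution of the consortium ODE system on a time grid."""

    times: np.ndarray
    states: np.ndarray
    species: tuple

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.states, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise DomainError("times must be strictly increasing")
        if y.shape != (t.size, 3 + 2 * len(self.species)):
            raise DomainError("states shape does not match times/species")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", y)
        object.__setattr__(self, "species", tuple(self.species))

    @property
    def S(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def A(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def L(self) -> np.ndarray:
        return self.states[:, 2]

    def _idx(self, name: str) -> int:
        return self.species.index(name)

    def X(self, name: str) -> np.ndarray:
        return self.states[:, 3 + 2 * self._idx(name)]

    def Xm(self, name: str) -> np.ndarray:
        return self.states[:, 4 + 2 * self._idx(name)]

    def state_names(self) -> tuple:
        out = ["S", "A", "L"]
        for n in self.species:
            out += [f"X_{n}", f"Xm_{n}"]
        return tuple(out)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.state_names()))
        df.insert(0, "time_h", self.times)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Trajectory":
        species = tuple(c[2:] for c in df.columns if c.startswith("X_"))
        cols = ["S", "A", "L"]
        for n in species:
            cols += [f"X_{n}", f"Xm_{n}"]
        return cls(times=df["time_h"].to_numpy(),
                   states=df[cols].to_numpy(), species=species)


@dataclass(frozen=True)
class QpcrCalibration:
    """Constants converting DNA mass and model biomass to genome copies."""

    genome_size: float
    copies_16s: int = 1
    cells_per_gram: float = 1e12

    def __post_init__(self):
        if self.genome_size <= 0:
            raise ParameterError("genome_size must be > 0")
        if int(self.copies_16s) < 1:
            raise ParameterError("copies_16s must be an integer >= 1")
        if self.cells_per_gram <= 0:
            raise ParameterError("cells_per_gram must be > 0")

    def to_dict(self) -> dict:
        return {"genome_size": self.genome_size, "copies_16s": int(self.copies_16s),
                "cells_per_gram": self.cells_per_gram}

    @classmethod
    def from_dict(cls, d: Mapping) -> "QpcrCalibration":
        return cls(float(d["genome_size"]), int(d.get("copies_16s", 1)),
                   float(d.get("cells_per_gram", 1e12)))


# ---------------------------------------------------------------------------
# growth laws
# ---------------------------------------------------------------------------

def interaction_multiplier(ef_ji: float, x_j: float,
                           cap: float = INTERACTION_CAP) -> float:
    """Dimensionless factor ``clamp(1 - X_j/ef_ji, 0, cap)``.

    Positive ``ef`` inhibits (factor < 1 once X_j is comparable to ef),
    negative ``ef`` promotes (factor > 1, clamped at ``cap``), and
    ``|ef|`` at the bound leaves growth essentially untouched.
    """
    if ef_ji == 0:
        raise ParameterError("interaction parameter ef must be nonzero")
    if x_j < 0:
        raise DomainError("neighbor biomass must be >= 0")
    f = 1.0 - x_j / ef_ji
    if f < 0.0:
        return 0.0
    return min(f, cap)


def specific_growth_rate(p: SpeciesParams, S: float, A: float, L: float,
                         t: float, neighbor_terms: Sequence[tuple] = ()) -> float:
    """Specific growth rate (1/h) on the primary substrate.

    Monod uptake with non-competitive product inhibition by both acids and
    multiplicative pairwise interaction factors; zero before the lag time.
    """
    if S < 0 or A < 0 or L < 0:
        raise DomainError("concentrations must be >= 0")
    if t < 0:
        raise DomainError("time must be >= 0")
    if t < p.t_lag or S == 0:
        return 0.0
    mu = (p.mu_max * S / (p.K_s + S)
          * p.I_a / (p.I_a + A)
          * p.I_l / (p.I_l + L))
    for ef_ji, x_j in neighbor_terms:
        mu *= interaction_multiplier(ef_ji, x_j)
        if mu == 0.0:
            break
    return mu


def build_rhs(model: ConsortiumModel,
              growth_law: Callable | None = None) -> Callable:
    """Assemble the time-derivative function of the full state vector.

    Returns ``f(t, y) -> dy`` with ``y = [S, A, L, X_1, X_1m, ...]``.
    ``growth_law`` may replace the built-in primary growth law; it must have
    the signature of :func:`specific_growth_rate`.
    """
    sp = model.species
    n = len(sp)
    P = {s: np.array([getattr(p, s) for p in sp]) for s in PARAM_SLOTS}
    inter = model.interactions
    neighbors: list = []
    for i in range(n):
        row = []
        if inter is not None:
            for j in range(n):
                if j != i:
                    row.append((j, float(inter.ef[i, j])))
        neighbors.append(tuple(row))

    mu_max, K_s, Y_sx = P["mu_max"], P["K_s"], P["Y_sx"]
    Y_a, Y_l, I_a, I_l = P["Y_a"], P["Y_l"], P["I_a"], P["I_l"]
    k_d, t_lag, m_s, K_rep = P["k_d"], P["t_lag"], P["m_s"], P["K_rep"]
    mu_maxA, K_sA, Y_sxA = P["mu_maxA"], P["K_sA"], P["Y_sxA"]
    mu_maxL, K_sL, Y_sxL = P["mu_maxL"], P["K_sL"], P["Y_sxL"]

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        S = y[0] if y[0] > 0.0 else 0.0
        A = y[1] if y[1] > 0.0 else 0.0
        L = y[2] if y[2] > 0.0 else 0.0
        X = np.maximum(y[3::2], 0.0)
        d = np.zeros_like(y)
        dS = dA = dL = 0.0
        for i in range(n):
            Xi = X[i]
            mu = muA = muL = 0.0
            if t >= t_lag[i]:
                if growth_law is None:
                    if S > 0.0:
                        mu = (mu_max[i] * S / (K_s[i] + S)
                              * I_a[i] / (I_a[i] + A)
                              * I_l[i] / (I_l[i] + L))
                        for j, ef in neighbors[i]:
                            f = 1.0 - X[j] / ef
                            if f <= 0.0:
                                mu = 0.0
                                break
                            mu *= f if f < INTERACTION_CAP else INTERACTION_CAP
                else:
                    terms = [(ef, X[j]) for j, ef in neighbors[i]]
                    mu = growth_law(sp[i], S, A, L, t, terms)
                rep = K_rep[i] / (K_rep[i] + S)
                if mu_maxA[i] > 0.0 and A > 0.0:
                    muA = mu_maxA[i] * A / (K_sA[i] + A) * rep
                if mu_maxL[i] > 0.0 and L > 0.0:
                    muL = mu_maxL[i] * L / (K_sL[i] + L) * rep
            g = mu + muA + muL
            d[3 + 2 * i] = (g - k_d[i]) * X[i] if y[3 + 2 * i] > 0.0 else 0.0
            d[4 + 2 * i] = g * Xi
            if S > 0.0:
                dS -= (mu / Y_sx[i] + m_s[i]) * Xi
            if mu > 0.0:
                q = mu / Y_sx[i] * Xi
                dA += Y_a[i] * q
                dL += Y_l[i] * q
            if muA > 0.0:
                dA -= muA / Y_sxA[i] * Xi
            if muL > 0.0:
                dL -= muL / Y_sxL[i] * Xi
        d[0] = dS
        d[1] = dA
        d[2] = dL
        return d

    return rhs


def simulate(model: ConsortiumModel, t_grid: Sequence[float],
             rtol: float = 1e-8, atol: float = 1e-10,
             method: str = "LSODA",
             growth_law: Callable | None = None) -> Trajectory:
    """Integrate the model over ``t_grid`` (hours, strictly increasing, from 0).

    Integration is restarted at every species lag time so the hard growth
    switch never sits inside an adaptive step.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise DomainError("t_grid must be strictly increasing with >= 2 points")
    if t[0] != 0.0:
        raise DomainError("t_grid must start at 0")
    rhs = build_rhs(model, growth_law=growth_law)
    t_end = float(t[-1])
    lags = sorted({float(p.t_lag) for p in model.species if 0.0 < p.t_lag < t_end})
    edges = [0.0, *lags, t_end]

    y = model.initial_state()
    out = np.empty((t.size, y.size))
    out[0] = y
    for a, b in zip(edges[:-1], edges[1:]):
        inside = t[(t > a) & (t <= b)]
        t_eval = np.unique(np.concatenate([inside, [b]]))
        sol = solve_ivp(rhs, (a, b), y, method=method, t_eval=t_eval,
                        rtol=rtol, atol=atol)
        if not sol.success:
            last = float(sol.t[-1]) if sol.t.size else a
            raise SimulationError(f"integrator failed: {sol.message}", last)
        for k, tk in enumerate(sol.t):
            hits = np.nonzero(np.isclose(t, tk, rtol=0, atol=1e-12))[0]
            for h in hits:
                out[h] = sol.y[:, k]
        y = sol.y[:, -1]
    np.clip(out, 0.0, None, out=out)
    return Trajectory(times=t, states=out, species=model.names)


# ---------------------------------------------------------------------------
# observation operators
# ---------------------------------------------------------------------------

def qpcr_copies_per_ml(dna_conc: float, cal: QpcrCalibration) -> float:
    """Genome copies per mL from a DNA concentration in g/mL."""
    if dna_conc < 0:
        raise DomainError("DNA concentration must be >= 0")
    return AVOGADRO * dna_conc * cal.copies_16s / (cal.genome_size * BP_GRAMS_PER_MOL)


def biomass_to_copies(x_g_per_l: np.ndarray | float, cal: QpcrCalibration):
    """Model biomass (g/L) to observed genome copies/mL."""
    return np.asarray(x_g_per_l, dtype=float) * cal.cells_per_gram


def copies_to_biomass(copies_per_ml: np.ndarray | float, cal: QpcrCalibration):
    """Observed genome copies/mL back to model biomass (g/L)."""
    return np.asarray(copies_per_ml, dtype=float) / cal.cells_per_gram


def percent_abundance(traj: Trajectory,
                      calibrations: Mapping[str, QpcrCalibration] | QpcrCalibration,
                      ) -> pd.DataFrame:
    """Per-time percentage composition from measured biomass in copy units.

    Rows sum to 100. A time point where every species' measured biomass is
    zero is undefined and returned as a row of NaN rather than 0/0.
    """
    if isinstance(calibrations, QpcrCalibration):
        calibrations = {n: calibrations for n in traj.species}
    copies = np.column_stack([
        biomass_to_copies(traj.Xm(n), calibrations[n]) for n in traj.species])
    total = copies.sum(axis=1)
    pct = np.full_like(copies, np.nan)
    ok = total > 0
    pct[ok] = 100.0 * copies[ok] / total[ok, None]
    df = pd.DataFrame(pct, columns=list(traj.species))
    df.insert(0, "time_h", traj.times)
    return df
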