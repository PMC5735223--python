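"""Practical identifiability and local sensitivity analyses.

Identifiability is judged from the parameter correlation matrix derived
from the residual Jacobian at a fit: covariance proportional to the
pseudo-inverse of J'J, correlations near +/-1 meaning the data constrain
only combinations of the involved parameters.

Sensitivity comes in two flavors: a time-averaged normalized local
derivative of every state with respect to every kinetic slot, and
Monte-Carlo perturbation bands obtained by repeatedly re-simulating with a
parameter drawn uniformly within a relative fraction of its value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import ConfigurationError, FitProblem, FitResult
from .model_core import (
    ConsortiumModel,
    PARAM_SLOTS,
    SimulationError,
    simulate,
)

__all__ = [
    "UnderdeterminedError",
    "CorrelationReport",
    "SensitivityReport",
    "parameter_correlation",
    "average_sensitivity",
    "perturbation_bands",
]


class UnderdeterminedError(ValueError):
    """Fewer residuals than free parameters."""


@dataclass(frozen=True)
class CorrelationReport:
    """Parameter correlation matrix with flagged high-correlation pairs."""

    parameters: tuple
    matrix: np.ndarray
    threshold: float
    flagged: tuple
    rank: int

    def __post_init__(self):
        if not (0.0 < self.threshold < 1.0):
            raise ConfigurationError("threshold must be in (0, 1)")
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T, atol=1e-10):
            raise ConfigurationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-8):
            raise ConfigurationError("correlation matrix must have unit diagonal")
        object.__setattr__(self, "matrix", m)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.parameters),
                            columns=list(self.parameters))


@dataclass(frozen=True)
class SensitivityReport:
    """Average sensitivities and/or Monte-Carlo perturbation bands."""

    settings: dict
    average: pd.DataFrame | None = None
    band_mean: pd.DataFrame | None = None
    band_sd: pd.DataFrame | None = None
    dropped_iterations: int = 0

    def __post_init__(self):
        if self.band_sd is not None:
            sd = self.band_sd.drop(columns=["time_h"], errors="ignore").to_numpy()
            if np.any(sd < 0):
                raise ConfigurationError("band SD must be >= 0")


def _central_jacobian(residual_fn, x: np.ndarray, rel_step: float,
                      abs_floor: float) -> np.ndarray:
    r0 = residual_fn(x)
    J = np.empty((r0.size, x.size))
    for k in range(x.size):
        h = max(rel_step * abs(x[k]), abs_floor)
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        xm[k] -= h
        J[:, k] = (residual_fn(xp) - residual_fn(xm)) / (2.0 * h)
    return J


def parameter_correlation(fit: FitResult, problem: FitProblem,
                          threshold: float = 0.95, rel_step: float = 0.01,
                          abs_floor: float = 1e-8) -> CorrelationReport:
    """Correlation matrix of the free parameters at a fit.

    Rank deficiency of J'J is reported, not fatal: the covariance uses the
    pseudo-inverse, and parameters with no measurable effect get zero
    correlation rather than 0/0.
    """
    names = list(problem.free_names)
    x = fit.vector(names)
    r0 = problem.residual_vector(x)
    if r0.size < len(names):
        raise UnderdeterminedError(
            f"{r0.size} residuals cannot constrain {len(names)} parameters")
    J = _central_jacobian(problem.residual_vector, x, rel_step, abs_floor)
    jtj = J.T @ J
    rank = int(np.linalg.matrix_rank(jtj))
    cov = np.linalg.pinv(jtj)  # sigma^2 cancels in the correlations
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(sd, sd)
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    flagged = tuple(
        (names[i], names[j], float(corr[i, j]))
        for i in range(len(names)) for j in range(i + 1, len(names))
        if abs(corr[i, j]) > threshold)
    return CorrelationReport(parameters=tuple(names), matrix=corr,
                             threshold=threshold, flagged=flagged, rank=rank)


def average_sensitivity(model: ConsortiumModel, t_grid: Sequence[float],
                        rel_step: float = 0.01, eps: float = 1e-6,
                        rtol: float = 1e-8, atol: float = 1e-10) -> pd.DataFrame:
    """Time-averaged normalized sensitivity of every state to every slot.

    Entry (p, k) is ``mean_t |dx_k/dp * p / max(|x_k(t)|, eps)|`` by central
    differences. Slots that are zero (disabled capabilities) and parameters
    of species with zero inoculum contribute exactly zero.
    """
    base = simulate(model, t_grid, rtol=rtol, atol=atol)
    scale = np.maximum(np.abs(base.states), eps)
    rows = {}
    for i, sp in enumerate(model.species):
        for slot in PARAM_SLOTS:
            p = float(getattr(sp, slot))
            key = f"{sp.name}.{slot}"
            if p == 0.0 or model.X0[i] == 0.0:
                rows[key] = np.zeros(model.state_dim)
                continue
            h = rel_step * p
            up = model.replace_species(sp.name, sp.with_values(**{slot: p + h}))
            dn = model.replace_species(sp.name, sp.with_values(**{slot: p - h}))
            yp = simulate(up, t_grid, rtol=rtol, atol=atol).states
            ym = simulate(dn, t_grid, rtol=rtol, atol=atol).states
            sens = np.abs((yp - ym) / (2.0 * h) * (p / scale))
            rows[key] = sens.mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(model.state_names()))


def perturbation_bands(model: ConsortiumModel, parameter: str,
                       fraction: float = 0.05, iterations: int = 5000,
                       seed: int = 0, t_grid: Sequence[float] | None = None,
                       rtol: float = 1e-8, atol: float = 1e-10) -> SensitivityReport:
    """Monte-Carlo bands from uniform relative perturbation of one parameter.

    Each iteration draws ``p' = p * (1 + U(-fraction, fraction))``,
    re-simulates, and the per-time mean and standard deviation across
    iterations are aggregated with Welford updates. Iterations producing
    non-finite states are dropped and counted.
    """
    if not (0.0 <= fraction <= 0.5):
        raise ConfigurationError("fraction must be in [0, 0.5]")
    if iterations < 1:
        raise ConfigurationError("iterations must be >= 1")
    sp_name, slot = parameter.split(".")
    if slot not in PARAM_SLOTS:
        raise ConfigurationError(f"unknown slot {slot!r}")
    sp = next((p for p in model.species if p.name == sp_name), None)
    if sp is None:
        raise ConfigurationError(f"unknown species {sp_name!r}")
    p0 = float(getattr(sp, slot))
    if t_grid is None:
        t_grid = np.linspace(0.0, 72.0, 73)
    rng = np.random.default_rng(seed)

    mean = None
    m2 = None
    n_ok = 0
    dropped = 0
    for _ in range(iterations):
        delta = rng.uniform(-fraction, fraction)
        pert = model.replace_species(sp_name, sp.with_values(**{slot: p0 * (1.0 + delta)}))
        try:
            y = simulate(pert, t_grid, rtol=rtol, atol=atol).states
        except SimulationError:
            dropped += 1
            continue
        if not np.all(np.isfinite(y)):
            dropped += 1
            continue
        n_ok += 1
        if mean is None:
            mean = y.copy()
            m2 = np.zeros_like(y)
        else:
            d = y - mean
            mean += d / n_ok
            m2 += d * (y - mean)
    if n_ok == 0:
        raise SimulationError("every perturbation iteration failed", 0.0)
    sd = np.sqrt(m2 / n_ok)
    cols = list(model.state_names())
    t = np.asarray(t_grid, dtype=float)
    band_mean = pd.DataFrame(mean, columns=cols)
    band_mean.insert(0, "time_h", t)
    band_sd = pd.DataFrame(sd, columns=cols)
    band_sd.insert(0, "time_h", t)
    settings = {"parameter": parameter, "fraction": fraction,
                "iterations": iterations, "seed": int(seed)}
    return SensitivityReport(settings=settings, band_mean=band_mean,
                             band_sd=band_sd, dropped_iterations=dropped)
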