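"""Calibration of kinetic and interaction parameters from observed datasets.

The objective is a max-normalized sum of squared residuals: for every
observable the residuals are divided by the largest observed magnitude of
that observable in its dataset, squared, summed over time and averaged over
replicates, so the error is invariant to the units each observable happens
to be recorded in.

Optimization follows a scatter-search scheme: Latin-hypercube
diversification, a reference set of best plus maximally diverse points,
pairwise linear combinations, and a local polish (trust-region least
squares on the residual vector, or Powell when only a scalar objective is
available), restarting with fresh diversification while evaluation budget
remains. The evaluation sequence for a given seed is independent of the
budget, so a larger budget can never return a worse objective.

Calibration is staged: mono-culture parameters are fitted first (or pinned),
then each paired co-culture fixes those values and fits only its two
interaction parameters.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize

from .model_core import (
    ConsortiumModel,
    DEFAULT_EF_LIMIT,
    DEFAULT_EF_MIN,
    InteractionMatrix,
    ParameterError,
    QpcrCalibration,
    SimulationError,
    SpeciesParams,
    copies_to_biomass,
    simulate,
)
from .reference import reference_calibrations
from .synthetic_data import CultureDesign, ObservedDataset, design_model

__all__ = [
    "PENALTY",
    "DEFAULT_SLOT_BOUNDS",
    "DEFAULT_FREE_MONO",
    "ConfigurationError",
    "CalibrationError",
    "FreeParam",
    "FitProblem",
    "FitResult",
    "fit_error",
    "normalized_sse",
    "minimize_scatter",
    "scatter_search",
    "profile_objective",
    "CalibrationConfig",
    "CalibrationResult",
    "staged_calibration",
]

log = logging.getLogger(__name__)

#: large finite objective returned when a candidate cannot be simulated
PENALTY = 1e9

#: default search bounds per kinetic slot
DEFAULT_SLOT_BOUNDS = {
    "mu_max": (0.01, 2.0),
    "K_s": (0.005, 5.0),
    "Y_sx": (0.01, 1.0),
    "Y_a": (0.0, 1.0),
    "Y_l": (0.0, 1.0),
    "I_a": (0.01, 50.0),
    "I_l": (0.01, 50.0),
    "k_d": (0.0, 0.5),
    "t_lag": (0.0, 12.0),
    "mu_maxA": (0.0, 1.0),
    "K_sA": (0.005, 5.0),
    "Y_sxA": (0.01, 1.0),
    "mu_maxL": (0.0, 1.0),
    "K_sL": (0.005, 5.0),
    "Y_sxL": (0.01, 1.0),
    "K_rep": (0.005, 1.0),
    "m_s": (0.0, 0.2),
}

#: canonical eight free slots per mono-culture fit
DEFAULT_FREE_MONO = ("mu_max", "K_s", "Y_sx", "Y_a", "Y_l", "I_a", "I_l", "t_lag")


class ConfigurationError(ValueError):
    """The fit problem or calibration configuration is inconsistent."""


class CalibrationError(ValueError):
    """Required datasets are missing from a staged calibration."""


@dataclass(frozen=True)
class FreeParam:
    """A named free parameter with finite bounds.

    Names address either a kinetic slot (``"Bi.mu_max"``) or an interaction
    entry ``"ef.<affected>.<affecting>"`` (``"ef.Bv.Ec"``).
    """

    name: str
    lower: float
    upper: float

    def __post_init__(self):
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ConfigurationError(f"{self.name}: bounds must be finite")
        if self.lower >= self.upper:
            raise ConfigurationError(f"{self.name}: lower must be < upper")


def _split_name(name: str) -> tuple:
    parts = name.split(".")
    if parts[0] == "ef":
        if len(parts) != 3:
            raise ConfigurationError(f"bad interaction name {name!r}")
        return ("ef", parts[1], parts[2])
    if len(parts) != 2:
        raise ConfigurationError(f"bad parameter name {name!r}")
    return ("slot", parts[0], parts[1])


def _snap_ef(value: float, ef_min: float = DEFAULT_EF_MIN) -> float:
    """Keep interaction magnitudes legal: push values in the illegal
    near-zero band out to just above ``ef_min`` (sign preserved)."""
    floor = ef_min * 1.01
    if abs(value) < floor:
        return floor if value >= 0 else -floor
    return value


def normalized_sse(obs: np.ndarray, sim: np.ndarray) -> float:
    """Max-normalized SSE of one observable: invariant to rescaling both
    ``obs`` and ``sim`` by a common factor."""
    obs = np.asarray(obs, dtype=float)
    sim = np.asarray(sim, dtype=float)
    norm = np.max(np.abs(obs))
    if norm == 0:
        return 0.0
    return float(np.sum(((sim - obs) / norm) ** 2))


@dataclass
class FitProblem:
    """Datasets plus the free/fixed parameterization of the model family."""

    datasets: tuple
    library: Mapping[str, SpeciesParams]
    free: tuple
    interactions: InteractionMatrix | None = None
    fixed: Mapping[str, float] = field(default_factory=dict)
    weights: Mapping[str, float] = field(default_factory=dict)
    calibrations: Mapping[str, QpcrCalibration] | None = None
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self):
        self.datasets = tuple(self.datasets)
        self.free = tuple(p if isinstance(p, FreeParam) else FreeParam(*p)
                          for p in self.free)
        names = [p.name for p in self.free]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate free parameter names")
        overlap = set(names) & set(self.fixed)
        if overlap:
            raise ConfigurationError(f"parameters both free and fixed: {sorted(overlap)}")
        for name in list(names) + list(self.fixed):
            _split_name(name)
        if self.calibrations is None:
            self.calibrations = reference_calibrations()

    # -- parameter plumbing ------------------------------------------------

    @property
    def free_names(self) -> tuple:
        return tuple(p.name for p in self.free)

    @property
    def bounds(self) -> tuple:
        return tuple((p.lower, p.upper) for p in self.free)

    def _materialize(self, values: Mapping[str, float]):
        """Library and interaction matrix with all overrides applied."""
        lib = dict(self.library)
        ef_entries: dict = {}
        for name, v in values.items():
            kind, a, b = _split_name(name)
            if kind == "slot":
                if a not in lib:
                    raise ConfigurationError(f"unknown species {a!r} in {name!r}")
                lib[a] = lib[a].with_values(**{b: float(v)})
            else:
                ef_entries[(a, b)] = _snap_ef(float(v))
        inter = self.interactions
        if ef_entries:
            involved = sorted({s for pair in ef_entries for s in pair})
            if inter is None:
                order = [m for m in lib if m in involved]
                n = len(order)
                mat = np.full((n, n), DEFAULT_EF_LIMIT)
                inter = InteractionMatrix(order, mat)
            mat = inter.ef.copy()
            for (a, b), v in ef_entries.items():
                mat[inter.species.index(a), inter.species.index(b)] = v
            inter = InteractionMatrix(inter.species, mat, inter.ef_limit, inter.ef_min)
        return lib, inter

    def models(self, x: Sequence[float]) -> list:
        values = dict(self.fixed)
        values.update(zip(self.free_names, np.asarray(x, dtype=float)))
        lib, inter = self._materialize(values)
        return [design_model(ds.design, lib, inter) for ds in self.datasets]

    # -- residuals ---------------------------------------------------------

    def _observable_blocks(self, ds: ObservedDataset):
        """(column, weight, obs matrix [rep x time] in model units, norm).

        Independent of the candidate, so computed once per dataset.
        """
        cache = getattr(self, "_block_cache", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_block_cache", cache)
        key = id(ds)
        if key in cache:
            return cache[key]
        blocks = []
        for col in ds.value_columns():
            w = float(self.weights.get(col, 1.0))
            if w == 0.0:
                continue
            piv = ds.records.pivot_table(index="replicate", columns="time_h",
                                         values=col)
            piv = piv.reindex(columns=list(ds.design.times))
            obs = piv.to_numpy(dtype=float)
            if col.startswith("X_"):
                obs = copies_to_biomass(obs, self.calibrations[col[2:]])
            norm = np.max(np.abs(obs))
            blocks.append((col, w, obs, norm))
        cache[key] = blocks
        return blocks

    def residual_vector(self, x: Sequence[float]) -> np.ndarray:
        """Weighted normalized residuals; squared sum equals :meth:`fit_error`."""
        parts = []
        for ds, model in zip(self.datasets, self.models(x)):
            traj = simulate(model, ds.design.times, rtol=self.rtol, atol=self.atol)
            sim = {"S": traj.S, "A": traj.A, "L": traj.L}
            for m in ds.design.members:
                sim[f"X_{m}"] = traj.Xm(m)
            for col, w, obs, norm in self._observable_blocks(ds):
                if norm == 0:
                    continue
                n_rep = obs.shape[0]
                r = (sim[col][None, :] - obs) / norm
                parts.append((np.sqrt(w / n_rep) * r).ravel())
        if not parts:
            raise ConfigurationError("no usable observables in datasets")
        return np.concatenate(parts)

    def residuals_by_observable(self, x: Sequence[float]) -> dict:
        out: dict = {}
        for ds, model in zip(self.datasets, self.models(x)):
            traj = simulate(model, ds.design.times, rtol=self.rtol, atol=self.atol)
            sim = {"S": traj.S, "A": traj.A, "L": traj.L}
            for m in ds.design.members:
                sim[f"X_{m}"] = traj.Xm(m)
            for col, w, obs, norm in self._observable_blocks(ds):
                if norm == 0:
                    continue
                key = f"{ds.design.name}:{col}"
                out[key] = ((sim[col][None, :] - obs) / norm).tolist()
        return out

    def fit_error(self, x: Sequence[float]) -> float:
        """Scalar objective; simulation failure maps to a large penalty."""
        try:
            r = self.residual_vector(x)
        except (SimulationError, ParameterError, FloatingPointError,
                ValueError, OverflowError) as exc:
            log.debug("candidate rejected: %s", exc)
            return PENALTY
        val = float(np.dot(r, r))
        return val if np.isfinite(val) else PENALTY


def fit_error(candidate: Sequence[float], problem: FitProblem) -> float:
    """Module-level alias of :meth:`FitProblem.fit_error`."""
    return problem.fit_error(candidate)


@dataclass(frozen=True)
class FitResult:
    """Outcome of one optimization run."""

    estimates: dict
    objective: float
    n_evaluations: int
    seed: int
    residuals: dict
    converged: bool
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.objective < 0:
            raise ConfigurationError("objective must be >= 0")

    def vector(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.estimates[n] for n in names], dtype=float)

    def to_dict(self) -> dict:
        return {"estimates": dict(self.estimates), "objective": self.objective,
                "n_evaluations": int(self.n_evaluations), "seed": int(self.seed),
                "residuals": self.residuals, "converged": bool(self.converged),
                "provenance": dict(self.provenance)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "FitResult":
        return cls(estimates=dict(d["estimates"]), objective=float(d["objective"]),
                   n_evaluations=int(d["n_evaluations"]), seed=int(d["seed"]),
                   residuals=dict(d.get("residuals", {})),
                   converged=bool(d.get("converged", False)),
                   provenance=dict(d.get("provenance", {})))


class _BudgetExhausted(Exception):
    pass


class _Tracker:
    """Objective wrapper counting evaluations and tracking the best point."""

    def __init__(self, fun: Callable, budget: int):
        self.fun = fun
        self.budget = int(budget)
        self.n = 0
        self.best_x: np.ndarray | None = None
        self.best_f = np.inf

    def __call__(self, x) -> float:
        if self.n >= self.budget:
            raise _BudgetExhausted
        self.n += 1
        f = float(self.fun(np.asarray(x, dtype=float)))
        if f < self.best_f:
            self.best_f = f
            self.best_x = np.array(x, dtype=float)
        return f


def _latin_hypercube(rng: np.random.Generator, n: int, lo: np.ndarray,
                     hi: np.ndarray) -> np.ndarray:
    dim = lo.size
    u = (rng.permuted(np.tile(np.arange(n), (dim, 1)), axis=1).T
         + rng.random((n, dim))) / n
    return lo + u * (hi - lo)


def minimize_scatter(fun: Callable, bounds: Sequence[tuple], budget: int,
                     seed: int = 0, n_diverse: int = 50, refset_size: int = 10,
                     combo_passes: int = 2, offsets: Sequence[float] = (0.3, 0.7, 1.3),
                     polish: bool = True,
                     residual_fun: Callable | None = None) -> tuple:
    """Scatter-search minimization of ``fun`` over box ``bounds``.

    Returns ``(x_best, f_best, n_evaluations, converged)``. Deterministic
    for a given seed; for budgets that truncate the run, the evaluation
    sequence is a prefix of the full run, so best-so-far is monotone in the
    budget.

    When ``residual_fun`` is given (``fun`` must equal its squared norm) the
    local polish uses a trust-region least-squares step instead of the
    derivative-free Powell search; residual evaluations count against the
    same budget.
    """
    bounds = [(float(a), float(b)) for a, b in bounds]
    if not bounds:
        raise ConfigurationError("empty free-parameter set")
    if budget < refset_size:
        raise ConfigurationError("budget must be at least the reference-set size")
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    span = hi - lo
    rng = np.random.default_rng(seed)
    tracker = _Tracker(fun, budget)
    converged = False
    try:
        while tracker.n < budget and tracker.best_f > 1e-12:
            _scatter_round(tracker, rng, lo, hi, span, bounds, n_diverse,
                           refset_size, combo_passes, offsets, polish,
                           residual_fun)
            converged = converged or tracker.polish_converged
    except _BudgetExhausted:
        converged = False
    return tracker.best_x, tracker.best_f, tracker.n, converged


def _scatter_round(tracker, rng, lo, hi, span, bounds, n_diverse, refset_size,
                   combo_passes, offsets, polish, residual_fun):
    budget = tracker.budget
    tracker.polish_converged = False
    # diversification
    pts = _latin_hypercube(rng, n_diverse, lo, hi)
    evals = [(tracker(p), tuple(p)) for p in pts]
    # reference set: half best, half maximally diverse
    evals.sort(key=lambda e: e[0])
    n_best = refset_size // 2
    refset = [[f, np.array(x)] for f, x in evals[:n_best]]
    pool = [np.array(x) for _, x in evals[n_best:]]
    while len(refset) < refset_size and pool:
        dists = [min(np.linalg.norm((p - rx) / span) for _, rx in refset)
                 for p in pool]
        k = int(np.argmax(dists))
        p = pool.pop(k)
        fp = next(f for f, x in evals if np.array_equal(np.array(x), p))
        refset.append([fp, p])
    # combination passes
    for _ in range(combo_passes):
        order = sorted(range(len(refset)), key=lambda i: refset[i][0])
        for i, j in itertools.combinations(order, 2):
            xi, xj = refset[i][1], refset[j][1]
            for r in offsets:
                cand = np.clip(xi + r * (xj - xi), lo, hi)
                f = tracker(cand)
                worst = max(range(len(refset)), key=lambda k: refset[k][0])
                if f < refset[worst][0]:
                    refset[worst] = [f, cand]
    # local polish: best point first, then remaining refset starts
    if polish and tracker.n < budget:
        starts = [tracker.best_x.copy()]
        for _, rx in sorted(refset, key=lambda e: e[0]):
            if not any(np.array_equal(rx, s) for s in starts):
                starts.append(rx.copy())
        if residual_fun is not None:
            m = np.atleast_1d(np.asarray(residual_fun(starts[0]))).size

            def counted_residuals(x):
                if tracker.n >= tracker.budget:
                    raise _BudgetExhausted
                tracker.n += 1
                try:
                    r = np.asarray(residual_fun(np.asarray(x, dtype=float)))
                    f = float(np.dot(r, r))
                    if not np.isfinite(f):
                        raise FloatingPointError
                except _BudgetExhausted:
                    raise
                except Exception:
                    return np.full(m, np.sqrt(PENALTY / m))
                if f < tracker.best_f:
                    tracker.best_f = f
                    tracker.best_x = np.array(x, dtype=float)
                return r

            ls_bounds = (np.nextafter(lo, -np.inf), np.nextafter(hi, np.inf))
            queue = list(starts)
            while queue and tracker.best_f > 1e-12 and tracker.n < budget:
                x0 = queue.pop(0)
                f_before = tracker.best_f
                res = least_squares(
                    counted_residuals, np.clip(x0, *ls_bounds),
                    method="trf", jac="2-point", bounds=ls_bounds,
                    diff_step=1e-4,  # keep FD steps above the ODE noise floor
                    xtol=1e-14, ftol=1e-14, gtol=1e-14)
                tracker.polish_converged = tracker.polish_converged or res.status > 0
                # a stalled trust region restarts fresh from the improved point
                if tracker.best_f < f_before * (1.0 - 1e-6):
                    queue.insert(0, tracker.best_x.copy())
        else:
            for x0 in starts:
                res = minimize(tracker, x0, method="Powell", bounds=bounds,
                               options={"maxfev": budget - tracker.n,
                                        "xtol": 1e-10, "ftol": 1e-12})
                tracker.polish_converged = tracker.polish_converged or bool(res.success)
                if tracker.best_f < 1e-12 or tracker.n >= budget:
                    break


def scatter_search(problem: FitProblem, budget: int = 2000, seed: int = 0,
                   **kwargs) -> FitResult:
    """Fit the problem's free parameters by scatter search."""
    if not problem.free:
        raise ConfigurationError("empty free-parameter set")
    kwargs.setdefault("residual_fun", problem.residual_vector)
    x, f, nev, converged = minimize_scatter(
        problem.fit_error, problem.bounds, budget=budget, seed=seed, **kwargs)
    estimates = dict(zip(problem.free_names, x.tolist()))
    try:
        residuals = problem.residuals_by_observable(x)
    except Exception:  # penalized optimum: keep the result, skip residuals
        residuals = {}
    provenance = {
        "free": [{"name": p.name, "lower": p.lower, "upper": p.upper}
                 for p in problem.free],
        "fixed": dict(problem.fixed),
        "weights": dict(problem.weights),
        "budget": int(budget),
        "datasets": [ds.design.name for ds in problem.datasets],
    }
    return FitResult(estimates=estimates, objective=f, n_evaluations=nev,
                     seed=seed, residuals=residuals, converged=converged,
                     provenance=provenance)


def profile_objective(problem: FitProblem, param: str,
                      values: Sequence[float],
                      nuisance: Sequence[str] | None = None,
                      budget: int = 200) -> np.ndarray:
    """Objective profile along one parameter.

    At each grid value the parameter is fixed and the ``nuisance``
    parameters (a subset of the problem's free set) are re-optimized with a
    derivative-free local search, the standard profile construction for
    judging whether a parameter is practically insensitive.
    """
    free_names = list(problem.free_names)
    if param not in free_names:
        raise ConfigurationError(f"{param!r} is not a free parameter")
    nuisance = [n for n in (nuisance or []) if n != param]
    out = []
    start = {p.name: float(np.clip(0.0, p.lower, p.upper)) for p in problem.free}
    for p in problem.free:
        lib_val = None
        kind, a, b = _split_name(p.name)
        if kind == "slot":
            lib_val = getattr(problem.library[a], b)
        if lib_val is not None:
            start[p.name] = float(np.clip(lib_val, p.lower, p.upper))
    for v in values:
        fixed = dict(problem.fixed)
        fixed[param] = float(v)
        for name in free_names:
            if name not in nuisance and name != param:
                fixed[name] = start[name]
        sub = FitProblem(
            datasets=problem.datasets, library=problem.library,
            free=tuple(p for p in problem.free if p.name in nuisance),
            interactions=problem.interactions, fixed=fixed,
            weights=problem.weights, calibrations=problem.calibrations,
            rtol=problem.rtol, atol=problem.atol)
        if nuisance:
            x0 = np.array([start[n] for n in nuisance])
            tracker = _Tracker(sub.fit_error, budget)
            try:
                minimize(tracker, x0, method="Powell", bounds=sub.bounds,
                         options={"maxfev": budget, "xtol": 1e-10, "ftol": 1e-12})
            except _BudgetExhausted:
                pass
            out.append(tracker.best_f)
        else:
            out.append(sub.fit_error(np.empty(0)))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# staged calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationConfig:
    """Settings of the two-stage mono-then-pair calibration."""

    library: Mapping[str, SpeciesParams]
    free_mono: Mapping[str, Sequence[str]] | None = None
    fix_mono_at: Mapping[str, SpeciesParams] = field(default_factory=dict)
    slot_bounds: Mapping[str, tuple] = field(default_factory=lambda: dict(DEFAULT_SLOT_BOUNDS))
    ef_limit: float = DEFAULT_EF_LIMIT
    budget_mono: int = 3000
    budget_pair: int = 1000
    seed: int = 0
    weights: Mapping[str, float] = field(default_factory=dict)
    calibrations: Mapping[str, QpcrCalibration] | None = None
    rtol: float = 1e-8
    atol: float = 1e-10

    def free_slots(self, species: str) -> tuple:
        if self.free_mono and species in self.free_mono:
            return tuple(self.free_mono[species])
        return DEFAULT_FREE_MONO


@dataclass
class CalibrationResult:
    params: dict
    interactions: InteractionMatrix
    mono_results: dict
    pair_results: dict

    def __iter__(self):
        yield self.params
        yield self.interactions


def staged_calibration(mono_datasets: Iterable[ObservedDataset],
                       pair_datasets: Iterable[ObservedDataset],
                       config: CalibrationConfig) -> CalibrationResult:
    """Mono fits first, then per-pair interaction fits with mono values pinned.

    Each pair contributes exactly two interaction parameters (the mutual
    ``ef`` entries). The species set is taken from the pair designs; every
    species needs either a mono dataset or a pinned parameter set, and every
    unordered pair needs a dataset.
    """
    monos = {ds.design.members[0]: ds for ds in mono_datasets
             if len(ds.design.members) == 1}
    pairs = {frozenset(ds.design.members): ds for ds in pair_datasets
             if len(ds.design.members) == 2}
    species = sorted({s for key in pairs for s in key} | set(monos))
    missing = []
    for s in species:
        if s not in monos and s not in config.fix_mono_at:
            missing.append(f"mono dataset for {s}")
    for a, b in itertools.combinations(species, 2):
        if frozenset((a, b)) not in pairs:
            missing.append(f"pair dataset for {a}{b}")
    if missing:
        raise CalibrationError("missing inputs: " + "; ".join(missing))

    lib = {s: config.library[s] for s in species}
    mono_results: dict = {}
    for s in species:
        if s in config.fix_mono_at:
            lib[s] = config.fix_mono_at[s]
            continue
        slots = config.free_slots(s)
        free = tuple(FreeParam(f"{s}.{slot}", *config.slot_bounds[slot])
                     for slot in slots)
        problem = FitProblem(datasets=(monos[s],), library=lib, free=free,
                             weights=config.weights,
                             calibrations=config.calibrations,
                             rtol=config.rtol, atol=config.atol)
        result = scatter_search(problem, budget=config.budget_mono, seed=config.seed)
        mono_results[s] = result
        updates = {name.split(".")[1]: v for name, v in result.estimates.items()}
        lib[s] = lib[s].with_values(**updates)

    n = len(species)
    ef = np.full((n, n), config.ef_limit)
    pair_results: dict = {}
    for a, b in itertools.combinations(species, 2):
        ds = pairs[frozenset((a, b))]
        free = (FreeParam(f"ef.{a}.{b}", -config.ef_limit, config.ef_limit),
                FreeParam(f"ef.{b}.{a}", -config.ef_limit, config.ef_limit))
        problem = FitProblem(datasets=(ds,), library=lib, free=free,
                             weights=config.weights,
                             calibrations=config.calibrations,
                             rtol=config.rtol, atol=config.atol)
        result = scatter_search(problem, budget=config.budget_pair, seed=config.seed)
        pair_results[(a, b)] = result
        i, j = species.index(a), species.index(b)
        ef[i, j] = _snap_ef(result.estimates[f"ef.{a}.{b}"])
        ef[j, i] = _snap_ef(result.estimates[f"ef.{b}.{a}"])
    interactions = InteractionMatrix(species, ef, ef_limit=config.ef_limit)
    return CalibrationResult(params=lib, interactions=interactions,
                             mono_results=mono_results, pair_results=pair_results)
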