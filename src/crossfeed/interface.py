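"""Command-line interface and file formats.

Time series travel as CSV with a ``#``-prefixed provenance header (package
version, seed, config hash); parameters, fits and designs travel as JSON
with an embedded ``provenance`` object. Every writer has a matching reader
so outputs round-trip through the package's own serializers.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import __version__
from .diagnostics import parameter_correlation, perturbation_bands
from .estimation import (
    DEFAULT_SLOT_BOUNDS,
    FitProblem,
    FitResult,
    FreeParam,
    scatter_search,
)
from .model_core import ConsortiumModel, Trajectory, percent_abundance
from .reference import reference_calibrations, reference_model, reference_species
from .scenarios import KnockoutSpec, knockout as run_knockout
from .synthetic_data import (
    CultureDesign,
    NoiseModel,
    ObservedDataset,
    design_model,
    generate_dataset,
    scenario_catalog,
)

__all__ = [
    "provenance",
    "write_model_json", "read_model_json",
    "write_dataset_csv", "read_dataset_csv",
    "write_trajectory_csv", "read_trajectory_csv",
    "write_fit_json", "read_fit_json",
    "cli", "main",
]


def provenance(seed: int | None = None, config: dict | None = None) -> dict:
    cfg = json.dumps(config or {}, sort_keys=True, default=str)
    return {
        "package": "crossfeed",
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha1(cfg.encode()).hexdigest()[:12],
    }


def _header_lines(prov: dict) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in prov.items())


# -- JSON ------------------------------------------------------------------

def write_model_json(model: ConsortiumModel, path, seed: int | None = None):
    doc = {"format": "crossfeed-model", "provenance": provenance(seed, model.to_dict())}
    doc.update(model.to_dict())
    Path(path).write_text(json.dumps(doc, indent=2))


def read_model_json(path) -> ConsortiumModel:
    return ConsortiumModel.from_dict(json.loads(Path(path).read_text()))


def write_fit_json(result: FitResult, path):
    doc = {"format": "crossfeed-fit",
           "provenance": provenance(result.seed, result.provenance)}
    doc.update(result.to_dict())
    Path(path).write_text(json.dumps(doc, indent=2))


def read_fit_json(path) -> FitResult:
    return FitResult.from_dict(json.loads(Path(path).read_text()))


# -- CSV -------------------------------------------------------------------

def write_trajectory_csv(traj: Trajectory, path, seed: int | None = None):
    prov = provenance(seed, {"species": list(traj.species)})
    with open(path, "w") as fh:
        fh.write(_header_lines(prov))
        traj.to_frame().to_csv(fh, index=False)


def read_trajectory_csv(path) -> Trajectory:
    return Trajectory.from_frame(pd.read_csv(path, comment="#"))


def write_dataset_csv(dataset: ObservedDataset, path, seed: int | None = None):
    """Tidy CSV plus a JSON sidecar (same path with ``.json``) holding the
    design and generation provenance."""
    path = Path(path)
    prov = provenance(seed, dataset.design.to_dict())
    with open(path, "w") as fh:
        fh.write(_header_lines(prov))
        dataset.to_tidy().to_csv(fh, index=False)
    sidecar = {"format": "crossfeed-dataset", "provenance": prov,
               "design": dataset.design.to_dict(),
               "generation": dataset.provenance}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def read_dataset_csv(path) -> ObservedDataset:
    path = Path(path)
    tidy = pd.read_csv(path, comment="#")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    design = CultureDesign.from_dict(sidecar["design"])
    return ObservedDataset.from_tidy(tidy, design,
                                     provenance=sidecar.get("generation", {}))


# -- CLI -------------------------------------------------------------------

@click.group()
@click.version_option(version=__version__, prog_name="crossfeed")
def cli():
    """Kinetic modeling of cross-feeding microbial consortia."""


def _load_model(spec: str) -> ConsortiumModel:
    if spec == "reference":
        return reference_model()
    return read_model_json(spec)


@cli.command()
@click.option("--scenario", required=True,
              help="Design name from the packaged catalog (e.g. mono-Bi, pair-BvEc, all-bioreactor).")
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--qpcr-cv", type=float, default=0.20, show_default=True)
@click.option("--conc-sd", type=float, default=0.15, show_default=True)
@click.option("--out", required=True, type=click.Path(dir_okay=False))
def generate(scenario, seed, qpcr_cv, conc_sd, out):
    """Generate a synthetic observed dataset for a packaged scenario."""
    designs = scenario_catalog()
    if scenario not in designs:
        raise click.ClickException(
            f"unknown scenario {scenario!r}; choose from {sorted(designs)}")
    design = designs[scenario]
    model = design_model(design, reference_species(),
                         None if len(design.members) == 1 else
                         reference_model(design.members).interactions)
    noise = NoiseModel(qpcr_cv=qpcr_cv, conc_sd=conc_sd, seed=seed)
    ds = generate_dataset(model, design, noise)
    write_dataset_csv(ds, out, seed=seed)
    click.echo(f"wrote {out} (+ sidecar)", err=True)


@cli.command("simulate")
@click.option("--model", "model_spec", default="reference", show_default=True,
              help="'reference' or a model JSON path.")
@click.option("--members", default=None,
              help="Comma-separated subset of reference species (with --model reference).")
@click.option("--t-end", type=float, default=72.0, show_default=True)
@click.option("--dt", type=float, default=0.5, show_default=True)
@click.option("--out", required=True, type=click.Path(dir_okay=False))
def simulate_cmd(model_spec, members, t_end, dt, out):
    """Simulate a model and write the trajectory CSV."""
    from .model_core import simulate as _simulate
    if members and model_spec == "reference":
        model = reference_model(tuple(members.split(",")))
    else:
        model = _load_model(model_spec)
    t = np.arange(0.0, t_end + dt / 2, dt)
    traj = _simulate(model, t)
    write_trajectory_csv(traj, out)
    click.echo(f"wrote {out}", err=True)


@cli.command()
@click.option("--datasets", required=True, multiple=True,
              help="Dataset CSV path(s); repeatable.")
@click.option("--stage", type=click.Choice(["mono", "pair"]), required=True)
@click.option("--free", required=True,
              help="Comma-separated free parameter names (e.g. Bi.mu_max,Bi.Y_sx or ef.Bv.Ec,ef.Ec.Bv).")
@click.option("--budget", type=int, default=2000, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", required=True, type=click.Path(dir_okay=False))
def fit(datasets, stage, free, budget, seed, out):
    """Fit free parameters to datasets by scatter search."""
    data = tuple(read_dataset_csv(p) for p in datasets)
    for ds in data:
        expected = 1 if stage == "mono" else 2
        if len(ds.design.members) != expected:
            raise click.ClickException(
                f"{ds.design.name}: {len(ds.design.members)} members, "
                f"stage {stage!r} expects {expected}")
    free_params = []
    for name in free.split(","):
        name = name.strip()
        if name.startswith("ef."):
            free_params.append(FreeParam(name, -100.0, 100.0))
        else:
            slot = name.split(".")[1]
            if slot not in DEFAULT_SLOT_BOUNDS:
                raise click.ClickException(f"unknown slot in {name!r}")
            free_params.append(FreeParam(name, *DEFAULT_SLOT_BOUNDS[slot]))
    interactions = None
    if stage == "pair":
        members = data[0].design.members
        interactions = reference_model(members).interactions
    problem = FitProblem(datasets=data, library=reference_species(),
                         free=tuple(free_params), interactions=interactions)
    result = scatter_search(problem, budget=budget, seed=seed)
    write_fit_json(result, out)
    click.echo(json.dumps({"objective": result.objective,
                           "estimates": result.estimates}), err=True)


@cli.command()
@click.option("--fit", "fit_path", required=True, type=click.Path(exists=True))
@click.option("--datasets", required=True, multiple=True)
@click.option("--threshold", type=float, default=0.95, show_default=True)
@click.option("--out", required=True, type=click.Path(dir_okay=False))
def identify(fit_path, datasets, threshold, out):
    """Parameter correlation report for an existing fit."""
    result = read_fit_json(fit_path)
    data = tuple(read_dataset_csv(p) for p in datasets)
    free = tuple(FreeParam(f["name"], f["lower"], f["upper"])
                 for f in result.provenance["free"])
    interactions = None
    if any(f.name.startswith("ef.") for f in free):
        members = data[0].design.members
        interactions = reference_model(members).interactions
    problem = FitProblem(datasets=data, library=reference_species(),
                         free=free, interactions=interactions,
                         fixed=result.provenance.get("fixed", {}),
                         weights=result.provenance.get("weights", {}))
    report = parameter_correlation(result, problem, threshold=threshold)
    with open(out, "w") as fh:
        fh.write(_header_lines(provenance(result.seed, {"threshold": threshold})))
        report.to_frame().to_csv(fh)
    click.echo(f"flagged pairs: {report.flagged}", err=True)


@cli.command()
@click.option("--model", "model_spec", default="reference", show_default=True)
@click.option("--param", required=True, help="e.g. Bi.mu_max")
@click.option("--fraction", type=float, default=0.05, show_default=True)
@click.option("--iters", type=int, default=5000, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--t-end", type=float, default=72.0, show_default=True)
@click.option("--dt", type=float, default=1.0, show_default=True)
@click.option("--out", required=True, type=click.Path(dir_okay=False))
def sense(model_spec, param, fraction, iters, seed, t_end, dt, out):
    """Monte-Carlo perturbation bands for one parameter."""
    model = _load_model(model_spec)
    t = np.arange(0.0, t_end + dt / 2, dt)
    report = perturbation_bands(model, param, fraction=fraction,
                                iterations=iters, seed=seed, t_grid=t)
    mean = report.band_mean.add_suffix("_mean").rename(
        columns={"time_h_mean": "time_h"})
    sd = report.band_sd.drop(columns="time_h").add_suffix("_sd")
    with open(out, "w") as fh:
        fh.write(_header_lines(provenance(seed, report.settings)))
        pd.concat([mean, sd], axis=1).to_csv(fh, index=False)
    click.echo(f"wrote {out} (dropped {report.dropped_iterations})", err=True)


@cli.command("knockout")
@click.option("--model", "model_spec", default="reference", show_default=True)
@click.option("--target", required=True)
@click.option("--t-end", type=float, default=72.0, show_default=True)
@click.option("--out", required=True, type=click.Path(dir_okay=False))
def knockout_cmd(model_spec, target, t_end, out):
    """Bacteriostatic knockout simulation; writes trajectory, prints ranking."""
    model = _load_model(model_spec)
    t = np.linspace(0.0, t_end, int(2 * t_end) + 1)
    result = run_knockout(model, KnockoutSpec(target=target), t_grid=t)
    write_trajectory_csv(result.trajectory, out)
    click.echo(json.dumps({"ranking": list(result.ranking)}))


@cli.command()
@click.option("--traj", "traj_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_dir", required=True, type=click.Path(file_okay=False))
def report(traj_path, out_dir):
    """Percent-abundance and pool tables from a trajectory CSV."""
    traj = read_trajectory_csv(traj_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cal = reference_calibrations()
    cal = {n: cal.get(n) or next(iter(cal.values())) for n in traj.species}
    pct = percent_abundance(traj, cal)
    pct.to_csv(out / "percent.csv", index=False)
    pd.DataFrame({"time_h": traj.times, "S": traj.S}).to_csv(
        out / "substrate.csv", index=False)
    pd.DataFrame({"time_h": traj.times, "A": traj.A, "L": traj.L}).to_csv(
        out / "acids.csv", index=False)
    click.echo(f"wrote {out}/percent.csv, substrate.csv, acids.csv", err=True)


def main(argv=None) -> int:
    """Entry point returning an exit status (0 on success)."""
    try:
        cli.main(args=argv, standalone_mode=False)
        return 0
    except click.ClickException as exc:
        exc.show(file=sys.stderr)
        return exc.exit_code or 1
    except click.exceptions.Abort:
        return 1
    except SystemExit as exc:  # --help / --version paths
        return int(exc.code or 0)


if __name__ == "__main__":
    sys.exit(main())
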