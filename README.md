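# crossfeed

Kinetic modeling, calibration and analysis of small cross-feeding microbial
consortia growing on a prebiotic carbohydrate.

The package models batch co-cultures of up to four gut bacteria (labels
`Bi`, `Bv`, `Ec`, `La`) on a single substrate with two fermentation acids
(acetate, lactate) that simultaneously inhibit growth, serve as secondary
cross-feeding substrates, and carry pairwise interaction effects. It ships:

- **`crossfeed.model_core`** — parameter types (17-slot kinetic vector per
  species, pairwise interaction matrix `ef`), Monod growth with
  non-competitive acid inhibition, lag phases, interaction multipliers,
  ODE assembly (`build_rhs`), adaptive simulation (`simulate`), and
  observation operators (qPCR copy conversion, percent abundance).
- **`crossfeed.synthetic_data`** — culture designs (4 mono, 6 pairs,
  four-species microplate and bioreactor runs), observational noise models,
  and reproducible dataset generation.
- **`crossfeed.estimation`** — max-normalized least-squares objective,
  scatter-search optimization (Latin-hypercube diversification, reference
  set, combinations, least-squares polish), and the staged
  mono-then-pair calibration that fits two interaction parameters per pair.
- **`crossfeed.diagnostics`** — practical identifiability via the parameter
  correlation matrix, time-averaged local sensitivities, and Monte-Carlo
  perturbation bands.
- **`crossfeed.scenarios`** — consortium runs with composition summaries,
  bacteriostatic knockout simulations with dominance rankings, and linear
  time alignment between sampling grids.
- **`crossfeed.reference`** — a packaged reference parameter library
  (interaction matrix plus documented kinetic defaults) powering all
  scenarios out of the box.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (structural
counts, yield identities, interaction-parameter recovery, numerical
property suites, qualitative consortium behaviors); the other files are
per-module unit and property tests.

## CLI

The console script `crossfeed` (equivalently `python -m crossfeed.interface`)
exposes the full workflow. Examples:

```sh
# synthetic dataset for a packaged scenario (CSV + JSON sidecar)
crossfeed generate --scenario mono-Bi --seed 1 --out mono_bi.csv

# simulate the packaged four-species reference model
crossfeed simulate --members Bi,Bv,Ec,La --t-end 72 --dt 0.5 --out traj.csv

# composition / substrate / acid tables from a trajectory
crossfeed report --traj traj.csv --out report/

# fit parameters by scatter search
crossfeed fit --datasets mono_bi.csv --stage mono \
    --free Bi.mu_max,Bi.Y_sx --budget 2000 --seed 0 --out fit.json

# parameter correlation report for an existing fit
crossfeed identify --fit fit.json --datasets mono_bi.csv --out corr.csv

# Monte-Carlo perturbation bands for one parameter
crossfeed sense --param Bi.mu_max --fraction 0.05 --iters 5000 --seed 0 --out bands.csv

# bacteriostatic knockout of one species
crossfeed knockout --target Bi --out ko_Bi.csv
```

Time series are CSV with a `#`-prefixed provenance header; parameters,
fits and designs are JSON. Every writer has a matching reader
(`crossfeed.interface`).

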