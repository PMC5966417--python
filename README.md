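# langcoevo

Agent-based gene–culture coevolution of language, plus the two quantitative
analyses of its output:

* **Simulator** (`langcoevo.core`): `N` agents with an innate-ability
  genotype `a` and a plasticity half-width `p`; languages as points on a
  one-dimensional expressiveness axis. Each generation runs all-pairs
  communication (a pair succeeds iff a language lies in the intersection of
  both plasticity intervals; one shared language is drawn per pair), fitness
  `W1 * sum(used expressiveness) - W2 * (p+1)^a`, roulette-wheel
  reproduction with Gaussian mutation, then four cultural processes on the
  language population: change (displacement `F/n_i` per user toward each
  user's innate ability), division (when both pull directions exceed `Fd`),
  extinction (unused languages), and fusion (closer than `Tf`, merged at the
  midpoint). Fully seeded and bit-reproducible.
* **Evolutionary rates** (`langcoevo.rates`): rates in darwins
  (`(ln v2 - ln v1)/dt`, one generation as the time unit) for the
  biological series over non-overlapping windows and per cultural event,
  swept over a grid of measurement intervals.
* **Directional effects** (`langcoevo.infotheory`): five-level
  discretization of the windowed series by rate of change, plug-in transfer
  entropy, effective transfer entropy via surrogate shuffling, and the
  per-interval Wilcoxon rank-sum comparison of the two directions across
  replicate runs.
* **Fixtures** (`langcoevo.fixtures`): analytic test processes (iid/lag-1
  copy/noisy-copy symbol pairs, exponential/alternating/constant trends)
  with closed-form TE and rate values.
* **Experiments** (`langcoevo.experiments`): replicate runs, one-axis
  parameter sweeps (with the `Fd = F * 300` linkage when sweeping `F`),
  manifests, and summary proxies.

## CLI

```bash
# one seeded run
langcoevo simulate --config examples/params.yaml --seed 1 --out runs/r1

# analyses over its outputs
langcoevo rates --trace runs/r1/trace.csv --events runs/r1/events.jsonl \
    --dt-grid 1,10,50,110,200,400,700,1100,1500,2000 --out rates.csv
langcoevo te --traces runs/r1/trace.csv,runs/r2/trace.csv \
    --dt-grid 10,30,50,70,90,110 --shuffles 100 --out te.csv

# sweeps, fixtures, quick-look plots
langcoevo sweep --axis F --values 1e-7,1e-6,1e-5,1e-4 --replicates 5 \
    --out sweeps/F --stop-on-extinction
langcoevo fixtures --kind lag1_copy --length 100000 --seed 1 --out pair.csv
langcoevo plot --trace runs/r1/trace.csv --out evo.png
```

The YAML config mirrors `SimParams` field-for-field (`N`, `W1`, `W2`, `Pm`,
`mut_var`, `F`, `Fd`, `Tf`, `generations`, `init_num_languages`, `seed`,
`fitness_floor`, `displacement_weighting`); flags override the file.
Output columns are documented in `docs/data_dictionary.md`.

## Library example

```python
from langcoevo import SimParams, run_simulation, rate_interval_sweep, \
    directional_analysis

traces = [run_simulation(SimParams(N=200, generations=2000, seed=s))
          for s in range(20)]
sweep = rate_interval_sweep(traces, dt_grid=[1, 10, 50, 110, 200, 400])
trials, summary = directional_analysis(
    [t for t in traces if t.total_extinction_generation is None],
    dt_grid=[10, 30, 50, 70, 90, 110], n_shuffles=100, seed=0)
```
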