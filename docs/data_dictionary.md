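# Data dictionary

## `trace.csv` — one row per generation

| column          | type  | meaning |
|-----------------|-------|---------|
| `gen`           | int   | Generation index, starting at 0. |
| `mean_a`        | float | Mean innate language ability of the end-of-generation (offspring) population. |
| `mean_p`        | float | Mean plasticity half-width of the end-of-generation population. |
| `mean_fitness`  | float | Mean fitness of the communicating (parent) population this generation. |
| `mean_lang_pos` | float | Mean language expressiveness after all cultural processes; NaN when the language population is empty. |
| `n_langs`       | int   | Language count after all cultural processes. |
| `n_successes`   | int   | Number of successful unordered agent pairs in this generation's communication round. |

## `events.jsonl` — one cultural event per line

JSON objects with keys `kind` (`change` | `division` | `fusion` |
`extinction`), `generation`, `parent_positions`, `child_positions`,
`parent_lineages`, `child_lineages`. Arity per kind: change 1→1,
division 1→2, fusion 2→1, extinction 1→0.

## `params.json`

Resolved run configuration (every `SimParams` field, including the seed)
plus `total_extinction_generation` (null if the language population never
emptied).

## `manifest.json` (replicates / sweeps)

`params`, `params_hash` (sha256 of the sorted parameter JSON),
`code_version`, and one record per run: `run`, `seed`, `status`,
`params_hash`, `total_extinction_generation`, `path`.

## `rates` command output

One row per (`dt`, `source`, `event_kind`): `dt`, `source`
(`biological` | `cultural`), `event_kind` (`all` pools the cultural kinds;
biological rows use `all`), `n` samples, `median`, `q25`, `q75` of the
rate magnitude in darwins-per-generation, and `n_skipped` samples dropped
for a non-positive endpoint.

## `te` command output

Trials file: `dt`, `trial`, `direction` (`L->B` | `B->L`), `te_bits`,
`ete_bits`. Summary file: per-`dt` `n_trials`, `median_ete_L_to_B`,
`median_ete_B_to_L`, `median_gap` (B→L minus L→B), `wilcoxon_stat`,
`wilcoxon_p` (two-sided rank-sum between the two ET samples).

## Units

Rates are darwins with **one generation as the time unit** (e-folds of the
trait value per generation); the model has no calendar mapping. Transfer
entropies are in bits (log base 2) unless `base` is overridden.
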