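# ctvert

Scoring, classification and exact small-sample statistics for cervico-thoracic
(C/T) transitional vertebrae in skeletal collections.

Mammals almost universally have seven cervical vertebrae; a partial homeotic
cervical→thoracic transformation shows up osteologically as rib articulation
facets on the last cervical vertebra. This package implements a 12-character
diagnostic scoring scheme for distinguishing a normal last cervical (C7), a
transitional facet-bearing vertebra (C/T), and a regular first thoracic (T1),
plus the exact statistics needed to compare C/T incidence between small
specimen samples.

## Components

- `ctvert.characters` — the 12-character scheme (ids `a`–`l`): definitions,
  quantitative ratio bands (`b`-juvenile, `d`, `e`, `f`, `j`), derivation of
  trichotomous states from raw measurements, per-side (bilateral) states, and
  profile validation. The character dictionary can be exported as CSV or YAML
  (`export_definitions`).
- `ctvert.classifier` — identity calls: no rib facets → C7; facets plus ≥ 6 of
  12 characters cervical-or-transitional → C/T; facets with fewer → T1;
  unresolvable (facet characters unscored, or too many missing characters for
  the threshold to be decidable) → indeterminate. Also flags left–right
  asymmetry. `classify_dataset` produces a per-specimen table with summary
  counts.
- `ctvert.stats` — hypergeometric PMF in log-space, Fisher's exact test by
  full enumeration (two-sided p via the minimum-likelihood rule), exact
  Clopper–Pearson binomial intervals, conditional-MLE odds ratio, and
  `compare_incidence` for two classified datasets.
- `ctvert.synthetic` — seeded synthetic populations with known ground truth
  (configurable C/T prevalence, T1 contamination, one-step state noise,
  missingness, per-side asymmetry), plus Monte-Carlo type-I-error and power
  estimation with paired per-replicate seeds.
- `ctvert.datasets` — the CSV specimen-table schema (reader/writer, lossless
  round-trip) and three packaged fixtures: `coelodonta_c7` (32 Late
  Pleistocene woolly-rhinoceros vertebrae), `extant_rhino` (56 extant
  rhinocerotid C7s), `table4_matrix` (the 12 fully characterized vertebrae
  with at least one transitional character).
- `ctvert.cli` — the `ctvert` command.

## CLI

```sh
ctvert classify table4_matrix                   # fixture name or CSV path
ctvert compare coelodonta_c7 extant_rhino       # incidences, CIs, exact test
ctvert simulate power.yaml --seed 1             # type-I / power simulation
ctvert reproduce                                # re-check the published numbers
```

All commands take `--alpha`, `--ci-level`, `--seed`, `--out`, `--format
{text,json}`, `--log-level`. Exit codes: 0 success, 1 usage error, 2 data /
verification error. A simulation config is a small YAML file, e.g.

```yaml
mode: power          # or: type1 (then give `prevalence:` instead of a/b)
prevalence_a: 0.15625
prevalence_b: 0.0
n_a: 32
n_b: 56
reps: 2000
```

## Conventions worth knowing

- Ratio values falling strictly inside the gap between the printed cervical
  and thoracic bands score TRANSITIONAL; band edges are inclusive exactly as
  worded.
- For bilateral characters the specimen-level state is the more thoracic of
  the two sides; asymmetry is tracked separately.
- Indeterminate calls are excluded from all incidence denominators and
  reported alongside the results.
- Synthetic-population defaults (archetype mixes, noise model) are package
  conventions: true per-character state frequencies in wild populations are
  not knowable from collection data of this kind.
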