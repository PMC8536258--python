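# File schemas

All inputs and outputs are delimited text (comma default) or JSON.

## Per-ovariole records CSV (`ovoclone simulate` output; `read_records_csv`)

One row per scored ovariole, header row required.

| column | type | notes |
|---|---|---|
| `ovariole_id` | string | unique per row |
| `n_r1_ec` | int, optional | region-1 marked ECs; give both split columns or neither |
| `n_r2a_ec` | int, optional | region-2a marked ECs |
| `n_ec` | int, optional | total marked ECs; derived from the split when absent, must agree when both present |
| `n_fsc` | int | marked FSCs |
| `fc_locations` | string | semicolon-joined codes from `I;G;E1;E2;E3;E4`; empty = no marked FCs |
| `basal_stalk` | enum | `marked` / `unmarked` / `not_imaged` (default) |
| `scoring_age` | enum | `eclosion_day0` (default) / `adult_day2` |

## Aggregated category-table CSV (`ovoclone census --counts`, `ovoclone deconvolve --counts`)

Mirrors the published raw-data rows. Columns `category,n,mean_ec,mean_fsc`;
one row per clone category (`EC_only`, `EC_FSC`, `FSC_only`, `FC_only`,
`EC_plus_FC`), plus optional special rows whose value sits in the `n`
column:

```
category,n,mean_ec,mean_fsc
EC_only,46,2.4,
EC_FSC,24,4.0,4.0
FSC_only,3,,4.667
FC_only,9,,
EC_plus_FC,16,2.9,
unlabeled,109,,
total_EC_marked,253,,
total_FSC_marked,111,,
```

`total_EC_marked` / `total_FSC_marked` are experiment-wide marked-cell
totals; they are required for the EC/FSC yield subtraction and take
precedence over category-weighted sums of the (typically rounded) means.

## Production totals CSV (`ovoclone table2 --totals`)

| column | meaning |
|---|---|
| `days_before_eclosion` | clone-induction time |
| `x_r1` | total marked r1 ECs over all clones |
| `y_r2a` | total marked r2a ECs |
| `z_fsc` | total marked FSCs |

Output CSV adds `r1_made, r2a_made, ec_made` (= 16x/z, 16y/z, 16(x+y)/z)
and `fsc_made` (the 16-FSC normalization).

## Simulation config YAML (`ovoclone simulate/recover --config`)

```yaml
n_ovarioles: 5000
labeled_fraction: 0.47     # fraction of ovarioles with any marked cell
sigma_true: 0.30           # single-lineage fraction among marked ovarioles
true_freqs: {p_ec: 0.63, p_ecfsc: 0.13, p_fsc: 0.05, p_fc: 0.19}
yield_means:               # mean marked cells per single lineage (all >= 1)
  ec_per_ec_lineage: 1.76
  fsc_per_fsc_lineage: 4.32
  ec_per_ecfsc_lineage: 3.15
  fsc_per_ecfsc_lineage: 3.47
yield_dispersion: 2.0      # NB dispersion k of the shifted count draws
r1_fraction: 0.6           # binomial split of ECs into region 1
fc_given_fsc_prob: 0.7     # FSC-containing lineages that also show FCs
terminal_zone_prob: 0.7    # FC-only lineages drawing terminal-chamber codes
```

The seed comes from `--seed`. Omitting `--config` uses the built-in
pupariation-stage-like truth above.

## JSON reports

`ovoclone census` emits a report object with keys `label`,
`n_marked_ovarioles`, `observed_frequencies` (`f_EC_obs`, `f_FC_obs`,
`f_FSC_obs`, `f_ECFC_obs`), `sigma` (`value`, `mode`, `residual`,
`decision_path`), `lineage_frequencies` (`p_EC`, `p_ECFSC`, `p_FSC`,
`p_FC`), `per_lineage_yields`, `census` (`n_total`, per-type counts,
`total_lineages`, `fsc_normalization`), `notes`, and — for built-in
datasets — `published_reference` and `deltas_vs_published`. A markdown
rendering of the same row is written alongside (`report.md`) or to stderr.

`ovoclone recover` emits `n_replicates`, `n_succeeded`, `truth`, `bias`,
`rmse`, `sigma_hit_rate`, `estimates` (per replicate), and `errors` as
`(replicate_index, message)` pairs.

`ovoclone simulate` writes `records.csv` (schema above) and `truth.json`
(the config echo, the implied census, and per-ovariole realized lineage
types keyed by `ovariole_id`).
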