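# File format reference

All files are plain text. Paths below are relative to a study directory
(written by `meioseq simulate`) or a pipeline output directory (written
by `meioseq run-all` / `classify`).

## Binned counts — `counts/<sample_id>.tsv` (+ `.tsv.json` sidecar)

BED-like TSV, no header, one row per genome bin in canonical order:

| column | meaning |
|---|---|
| 1 | chromosome name (`1`–`19`, `X`, `Y`) |
| 2 | bin start, 0-based inclusive |
| 3 | bin end, exclusive |
| 4 | raw read count |

The bin intervals must match the binning in use; readers verify this
and refuse mismatched files. The JSON sidecar of the same name carries
sample metadata:

```json
{
  "sample_id": "normal_panel",
  "sample_role": "panel",        // egg | pb | panel
  "mapped_fraction": 0.9579,     // may be null (QC indeterminate)
  "total_reads": 98319.0
}
```

## Chromosome table — two-column TSV

`name<TAB>length` per line; `#` comments allowed. Names `X`/`Y` are
treated as sex chromosomes, everything else as autosomes. Rows are
reordered canonically (autosomes numerically, then X, then Y).

## Pair manifest — `pairs.json`

List of `{"pair_id": ..., "egg": "<file>.tsv", "pb": "<file>.tsv"}`
entries; file names are relative to `counts/`.

## Simulation truth — `truth.json`

Map of pair id to `{"treatment": <group>, "counts": {<chrom>: [egg,
pb]}}` — the ground-truth chromatid counts (egg + pb = 4, no Y).

## Morphokinetic events — `morphokinetics.csv`

| column | meaning |
|---|---|
| `sample_id` | pair id (sequenced) or synthetic id (immature oocytes) |
| `group` | treatment group |
| `t0` | imaging start, hours (0.0) |
| `tGVBD_h` | germinal vesicle breakdown time; empty if not reached |
| `tPB1_h` | first-polar-body extrusion time; empty if not reached |
| `dMI_h` | `tPB1_h - tGVBD_h`; empty unless both events present |
| `status` | `GV` \| `GVBD-only` \| `MII` |
| `severity` | ploidy class when known (`euploid` \| `1-3` \| `>=4`) |
| `exclusion_flag` | e.g. `invalid-annotation` (tPB1 ≤ tGVBD) |

Only `sample_id`, `tGVBD_h`, `tPB1_h` (and optionally a grouping
column) are required on input; `derive_variables` fills the rest.

## Simulation config — `config.yaml`

YAML rendering of `SimulationConfig`: `groups` (per-group `n_pairs`,
`p_err`, `p_cat`, `n_gv`, `n_gvbd_only`), `q_ndj`, `p_egg_retains`,
`depth`, `nb_size` (null = deterministic), `bias_sigma`,
`frac_overrepresented`, `p_qc_fail`, `window_size`, and
`morphokinetics` (per ploidy class: `tgvbd_mean`, `tgvbd_sem`,
`tpb1_mean`, `tpb1_sem`, `n`).

## Cohort table — `cohort.csv`

One row per egg/PB pair:

| column | meaning |
|---|---|
| `pair_id`, `treatment` | identifiers |
| `status` | `analyzed` \| `qc-failed` |
| `qc_reason` | which sample failed and why (empty when analyzed) |
| `egg_karyotype`, `pb_karyotype` | `sseq` strings |
| `aneuploidy_type` | `euploid` \| `NDJ` \| `PSSC` \| `NDJ+PSSC` |
| `n_errors` | chromosomes designated non-(2,2) |
| `n_discordant` | chromosomes refused (residual > tolerance) |
| `severity` | `euploid` \| `1-3` \| `>=4` |

## Error spectrum — `error_spectrum.tsv`

Header `chromosome<TAB>NDJ<TAB>PSSC`; one row per chromosome with event
counts over all analyzed pairs (each reciprocal event counted once).

## Report — `report.json`

```
{
  "rows": [...],          // cohort.csv rows as objects
  "aggregates": {
    "n_pairs", "n_analyzed", "n_qc_failed",
    "incidence_by_group": {group: {analyzable, aneuploid, incidence_pct}},
    "type_counts", "severity_counts",
    "morphokinetics": {grouping: {variable: {groups, test_used,
                                             p_value, pairwise}}},
    "maturation": {proportions, test_used, p_value}
  },
  "log": ["seed: ...", "pair X: excluded at QC (...)",
          "pairs in: N; analyzed: A; qc-failed: Q"]
}
```

## Copy-number calls — `call-cn --out`

TSV with header `chromosome, observed_cn, n_bins_used`: one row per
chromosome with a defined call, reporting the median-based observed
copy number and how many of the chromosome's bins survived masking.
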