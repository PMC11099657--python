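# meioseq

Sequencing-based detection of meiotic chromosome segregation errors in
single mouse oocytes, with a first-class synthetic-data generator.

When an oocyte completes meiosis I it splits each chromosome's four
chromatids between the egg and the first polar body (PB1). Faithful
segregation leaves two chromatids in each cell; errors produce
*reciprocal* aneuploidies — whatever the egg gains, the polar body
loses. `meioseq` calls chromosome copy numbers from shallow
whole-genome sequencing of matched egg/PB1 pairs, designates the
underlying chromatid partition under the conservation constraint
(egg + PB1 = 4), classifies each error as whole-bivalent
non-disjunction (NDJ, 4/0) or premature sister-chromatid separation
(PSSC, 3/1), and analyses time-lapse maturation timings (tGVBD, tPB1,
dMI) alongside the genomic calls.

Because matched single-cell pairs with known ground truth are scarce,
the package ships a calibrated simulator that generates complete
studies — segregation truth, binned read counts with negative-binomial
noise and shared bin biases, a euploid male reference panel, and
morphokinetic records — so every stage of the pipeline can be validated
against known answers.

## What it does

- **Genome model** — gap-free 10 Mb bin tiling of the mouse (GRCm39)
  chromosome lengths (bundled), or any genome given as a two-column TSV.
- **Copy-number calling** — per-sample QC (mapped fraction ≥ 0.90),
  masking of overrepresented bins (raw count > 1000), normalization to
  1,000,000 autosomal counts, fold change against a normalized euploid
  male (40,XY) panel, and per-chromosome observed copy number as the
  median bin fold change × 2 (autosomes) or × 1 (sex chromosomes).
- **Reciprocal designation** — for each chromosome, the integer
  partition (egg, pb) with egg + pb = 4 nearest the observed pair;
  residuals above 0.5 are flagged discordant rather than forced. A
  ridge-regularized joint rescaling of the pair fixes the per-sample
  scale ambiguity that otherwise breaks near-whole-complement samples.
- **Classification** — per-chromosome NDJ/PSSC labels, per-pair
  aneuploidy type (NDJ / PSSC / NDJ+PSSC), error counts, and severity
  class (euploid, 1–3 errors, ≥4 errors).
- **Karyotype nomenclature** — a writer and a strict, position-aware
  parser for strings like `sseq cht(2,16,18)x4, cht(5-9)x0`
  (`sseq euploid` for no abnormality).
- **Morphokinetics** — tGVBD/tPB1/dMI derivation, iterated two-sided
  Grubbs outlier screening, and a fixed statistical gate: Shapiro–Wilk
  per group, then Student's t / one-way ANOVA with Tukey's HSD /
  Kruskal–Wallis with Dunn's test as appropriate; maturation-stage
  contingency tables tested with Fisher's exact or chi-square.
- **Simulation** — dose-calibrated group error rates, independent
  per-chromosome errors plus catastrophic whole-complement events, read
  depth scaled to each cell's actual DNA content, and class-conditional
  timing draws.

## Quick start

Simulate a study, call every pair, and produce the cohort report:

```bash
$ meioseq run-all --seed 7 --out results/run7
analyzed 42/47 pairs (5 QC failures)
  control: 0/9 aneuploid (0.00%)
  25 nM: 2/11 aneuploid (18.18%)
  50 nM: 15/22 aneuploid (68.18%)
```

`results/run7/` then contains `cohort.csv` (one row per pair with both
karyotype strings, type, error count, and severity), `report.json`
(aggregates including the morphokinetic statistics), an
`error_spectrum.tsv` chromosome × {NDJ, PSSC} table, and
`pipeline.log` with the full n-accounting.

Parse a karyotype string:

```bash
$ meioseq karyotype "sseq cht(2,16,18)x4"
{
  "X": 2, "1": 2, "2": 4, ...
}
```

The individual stages are also available as subcommands: `simulate`
(write a study directory), `call-cn` (one sample against a panel),
`classify` (a study directory to a cohort CSV), and `morphokinetics`
(an event-time CSV to group-comparison JSON).

### Python API

```python
from meioseq import (
    SimulationConfig, simulate_study, build_panel, call_profile,
    designate_pair, classify_sample,
)

study = simulate_study(SimulationConfig(), seed=7)
panel = build_panel([study.panel], study.binning)
egg, pb = study.sample_pairs[0]
egg_cn = call_profile(egg, panel, study.binning).observed_cn
pb_cn = call_profile(pb, panel, study.binning).observed_cn
calls = designate_pair(
    {c: v for c, v in egg_cn.items() if c != "Y"},
    {c: v for c, v in pb_cn.items() if c != "Y"},
    rescale=True,
)
print(classify_sample(calls).egg_karyotype)   # e.g. "sseq euploid"
```

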