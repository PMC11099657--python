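# Methods

This note describes the statistical and computational model implemented
by `meioseq`: the genome binning, the copy-number calling rules, the
conservation-constrained reciprocal designation, the karyotype
nomenclature, the morphokinetic statistics, and the synthetic-data
generator with the rationale for its default parameters.

## 1. Genome model

The genome is tiled into fixed, gap-free, non-overlapping windows of
10 Mb (configurable). Each chromosome is tiled independently from
position 0; the terminal window is shortened to the chromosome end, so
every base belongs to exactly one bin. Mouse GRCm39 chromosome lengths
(19 autosomes, X, Y) are bundled; any other genome can be supplied as a
two-column `name<TAB>length` TSV. Chromosomes are kept in the canonical
order 1–19, X, Y. The default tiling yields 285 bins.

Oocyte-derived cells (MII egg and PB1) carry no Y; Y bins are used for
the male reference panel but excluded from egg/PB designation.

## 2. Copy-number calling

Calling one sample against the reference panel proceeds in five steps:

1. **Sample QC.** A sample whose mapped-read fraction is below 0.90
   fails QC; a missing mapped fraction is *indeterminate* (also not
   analyzable). Failed pairs are excluded and logged, never silently
   dropped.
2. **Bin masking.** Bins whose raw count exceeds 1,000 are masked as
   overrepresented (a count of exactly 1,000 is kept). These bins are
   removed from all later arithmetic for that sample.
3. **Normalization.** Counts are scaled so the unmasked autosomal bins
   total 1,000,000. The scale is anchored on autosomes only but applied
   to all unmasked bins (including X), so sex-chromosome dosage is read
   on the same footing. Masked bins come back NaN.
4. **Fold change.** Each normalized bin is divided by the corresponding
   bin of the normalized reference panel — the mean of one or more
   normalized euploid male (40,XY) samples. Bins with zero panel signal
   are masked with reason `zero-panel`.
5. **Observed copy number.** Per chromosome, the median of its unmasked
   bin fold changes, multiplied by the panel's copy count: × 2 for
   autosomes, × 1 for X and Y (the male panel carries one of each). A
   chromosome with no unmasked bins is reported *undefined*, not 0.

The median over ~5–20 bins per chromosome makes the call robust to a
few noisy bins (notably short terminal bins, whose expected counts are
small and whose individual fold changes are therefore wide).

## 3. Reciprocal designation and classification

For each chromosome of a matched egg/PB1 pair, the four chromatids must
partition as egg + pb = 4. Designation therefore searches the five
integer partitions (0,4) … (4,0) for the one minimizing the Euclidean
distance to the observed pair (egg_cn, pb_cn):

- residual ≤ 0.5: the nearest partition is assigned;
- residual > 0.5: the chromosome is flagged **discordant** and excluded
  from error counting (a conservative refusal, not a call);
- exact ties are resolved toward the partition closest to euploid
  (ties are in fact geometrically unreachable at tolerance 0.5: the
  bisector between adjacent partitions never comes within 0.707 of
  either, so the rule only matters for widened tolerances).

**Pair rescaling.** Within-sample normalization fixes each sample's
total, not its scale per chromatid: a near-empty egg spreads its
1,000,000 counts over few chromosomes, so its observed values are
inflated by a common factor (and the factor differs between egg and
PB). Observed values are therefore modelled as `a·egg_obs ≈ egg_cht`,
`b·pb_obs ≈ pb_cht` with chromatid conservation `egg_cht + pb_cht = 4`,
and (a, b) is obtained in closed form from the ridge-regularized least
squares

    min_{a,b} Σ_c (a·egg_obs_c + b·pb_obs_c − 4)² + λ·n·((a−1)² + (b−1)²)

with λ = 0.05. The data term pins the well-identified combination of
scales; the ridge resolves the direction left unidentified when one
side is nearly empty, defaulting both scales to 1 for ordinary pairs
(for an exactly euploid pair the fit returns a = b = 1). Rescaling is
applied by the pipeline before designation; `designate_pair` itself
takes it as an option (`rescale=True`).

Per-chromosome labels follow the designated partition: (2,2) euploid,
(3,1)/(1,3) **PSSC** (premature sister-chromatid separation — one
sister travels with the wrong cell), (4,0)/(0,4) **NDJ**
(non-disjunction of the whole bivalent). Per pair, the aneuploidy type
is NDJ, PSSC, or NDJ+PSSC according to which labels occur, the error
count is the number of non-(2,2) chromosomes, and the severity class is
euploid / 1–3 errors / ≥4 errors. Discordant chromosomes are tallied
separately.

## 4. Karyotype nomenclature

A sample's chromatid copy numbers are rendered as `sseq` strings:
comma-separated clauses `cht(<chromosomes>)x<copies>` listing all
chromosomes at each non-2 copy number, e.g.

    sseq cht(2,16,18)x4, cht(5-9)x0

Rules: X is listed first within a clause, then autosomes ascending;
runs of three or more consecutive autosomes collapse to `a-b` while
runs of two stay explicit; clauses are ordered by their lowest
chromosome (X counting lowest); a fully euploid sample is written
`sseq euploid`. The parser accepts whitespace variations, validates
copy numbers (0–4), chromosome names, range direction, and duplicate
mentions, and reports the offending position in `KaryotypeParseError`.
Write→parse round-trips are exact for every configuration.

## 5. Morphokinetics

Event times are hours from imaging start (t0 = 0): `tGVBD` (germinal
vesicle breakdown), `tPB1` (completed first-polar-body extrusion), and
`dMI = tPB1 − tGVBD` computed exactly. Status is GV (no GVBD),
GVBD-only (no PB1), or MII; records with tPB1 ≤ tGVBD are flagged
`invalid-annotation` and their dMI withheld.

**Outlier screen.** An iterated two-sided Grubbs test at α = 0.05:
while G = max|x − mean|/SD exceeds the critical value
G_crit = ((n−1)/√n)·√(t²/(n−2+t²)), t the upper α/(2n) t-quantile with
n−2 df, the most extreme point is removed. Groups with n < 3 or zero
spread are left untouched. The implementation reproduces published
critical values (1.715 at n = 5, 2.290 at n = 10) and holds its type-I
rate at ≈ α on null simulations.

**Group comparisons** follow a fixed gate. Shapiro–Wilk per group at
α = 0.05 (groups with n < 3 are treated as normal — the test is
undefined there); all groups normal and exactly two → Student's t;
all normal and more → one-way ANOVA with Tukey's HSD; any non-normal
group → Kruskal–Wallis with Dunn's pairwise comparisons (midranks,
tie-corrected variance, Bonferroni adjustment — implemented in-package
because no maintained implementation is available in the dependency
set). Groups reduced below two observations are dropped with a note.

**Maturation rates.** The group × stage (GV / GVBD-only / MII)
contingency table is tested with Fisher's exact test when it is 2×2
with any expected cell < 5, otherwise with the chi-square test (flagged
when expected cells are small).

## 6. Synthetic-data generator

A study draws, per treatment group, a configured number of egg/PB pairs
plus immature (GV, GVBD-only) oocytes.

**Segregation truth.** With probability `p_cat` a pair suffers a
catastrophic whole-complement event: all chromosomes segregate to one
cell except 1–4 exception autosomes that travel the other way as a full
bivalent (probability 0.4), a 3-chromatid PSSC pattern (0.5), or a
single chromatid (0.1); X always stays with the bulk. Otherwise each
chromosome independently errs with probability `p_err`; an error is NDJ
with probability `q_ndj` (else PSSC) and favours the egg with
probability 0.5. Every configuration satisfies egg + pb = 4.

**Read counts.** Expected bin counts are width × bias × copies/2,
scaled so a cell of diploid DNA content yields `depth` reads in total —
a near-empty egg yields proportionally fewer reads rather than
concentrating a full library on its remaining chromosomes, matching the
physics of whole-genome amplification from less template. Bin biases
are shared across all samples of a study (log-normal, σ = 0.1 by
default), mimicking mappability/GC structure that the panel largely
divides out. Counts are negative-binomial with size `nb_size`
(`None` = deterministic expectations, used by the noiseless oracles).
Overrepresented-bin artifacts and sub-threshold mapped fractions can be
injected at configurable rates. Reproducibility: the study seed spawns
independent child streams (biases, segregation, panel, counts,
morphokinetics), so each component is stable against changes in the
others' draw counts.

**Morphokinetics.** Timings are drawn per ploidy class from normal
distributions whose per-oocyte SD is reconstructed as SEM·√n from the
published class summaries, rejection-sampled to satisfy
0 < tGVBD < tPB1; dMI is the exact difference.

### Default parameters and calibration

| Parameter | Default | Rationale |
|---|---|---|
| `window_size` | 10 Mb | assay bin width |
| group sizes | 11 / 13 / 23 | reference study design (control / 25 nM / 50 nM) |
| `p_err` (25 nM) | 0.0040 | solves 1 − (1−p)²⁰ = 7.69%, the observed incidence |
| `p_err` (50 nM) | 0.067 | matches 12/16 aneuploid among non-catastrophic pairs |
| `p_cat` (50 nM) | 0.304 | 7 of 23 pairs showed whole-complement events |
| `q_ndj` | 0.935 | 29 of 31 tabulated errors were NDJ |
| `depth` | 100,000 | shallow-WGS scale; ~37 reads/Mb keeps bins far from the 1,000 mask |
| `nb_size` | 200 | per-bin CV ≈ 9% at default depth — a working assay; panel noise is shared across all fold changes of a study, so much larger dispersions shift whole chromosomes coherently |
| `bias_sigma` | 0.1 | moderate shared bin-level structure, removed by the panel |
| `p_qc_fail` | 0.02 | occasional failed libraries exercise the n-accounting |
| timing classes | means/SEMs per ploidy class | published class-conditional summaries (e.g. euploid dMI 8.27 h, ≥4-error class 12.85 h) |

With these defaults the end-to-end pipeline recovers simulated
designations essentially perfectly (0–1 conservative discordant flags
per 940 chromosome calls across seeds), and the noiseless configuration
recovers 100% exactly; both are enforced by the test suite, along with
designation-vs-enumeration equivalence on 10,000 random observations
and the statistical properties in §5.

### Limitations

- Bins are independent in the simulator; real shallow-WGS has
  autocorrelated coverage (GC waves), which the shared-bias term only
  approximates.
- Mosaicism and segmental (sub-chromosomal) aneuploidy are out of
  scope: calls are whole-chromosome integers.
- The discordance tolerance (0.5) and bin mask (>1,000) are the assay's
  published operating points, not re-derived optima.
- Fisher's exact test is applied only to 2×2 tables; larger tables with
  small expected cells fall back to chi-square with a warning note
  rather than an exact network algorithm.
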