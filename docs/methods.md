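# Methods

`immunoflux` re-implements, as one tested pipeline, the computational
procedures of a multi-assay comparison of CD4+ T cells from young and old
donors: isobaric-tag (iTRAQ 8plex) proteomic ratio analysis, Z-ratio / PAGE
transcriptomic enrichment, high-resolution respirometry with the
Bioenergetic Health Index (BHI), TEM autophagy morphometry, and
mitophagy-dye flow-cytometry gating.  Every arm can be exercised on seeded
synthetic data whose statistical structure mirrors the original study
design, so each procedure is testable end to end without any deposited
dataset.

## Proteomics: reference-channel normalization and the filter cascade

**Model.**  Four 8plex runs quantify 4 young and 18 old cytoplasmic
extracts; one common reference sample occupies one channel of every plex,
and spare channels carry technical duplicates (one within-plex, the rest
between plexes).  Reporter intensities are treated as proportional to
abundance up to a per-plex batch factor and multiplicative measurement
noise.

**Normalization.**  Each channel is divided, protein by protein, by the
same-protein reference intensity of its own plex.  Because the reference is
the same physical sample everywhere, plex batch factors cancel exactly and
channels from different runs become commensurate; the reference column is
identically 1 afterwards, which makes the operation idempotent.  Proteins
missing from any plex, or with a zero reference intensity, are dropped with
a logged reason — the merge rule across runs is intersection, because a
protein without a reference anchor in some run cannot be placed on the
common scale.  Technical duplicates are averaged into their donor before
testing, so donors are the replication unit.

**Statistics.**  Per protein: group means of the normalized abundances,
their old/young ratio, and a two-tailed pooled-variance Student t
(equal-variance, matching the arm's original analysis choice).  The screen
then applies, in order: |fold| outside [0.7, 1.3]; p < 0.05; and evidence
(>= 2 unique peptides, high sequence confidence, ion score > 30).  The
stage order matters only for the per-stage counts the report carries; the
surviving set is the conjunction.  Thresholds are config fields
(`CascadeConfig`) so the defaults are auditable.

## Transcriptomics: Z-ratio and PAGE

Genes are first filtered on detection p-values (detected at p <= 0.02 in at
least half the samples; thresholds configurable — a common BeadArray
convention, since the source pipeline does not state its values).  Each
sample is then Z-transformed over its genes (array-wise standardization),
which removes per-sample location/scale so arrays are comparable.

Per gene, the **Z-ratio** is the old-minus-young difference of group-mean
Z-scores divided by the standard deviation of those per-gene differences
across genes; by construction the Z-ratio vector has unit spread.  Genes
are called changed at |Z-ratio| >= 1.5, p <= 0.05 (two-sample Student t on
the Z values; the original tool's exact per-gene test is unspecified) and
Benjamini–Hochberg FDR <= 0.3.  BH was chosen because the source names only
"FDR" without a procedure; it is the standard step-up control in microarray
work and is exposed as a configurable choice.

**PAGE** scores a gene set of size m against the all-gene score
distribution: Z = (S_m − μ)·√m / δ, with S_m the mean score of set members
and μ, δ the mean and sd of all scores; two-sided p from the standard
normal.  The normal approximation is trusted for m >= 10 (default);
smaller sets are scored but flagged.  For the **pathway contrast**, PAGE
scores are computed per donor (each donor's Z-profile is a score vector),
averaged within age group, and ranked by the young-minus-old difference;
per-set p-values compare the per-donor scores between groups with a
Student t, and the top-K (default 50) passing p <= 0.05 and FDR <= 0.3 in
each direction are selected.  Computing per donor then averaging (rather
than one pooled group profile) keeps donors the unit of replication and
lets the same scores feed the per-set test.

A note on calibration: for a set drawn without replacement from a finite
universe, the exact variance of S_m carries a finite-population factor
(N−m)/(N−1) that PAGE's Z ignores; for the set sizes used here (m <= 50,
N >= 5000) the inflation is below 0.5% and the null significant-set rate
stays within Monte-Carlo error of nominal.  Similarly, a planted shift of
+1δ on m of N genes contaminates μ and δ, so the exact expected Z is
(1 − m/N)·√m/δ′, slightly below the naive √m (about 10% for m/N = 0.1).

## Respirometry: coupling-control fluxes and the BHI

**Flux.**  The oxygraph trace is O2 concentration (nmol/mL) in a closed
2 mL chamber holding 5×10⁶ cells.  Oxygen flux is the negative slope of a
centered sliding least-squares fit (default 30 s window), scaled to
pmol O2·s⁻¹ per 10⁶ cells: flux = −slope × volume × 1000 / (cells/10⁶).

**States.**  The coupling-control protocol yields ROUTINE (before
oligomycin), LEAK (after ATP-synthase inhibition), ETS (maximal uncoupled
capacity — the *maximum* over the per-FCCP-step plateaus, because the
uncoupler is titrated through its optimum) and ROX (residual consumption
after rotenone + antimycin A).  Each state is the *median* flux in its
window after trimming a 60 s settle period past each injection; the median
resists the injection transients, and the settle default comfortably covers
the slope-window half-width.  The expected ordering ETS >= ROUTINE >= LEAK
>= ROX is checked and violations flagged, not fatal.

**Profile.**  ATP-linked = ROUTINE − LEAK; proton leak = LEAK − ROX;
reserve capacity = ETS − ROUTINE; non-mitochondrial = ROX.  ROX is
subtracted only where a component is defined relative to mitochondrial
respiration; ATP-linked and reserve use the raw ROUTINE/ETS differences,
matching the component definitions the index names.  Then

    BHI = log10[(reserve × ATP-linked) / (non-mitochondrial × proton leak)],

base 10 by convention for this index (configurable).  BHI is dimensionless
and invariant to any common rescaling of the four components (hence to
calibration of the oxygen signal); it is undefined (NaN, flagged) if any
component is non-positive.

**Cohort comparison.**  Because the memory/naive composition of the CD4
pool differs between donors and memory cells respire differently, the
young/old BHI comparison is adjusted for the percentage of memory cells by
OLS: bhi = β0 + β1·[old] + β2·memory_pct.  Adjusted group means are the
fitted values at the grand-mean memory percentage; the group p is the t of
β1.  Regression adjustment was chosen over stratification because the
cohort is small and memory_pct continuous.  Donors with an atypical memory
fraction are flagged when |memory_pct − median| > 1.5 × IQR, both computed
over the whole cohort: a single aberrant donor is most visible against all
remaining samples, and a group-scoped Tukey fence (Q3 + 1.5·IQR) fails to
flag the canonical case of one 59% donor among a 26–48% cohort (the fence
lands near 66–70%).  Flagged donors are never silently excluded — the
adjusted analysis is reported both with and without them.  Welch tests
(unequal variance) compare BHI, non-mitochondrial respiration and reserve
capacity between groups, as appropriate for small groups with unequal
spread.

## Morphometry: AP/AL rule table and per-cell summaries

A vesicle (minimum diameter 0.5 µm, configurable; smaller structures are
left unclassified) is an **autophagosome (AP)** when at least two of four
criteria hold: a double membrane (complete or partial, operationalized as
double-membrane fraction > 0), no ribosomes on the cytosolic face, luminal
density similar to cytosol, identifiable organelle content.  A non-AP
vesicle is an **autolysosome (AL)** when its membrane is single or < 40%
double and its lumen is either more lucent than cytosol or consists of
multiple single-membrane inner vesicles with light or dense amorphous
content.  Everything else is `unclassified` — a valid outcome, reported but
excluded from AV counts, since the criteria do not cover every structure.
The rule table is deterministic and total, and is verified exhaustively
against an independently written decision list over the discretized feature
space.

Per cell: AP/AL/AV counts (AV = AP + AL), maturation = 100·AL/AV (undefined
for AV-free cells and excluded from maturation averages), mitochondrion
count and mean area (arbitrary units; no nm calibration is attempted), AP
area and AP area as % of cytosol.  Comparisons are two-tailed Student
t-tests with cells (TEM images) as replicates, matching the per-image
design of the original figures; donor-level aggregation is available as an
option.  Contrasts: naive vs memory within each age group, and young vs
old within each subset; means ± SEM are reported for plotting parity.

## Mitophagy flux: lo/int/hi gating

The dye is mitochondria-targeted and pH-sensitive: cytosolic mitochondria
fluoresce dimly, mitochondria inside not-yet-acidified autophagic
compartments at intermediate intensity, and mitochondria in acidified
autolysosomes brightly.  One gate pair is shared by all samples of an
experiment (the design compares fixed regions across samples): the lo/int
boundary is the 0.99 quantile of the unstained (autofluorescence)
distribution and the int/hi boundary the 0.90 quantile of the pooled young
dye-only distribution; both quantiles are configurable and explicit values
override derivation.  The absolute boundary values are design choices — no
published numeric boundaries exist — so only relative/qualitative contrasts
are meaningful.  Binning is half-open (lo: x < g1; int: g1 <= x < g2; hi:
x >= g2), percentages sum to 100 exactly, and fractions are invariant under
any strictly monotone transform applied to events and gates together
(so linear-vs-log display is purely cosmetic).  Intensities are analyzed on
the raw scale.  Contrasts: young vs old per bin per condition (Student,
unpaired across donors) and, within each age group, CCCP vs dye-only and
bafilomycin A1 vs dye-only paired by donor.

## Synthetic-data generators

Each generator is a pure function of (config, seed) built on
`numpy.random.default_rng([seed, stream])`; identical inputs give identical
outputs, and every generator returns a ground-truth sidecar sufficient to
score recovery.  Default group sizes mirror the study: proteomics 4 young /
18 old over four 8plexes with a shared reference and six technical-duplicate
channels; expression 8 young (5 M / 3 F) / 25 old (19 M / 6 F);
respirometry 7 / 7; TEM 5 / 4 donors with 15 / 12 images per stratum; flow
12 / 12 donors at 20,000 events per sample.  Default effect *directions*
mirror the study's findings; effect *magnitudes* are unpublished, so they
are config knobs with documented defaults chosen as plausible for the
assay:

- **Proteomics**: log-normal intensities (CV 10%), per-plex batch factors,
  60 of 600 proteins ("MITO…" accessions) multiplied by 1.5 in old
  channels; evidence drawn so 5% of planted and 30% of null proteins fail
  the evidence stage.
- **Expression**: Gaussian log-signals (gene spread 1.5, sample noise 0.3);
  three disjoint 30-gene OXPHOS sets shifted by −0.5 array-Z units in old
  samples; 40 random null sets; 10% of non-set genes are dropouts with high
  detection p everywhere.
- **Respirometry**: piecewise-linear O2 decline whose segment slopes encode
  the donor's true state fluxes (young means 50/12/130/6, old 45/14/90/10
  pmol·s⁻¹·10⁻⁶ cells — lower reserve and higher ROX in old), 10%
  between-donor CV, FCCP titration plateaus at 75/100/90% of ETS, Gaussian
  concentration noise (sd = 1% of the donor's ROUTINE flux) plus small
  decaying post-injection transients; memory percentages N(30, 6) young
  and N(40, 6) old.
- **Morphometry**: Poisson counts per stratum (AP inflated in old: naive
  2 young vs 6 old; AL equal at 2; mitochondria higher in memory),
  log-normal areas, vesicle features drawn consistent with the intended
  class except for a 2% scrambled fraction (planted-label recovery stays
  above 95%).  AL feature draws never combine a partial double membrane
  with a ribosome-free face, which would legitimately satisfy two AP
  criteria.
- **Flow**: three-component log-normal mixtures (medians 30 / 300 / 3000
  a.u., σ_ln 0.5); dye-only intermediate weight N(0.20, 0.06) young vs
  N(0.35, 0.06) old with a fixed 0.10 high weight; CCCP moves 60% of lo+int
  mass to hi and bafilomycin moves 50% of lo and hi mass to int, both
  applied to the donor's own dye-only weights so the drug direction holds
  within every donor.  The unstained sample is pure low-component
  autofluorescence, which is what places the derived lo/int gate between
  the lo and int mixture components.

**What the generators do not emulate** — and hence what passing tests do
not establish about real data: peptide-level missingness and ratio
compression in isobaric quantification; probe-level effects and
batch/hybridization structure in arrays; oxygen back-diffusion, sensor
drift and chemical side-reactions in respirometry; segmentation error and
observer variability in TEM annotation; spectral spillover, debris and
doublets in cytometry.  The tests demonstrate that the *procedures* are
implemented correctly and have the claimed statistical behaviour under
their stated noise models, not that those models capture every property of
the instruments.

## Numerical choices and scaling

- Sliding-window slopes use exact least squares via cumulative sums
  (O(n) for the whole trace); plateau estimates are medians over the
  trimmed windows.
- Zero-variance two-sample comparisons raise a typed
  `DegenerateDataError` rather than returning NaN; the two matrix-wide
  screens (per-gene tests, bin contrasts) map the identical-constant case
  to p = 1 instead, because a flat feature in a screen carries no evidence
  and aborting the whole table would be unhelpful.
- Ratios are reported at 4 decimals in outputs to match the published
  table's presentation; internal precision is full.
- Problem sizes in the test-suite and acceptance computations (600
  proteins, 2,000 genes, 51 recovery traces, 5,000-event power-simulation
  samples, 400 Monte-Carlo seeds for the count-power rate) were chosen to
  keep each check well-resolved while the full suite runs in well under a
  minute; all are config parameters.
- Detection-power checks use more Monte-Carlo replicates than the minimum
  the acceptance bands name (400 instead of 100 where the underlying power
  is close to the band edge): this narrows the Monte-Carlo error of the
  estimated rate without changing the quantity or the threshold.

## Known limitations

- The evidence screen consumes per-protein summaries (unique peptides,
  confidence, ion score); peptide-level inference is out of scope.
- PAGE is the only enrichment method; permutation-based GSEA is
  deliberately not implemented.
- Gate boundaries and the detection-filter thresholds are conventions, not
  published values; quantitative bin percentages are therefore not
  comparable to the original figures, only directions and contrasts are.
- The memory-fraction outlier rule is a robust screen, not a formal test;
  with ~14 donors its false-flag probability is non-negligible, which is
  why flagged analyses are reported alongside, never substituted.
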