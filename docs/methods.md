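# Methods

## Data model

A *signature* is a vector of moderated z-scores over 978 landmark genes,
summarizing differential expression of a perturbed sample against its plate
controls (Level-5 style, replicates already collapsed). Signatures travel as
GCT 1.3 text or GCTX HDF5 matrices (genes × signatures; the GCTX layout uses
the `0/DATA/0/matrix` dataset stored signature-major with `0/META/ROW/id` /
`0/META/COL/id` identifier vectors). Metadata travels as a TSV shaped like
the GEO `sig_info` tables; the reader takes a configurable field-name
dialect, defaulting to those names, so synthetic fixtures and repository
files go through one code path.

Canonicalization on ingest:

- **Dose** → micromolar. Recognized units: nM (÷1000), uM/µM/μM (×1),
  mM (×1000). The repository sentinel `-666`, empty, non-positive and
  non-numeric values, and unrecognized units all map to *missing* (with a
  logged warning for unrecognized units); dose parsing never raises.
- **Time** → hours; a trailing `h` is stripped; non-numeric time drops the
  row (with a logged count), since every analysis conditions on time.
- **Perturbation category** → the closed six-value set {control, ligand,
  poscon, compound, overexpression, shRNA} from the standard `pert_type`
  codes (`trt_cp` → compound, `ctl_vehicle` → control, …). Unknown codes map
  to a distinct `unknown` value and the row is dropped, never silently
  binned.
- Duplicate `sig_id` rows keep the first occurrence; the drop count is
  logged.

## Layer 1 — metadata summaries

Profile counts per cell line are sorted by descending count with
lexicographic tie-break, so results are invariant to input row order.
"Highly profiled" selection uses a strict inequality (count > 20,000 by
default): a cell line exactly at the threshold is excluded. Replicate, dose-
and time-multiplicity distributions use a capped histogram: integer bins
1..cap−1 plus a pooled `cap+` bucket (default cap 9, i.e. "9 or more").
Dose multiplicity counts *distinct canonical µM values* per (cell,
perturbagen) pair, so 500 nM and 0.5 µM are one dose; time multiplicity
counts distinct time points per perturbagen.

## Layer 2 — DEG activity

A gene is a DEG when z > `z_hi` (up) or z < `z_lo` (down); defaults +2.0 /
−2.0, strict, so a value of exactly ±2.0 is not significant. NaN z-scores
are excluded from both counts rather than failing the signature. The
analysis set is, by default, compound signatures in the selected cell lines
at 6, 24 and 48 h.

Cumulative categories count profiles with at least k DEGs for
k ∈ {1, 50, 100} (configurable). A distinct small molecule (`pert_id`) is in
category ≥k when *any* of its signatures reaches k — equivalently when the
maximum DEG total over its signatures reaches k; both spellings are exposed
and coincide. "None" counts profiles with zero DEGs, and molecules all of
whose signatures have zero DEGs, so none + ≥1 equals the total for profiles
*and* for molecules in this package's output. (Published compendium
summaries of this kind do not always satisfy the molecule identity, since a
molecule can be counted once as inactive and once as active under other
conventions; we keep the partition exact and note the difference rather than
reconcile it.)

Dose groups split at 5 µM, boundary inclusive to low, so all nanomolar
doses are low. Dose-stratified analyses exclude dose-missing records
(genetic perturbations and controls have no dose) and log the excluded
count. Direction calls (`behavior_direction`) compare one category's count
across two ordered levels with an integer tolerance (default 0): increasing,
decreasing, unchanged on ties, or not-evaluable when a level is absent.

## Change fractions and segment geometry

For a cell line and a contrast with levels A and B, f_X50 and f_X100 are
the ≥50 and ≥100 counts divided by a ≥1 denominator. Two conventions:

- **stratum** (default): each level is normalized by its own ≥1 count.
  All fractions lie in [0, 1] and f100 ≤ f50 within each level; this is the
  convention under which reported percentages stay below 100%.
- **as_printed**: all four fractions share the A-level ≥1 denominator, the
  literal reading of the defining ratios; f_B can then exceed 1. Both are
  kept because the two readings genuinely differ and the intended one is
  ambiguous; the default follows the bounded-percentage behavior.

Segments are coded over abscissa A=0 → B=1, so slope = f_B − f_A; any
affine recoding of the abscissa rescales both slopes equally and leaves
classifications unchanged. A dose-contrast segment and a time-contrast
segment at the same category level are classified as **intersecting** when
the endpoint differences change sign ((p_A−q_A)(p_B−q_B) < 0), else
**parallel** when |slope(p) − slope(q)| ≤ `slope_tol`, else **neither**
(emitted rather than forcing a binary call when the two tests disagree).
The reporting default `slope_tol = 0.02` (absolute, on fractions) is
appropriate for compendium-scale strata where fraction standard errors are
well below 0.01.

## Synthetic generator

The generator emulates the *statistical* setting of a Level-5 compendium,
not its biology: per cell line it draws categories from a configurable mix,
(dose, time) conditions for compounds from either independent uniform levels
or an explicit joint weight table, replicate counts from a configurable
distribution (default mass on 2–4, ~1% at 9+), and z-scores as N(0, 1)
noise plus planted effects. Each compound signature receives a hit-gene set
of drawn size whose z-scores are shifted by ±µ (signs 50/50, since up- and
down-regulation are counted symmetrically), with

    µ = base_effect · g(dose) · h(time)

and monotone multipliers g, h per the configured response direction: flat
= 1, increasing = level/max(levels), decreasing = min(levels)/level —
deliberately simple monotone forms, since only the direction is asserted.
An explicit per-condition effect table can override g·h for designed
experiments. Defaults: nine cell lines named after the deeply profiled
lines of the phase-I compendium, doses {0.1, 1, 5, 10} µM, times
{6, 24, 48} h, 978 genes, noise SD 1 — small enough to simulate in seconds
yet structurally faithful.

What the generator does **not** emulate: gene–gene correlation, plate and
batch effects, replicate-number effects on z-score moderation,
heavy-tailed real z-score distributions, shared molecules across cell
lines, and molecule-level (rather than signature-level) hit identity.
Passing tests therefore certify the counting, stratification and geometry
machinery — not robustness to real-data artifacts.

Randomness: one named RNG stream per purpose (metadata, signatures),
`numpy` `default_rng([seed, stream])`, so tables and matrices are bitwise
reproducible for a given seed across platforms.

### Analytic oracles

With p₀ = 2Φ(−2) ≈ 0.0455 and q(µ) = Φ(µ−2) + Φ(−µ−2), the DEG count of a
signature with m hits is Binom(m, q(µ)) + Binom(978−m, p₀); its pmf is
computed exactly by convolution, giving closed-form expectations (null mean
978·p₀ = 44.50) and tail probabilities P(DEG ≥ k) for every stratum mixture.
`mu_for_tail_probability` inverts the tail by bisection (80 iterations on
µ ∈ [0, 12]), which is how designed experiments calibrate effect sizes to
target population fractions.

## Designed recovery experiments (`lincscope.experiments`)

- **Direction recovery**: one compound-only cell line, doses {1, 10} µM,
  times {6, 24} h, 150 hits per signature, base effect µ₀ = 3, 1,000
  signatures per dose stratum; the ≥100-category direction across dose
  groups and across 6/24 h is compared to the planted monotone direction.
- **Geometry recovery**: explicit per-condition effects calibrated with the
  exact oracle so the population ≥50 fractions hit pre-chosen values.
  *Intersecting*: a pure dose effect (fractions 0.25 → 0.75) with uniform
  weights makes the time segment flat at the grand mean, which the dose
  segment must cross. *Parallel*: additive fraction offsets (dose +0.30,
  time +0.345) combined with a skewed joint condition-weight table
  (w(1 µM, 6 h) = 0.01, w(1 µM, 24 h) = 0.59, w(10 µM, 6 h) = w(10 µM,
  24 h) = 0.20) separate the two segments by ≈0.05 at both endpoints with
  equal population slopes — with balanced weights the two marginalized
  segments of a 2×2 design always share their midpoint and *must* cross, so
  skewed weights are the only way to plant genuinely parallel geometry.
  4,000 signatures per replicate put the endpoint standard errors near
  0.01–0.02, i.e. ≥2.5 standard errors inside the planted margins.
  The experiments classify with `slope_tol = 0.1` rather than the reporting
  default 0.02 because a finite-replicate slope difference has a standard
  error near 0.03 at this size; 0.1 ≈ three standard errors distinguishes
  the planted slope difference (~0.002) from sampling noise. The population
  geometry of each configuration is itself checked against the analytic
  fractions, so the planted label never relies on simulation.

## Numerical and design choices

- Strict thresholds everywhere the contract says "more than" / "> 2.0":
  profile-count selection, z thresholds, dose-group boundary to low.
- Ties in ordered outputs break lexicographically after count, making every
  table order-deterministic.
- Zero ≥1 denominators in change fractions raise a named error rather than
  emitting NaN; cells missing a contrast appear in the report with explicit
  `not_evaluable` markers.
- GCT text serializes floats with `repr` (shortest round-trip
  representation), so a text round-trip is exact for float64 values; GCTX
  stores binary float64.
- The pipeline writes a JSON manifest of every parameter and seed;
  `PipelineConfig(**manifest["parameters"])` reruns the analysis with
  byte-identical tables.
- Default pipeline problem sizes (nine cell lines × 222 signatures;
  10,000-signature null batches; 100-replicate recovery experiments at
  2,000–4,000 signatures each) keep a full run on one CPU in the minutes
  range while leaving binomial standard errors far below the tested margins.

## Limitations

- Accession-scale headline counts (hundreds of thousands of profiles) are
  only reproducible against the real repository files; this package
  validates the machinery on synthetic data and accepts real GCT/GCTX +
  `sig_info` inputs, but ships no downloader.
- Quality-control flags of real signature metadata are passed through, not
  interpreted; the analysis-set filter is configurable so any QC convention
  can be expressed upstream.
- Only the 978 landmark genes are considered; inferred (non-landmark)
  transcripts are out of scope.
- The molecule-level category counts assume signature-level hit planting;
  molecule-coherent effects would need a molecule-keyed effect table.
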