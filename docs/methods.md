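# Methods

## Scope and data model

`sipgrad` analyses DNA-SIP experiments in which an amended (¹³C substrate)
and an unamended control incubation are each fractionated on a CsCl
gradient into ten fractions collected bottom-first, so fraction 1 is the
heaviest. Inputs are taxa × samples relative-abundance tables (TSV/CSV;
counts are renormalized on read and the depths kept) plus a sample
metadata table linking each column to a treatment, control treatment,
fraction index, CsCl density, batch and timepoint. Amended and control
gradients are paired **by fraction index**, not by density: the gradients
are run in parallel and collected position-wise, and residual density
differences between CsCl batches are handled by the batch normalization
step instead. Relative abundances are stored as proportions in [0, 1];
the conventional percent thresholds are converted once at the boundary
(0.1 % → 1e-3, 0.0001 % → 1e-6).

## Density profiles and mean density

For each taxon the amended/control abundance ratio SA is computed per
retained fraction, normalized across fractions to fSA (Σ fSA = 1), and
summarized as the fSA-weighted mean CsCl density. Numerical conventions:

* **End-fraction exclusion.** Fractions 1 and 10 are dropped before any
  profile computation (configurable); in a real gradient they are mixed
  with CsCl or overlay water and carry almost no DNA. At least three
  fractions must remain.
* **Zero-control pseudo-abundance.** Where the control abundance is zero,
  SA would be infinite; half the smallest nonzero control abundance in
  that gradient is substituted and the event logged. This preserves rank
  structure while keeping SA finite. Configurable.
* **Batch density normalization.** Each CsCl batch's reference is the
  measured density of its whole unfractionated sample (mean when several
  exist). All fraction densities in a batch are shifted by the difference
  between the cross-batch mean reference and the batch's own reference,
  which preserves within-gradient ordering. Unfractionated samples may
  therefore carry a density value in the metadata; it is required only
  for fractionated samples.
* Mean density always lies within the range of the retained fraction
  densities, and is invariant to rescaling SA by any positive constant.

## Incorporator calling

Three criteria, all strict inequalities (boundary equality fails):

1. **Detection** — amended-gradient abundance > 1e-6 in ≥ 3 retained
   fractions.
2. **Prevalence** — abundance > 1e-3 in the amended *or* control
   unfractionated community.
3. **Pattern** — the log₂(SA) range across fractions exceeds 0.53
   (≈ 2·log₂(1.2), the range produced by ±20 % labeling, the practical
   detection limit of density separation) *and* the profile shape is that
   of a labeled population.

The shape rules are quantitative surrogates for what is conventionally a
visual call, chosen to be monotone-respecting and reproducible:

* **well_labeled** — Spearman correlation of log₂(SA) against density
  ≥ +0.6 and the profile maximum lies in the heavy half (density ≥ median
  retained density; ties count as heavy).
* **partially_labeled** — both terminal thirds of the profile (heaviest
  and lightest fractions) lie at least 0.53/2 above the interior minimum.
  *Every* fraction of each terminal third must be elevated, not just one:
  in near-empty heavy fractions a single stray read against a
  pseudo-count denominator can spike one value, and requiring the whole
  third suppresses these false V shapes without touching genuine bimodal
  profiles.
* **unlabeled** — range ≤ 0.53, or Spearman ≤ −0.6 (abundance draining
  toward the light end, the compositional signature of an unlabeled taxon
  when other taxa move heavy).
* **ambiguous** — anything else. Ambiguous and unlabeled patterns are
  never incorporators.

Non-finite log₂ values (taxon absent from a fraction) are ignored in the
range and shape statistics; fewer than three finite values yields an
ambiguous call. Cutoffs (±0.6, 0.53, margin 0.53/2) are configurable.
Input tables are assumed aggregated to the rank at which calls are wanted
(conventionally family); `tables_io.aggregate_taxa` collapses finer
tables.

In simulation, a partially labeled population whose control-normalized
ratio is a two-component Gaussian mixture produces a *monotone* log₂
profile (the mixture ratio is increasing in density), so such taxa
usually classify well_labeled rather than partially_labeled; a true V
additionally needs light-end elevation from compositional suppression.
Either class counts as an incorporator, so detection performance is
unaffected by where that boundary falls.

## The simulator

The generator emulates: GC-dependent unlabeled buoyant density
(ρ = 1.660 + 0.00098·GC %, a Schildkraut-type linear calibration),
a labeling shift of 0.036·a g mL⁻¹ at ¹³C atom fraction *a* (hence an
observed 0.010 g mL⁻¹ shift ↔ ≈ 28 % incorporation), within-taxon
Gaussian smearing (`smear_sd`), partial labeling as a two-component
mixture weighted by the labeled cell fraction, equal-width density bins
ordered heavy→light with out-of-span mass assigned to the terminal
fractions (mimicking the mixed end fractions the analysis excludes), and
multinomial read sampling per fraction at fixed depth — amplicon
sequencing yields a fixed read budget regardless of how little DNA a
fraction holds, which is exactly why near-empty fractions are
compositionally noisy. A fraction containing no DNA at all returns
uniform read probabilities. Unfractionated samples are multinomial draws
from the growth-weighted community. Control treatments use atom fraction
zero and per-taxon control growth factors. Taxa are processed in sorted
name order, making output invariant to input ordering; a fixed seed gives
byte-identical tables.

The benchmark scenario (`demo_community`, `demo_gradient`) is a 20-taxon
marine community: six incorporators (atom fractions 0.3–1.0, labeled cell
fractions 0.6–1.0, growth 2–8×), two weakly/partially labeled edge cases
(including an abundant SAR11-like taxon at 25 % labeled cells), and
twelve unlabeled taxa including a bloom-former growing 12× in both
treatments (the classic false-positive trap) and low-GC oligotrophs
banding at the light edge. GC contents span 29–65 %. The gradient spans
1.685–1.755 g mL⁻¹ (`smear_sd` 0.008, bin width 0.007) so that the
retained fractions 2–9 all contain appreciable DNA, as in a real
fractionation; a wider span would leave heavy retained fractions DNA-free
and purely noisy. Default depth is 10⁵ reads per fraction.

What the simulator does **not** model: PCR and primer bias, 16S
copy-number variation, chimeras, cross-feeding of labeled metabolites,
trace-contamination smearing beyond the Gaussian term, and density-
gradient nonlinearity. Passing tests therefore demonstrate that the
criteria recover planted labeling under idealized sampling noise and
compositional distortion — not that they are robust to amplification
artifacts in real libraries.

Measured performance under these conditions (recomputed by
`scripts/acceptance.py` and the test suite, never asserted as constants):
mean sensitivity ≥ 0.9 for taxa with a ≥ 0.28 and ≥ 50 % labeled cells,
false-positive rate ≤ 0.1 for unlabeled taxa, over 10 seeded replicates.

## Community metrics

Z-scores standardize each taxon's relative abundance across all included
(unfractionated) samples using the sample standard deviation (ddof = 1,
conventional at these sample counts; configurable). Constant taxa get
z = 0 with a warning. Z-score changes (amended − control) are flagged at
|Δz| > 1. Bray-Curtis distances and average-linkage cut-height clustering
(default cut 0.70) are provided for community comparison; a dominant
taxon can be excluded, with the remaining proportions renormalized before
the distance computation. Ordination and permutation-based cluster
significance are out of scope.

## Growth and BGE

* Biovolume uses the rod formula at L/W ≥ 1.5 and the sphere below it;
  the two branches are discontinuous at 1.5, so a convention is needed
  and equality is assigned to the rod branch.
* Bacterial carbon: BC = BA·V·148 fg C μm⁻³, converted to μmol C L⁻¹ via
  12.011 g mol⁻¹.
* The specific growth rate is the least-squares slope of ln(BA) on time;
  without a user window, the contiguous ≥ 3-point window with the best R²
  (preferring positive slope, then longer windows) is selected.
* Stationary time is 2·t_mid from a least-squares logistic fit
  N(t) = K/(1 + ((K−N0)/N0)e^(−rt)), initialized from the series extrema
  and endpoint log-ratio. Declining or non-convergent series return an
  explicit no-fit result rather than raising.
* BGE integrates **BC production** (BC_t − BC_T0, clipped at 0) and DOC
  removal (DOC_T0 − DOC_t, clipped at 0) by the trapezoid rule over
  [T0, t_stationary], linearly interpolating at t_stationary when it is
  not a sampled timepoint, and divides each integral by the elapsed time.
  The baseline subtraction makes the numerator a production term,
  symmetric with the removal denominator; the shared time normalization
  cancels in the ratio. A total DOC change below the ~1 μmol C L⁻¹
  analytical resolution leaves BGE not resolvable (`None`) instead of
  reporting a meaningless ratio.
* Reported percentages (BGE, TDAA-C yield) are rounded half-up to
  integers; TDAA yield and the expected-DOC back-calculation
  (DOC = TDAA-C / yield) are mutual inverses up to that rounding.

## Reproducibility

Every stochastic routine takes an explicit seed (`numpy.random.
default_rng`); the CLI threads one seed through the whole run and writes
a manifest with the config hash. Problem sizes in the acceptance script —
10⁵ reads per fraction, 10 community replicates, a 5-level labeling
ladder, 100 logistic fits — were chosen as the smallest sizes at which
the Monte-Carlo error is well below the effect sizes being measured.
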