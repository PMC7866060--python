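# Methods

## The single-case deregulation model

Most case–control methylation analyses compare group means and therefore
miss rare, large, patient-private epigenetic events. `sevscan` implements
the complementary single-case strategy: every sample — each case and, in
turn, each control — is compared probe-by-probe against a reference range
built from the healthy-control cohort, and its private extreme outliers
are aggregated into candidate deregulated regions.

### Stochastic epigenetic variants (SEVs)

For each probe the controls define Tukey fences on the beta scale

    upper = Q3 + k·IQR        lower = Q1 − k·IQR        IQR = Q3 − Q1

with k = 3, the conventional "extreme outlier" multiplier. A sample's
beta-value strictly outside the fences is a stochastic epigenetic variant,
classified hyper-methylated (above the upper fence, above the control
median) or hypo-methylated (below the lower fence). Design points:

- **Quartile convention.** The formula leaves the quartile estimator open;
  we fix linear interpolation between order statistics (type 7, the numpy
  default) and expose it (`quartile_method`). The worked example in the
  test suite — controls {0.10, 0.12, 0.14, 0.16, 0.18} giving fences
  [0.00, 0.28] — assumes this convention.
- **Strict comparison.** A value exactly on a fence is not an outlier.
  With continuous data the choice is immaterial; it matters only for
  degenerate fences.
- **Degenerate IQR.** If the controls are constant the fences collapse and
  any deviation is an SEV. This is faithful to the formula; an optional
  `min_fence_halfwidth` (default 0, i.e. off) widens fences to at least
  median ± h for pathological synthetic inputs.
- **No leave-one-out.** One reference is built from all controls and every
  sample, controls included, is scored against it. Controls are therefore
  scored partly against themselves, which slightly depresses their SEV
  counts relative to cases (see *Calibration* below); a leave-one-out
  variant would remove this at the cost of per-sample references, and can
  be emulated by calling `reference_ranges` on control subsets.
- Probes whose fences cover all of [0, 1] can never fire; their fraction
  is reported (`saturated_fraction`) as a sanity metric of the reference.

### Sliding-window enrichment

Raw SEV lists mix clustered deregulations with isolated, likely spurious
calls. For each sample the scan walks the QC-retained probe universe in
manifest (chromosome, position) order. Around each central probe a window
of n consecutive probes (default 11) is tested for SEV over-representation
with the exact cumulative hypergeometric upper tail P(X ≥ x), where x is
the sample's SEVs in the window, K its genome-wide SEV count, and N the
universe size. The central probe is *retained* iff the window p-value is
below α (default 0.05, configurable — the threshold is a package default,
reported in output) and the central probe is itself an SEV of that sample.

- Windows never span chromosomes, and centers lacking (n−1)/2 flanks on
  either side are skipped rather than tested with a truncated window, so
  every test uses the same n.
- N and K are genome-wide (not per-chromosome) so the null is a single
  urn per sample.
- Hyper and hypo calls are pooled for K and x by default; direction is
  re-attached per retained probe. A `per_direction` mode scans each
  direction separately.
- The tail is computed with exact integer combinatorics (`math.comb`),
  not a normal approximation and not a generic 1−CDF (which loses relative
  precision in deep tails). Only distinct (x, K) pairs are evaluated per
  sample, so the scan is O(universe) per sample in practice.
- No multiple-testing correction is applied across windows; specificity
  comes from the central-outlier requirement, the control subtraction and
  the single-variant exclusion downstream.
- With very small K the tail for x = 1 can fall below α (e.g. K = 1,
  n = 11, N = 10⁴ gives p = 0.0011), so a lone SEV can survive the scan;
  the later single-variant locus exclusion removes such singletons anyway.

### From retained SEVs to gene loci

Deregulations observed in any control are treated as non-specific: every
case retained SEV whose probe appears in the union of control retained
SEVs is removed (probe-level subtraction, the strictest reading; a
gene-level mode subtracts whole control-deregulated genes). Survivors are
grouped by (sample, manifest gene label) — multi-gene annotations such as
`"SIX3;SIX2"` are kept verbatim as locus keys — intergenic probes are
dropped with a logged count, and groups of size one are excluded: a
deregulated gene locus is ≥ 2 retained SEVs of one sample in one gene.
Loci with unanimous direction are hyper or hypo; discordant loci are
`mixed` and excluded from the directional shared-gene tables. Retained
SEVs can also be intersected with labelled BED region sets (imprinted
DMRs, retinoic-acid response elements ± 10 kb); the report counts, per
(region, sample), the retained probes inside the interval against the
total universe probes there ("x of y probes"). BED intervals are 0-based
half-open; manifest positions are 1-based, converted internally.

### Pre-processing

Filtering mirrors the single-case branch of the 450K workflow: probes
fail on detection p > 0.01 in any sample (an `det_p_frac` option relaxes
"any" to a fraction), bead count < 3 in ≥ 5 % of samples, then the
manifest flags non-CpG, SNP-affected, multi-mapping and sex-chromosome,
in that order with first-match accounting so the per-rule removal counts
partition the input. Quantile normalization forces every sample onto the
mean sorted profile; ties receive the mean of the reference values at
their tied ranks; missing values must be dropped or imputed first.

### Burden statistics

Per-sample SEV counts (raw, and retained after enrichment) are compared
between groups with a Poisson log-link GLM, `count ~ group + sex + age` —
sex as a two-level factor, age in years linear, the minimal covariate
adjustment. The model family is a package choice: counts of rare
independent events are natural Poisson material, and a Pearson χ²/df
check (> 2) switches the covariance to the quasi-Poisson Pearson scale,
which is reported in the model descriptor. Covariates themselves (age,
cell-type proportions if available) are compared with the two-sided
Wilcoxon rank-sum test. Clinical prevalences are summarised as n/N with
half-up integer percent rounding, one decimal when the exact percent is
below 10.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes of
a 450K-style cohort; its defaults are the study conditions of the
package's validation suite.

- **Manifest**: probes split evenly across chromosomes, strictly
  increasing positions (gaps uniform 200–5000 bp), contiguous gene blocks
  (10 % intergenic, 5 % two-gene labels), island-relation labels, and QC
  flags at realistic manifest rates (SNP 2 %, non-CpG 0.5 %,
  multi-mapping 0.2 %); optionally a chrX whose probes carry the
  sex-chromosome flag.
- **Beta values**: per-probe baselines from the bimodal mixture typical of
  methylation arrays — modes near 0.85 (methylated), 0.10 (unmethylated)
  and 0.50, weights 0.4/0.4/0.2, with 0.02 jitter — plus per-sample
  truncated-normal technical noise, sd 0.03 truncated at 2.5 sd, clipped
  to [0, 1].
- **Background epimutations**: a rare heavy-tail component (3 × 10⁻⁴ per
  probe–sample entry, shift magnitude uniform 0.25–0.45, random sign,
  clipped) models the stochastic outliers real arrays show, so controls
  carry a small nonzero SEV burden as the method expects. The magnitude
  floor is deliberately beyond any k = 3 fence so background events are
  unambiguous outliers; with bounded technical noise this keeps the
  case-vs-control burden test calibrated under the null (see below).
- **QC layers**: detection p-values < 0.01 except ~10⁻⁴ of entries
  (≈ 1 % of probes under the any-sample rule); bead counts ≥ 3 except
  ~10⁻⁴ random entries plus 5 × 10⁻⁴ systematically bead-poor probes
  (15 % per-sample low-bead probability) — only probe-correlated failures
  can trip the ≥ 5 %-of-samples rule.
- **Demographics**: cohort of 41 cases and 48 controls by default;
  case P(F) = 19/41 with log-normal ages of median ≈ 6 y, control
  P(F) = 34/48 with median ≈ 12.9 y.
- **Injection**: planted events are defined relative to the control
  fences (value = fence ± margin, default 0.10), so they are SEVs by
  construction; region injections shift `region_length` consecutive
  same-gene probes of one case; isolated injections pick probes whose
  (sample, gene) carries no other beyond-fence value, so planted
  singletons are isolated by construction. All randomness flows from one
  integer seed through one generator.

**What the generator does not model**: IDAT intensities and the red/green
channel chemistry, batch and chip-position effects, cell-type
composition, probe cross-hybridization structure, or spatially correlated
noise. Passing the validation suite therefore shows the *algorithmic*
chain is correct and calibrated under clean assumptions, not that the
pipeline is robust to the technical artifacts of production array data.

## Calibration and pilot results

Design choices that were genuinely open were settled by seeded pilots,
re-run by `scripts/acceptance.py` and the test suite:

- **Null calibration.** Because one reference serves all samples and
  controls are in-sample, unbounded noise tails make case SEV rates
  exceed control rates under the null (the fence sits ≈ 4.7 sd out with
  ≈ 0.45 sd estimation noise; exceedance probability is convex in fence
  position and negatively correlated with a control's own values). With
  the generator's bounded noise (2.5 sd) and decisive background
  epimutations (floor 0.25) the burden GLM rejects at ≈ 4–7 % at
  α = 0.05 over 200 null cohorts of 4 000 probes × (41 + 48) samples —
  the design the type-I acceptance check re-runs.
- **Recovery.** Planted contiguous deregulations (length 5, margin 0.15
  beyond the fences) in cohorts of 3 000 probes × (8 + 24) samples are
  recovered as gene loci with correct direction in ≈ 98 % of 100
  simulations; planted singletons are never recovered as loci (the ≥ 2
  rule makes this structural). Misses come from control retained SEVs
  occasionally deleting region probes.
- **Power.** At per-sample mean counts 30 vs 10 (n = 20 + 20) the GLM
  detects the threefold burden at p < 0.01 in ≥ 95/100 replicates
  (observed 100/100).
- **Problem sizes.** The validation suite uses 3 000–20 000-probe
  universes and the 41/48 cohort shape; these are the package's standard
  simulation designs, chosen to exercise every code path with realistic
  per-sample SEV counts.

## Numerical notes and limitations

- Quartiles and fences are plain floating point; the fence identity
  lower = Q1 − k·IQR holds exactly as computed, and tests compare fences
  at 1e−12 absolute tolerance.
- `hypergeom_upper_tail` is exact (integer rationals rounded once to
  float); the test suite checks it against an independent factorial-based
  rational oracle and scipy's survival function.
- The group-level module is a deliberately minimal stand-in for full
  array pipelines: an unadjusted Welch t-test per site (optional
  empirical-Bayes variance moderation by moment-matched inverse-chi-square
  shrinkage), with no surrogate-variable adjustment, no normalization
  beyond the shared QC, and no region-level combined p-values — its
  outputs are for exploration next to the single-case analysis, not a
  replacement for limma-class group inference.
- The burden GLM conditions on the observed counts; it does not propagate
  fence-estimation uncertainty. With few controls the no-leave-one-out
  design biases control counts low; users with small reference cohorts
  should interpret marginal burden p-values cautiously.
- Gene assignment is whatever the manifest's gene column says; no
  transcript-model re-annotation is performed.
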