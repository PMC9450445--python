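# Methods

This note documents the statistical model behind `bavscreen`, the
choices made where the design was genuinely open, and what the test
suite does and does not demonstrate.

## Discovery-stage cascade

The cascade is a conjunction of per-variant predicates applied in a
fixed order, with the count surviving each stage reported:

| stage | predicate | default |
|---|---|---|
| nonsynonymous | functional class ∈ {missense, stopgain, stoploss, splicing} | — |
| rare_both_panels | MAF < `maf_max` in both population panels | 0.05, strict `<` |
| in_silico_implicated | SIFT < `sift_max` AND PolyPhen class ∈ `polyphen_damaging_classes` | 0.05 strict; {D, P} |
| recurrent | distinct carrier patients ≥ `min_case_count` | 2 |
| gene_allowlist | gene ∈ user-supplied set | off |

Because the predicates are pure per-variant tests, the surviving *set*
is order-independent; the per-stage *counts* are not, so stage order is
part of the contract. Thresholds are compared strictly (`<`): a variant
with MAF exactly 0.05 or SIFT exactly 0.05 fails, matching the usual
reading of "below the cutoff".

PolyPhen bins are published as three closed ranges — B: 0–0.452, P:
0.453–0.956, D: 0.957–1 — that leave open gaps (0.452, 0.453) and
(0.956, 0.957). A score strictly inside a gap is assigned to the upper,
more damaging class: for a screening filter the conservative direction
is to keep, not discard. "Unanimous" in-silico implication is
interpreted as SIFT-deleterious AND PolyPhen-damaging with the damaging
set defaulting to {D, P}; restricting to {D} is a one-flag change
(`polyphen_damaging_classes`), since published descriptions of such
consensus calls rarely state whether "possibly damaging" counts.

Missing annotations: a variant lacking a SIFT or PolyPhen score parses
fine but can never be *implicated* (unanimity requires both votes). A
missing population MAF is resolved to 0 at read time — absence from the
panel is evidence of rarity, which is the standard prioritization
convention. Recurrence counts distinct carrier patients (dosage ≥ 1),
not allele copies, so a homozygote counts once.

## Validation-stage statistics

All gene-level tables use dominant (carrier) coding: the 2×2 entries
are patient counts, carriers vs non-carriers by cohort. A patient whose
dosages for a gene are all missing is counted as a non-carrier —
carriage must be observed to be claimed.

The Pearson χ² (1 df) is computed **without** continuity correction by
default; Yates' correction is available by flag. The uncorrected
statistic is the variant that reproduces published carrier-enrichment
p-values of this design at 3-decimal rounding (0.004, 0.003, 0.001 on
the packaged carrier counts). Fisher's exact test is two-sided by the
minimum-likelihood rule: the p-value sums hypergeometric probabilities
of all tables with the observed margins whose probability does not
exceed the observed table's. The `auto` policy applies the classical
expected-count rule: Fisher whenever any expected count under
independence is below 5 (configurable), χ² otherwise. Note the two
two-sided constructions differ persistently even for well-populated
tables (gaps above 0.01 occur at moderate p for minimum expected counts
in the hundreds); the suite asserts agreement within 0.02 only in the
rejection region (either p < 0.05, all expected counts ≥ 20), which is
the empirically true statement.

t-tests are unpaired and two-sided. Welch (unequal variances,
Satterthwaite df) is the default because it is valid whether or not the
group variances match; the pooled form is available and both reproduce
the published phenotype p-bounds. `ttest_from_summary` works directly
from (n, mean, SD) triples — the only form in which validation
phenotypes are usually published. Degenerate inputs: both SDs zero with
equal means gives t = 0, p = 1; with unequal means, an infinite
statistic and p = 0. No multiplicity correction is applied by default
(matching the source design); Benjamini–Hochberg adjusted p-values can
be appended (`adjust_bh`).

## Synthetic cohorts

The generator emulates the *statistical structure* the analysis
assumes, starting at the annotated-variant level. It does not simulate
reads, alignment, calling error, linkage, population structure, or
relatedness — so passing tests demonstrate correctness of the
*analysis*, not robustness to upstream artifacts.

Defaults are the study conditions: 20 discovery, 137 validation and 130
control patients. Background variants (default 2,000 — a scaled-down
stand-in for the ~300,000 SNVs of a real exome, chosen so the test
suite runs in seconds; full scale is just `n_variants=300_000`) draw
their functional class from the published per-exome count proportions,
global MAF log-uniform on [1e-4, 0.5] (straddling the 0.05 threshold),
East Asian MAF as the global value times a lognormal factor (log-sd
0.5, clipped to [0, 0.5]), and SIFT/PolyPhen scores uniform on
configurable ranges straddling both cutoffs. Background dosages are
Binomial(2, MAF) per sample — Hardy–Weinberg carriage at the panel
frequency, the simplest model consistent with exome-scale counts.
`ScoreModel.clean_background()` draws background scores entirely
outside the deleterious region, making planted-variant recovery exact
by construction; this is the configuration used for recovery tests.

Planted variants are realized with exactly their intended discovery
carrier counts (heterozygous, sampled without replacement) and recorded
in a ground-truth ledger. In the validation cohort, carrier status per
planted gene is Bernoulli at per-cohort rates defaulting to the
published per-gene carrier counts divided by the cohort sizes.
Phenotypes follow a dominant two-group mean-shift model: carriers of ≥ 1
panel variant draw from the carrier distributions (LVEF 58.4 ± 5.2 %,
calcification 1261.8 ± 123 mm³), others from the non-carrier ones
(63.8 ± 7.5 %, 1129.3 ± 154 mm³), as truncated Gaussians (LVEF in
(0, 100], volume ≥ 0, truncation by redraw — the bounds are many SDs
out, so the realized moments are unaffected). Gaussianity is a modeling
choice of the simulator: the source summaries are mean ± SD only, and
no per-gene dose effects or between-gene phenotype differences are
modeled unless configured.

`table_fixture_cohort()` is deterministic: per-gene carrier counts
equal the published validation/control values exactly, the 123
validation gene-carrier slots are laid out round-robin over the first
87 patients (giving the published 87/50 carrier split; the overlap
arrangement is one of many consistent with the marginals, since
patient-level co-carriage was never published), and phenotypes are
affine-standardized Gaussian quantile scores, so each group's sample
mean and SD equal the published summaries to machine precision.

Determinism: all sampling flows through one `numpy` PCG64 generator
seeded from `SimSpec.seed` (validation uses `seed + 1` so the two
cohorts are decoupled); equal seeds give byte-identical cohorts across
runs and platforms.

## Numerical and testing choices

- Candidate tables are written with 6-significant-digit numeric
  formatting; round-trips are exact for strings and to 6 significant
  digits for numerics. VCF INFO floats are single precision on read and
  are renormalized to 6 significant digits, so the VCF and TSV readers
  yield identical records for files the package wrote.
- Chromosome order is 1–22, X, Y, MT, then others lexicographically;
  candidate output is sorted by (chromosome, position).
- The Fisher-vs-enumeration check runs exhaustively over all 2×2 tables
  with N ≤ 26 (~28,000 tables) plus 2,000 seeded random tables with
  N ≤ 60, at relative tolerance 1e-7 — a problem size chosen to keep
  the check thorough but fast.
- Monte-Carlo calibration uses 1,000 null cohorts for the type-I-error
  check (rejection rate 5% ± 2% at α = 0.05) and 200 cohorts at the
  published effect sizes for power (≥ 95%). At these replicate counts
  the binomial standard error of the rejection rate is ≈ 0.7% and
  ≈ 0.7–1.5% respectively, well inside the asserted bands.

## Known limitations

- SNVs only; indels, structural variants and multi-nucleotide variants
  are out of scope, as is any annotation computation — gene, class,
  MAFs and scores are consumed as inputs.
- The packaged candidate table prints no genomic coordinates or
  in-silico scores; the fixture fills those columns with clearly-marked
  synthetic placeholders consistent with the published filters
  (positions order-preserving, scores inside the deleterious bins).
  Analyses that depend on true positions should not use the fixture.
- Carrier-frequency tests ignore covariates; no regression or survival
  modeling is provided.
- The simulator's independence assumptions (variants independent,
  genes' carrier statuses independent, phenotypes conditionally
  independent given carrier status) are idealizations; real cohorts
  have linkage and comorbidity structure the tests do not probe.
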