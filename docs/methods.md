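# Methods

## Weighted-ranking score

A full-face section is described by an intensity profile
`(p0, p1, p2, p3)`: the percent of tissue area at staining grade 0, 1+,
2+ and 3+. The cumulative intensity score is

    S = w1·p1 + w2·p2 + w3·p3,   defaults (w1, w2, w3) = (0.25, 0.5, 1)

so each grade step down halves the per-percent weight and S lies in
[0, 100], saturating at 100 only for a uniformly 3+ section. S is linear
in the profile and monotone under moving area mass to a higher grade.
Sections are banded at `low_cut = 33` and `high_cut = 66`: hypo-intense
below 33, hyper-intense above 66, intermediate between — **boundary
values band as intermediate**, matching the "<33 / 33–66 / >66" reading
of the band definitions, and boundary comparisons carry a 1e-9 absolute
tolerance so floating-point arithmetic that lands exactly on a cut
cannot flip the band.

Data-entry conventions, chosen to accept real score sheets:

- Grade-0 area is implicit: `p0` defaults to `100 − (p1+p2+p3)` and
  contributes nothing to S.
- Profiles whose graded percentages sum into (100, 101] are accepted
  with a warning and `p0` clamped to 0 — visual scoring in rough thirds
  (33/33/33) or quarters produces such sums routinely. Sums above 101
  are rejected, naming the total.
- Reported category percentages are rounded half-up to integers.
- Weights and thresholds are configurable but validated
  (0 ≤ w1 ≤ w2 ≤ w3; 0 < low_cut < high_cut < 100), and every report
  embeds the configuration used.

The bundled 25-case reference cohort (`hetrank fixtures --name table2`)
stores the published percentage profiles, per-grade components,
accumulated scores, bands and HER2 status. One case's printed
accumulated score ("4705") is inconsistent with its own printed
components (7.5 + 30 + 10); the fixture stores the arithmetic value 47.5
and notes the discrepancy in its `note` column. Either value bands as
intermediate. Component values are kept at full precision; rounding is
applied only at display time.

## TMA concordance

Each core receives one ordinal score in {0, 1, 2, 3}. A case's cores are
collapsed by **adopting the higher score** — the standard convention for
duplicate-core IHC — and dichotomized as high (exactly 3+) vs
low/moderate (0, 1+, 2+). Grade 0 is grouped with low/moderate so that
"high" stays exactly 3+ and the dichotomy is exhaustive.

Duplicate-core concordance is exact equality of all core scores of a
case; an `adjacent` option counts scores within one grade as concordant
but is off by default. Cases with a single core are counted separately,
never silently dropped, and an optional `restrict_to_high` flag limits
eligibility to cases whose maximum core score is 3+ (the cohort
definition used when discordance is reported only among marker-high
cases — whether to restrict is a caller decision). Fractions are
reported to the nearest integer percent.

## Association statistics

`pearson_chi2` computes `Σ (O − E)² / E` with
`E = row_total · col_total / N` and **no Yates continuity correction**
(the correction is a small-sample conservatism choice; the uncorrected
statistic is what SPSS-style "asymptotic significance" reports). The
p-value is the chi-square upper tail with `(r−1)(c−1)` degrees of
freedom, evaluated as the regularized upper incomplete gamma function
`Q(df/2, x/2)`; for df = 1 this equals `erfc(√(x/2))` and for df = 2
`exp(−x/2)`, identities the tests verify to 1e-12. Expected counts
below 5 trigger a warning, not an error; an empty row or column is an
error because the degrees of freedom are then ill-defined.

`fisher_exact_2x2` is two-sided by the **probability-mass rule**: it
enumerates every 2×2 table with the observed margins and sums the
hypergeometric probabilities of those no more likely than the observed
table. Probabilities are assembled in log space from log-gamma values,
and the comparison allows a 1e-7 relative tolerance so symmetric tables
that are equiprobable in exact arithmetic are always included. This is
the dominant convention in mainstream statistics software.

`crosstab` builds observed-count tables from a case table (pandas
underneath), optionally pooling row levels (e.g. hypo-intense +
intermediate vs hyper-intense for a dichotomized marker analysis) and
optionally keeping missing values as an explicit "Unspecified" level —
the right choice when unspecified status is itself an informative
stratum; dropping such rows changes the table's degrees of freedom and
its p-value. Excluded-row counts are always reported. Orientation does
not affect either test; reports place the exposure on rows for
readability. p-values are displayed to 3 decimals; full precision is
retained internally. No multiple-testing correction is applied across a
battery of crosstabs; callers testing many covariates should apply
their own.

## Virtual tissue simulator

The simulator makes the TMA-vs-full-face sampling question testable in
silico. A virtual section is a W×H lattice of grade labels built in two
steps: (1) a standard-normal noise field is smoothed with an isotropic
Gaussian kernel of bandwidth `patch_scale` lattice units (toroidal
boundary, so the field is stationary); (2) sorted field values are cut
at the target profile's cumulative fractions, lowest values becoming
grade 0 and highest 3+. Label counts are apportioned by largest
remainder, so realized marginals match the target to within one cell
regardless of patchiness, and `patch_scale` is the single heterogeneity
knob (`patch_scale = 0` gives i.i.d. cells). This construction was
preferred over Potts/MRF sampling for determinism, speed and exact
marginal control; its patches are smooth blobs without the anisotropy
or gland structure of real histology.

Cores are discs of radius `core_radius` placed uniformly at random with
full containment in the lattice, two per patient by default (mirroring
duplicate-core designs). A core is collapsed to an ordinal grade by a
**dominance rule**: the highest grade g whose cumulative area fraction
at g or stronger reaches `dominance_threshold` (default 30%). This
pathologist-emulation rule is an invention of this package and is
isolated in one function so alternatives (modal grade, any-focus-3+)
can be swapped in.

A cohort experiment draws, per patient: a binary label (prevalence
`label_prevalence`, default 0.4); a patient-specific target profile from
a Dirichlet with concentration `profile_concentration` (default 8)
around a label-dependent mean; a tissue; cores and a full-face profile.
The label-positive mean is the base profile mixed toward pure 3+ by
`association_effect ∈ [0, 1)`, so effect = 0 is an exact null. The base
profile default (5% grade 0, 20% 1+, 35% 2+, 40% 3+) represents a
strongly but heterogeneously stained marker whose cumulative score
(62.5) sits between the intermediate and hyper-intense bands, so
cohort-level category splits are informative on both pipelines. Both
pipelines are then tested against the label with the chi-square test:
TMA (max core grade, dichotomized 3+ vs rest) and full-face (weighted
score, hyper vs hypo/intermediate). A cohort draw in which one margin
of a 2×2 table is empty carries no evidence of association and is
recorded as p = 1 rather than aborting a Monte Carlo sweep. Every
output is a pure function of the configuration, including its seed.

Library defaults (512×512 lattice, core radius 25) give a core/section
area ratio of about 0.75%, echoing how little of a section a real TMA
core samples. The Monte Carlo tests in the suite run the same machinery
at reduced sizes chosen to keep the suite brisk while leaving the
tested behavior unambiguous: 64×64 lattices with radius-6 cores for the
type-I-error calibration (200 cohorts × 200 patients), 192×192 with
radius-57 cores (~10⁴ cells per core) for the i.i.d. concordance check,
and 96×96 with radius-8 cores for the patch-scale sweep and power
comparison.

What passing simulations do and do not show: the simulator demonstrates
the *mechanism* — patchy expression plus tiny sampled area makes
duplicate cores discordant and attenuates core-level associations that
full-face weighted ranking recovers — under a stylized spatial model.
No quantitative spatial statistics are available for real marker
patchiness, so `patch_scale` defaults are illustrative, not calibrated,
and simulation results quantify the sampling effect within the model,
not effect sizes in any real cohort. Real TMA discordance counts are
exercised only as arithmetic checks on fixture data.

## I/O and reproducibility

CSV is the interchange format (one row per case in full-face mode, one
row per core in TMA mode); JSON for nested reports; YAML for simulation
configs. Reading validates per-row and reports rejected row numbers
with reasons; covariates with a controlled vocabulary (HER2 status, sex,
survival status, Lauren class, Ki67 band — Ki67 stored as ordinal bands,
not raw percentages) are checked strictly or leniently. Report output
is byte-deterministic for fixed inputs, and CSV reports carry their
scoring configuration in a JSON sidecar. INFO-level logging records
counts in and out of every stage so cohort attrition leaves an audit
trail.
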