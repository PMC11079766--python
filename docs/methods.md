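# Methods

## Problem setting

A curated clinical cohort extract (records × variables) is to be shared
under a controlled-access model; anonymization guards against
reidentification if the data leak. The pipeline quantifies what enforcing
reidentification-risk thresholds costs in utility, separately for a generic
and a use-case-tailored anonymization configuration. All computations run
on synthetic data with the structure described below; nothing in this
repository contains or derives from real patient data.

## Synthetic cohort generator

`anoncost.cohort.generate_cohort` emulates the structural features the
downstream analyses rely on, not any real joint distribution. Every
numeric default lives in `anoncost/defaults.py` and is a plausibility
choice for a middle-aged chronic-kidney-disease cohort:

- **Shape**: 5217 records × 70 variables (15 clinical variables plus inert
  noise "filler" columns to reach the target width). Filler columns carry
  no clinical meaning; they only make the column count realistic.
- **Quasi-identifiers** at measurement resolution — age in whole years
  (truncated normal, mean 60, sd 12, range 18–74), gender (60% male),
  height conditional on gender (normal, 178/165 cm ± 7), weight via a
  latent BMI (normal, mean 29, sd 5) times squared height, recorded BMI =
  round(weight/(height/100)², 1), renal biopsy 25%. Resolution drives
  uniqueness: with these six variables ~96% of 5217 records are unique,
  reproducing the near-total uniqueness that motivates anonymization.
  Quasi-identifiers have no missing values by default.
- **Analysis variables** with diabetes-linked structure: diabetes 35%;
  eGFR mean 49 (−4 with diabetes); UACR category probabilities shift from
  (0.45, 0.35, 0.20) to (0.25, 0.35, 0.40) with diabetes; systolic BP +6
  mm Hg with diabetes; four medication flags; a five-level CKD-cause
  variable dominated by diabetic nephropathy among diabetics. Analysis
  variables carry realistic missingness (1–10%).

What passing tests on this cohort show: the machinery (risk accounting,
search optimality, metric calibration, CI scoring) is correct, and the
qualitative trade-off pattern emerges under realistic uniqueness. What
they do not show: quantitative utility numbers for any real cohort —
real joint distributions, coding practices and missingness patterns will
move every percentage.

## Threat model

Variables are screened with three ordinal components (availability,
replicability, distinguishability), each 1–3; the sum > 5 flags a
quasi-identifier. The shipped component scores are illustrative defaults
that flag exactly the six demographic variables; they are config, not
expert elicitation, and callers supply their own profiles in the scenario
YAML. The qualitative guideline-list screening step that precedes scoring
in practice is represented as user input, not automated.

Height, weight and BMI are mutually derivable, so generalizing them
independently can leak via back-calculation. One side of the dependency is
always dropped: generic keeps height/weight (drops BMI), use-case keeps
BMI (drops height/weight). Other derived-variable groups can be declared
via `extra_removals`.

## Hierarchies

Interval hierarchies are anchored at the domain minimum, left-closed
right-open, last interval closed at the maximum; each level multiplies the
interval width by the grouping factor (default 2). Anchoring and closure
are conventions of this implementation (any fixed convention works; this
one makes labels parse back to exact bounds). Default base widths: age 5
years, height 10 cm, weight 10 kg. Values outside the declared domain are
rejected rather than top/bottom-coded, because the generator guarantees
bounds; top-coding would be the right extension for wild data. Dichotomous
variables are never generalized — suppression only. The use-case scenario
caps age at 10-year intervals and coarsens BMI only into the three
clinical bands (<25.0, 25.0–29.9, ≥30.0); the generic scenario allows
generalization up to a single top interval.

## Risk accounting

Record risk is 1/u(r) over equivalence classes of the released
quasi-identifier tuples; PR = max, MR = mean = #classes/#records. Printed
thresholds are canonicalized to exact group sizes (0.5→2, 0.09→11,
0.03→33) so that a class of exactly k records satisfies a "1/k" threshold;
comparisons use a 1e-12 absolute epsilon. Suppressed records are excluded
from all risk statistics — they are not released. Missing quasi-identifier
values compare equal to each other (they form a class), the conservative
view of what a released empty field discloses.

## Lattice search and suppression

The anonymizer enumerates the entire lattice of level vectors (generic:
252 nodes; use-case: 6) — correctness over speed, since results must not
depend on a search heuristic. Per node: classes smaller than k are
suppressed; if an MR threshold remains violated, whole classes are removed
smallest-first (ties: first appearance) while the 10% suppression budget
allows — removing a small class cuts the class count, hence MR, fastest
per suppressed record. Among feasible nodes the search maximizes
granularity; ties go to the smaller level sum, then the lexicographically
smallest vector over alphabetically ordered quasi-identifiers. Granularity
is quantized at 1e-9 in the comparison key so float summation order cannot
break ties. If nothing is feasible the node whose k-rule suppresses the
fewest records is reported with `feasible=False`. The per-variable,
per-level generalizations and class partitions are cached so a whole
threshold sweep reuses one pass over the table.

The choice of granularity as the search objective is an assumption (the
evaluation also reports entropy and CI overlap for the chosen node);
suppression removes records from the release rather than blanking them, so
downstream analyses run on fewer records.

## Utility metrics

Both general-purpose metrics are computed over quasi-identifier columns
only. Averaging over all 70 columns would pin both metrics near 100% —
64 columns are never touched — and destroy the metric's resolution.
Domains are empirical (distinct values present in the data) and all
frequencies come from the original table, making values comparable across
thresholds. A kept missing cell contributes no granularity loss (there is
no information to lose); a suppressed record loses everything, including
its missing cells' frequency information under the entropy model.

CI-overlap scoring: Wilson score intervals for proportions (via
statsmodels), two-sided t intervals for means (scipy); the overlap of two
intervals is the symmetric average of the overlap length divided by each
interval's length. A zero-length interval counts as fully overlapping iff
its point lies in the other interval. Counts are reported but not scored
(they carry no interval); variables whose scale the anonymization changed
(age, BMI, height, weight) are excluded from scoring and handled by
histogram export instead. The battery's strata use raw values of
stratification variables, which therefore must stay at level 0 — gender
and diabetes do by construction. Analyses declared `affected=False`
(touching no transformed or suppressed-sensitive variable) enter the
overall average at 100%. The default battery mirrors a seven-analysis
baseline characterization (main burden table stratified by
gender × diabetes, inclusion criteria, biopsy-by-cause, two cardiovascular
tables, diabetic nephropathy, and an untouched category analysis); it is
fully configurable.

## Sweep and problem sizes

The default grid is 100 equally spaced thresholds from 1.00 down to 0.02
(grid spacing is unconstrained by the risk model; equal spacing is the
obvious reproducible choice), in two families: PR-only, and PR fixed at
50% with MR scaling. Four levels are highlighted: 50%PR+9.09%MR,
50%PR+3.03%MR, 9.09%PR, 3.03%PR. The analysis drivers and the acceptance
script run the full 100×2 sweep (~1 minute); the test suite exercises the
same code paths on a 20-point grid at full cohort size, a deliberate
problem-size choice that keeps the whole suite fast while preserving every
qualitative check.

## Numerical and degenerate-input conventions

- Threshold → group size uses floor(1/t + 1e-9) to absorb decimal rounding.
- Feasibility comparisons use 1e-12 epsilons; suppression-budget checks
  likewise.
- An empty quasi-identifier set returns the identity release.
- A table where every record would be suppressed yields `feasible=False`
  (unless the budget is 100%) and no risk summary.
- Zero-variance mean intervals are degenerate (length 0), handled by the
  overlap convention above; single-value means carry no interval.

## Known limitations

- Only prosecutor/marketer linkage risk is modelled: no journalist model,
  no population-uniqueness estimation, no attribute-disclosure (inference)
  protection.
- Transformation is full-domain generalization plus whole-record
  suppression: no local recoding, microaggregation or noise mechanisms.
- Reproducibility is scored for descriptive statistics only; inferential
  analyses (regression, survival) may disagree in ways CI overlap of
  descriptive estimates does not capture.
- The synthetic cohort is a structural stand-in; absolute utility numbers
  are properties of this generator, not of any real data set.
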