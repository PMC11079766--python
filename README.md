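# anoncost

**What does anonymizing a clinical cohort table actually cost in research
utility?** `anoncost` is an analysis pipeline for quantifying the
privacy–utility trade-off of k-anonymity-style anonymization on
record-level clinical study data. It is aimed at data custodians and
methodologists who must decide how strictly to anonymize a cohort extract
before sharing it, and who want the decision grounded in measurements
rather than generic information-loss folklore.

The pipeline works on a chronic-kidney-disease-flavoured cohort table
(records × variables, mixed continuous/categorical/dichotomous). Because
real patient-level extracts are confidential, a seeded synthetic generator
reproduces the structural features the analysis depends on: 5217 records ×
70 variables, six quasi-identifiers (age, gender, height, weight, BMI,
renal-biopsy history) that make ~96% of records unique in combination, an
interdependent height/weight/BMI triple, and diabetes-linked shifts in
eGFR, albuminuria and blood pressure.

## The model

Let u(r) be the number of records indistinguishable from record r on the
quasi-identifiers. Each record's reidentification risk is 1/u(r); the
**prosecutor risk** PR is the maximum of this distribution and the
**marketer risk** MR its average (= #classes / #records). Enforcing
PR ≤ 1/k is *k-anonymity*; bounding MR as well is the *strict-average-risk*
model. The anonymizer searches the full-domain generalization lattice
(every variable recoded consistently to one hierarchy level), suppresses
records in classes smaller than k (bounded at 10% of records), and returns
the feasible node with maximal **granularity**. Utility of a release is
scored three ways:

- **granularity** — per-cell loss (m−1)/(M−1) for a label covering m of the
  variable's M distinct original values; suppressed cells lose 1;
- **nonuniform entropy** — per-cell loss −log₂(f₀(v)/f₁(g(v))) from
  original-vs-generalized value frequencies, normalized per variable;
- **95% CI overlap (CIO)** — a battery of descriptive analyses (Wilson
  score intervals for proportions, t intervals for means) is run on the
  original and the released table and scored by the symmetric relative
  overlap of interval lengths, averaged cells → tables → overall.

Two scenarios are compared: a **generic** configuration (unrestricted
hierarchies, BMI removed) and a **use-case-specific** one (age capped at
10-year intervals, BMI kept in three clinical bands, height/weight
removed).

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_anonymize_highlights.py
```

prints (seed 42 cohort, abridged):

```
cohort: 5217 records x 70 variables
threat model flags 6 risky variables: age, gender, height, weight, bmi, renal_biopsy
96.1% of records are unique on the quasi-identifier combination ...

scenario   privacy_level  ... n_suppressed  max_pr_pct  avg_pr_pct  min_pr_pct
 generic 50% PR+9.09% MR  ...          147       50.00        7.26        0.99
 generic        9.09% PR  ...          367        9.09        1.65        0.27
 generic        3.03% PR  ...          376        2.70        0.58        0.16
use_case        3.03% PR  ...          297        3.03        0.85        0.27
```

Reading this: at the 9.09% PR threshold (group size 11) the generic
scenario suppresses 367 of 5217 records; the maximum empirical risk hits
the threshold exactly while the *average* risk lands at 1.65% — consistent
full-domain recoding overprotects most records. `analysis/03_sweep_tradeoff.py`
then sweeps 100 thresholds per scenario and shows the headline pattern:
general-purpose utility falls substantially (granularity ≈100→72%, entropy
≈100→47% in the generic scenario) while the overall 95% CI overlap of the
analysis battery stays high (>90% for most thresholds), and the use-case
configuration beats the generic one at matched privacy.
`analysis/04_reproducibility_detail.py` drills into estimate-level
agreement and exports age/BMI histograms.

There is also a CLI for the individual stages
(`anoncost simulate|assess-risk|anonymize|evaluate-generic|evaluate-usecase|sweep|report`).

## Layout

- `src/anoncost/` — library: cohort generator, threat model, hierarchies,
  risk models, lattice anonymizer, utility metrics, CI-overlap scoring,
  sweep pipeline, CLI
- `analysis/` — numbered narrative drivers writing tables to `results/`
- `tests/` — pytest suite with brute-force oracles for the risk statistics
  and the lattice search
- `docs/methods.md` — modelling assumptions, defaults and limitations
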