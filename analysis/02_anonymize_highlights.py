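"""Anonymize the cohort at the four highlighted privacy levels.

For each scenario (generic, use-case) and each highlighted level
(50%PR+9.09%MR, 50%PR+3.03%MR, 9.09%PR, 3.03%PR) the cohort is anonymized
and the empirical residual risks are tabulated (results/empirical_risks.csv
— the strict thresholds routinely overshoot, i.e. overprotection). The
released tables are parked under scratch/ for inspection.
"""

from pathlib import Path

import pandas as pd

from anoncost import PrivacyModel, anonymize, generate_cohort
from anoncost.pipeline import HIGHLIGHTS
from anoncost.scenarios import builtin_scenarios

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    cohort = generate_cohort()
    rows = []
    for cfg in builtin_scenarios():
        for label, pr, mr in HIGHLIGHTS:
            model = PrivacyModel(pr, mr_threshold=mr,
                                 suppression_limit=cfg.suppression_limit)
            res = anonymize(cohort, cfg.qis, cfg.hierarchies, model)
            tag = label.replace("% ", "").replace("+", "_").replace("%", "")
            res.table.to_csv(SCRATCH / f"release_{cfg.name}_{tag}.csv")
            rows.append({
                "scenario": cfg.name, "privacy_level": label,
                "feasible": res.feasible,
                "scheme": "/".join(f"{v}:{l}"
                                   for v, l in res.scheme.as_dict().items()),
                "n_suppressed": res.n_suppressed,
                "max_pr_pct": 100 * res.risk.pr_max,
                "avg_pr_pct": 100 * res.risk.pr_avg,
                "min_pr_pct": 100 * res.risk.pr_min,
            })
    tbl = pd.DataFrame(rows)
    tbl.to_csv(RESULTS / "empirical_risks.csv", index=False)
    print(tbl.to_string(index=False, float_format=lambda x: f"{x:.2f}"))
    print("\nEmpirical average and minimum prosecutor risk sit well below "
          "the specified thresholds: consistent full-domain transformation "
          "overprotects most records.")


if __name__ == "__main__":
    main()
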