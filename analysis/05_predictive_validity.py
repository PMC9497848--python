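#!/usr/bin/env python
"""Predictive validity: do synchrony measures track the clinical contrast?

Compares each measure between depressed-group and control dyads
(Kruskal-Wallis, Hedges g with the small-sample correction, patient minus
control) and correlates each measure with the PHQ9 and GAD7 symptom sums.
Writes results/predictive_groups.csv and results/predictive_symptoms.csv.
"""

from pathlib import Path

from movesync import io as msio
from movesync.validity import group_comparison, symptom_correlations

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = msio.read_cohort_csv(ROOT / "cohort_measures.csv")

    groups = group_comparison(table)
    groups.round(4).to_csv(ROOT / "predictive_groups.csv")
    sig = groups[groups["kw_p"] < 0.05].sort_values("kw_p")
    print(f"group differences at p < 0.05: {len(sig)} of {len(groups)} measures")
    if len(sig):
        print(sig[["kw_p", "hedges_g"]].round(3).to_string())

    sym = symptom_correlations(table)
    sym.round(4).to_csv(ROOT / "predictive_symptoms.csv")
    strongest = sym["phq9_spearman_r"].abs().idxmax()
    print(f"strongest PHQ9 link: {strongest} "
          f"(rho = {sym.loc[strongest, 'phq9_spearman_r']:.2f})")
    print(f"wrote {ROOT / 'predictive_groups.csv'} and predictive_symptoms.csv")


if __name__ == "__main__":
    main()
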