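#!/usr/bin/env python
"""Cohort statistics: exclusions, the nine-test battery, and persistence calls.

Reads the trajectory table and manifest from results/, applies the exam-count
and protocol exclusion rules, runs the nine Bonferroni-corrected Wilcoxon
signed-rank tests (T2 x 3 regions in the hormonal-therapy stratum, ADC x 3
regions x 2 strata) on pretreatment-vs-endpoint medians, classifies
per-patient persistent changes against the 11 % (T2) / 47 % (ADC)
repeatability intervals, and writes the full result JSON plus summary CSVs.
"""

from pathlib import Path

import pandas as pd

from prostate_qmri.stats import apply_exclusions, summarize_cohort

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = pd.read_csv(ROOT / "trajectories.csv", float_precision="round_trip")
    manifest = pd.read_csv(ROOT / "manifest.csv")
    exclusions = apply_exclusions(manifest)
    print(f"ADC analysis: {len(exclusions.adc_patients)} patients; "
          f"T2 analysis: {len(exclusions.t2_patients)} patients")
    for patient, analysis, reason in exclusions.excluded:
        print(f"  excluded {patient} from {analysis}: {reason}")

    result = summarize_cohort(table, exclusions)
    result.to_json(ROOT / "cohort_result.json")
    pd.DataFrame(result.tests).to_csv(ROOT / "report_tests.csv", index=False)
    result.population_medians.to_csv(ROOT / "report_population_medians.csv", index=False)

    print(f"\nnine-test battery at p < {result.threshold.display}:")
    for t in result.tests:
        flag = "*" if t["significant"] else " "
        print(
            f" {flag} {t['map_type']:>3} {t['roi']:>5} {t['stratum']:>4}: "
            f"week-5 change {t.get('week5_percent_change', float('nan')):+6.1f} %, "
            f"p = {t['p_value']:.4g} (n = {t['n_patients']})"
        )
    for t in result.skipped_tests:
        print(f"   {t['map_type']:>3} {t['roi']:>5} {t['stratum']:>4}: skipped "
              f"({t['reason']})")
    print("\npersistence counts:", result.persistence_counts)


if __name__ == "__main__":
    main()
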