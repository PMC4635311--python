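"""Behavioral analysis of the simulated cohort: psychometric fits, exclusion
rules, integration criteria, age-bin tests, and the developmental curve.

Reads results/cohort_trials.tsv (run 01_simulate_cohort.py first) and writes
per-subject sensitivities, the exclusion log, bin-wise paired t tests of
both fusion criteria, and the exponential age-trend fit under results/.
"""

import warnings
from pathlib import Path

from cuefuse.observer_models import read_trials
from cuefuse.pipeline import behavioral_summary

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    trials = read_trials(RESULTS / "cohort_trials.tsv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = behavioral_summary(trials)
    report.write(RESULTS / "behavioral")

    s = report.summary
    print(f"included {s['n_included']} of {s['n_subjects']} subjects "
          f"({s['n_excluded']} excluded)")
    bt = report.tables["bin_tests"]
    print("\nage-bin paired tests (both fusion criteria):")
    print(bt[bt.bin != "all"].to_string(index=False))
    for name in ("index1", "index2"):
        fit = s.get(f"developmental_fit_{name}")
        if fit:
            print(f"\n{name} age trend: best model = {fit['model_form']}, "
                  f"half-rise age = {fit['half_rise_age']}, "
                  f"zero crossing = {fit['zero_crossing_age']}")
    print(f"\nreport written to {RESULTS / 'behavioral'}")


if __name__ == "__main__":
    main()
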