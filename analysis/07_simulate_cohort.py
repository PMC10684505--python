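"""Simulate the remote-survey cohort (47 control / 56 semaglutide /
50 tirzepatide) from the generating models and write the three survey
tables (participants, daily TLFB diary, instrument responses) under
results/survey/.
"""

from _common import SURVEY_DIR
from glp1alc.synthetic import CohortSpec, generate_cohort, write_cohort_csvs

SEED = 20230902


def main() -> None:
    spec = CohortSpec(seed=SEED)  # default sizes and coefficients
    cohort = generate_cohort(spec)
    write_cohort_csvs(cohort, SURVEY_DIR)
    n = len(cohort.participants)
    by_group = cohort.participants["group"].value_counts().to_dict()
    print(f"simulated {n} participants: {by_group}")
    print(f"diary rows: {len(cohort.tlfb)}, instrument rows: {len(cohort.instruments)}")
    print(f"wrote participants/tlfb_daily/instruments CSVs -> {SURVEY_DIR}")


if __name__ == "__main__":
    main()
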