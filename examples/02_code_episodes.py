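"""Cohort filtering and clinical coding on a small constructed table.

Shows the conservative complication rules in action: an inclusion code only
counts among *additional* diagnoses, and an aetiology exclusion (urinary
principal diagnosis, paralysis codes) vetoes the flag.
"""

import pandas as pd

from excesscost import code_episodes, filter_cohort

episodes = pd.DataFrame(
    {
        "person_id": ["A", "A", "B", "C", "D"],
        "episode_id": [f"E{i}" for i in range(5)],
        "age": [82, 82, 49, 71, 90],
        "sex": ["female", "female", "male", "male", "female"],
        "los_days": [12, 8, 5, 95, 7],
        "drg": ["D1"] * 5,
        "principal_dx": ["R07", "N30", "R07", "R07", "R07"],
        "additional_dx": [["G30", "E11"], ["N390"], ["N390"], [], ["L89", "G81"]],
        "surgical": [False, True, False, False, False],
        "admission_date": pd.to_datetime(["2006-09-01", "2007-02-01", "2006-10-01",
                                          "2006-11-01", "2007-01-15"]),
    }
)

filtered, log = filter_cohort(episodes)  # age >= 50, LOS <= 90 days
print(f"exclusions: {log}")  # B is under 50; C stayed beyond 90 days

coded = code_episodes(filtered)
cols = ["episode_id", "person_id", "dementia", "charlson",
        "urinary_tract_infection", "pressure_injury", "n_complications"]
print(coded[cols].to_string(index=False))
# Person A: dementia code on one stay flags both stays (person linkage);
# Charlson=1 from diabetes (dementia never scores).  A's second stay has a
# UTI code but a urinary principal diagnosis, so the flag is vetoed.
# Person D: pressure-injury code voided by the paralysis exclusion (G81).
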