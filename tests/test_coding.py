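"""Cohort filters, dementia linkage, Charlson scoring and complication rules."""

import csv
from importlib import resources

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from excesscost.coding import (
    CohortValidationError,
    ComplicationRule,
    RuleValidationError,
    code_episodes,
    compute_charlson,
    filter_cohort,
    flag_complications,
    flag_dementia,
    load_charlson_config,
    load_complication_rules,
)
from conftest import make_episodes

# ---------------------------------------------------------------------------
# Cohort filter


def test_filter_cohort_boundaries_and_log():
    eps = make_episodes(
        [
            {"age": 50, "los_days": 90},   # both boundaries inclusive -> retained
            {"age": 49, "los_days": 5},    # under age
            {"age": 80, "los_days": 91},   # beyond max LOS
            {"age": 49, "los_days": 91},   # violates both; counted once (age first)
            {"age": 75, "los_days": 1},
        ]
    )
    kept, log = filter_cohort(eps, min_age=50, max_los=90)
    assert list(kept["episode_id"]) == ["E0000", "E0004"]
    assert log == {"age_lt_min": 2, "los_gt_max": 1}
    assert len(eps) == len(kept) + sum(log.values())


def test_filter_cohort_mixed_table_counts():
    # 10 rows, 3 violating filters -> 7 retained, log sums to 3.
    rows = [{"age": 60, "los_days": 10} for _ in range(7)]
    rows += [{"age": 40, "los_days": 10}, {"age": 60, "los_days": 95}, {"age": 30, "los_days": 5}]
    kept, log = filter_cohort(make_episodes(rows))
    assert len(kept) == 7
    assert sum(log.values()) == 3


def test_filter_cohort_rejects_malformed_rows():
    eps = make_episodes([{"los_days": 5, "principal_dx": "not-a-code"}])
    with pytest.raises(CohortValidationError, match="principal_dx"):
        filter_cohort(eps)


# ---------------------------------------------------------------------------
# Dementia linkage


def test_dementia_additional_code_propagates_to_all_episodes():
    eps = make_episodes(
        [
            {"person_id": "A", "additional_dx": ["G30"], "admission_date": "2006-05-01"},
            {"person_id": "A", "additional_dx": [], "admission_date": "2007-01-01"},
            {"person_id": "B", "additional_dx": ["I21"], "admission_date": "2006-05-01"},
        ]
    )
    flags = flag_dementia(eps)
    assert flags == {"A": True, "B": False}


def test_dementia_code_outside_lookback_window_does_not_count():
    eps = make_episodes(
        [
            {"person_id": "A", "additional_dx": ["G30"], "admission_date": "2004-01-01"},
            {"person_id": "A", "additional_dx": [], "admission_date": "2007-06-01"},
        ]
    )
    flags = flag_dementia(eps, lookback_years=2, window_end="2007-06-30")
    assert flags["A"] is False
    # Same episode inside the window qualifies.
    flags_wide = flag_dementia(eps, lookback_years=4, window_end="2007-06-30")
    assert flags_wide["A"] is True


def test_dementia_principal_code_counts():
    eps = make_episodes([{"person_id": "A", "principal_dx": "F01", "additional_dx": []}])
    assert flag_dementia(eps)["A"] is True


def test_dementia_invariant_to_episode_order(rng):
    rows = []
    for p in range(30):
        for e in range(rng.integers(1, 4)):
            codes = ["G30"] if rng.random() < 0.3 else ["I50"]
            rows.append({"person_id": f"P{p}", "additional_dx": codes,
                         "admission_date": "2006-06-01"})
    eps = make_episodes(rows)
    shuffled = eps.sample(frac=1.0, random_state=7).reset_index(drop=True)
    assert flag_dementia(eps) == flag_dementia(shuffled)


# ---------------------------------------------------------------------------
# Charlson


def test_charlson_empty_is_zero(charlson_cfg):
    assert compute_charlson([], charlson_cfg) == 0


def test_charlson_diabetes_plus_cancer_is_three(charlson_cfg):
    assert compute_charlson(["E11", "C50"], charlson_cfg) == 3


def test_charlson_dementia_codes_excluded(charlson_cfg):
    assert compute_charlson(["G30"], charlson_cfg) == 0
    assert compute_charlson(["F01", "F03"], charlson_cfg) == 0


def test_charlson_condition_counted_once(charlson_cfg):
    # Two diabetes codes still score 1.
    assert compute_charlson(["E11", "E119", "E10"], charlson_cfg) == 1


@settings(deadline=None, max_examples=50)
@given(st.permutations(["E11", "C50", "N18", "I21", "K25", "E11", "C50"]))
def test_charlson_order_invariant_and_idempotent(codes):
    cfg = load_charlson_config()
    base = compute_charlson(["E11", "C50", "N18", "I21", "K25"], cfg)
    assert compute_charlson(codes, cfg) == base
    assert compute_charlson(list(codes) + list(codes), cfg) == base


def _brute_force_charlson(codes, exclude={"dementia"}):
    """Independent oracle: re-read the packaged table with csv and loop."""
    path = resources.files("excesscost") / "data" / "charlson_icd10.csv"
    with path.open() as fh:
        table = list(csv.DictReader(fh))
    norm = [str(c).replace(".", "").upper() for c in codes]
    total = 0
    for row in table:
        if row["condition"] in exclude:
            continue
        prefixes = row["codes"].split(";")
        found = False
        for c in norm:
            for p in prefixes:
                if c.startswith(p):
                    found = True
        if found:
            total += int(row["weight"])
    return total


def test_charlson_matches_brute_force_on_random_code_lists(charlson_cfg, rng):
    vocab = ["E11", "C50", "N18", "I21", "I50", "K25", "G81", "B20", "G30",
             "M05", "K70", "R07", "Z50", "I70", "I63"]
    for _ in range(50):
        codes = list(rng.choice(vocab, size=rng.integers(0, 8)))
        assert compute_charlson(codes, charlson_cfg) == _brute_force_charlson(codes)


# ---------------------------------------------------------------------------
# Complication rules


def test_uti_blocked_by_urinary_principal(rules):
    ep = {"principal_dx": "N30", "additional_dx": ["N390"]}
    assert flag_complications(ep, rules)["urinary_tract_infection"] is False
    ep_ok = {"principal_dx": "R07", "additional_dx": ["N390"]}
    assert flag_complications(ep_ok, rules)["urinary_tract_infection"] is True


def test_pressure_injury_blocked_by_paralysis_anywhere(rules):
    ep = {"principal_dx": "R07", "additional_dx": ["L89", "G81"]}
    assert flag_complications(ep, rules)["pressure_injury"] is False
    ep2 = {"principal_dx": "G82", "additional_dx": ["L89"]}
    assert flag_complications(ep2, rules)["pressure_injury"] is False


def test_no_inclusion_codes_means_no_flags(rules):
    ep = {"principal_dx": "R07", "additional_dx": ["I21", "Z50"]}
    assert not any(flag_complications(ep, rules).values())


def test_principal_diagnosis_never_counts_as_hospital_acquired(rules):
    ep = {"principal_dx": "J18", "additional_dx": []}
    assert flag_complications(ep, rules)["pneumonia"] is False


def test_overlapping_rule_sets_rejected():
    with pytest.raises(RuleValidationError, match="overlap"):
        ComplicationRule(
            name="pneumonia",
            inclusion_codes=frozenset({"J18"}),
            exclusion_codes=frozenset({"J1"}),
        )


def test_rule_table_requires_all_four_complications(tmp_path):
    p = tmp_path / "rules.csv"
    p.write_text(
        "name,inclusion_codes,exclusion_codes,exclusion_scope\n"
        "pneumonia,J18,J69,principal_or_additional\n"
    )
    with pytest.raises(RuleValidationError):
        load_complication_rules(p)


def test_adding_exclusion_code_never_turns_flag_on(rules, rng):
    """Exclusion dominance: appending an exclusion code is monotone non-increasing."""
    vocab = ["N390", "L89", "J18", "F05", "I21", "R07", "E11"]
    for _ in range(100):
        codes = list(rng.choice(vocab, size=rng.integers(0, 5)))
        ep = {"principal_dx": "R07", "additional_dx": codes}
        before = flag_complications(ep, rules)
        for rule in rules:
            exc = sorted(rule.exclusion_codes)[0]
            ep_exc = {"principal_dx": "R07", "additional_dx": codes + [exc]}
            after = flag_complications(ep_exc, rules)
            assert not (after[rule.name] and not before[rule.name])


def _brute_force_flags(episode, rules):
    """Naive matcher testing every code against every rule."""
    out = {}
    principal = str(episode["principal_dx"]).replace(".", "").upper()
    additional = [str(c).replace(".", "").upper() for c in episode["additional_dx"]]
    for rule in rules:
        inc = False
        for c in additional:
            for p in rule.inclusion_codes:
                if c.startswith(p):
                    inc = True
        pool = [principal] + (additional if rule.exclusion_scope == "principal_or_additional" else [])
        exc = False
        for c in pool:
            for p in rule.exclusion_codes:
                if c.startswith(p):
                    exc = True
        out[rule.name] = inc and not exc
    return out


def test_flags_match_brute_force_on_random_fixture(rules, rng):
    vocab = ["N390", "T835", "L89", "J18", "J13", "F05", "G81", "N30", "J69",
             "F10", "I21", "R07", "E11", "Z50"]
    rows = []
    for i in range(50):
        rows.append(
            {
                "principal_dx": str(rng.choice(vocab)),
                "additional_dx": list(rng.choice(vocab, size=rng.integers(0, 6))),
            }
        )
    eps = make_episodes(rows)
    coded = code_episodes(eps, rules=rules)
    for i, row in eps.iterrows():
        expected = _brute_force_flags(row, rules)
        got_single = flag_complications(row, rules)
        assert got_single == expected
        for name, val in expected.items():
            assert bool(coded.loc[i, name]) == val, (i, name)


# ---------------------------------------------------------------------------
# Composition


def test_code_episodes_counts_and_hand_rates(rules, charlson_cfg):
    rows = [
        # UTI + pneumonia -> 2 complications
        {"person_id": "A", "additional_dx": ["N390", "J18"], "admission_date": "2006-06-01"},
        # pressure injury blocked by paralysis; charlson hemiplegia=2
        {"person_id": "B", "additional_dx": ["L89", "G81"], "admission_date": "2006-06-01"},
        # dementia person, no complications
        {"person_id": "C", "additional_dx": ["G30", "E11"], "admission_date": "2006-06-01"},
        # delirium only
        {"person_id": "D", "additional_dx": ["F05"], "admission_date": "2006-06-01"},
        # nothing
        {"person_id": "E", "additional_dx": [], "admission_date": "2006-06-01"},
    ]
    coded = code_episodes(make_episodes(rows), rules=rules, charlson_config=charlson_cfg)
    assert list(coded["n_complications"]) == [2, 0, 0, 1, 0]
    assert list(coded["dementia"]) == [False, False, True, False, False]
    assert list(coded["charlson"]) == [0, 2, 1, 0, 0]
    # Population summaries as hand-counted.
    assert coded["n_complications"].sum() == 3
    assert (coded["n_complications"] > 0).mean() == pytest.approx(2 / 5)


def test_code_episodes_deterministic(rules):
    eps = make_episodes(
        [{"person_id": f"P{i}", "additional_dx": ["N390"] if i % 2 else []} for i in range(20)]
    )
    a = code_episodes(eps, rules=rules)
    b = code_episodes(eps, rules=rules)
    pd.testing.assert_frame_equal(a, b)
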