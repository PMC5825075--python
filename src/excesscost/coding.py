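"""Cohort filters, dementia linkage, Charlson comorbidity and complication coding.

This module turns raw discharge episodes into analysis-ready coded episodes:

* :func:`filter_cohort` applies the age and length-of-stay filters with an
  exclusion log (one reason per excluded row).
* :func:`flag_dementia` is a person-linked lookback: a person is a dementia
  case if any of their episodes inside the lookback window carries a
  qualifying code as principal or additional diagnosis, and the flag then
  propagates to all of that person's episodes.
* :func:`compute_charlson` scores comorbidity with the classic 1/2/3/6
  weights over a configurable ICD-10 prefix map, counting each condition at
  most once.  Dementia is excluded from the index by default because it is
  modelled as its own predictor.
* :func:`flag_complications` applies conservative hospital-acquired
  complication rules: an inclusion code must appear among the *additional*
  diagnoses (a principal diagnosis is, by definition, not hospital-acquired)
  and no aetiology-exclusion code may match within the rule's scope.

All code matching is prefix-based on normalised codes (dots stripped,
upper-cased), the standard convention for administrative ICD-10 data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

DEMENTIA_CODES = frozenset({"F00", "F01", "F02", "G30", "G31"})
DEFAULT_LOOKBACK_YEARS = 2.0
DEFAULT_MIN_AGE = 50
DEFAULT_MAX_LOS = 90

COMPLICATION_NAMES = (
    "urinary_tract_infection",
    "pressure_injury",
    "pneumonia",
    "delirium",
)

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]*$")


class RuleValidationError(ValueError):
    """A complication rule table failed validation."""


class CohortValidationError(ValueError):
    """One or more episode rows are malformed."""


def normalize_code(code: str) -> str:
    """Normalise an ICD-10 code for prefix matching: strip dots, upper-case."""
    return str(code).replace(".", "").strip().upper()


def _matches_any(code: str, prefixes: Iterable[str]) -> bool:
    return any(code.startswith(p) for p in prefixes)


# ---------------------------------------------------------------------------
# Complication rules


@dataclass(frozen=True)
class ComplicationRule:
    """A named hospital-acquired complication with aetiology exclusions.

    ``exclusion_scope`` controls where exclusion codes are searched:
    ``principal_only`` (e.g. a urinary-tract principal diagnosis blocks the
    UTI flag) or ``principal_or_additional`` (e.g. paralysis anywhere blocks
    the pressure-injury flag).
    """

    name: str
    inclusion_codes: frozenset[str]
    exclusion_codes: frozenset[str]
    exclusion_scope: str = "principal_or_additional"

    def __post_init__(self):
        if self.exclusion_scope not in ("principal_only", "principal_or_additional"):
            raise RuleValidationError(
                f"rule {self.name!r}: unknown exclusion_scope {self.exclusion_scope!r}"
            )
        if not self.inclusion_codes:
            raise RuleValidationError(f"rule {self.name!r}: empty inclusion set")
        # Prefix overlap between the two sets would make the rule contradictory.
        for inc in self.inclusion_codes:
            for exc in self.exclusion_codes:
                if inc.startswith(exc) or exc.startswith(inc):
                    raise RuleValidationError(
                        f"rule {self.name!r}: inclusion code {inc!r} overlaps "
                        f"exclusion code {exc!r}"
                    )


def _default_rules_path():
    return resources.files("excesscost") / "data" / "complication_rules.csv"


def load_complication_rules(path=None) -> list[ComplicationRule]:
    """Load and validate the complication rule table (packaged table by default).

    The table must contain each of the four tracked complications exactly once.
    """
    df = pd.read_csv(path if path is not None else _default_rules_path())
    rules = []
    for row in df.itertuples(index=False):
        rules.append(
            ComplicationRule(
                name=row.name,
                inclusion_codes=frozenset(
                    normalize_code(c) for c in str(row.inclusion_codes).split(";") if c
                ),
                exclusion_codes=frozenset(
                    normalize_code(c)
                    for c in str(row.exclusion_codes).split(";")
                    if c and not pd.isna(row.exclusion_codes)
                ),
                exclusion_scope=row.exclusion_scope,
            )
        )
    names = [r.name for r in rules]
    for required in COMPLICATION_NAMES:
        if names.count(required) != 1:
            raise RuleValidationError(
                f"rule table must contain {required!r} exactly once, found "
                f"{names.count(required)}"
            )
    return rules


def flag_complications(episode, rules: list[ComplicationRule]) -> dict[str, bool]:
    """Flag hospital-acquired complications for a single episode.

    ``episode`` is any mapping-like object with ``principal_dx`` and
    ``additional_dx`` fields.  Returns ``{rule name: bool}``.
    """
    principal = normalize_code(episode["principal_dx"])
    additional = [normalize_code(c) for c in episode["additional_dx"]]
    flags = {}
    for rule in rules:
        included = any(_matches_any(c, rule.inclusion_codes) for c in additional)
        if not included:
            flags[rule.name] = False
            continue
        scope_codes = [principal]
        if rule.exclusion_scope == "principal_or_additional":
            scope_codes += additional
        excluded = any(_matches_any(c, rule.exclusion_codes) for c in scope_codes)
        flags[rule.name] = included and not excluded
    return flags


# ---------------------------------------------------------------------------
# Charlson comorbidity index


@dataclass(frozen=True)
class CharlsonConfig:
    """Condition weights and ICD-10 prefixes for the comorbidity index."""

    weights: Mapping[str, int]
    code_map: Mapping[str, tuple[str, ...]]
    exclude: frozenset[str] = frozenset({"dementia"})


def load_charlson_config(path=None, exclude=frozenset({"dementia"})) -> CharlsonConfig:
    df = pd.read_csv(path if path is not None else resources.files("excesscost") / "data" / "charlson_icd10.csv")
    weights = {row.condition: int(row.weight) for row in df.itertuples(index=False)}
    code_map = {
        row.condition: tuple(normalize_code(c) for c in str(row.codes).split(";"))
        for row in df.itertuples(index=False)
    }
    return CharlsonConfig(weights=weights, code_map=code_map, exclude=frozenset(exclude))


def compute_charlson(dx_codes: Iterable[str], config: CharlsonConfig | None = None) -> int:
    """Weighted comorbidity score over distinct conditions present in ``dx_codes``.

    Each condition counts at most once no matter how many of its codes occur;
    conditions in ``config.exclude`` (dementia by default) never contribute.
    Unknown codes are ignored.
    """
    if config is None:
        config = load_charlson_config()
    codes = [normalize_code(c) for c in dx_codes]
    score = 0
    for condition, prefixes in config.code_map.items():
        if condition in config.exclude:
            continue
        if any(_matches_any(c, prefixes) for c in codes):
            score += config.weights[condition]
    return score


# ---------------------------------------------------------------------------
# Cohort filter


def _validate_episodes(episodes: pd.DataFrame) -> None:
    errors = []
    for i, row in enumerate(episodes.itertuples(index=False)):
        if row.los_days < 1:
            errors.append(f"row {i}: los_days={row.los_days} < 1 (day-stays excluded upstream)")
        pdx = normalize_code(row.principal_dx)
        if not pdx:
            errors.append(f"row {i}: empty principal_dx")
        elif not _ICD10_RE.match(pdx):
            errors.append(f"row {i}: principal_dx {row.principal_dx!r} is not an ICD-10 code")
        for c in row.additional_dx:
            if not _ICD10_RE.match(normalize_code(c)):
                errors.append(f"row {i}: additional_dx {c!r} is not an ICD-10 code")
    if errors:
        raise CohortValidationError("; ".join(errors))


def filter_cohort(
    episodes: pd.DataFrame,
    min_age: int = DEFAULT_MIN_AGE,
    max_los: int = DEFAULT_MAX_LOS,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the cohort filters: age at least ``min_age``, LOS in [1, ``max_los``].

    Returns the retained episodes and an exclusion log counting excluded rows
    by (first applicable) reason, so input rows = retained + sum(log values).
    """
    _validate_episodes(episodes)
    age_ok = episodes["age"] >= min_age
    los_ok = episodes["los_days"] <= max_los
    log = {
        "age_lt_min": int((~age_ok).sum()),
        "los_gt_max": int((age_ok & ~los_ok).sum()),
    }
    return episodes.loc[age_ok & los_ok].reset_index(drop=True), log


# ---------------------------------------------------------------------------
# Dementia linkage


def flag_dementia(
    episodes: pd.DataFrame,
    codes: frozenset[str] = DEMENTIA_CODES,
    lookback_years: float = DEFAULT_LOOKBACK_YEARS,
    window_end=None,
) -> dict[str, bool]:
    """Person-level dementia ascertainment over a lookback window.

    A person is flagged if any of their episodes admitted within
    ``[window_end - lookback_years, window_end]`` carries a qualifying code
    (prefix match) as principal or additional diagnosis.  ``window_end``
    defaults to the latest admission date present.
    """
    dates = pd.to_datetime(episodes["admission_date"])
    if window_end is None:
        window_end = dates.max()
    window_end = pd.Timestamp(window_end)
    window_start = window_end - pd.Timedelta(days=round(lookback_years * 365.25))
    in_window = (dates >= window_start) & (dates <= window_end)

    prefixes = tuple(codes)
    principal = episodes["principal_dx"].map(normalize_code)
    has_code = principal.str.startswith(prefixes) | episodes["additional_dx"].map(
        lambda lst: any(normalize_code(c).startswith(prefixes) for c in lst)
    )
    qualifies = pd.Series(np.asarray(has_code) & np.asarray(in_window), index=episodes.index)
    by_person = qualifies.groupby(episodes["person_id"]).any()
    return {pid: bool(v) for pid, v in by_person.items()}


def lookup_dementia(flags: Mapping[str, bool], person_id: str) -> bool:
    if person_id not in flags:
        raise KeyError(f"unknown person_id {person_id!r}")
    return flags[person_id]


# ---------------------------------------------------------------------------
# Vectorised composition


def _exploded_codes(episodes: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Long-form (row index, normalised code) views of additional and principal dx."""
    add = episodes["additional_dx"].explode().dropna().astype(str)
    add = add.str.replace(".", "", regex=False).str.upper()
    principal = episodes["principal_dx"].astype(str).str.replace(".", "", regex=False).str.upper()
    return add, principal


def _any_match_by_row(codes: pd.Series, prefixes: frozenset[str], index) -> pd.Series:
    """Boolean per original row: does any code in the long-form series match?"""
    if len(codes) == 0 or not prefixes:
        return pd.Series(False, index=index)
    hit = codes.str.startswith(tuple(prefixes))
    per_row = hit.groupby(level=0).any()
    return per_row.reindex(index, fill_value=False)


def code_episodes(
    episodes: pd.DataFrame,
    rules: list[ComplicationRule] | None = None,
    charlson_config: CharlsonConfig | None = None,
    dementia_codes: frozenset[str] = DEMENTIA_CODES,
    lookback_years: float = DEFAULT_LOOKBACK_YEARS,
    window_end=None,
) -> pd.DataFrame:
    """Produce the coded episode table: dementia, Charlson, complication flags.

    Vectorised equivalent of applying :func:`flag_dementia`,
    :func:`compute_charlson` and :func:`flag_complications` row by row;
    adds ``dementia``, ``charlson``, one boolean column per complication and
    ``n_complications``.
    """
    if rules is None:
        rules = load_complication_rules()
    if charlson_config is None:
        charlson_config = load_charlson_config()

    coded = episodes.reset_index(drop=True).copy()
    add, principal = _exploded_codes(coded)

    # Complications: inclusion among additional dx, exclusion within scope.
    for rule in rules:
        included = _any_match_by_row(add, rule.inclusion_codes, coded.index)
        excluded = principal.str.startswith(tuple(rule.exclusion_codes)) if rule.exclusion_codes else pd.Series(False, index=coded.index)
        if rule.exclusion_scope == "principal_or_additional":
            excluded = excluded | _any_match_by_row(add, rule.exclusion_codes, coded.index)
        coded[rule.name] = (included & ~excluded).astype(bool)
    coded["n_complications"] = sum(coded[r.name].astype(int) for r in rules)

    # Charlson over principal + additional diagnoses, dementia excluded.
    score = np.zeros(len(coded), dtype=int)
    for condition, prefixes in charlson_config.code_map.items():
        if condition in charlson_config.exclude:
            continue
        present = _any_match_by_row(add, frozenset(prefixes), coded.index) | principal.str.startswith(tuple(prefixes))
        score += np.asarray(present, dtype=int) * charlson_config.weights[condition]
    coded["charlson"] = score

    flags = flag_dementia(coded, codes=dementia_codes, lookback_years=lookback_years, window_end=window_end)
    coded["dementia"] = coded["person_id"].map(flags).astype(bool)
    return coded
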