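"""Synthetic hospital discharge data with known log-linear excess-cost structure.

Real state administrative discharge data cannot be redistributed, so this
module emulates its structure: an episode-level table (person-linked, with
ICD-10 principal/additional diagnoses, DRG, whole-day LOS and demographics)
plus a DRG reference table with average overnight LOS, cost weight and the
sixteen treatment-expense subcategories.

The generative model mirrors the analysis model.  Each episode draws
covariates (age, sex, surgery, dementia, complication flags, Charlson
conditions, a DRG carrying its cost weight); a designated fraction of
episodes is "above average", and for those the latent excess cost is

    extra_cost = exp(intercept + sum(true_effects * covariates) + eps),
    eps ~ Normal(0, noise_sd)

LOS is then back-derived as ``round(avg_los + extra_cost / daily_variable_cost)``
so that the cost stage reproduces the intended excess cost up to whole-day
rounding.  Diagnosis lists are constructed so the coding stage recovers every
latent flag and score exactly: complication-bearing episodes carry the rule's
inclusion code and never a matching exclusion code, Charlson conditions carry
one representative code each, dementia persons carry a qualifying code on at
least one episode inside the window, and filler codes come from a vocabulary
disjoint from every rule and index code.

A ground-truth sidecar records the latent values for parameter-recovery
tests; the coding/cost/regression stages never read it.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as ecio
from .cost import ALL_SUBCATEGORIES, FIXED_SUBCATEGORIES, VARIABLE_SUBCATEGORIES

DEMENTIA_CODE_CHOICES = ("F00", "F01", "F02", "G30", "G31")

# Representative ICD-10 codes written onto episodes for each latent feature.
COMPLICATION_CODES = {
    "urinary_tract_infection": "N390",
    "pressure_injury": "L89",
    "pneumonia": "J18",
    "delirium": "F05",
}
CHARLSON_CONDITION_CODES = {
    "myocardial_infarction": "I21",
    "congestive_heart_failure": "I50",
    "peripheral_vascular_disease": "I70",
    "cerebrovascular_disease": "I63",
    "rheumatic_disease": "M05",
    "peptic_ulcer_disease": "K25",
    "liver_disease": "K70",
    "diabetes": "E11",
    "hemiplegia_paraplegia": "G81",
    "renal_disease": "N18",
    "any_cancer": "C50",
    "aids_hiv": "B20",
}
CHARLSON_WEIGHTS = {
    "myocardial_infarction": 1,
    "congestive_heart_failure": 1,
    "peripheral_vascular_disease": 1,
    "cerebrovascular_disease": 1,
    "rheumatic_disease": 1,
    "peptic_ulcer_disease": 1,
    "liver_disease": 1,
    "diabetes": 1,
    "hemiplegia_paraplegia": 2,
    "renal_disease": 2,
    "any_cancer": 2,
    "aids_hiv": 6,
}
# Marginal probability of each condition per episode; gives a mean index
# near 1 as observed in older above-average-stay inpatient populations.
CHARLSON_CONDITION_PREVALENCE = {
    "myocardial_infarction": 0.06,
    "congestive_heart_failure": 0.10,
    "peripheral_vascular_disease": 0.04,
    "cerebrovascular_disease": 0.10,
    "rheumatic_disease": 0.03,
    "peptic_ulcer_disease": 0.02,
    "liver_disease": 0.03,
    "diabetes": 0.20,
    "hemiplegia_paraplegia": 0.02,
    "renal_disease": 0.08,
    "any_cancer": 0.09,
    "aids_hiv": 0.004,
}

# Benign codes used for principal diagnoses and list padding; disjoint by
# construction from every complication-rule and Charlson prefix so latent
# flags stay exactly recoverable.
FILLER_CODES = ("A09", "H25", "H81", "R07", "R10", "R55", "M54", "S72", "T14", "Z50")

COMPLICATIONS = tuple(COMPLICATION_CODES)


class ConfigurationError(ValueError):
    """A generator configuration field is invalid."""


class GenerationError(RuntimeError):
    """The configured effects/prevalences produced an infeasible episode."""


def _default_prevalence() -> dict[str, float]:
    return {
        "dementia": 0.119,
        "urinary_tract_infection": 0.082,
        "pressure_injury": 0.026,
        "pneumonia": 0.037,
        "delirium": 0.019,
        "surgery": 0.237,
        "male": 0.470,
    }


def _default_true_effects() -> dict[str, float]:
    return {
        "intercept": 7.85,
        "age": 0.003,
        "male": 0.015,
        "surgical": 0.008,
        "dementia": 0.14,
        "cost_weight": 0.05,
        "charlson": 0.04,
        "n_complications": 0.13,
    }


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic discharge data.

    Defaults reproduce the analysis population's stated characteristics:
    age uniform on 50-107, 53% female, 23.7% surgical, 11.9% dementia,
    complication prevalences 8.2/2.6/3.7/1.9%, 37% of episodes above their
    DRG's average overnight LOS, and a Gaussian log-linear excess-cost model
    with residual SD 0.9.
    """

    n_persons: int = 15400
    episodes_per_person: float = 1.3
    n_drgs: int = 300
    date_window: tuple[str, str] = ("2005-07-01", "2007-06-30")
    prevalence: dict[str, float] = field(default_factory=_default_prevalence)
    true_effects: dict[str, float] = field(default_factory=_default_true_effects)
    noise_sd: float = 0.9
    frac_above_average: float = 0.37
    age_range: tuple[int, int] = (50, 107)
    mean_cost_all_separations: float = 3800.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_persons < 1:
            raise ConfigurationError("n_persons must be >= 1")
        if self.n_drgs < 1:
            raise ConfigurationError("n_drgs must be >= 1")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.episodes_per_person < 1:
            raise ConfigurationError("episodes_per_person must be >= 1")
        for key, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"prevalence[{key!r}]={p} outside [0, 1]")
        if not 0.0 <= self.frac_above_average <= 1.0:
            raise ConfigurationError("frac_above_average outside [0, 1]")
        start, end = (pd.Timestamp(d) for d in self.date_window)
        if (end - start).days < 729:
            raise ConfigurationError(
                "date_window must span at least two years for the dementia lookback"
            )

    def to_json(self, path: os.PathLike | str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)

    @classmethod
    def from_json(cls, path: os.PathLike | str) -> "GeneratorConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["date_window"] = tuple(raw["date_window"])
        raw["age_range"] = tuple(raw["age_range"])
        return cls(**raw)


def generate_drg_reference(config: GeneratorConfig) -> pd.DataFrame:
    """One row per DRG: average overnight LOS, cost weight, 16 subcategory costs.

    Total DRG cost is the cost weight times the mean cost of all separations;
    a variable share of 60-85% is spread over the eleven variable
    subcategories (Dirichlet) and the remainder over the five fixed ones.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    n = config.n_drgs
    drg = [f"D{i:03d}" for i in range(n)]
    cost_weight = np.clip(rng.lognormal(np.log(1.5), 0.6, size=n), 0.1, 46.0)
    # Resource-intensive DRGs keep patients longer: average LOS rises with
    # cost weight (sub-linearly), as in published casemix tables.  This also
    # keeps daily variable cost in a realistic band across DRGs.
    avg_los = np.maximum(
        rng.lognormal(np.log(4.0), 0.25, size=n) * (cost_weight / 1.5) ** 0.6, 1.5
    )
    total = cost_weight * config.mean_cost_all_separations
    var_share = rng.uniform(0.60, 0.85, size=n)
    var_split = rng.dirichlet(np.ones(len(VARIABLE_SUBCATEGORIES)), size=n)
    fix_split = rng.dirichlet(np.ones(len(FIXED_SUBCATEGORIES)), size=n)
    ref = pd.DataFrame({"drg": drg, "avg_overnight_los": avg_los, "cost_weight": cost_weight})
    var_amounts = var_split * (total * var_share)[:, None]
    fix_amounts = fix_split * (total * (1 - var_share))[:, None]
    for j, name in enumerate(VARIABLE_SUBCATEGORIES):
        ref[name] = var_amounts[:, j]
    for j, name in enumerate(FIXED_SUBCATEGORIES):
        ref[name] = fix_amounts[:, j]
    return ref


def _build_additional_dx(
    rng: np.random.Generator,
    charlson_matrix: np.ndarray,
    comp_matrix: np.ndarray,
    dementia_code_here: np.ndarray,
    person_dementia_code: np.ndarray,
) -> list[list[str]]:
    conditions = list(CHARLSON_CONDITION_CODES)
    n = charlson_matrix.shape[0]
    n_fillers = rng.integers(0, 3, size=n)
    filler_pick = rng.integers(0, len(FILLER_CODES), size=(n, 2))
    out = []
    for i in range(n):
        codes = [CHARLSON_CONDITION_CODES[c] for j, c in enumerate(conditions) if charlson_matrix[i, j]]
        codes += [COMPLICATION_CODES[c] for j, c in enumerate(COMPLICATIONS) if comp_matrix[i, j]]
        if dementia_code_here[i]:
            codes.append(person_dementia_code[i])
        codes += [FILLER_CODES[filler_pick[i, k]] for k in range(n_fillers[i])]
        out.append(codes)
    return out


def generate_episodes(
    config: GeneratorConfig, drg_ref: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the episode table and its ground-truth sidecar.

    Returns ``(episodes, ground_truth)``; episode observables (codes, LOS,
    DRG) are consistent with the latent record row by row.
    """
    config.validate()
    if drg_ref is None:
        drg_ref = generate_drg_reference(config)
    rng = np.random.default_rng([config.seed, 202])
    prev = {**_default_prevalence(), **config.prevalence}
    eff = {**_default_true_effects(), **config.true_effects}

    # Person-level draws.
    n_p = config.n_persons
    male_p = rng.random(n_p) < prev["male"]
    dementia_p = rng.random(n_p) < prev["dementia"]
    lo, hi = config.age_range
    age_p = rng.integers(lo, hi + 1, size=n_p)
    n_ep_p = 1 + rng.poisson(config.episodes_per_person - 1.0, size=n_p)
    dem_code_p = rng.integers(0, len(DEMENTIA_CODE_CHOICES), size=n_p)

    person_idx = np.repeat(np.arange(n_p), n_ep_p)
    n = len(person_idx)
    episode_order = np.arange(n)

    # Episode-level draws.
    start, end = (pd.Timestamp(d) for d in config.date_window)
    offsets = rng.integers(0, (end - start).days + 1, size=n)
    admission = start + pd.to_timedelta(offsets, unit="D")
    surgical = rng.random(n) < prev["surgery"]
    comp_matrix = np.column_stack([rng.random(n) < prev[c] for c in COMPLICATIONS])
    cond_names = list(CHARLSON_CONDITION_PREVALENCE)
    charlson_matrix = np.column_stack(
        [rng.random(n) < CHARLSON_CONDITION_PREVALENCE[c] for c in cond_names]
    )
    # Pressure-injury episodes cannot carry the paralysis exclusion codes,
    # so the hemiplegia condition is suppressed there (truth follows suit).
    pi_col = COMPLICATIONS.index("pressure_injury")
    hemi_col = cond_names.index("hemiplegia_paraplegia")
    charlson_matrix[comp_matrix[:, pi_col], hemi_col] = False
    weights = np.array([CHARLSON_WEIGHTS[c] for c in cond_names])
    charlson = charlson_matrix @ weights
    n_comp = comp_matrix.sum(axis=1)

    drg_idx = rng.integers(0, config.n_drgs, size=n)
    avg_los = drg_ref["avg_overnight_los"].to_numpy()[drg_idx]
    cost_weight = drg_ref["cost_weight"].to_numpy()[drg_idx]
    var_total = drg_ref[list(VARIABLE_SUBCATEGORIES)].sum(axis=1).to_numpy()[drg_idx]
    dvc = var_total / avg_los

    age = age_p[person_idx]
    male = male_p[person_idx]
    dementia = dementia_p[person_idx]

    eta = (
        eff["intercept"]
        + eff["age"] * age
        + eff["male"] * male
        + eff["surgical"] * surgical
        + eff["dementia"] * dementia
        + eff["cost_weight"] * cost_weight
        + eff["charlson"] * charlson
        + eff["n_complications"] * n_comp
    )
    eps = rng.normal(0.0, config.noise_sd, size=n)
    intended_cost = np.exp(eta + eps)
    intended_days = intended_cost / dvc

    above = rng.random(n) < config.frac_above_average
    los = np.empty(n, dtype=int)
    los[above] = np.rint(avg_los[above] + intended_days[above]).astype(int)
    below_cap = np.maximum(np.floor(avg_los[~above]).astype(int), 1)
    los[~above] = rng.integers(1, below_cap + 1)
    los = np.maximum(los, 1)
    if (los < 1).any():
        raise GenerationError("configuration produced an episode with LOS < 1 day")

    # Dementia documentation: guaranteed on one randomly chosen episode per
    # dementia person, re-documented on other episodes with probability 0.5.
    dem_here = dementia & (rng.random(n) < 0.5)
    person_start = np.concatenate([[0], np.cumsum(n_ep_p)[:-1]])
    anchor_global = person_start + rng.integers(0, n_ep_p)
    anchor = np.zeros(n, dtype=bool)
    anchor[anchor_global] = True
    dem_here |= dementia & anchor
    person_dem_code = np.array(DEMENTIA_CODE_CHOICES)[dem_code_p[person_idx]]

    principal = np.array(FILLER_CODES)[rng.integers(0, len(FILLER_CODES), size=n)]
    additional = _build_additional_dx(rng, charlson_matrix, comp_matrix, dem_here, person_dem_code)

    episodes = pd.DataFrame(
        {
            "person_id": [f"P{p:06d}" for p in person_idx],
            "episode_id": [f"E{i:07d}" for i in episode_order],
            "age": age,
            "sex": np.where(male, "male", "female"),
            "los_days": los,
            "drg": drg_ref["drg"].to_numpy()[drg_idx],
            "principal_dx": principal,
            "additional_dx": additional,
            "surgical": surgical,
            "admission_date": admission,
        }
    )
    truth = pd.DataFrame(
        {
            "person_id": episodes["person_id"],
            "episode_id": episodes["episode_id"],
            "age": age,
            "male": male.astype(int),
            "surgical": surgical.astype(int),
            "dementia": dementia.astype(int),
            "charlson": charlson,
            "n_complications": n_comp,
            "cost_weight": cost_weight,
            "eta": eta,
            "epsilon": eps,
            "intended_extra_cost": np.where(above, intended_cost, 0.0),
            "intended_extra_days": np.where(above, intended_days, 0.0),
            "above_average_assigned": above.astype(int),
        }
    )
    for j, c in enumerate(COMPLICATIONS):
        truth[c] = comp_matrix[:, j].astype(int)
    return episodes, truth


def write_fixture(
    outdir: os.PathLike | str,
    episodes: pd.DataFrame,
    drg_ref: pd.DataFrame,
    ground_truth: pd.DataFrame | None = None,
    config: GeneratorConfig | None = None,
) -> dict[str, str]:
    """Write the generated tables as CSV (plus JSON config) under ``outdir``.

    Round-trips losslessly through :mod:`excesscost.io` readers.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "episodes": os.path.join(outdir, "episodes.csv"),
        "drg_reference": os.path.join(outdir, "drg_reference.csv"),
    }
    ecio.write_episodes(paths["episodes"], episodes)
    ecio.write_drg_reference(paths["drg_reference"], drg_ref)
    if ground_truth is not None:
        paths["ground_truth"] = os.path.join(outdir, "ground_truth.csv")
        ecio.write_ground_truth(paths["ground_truth"], ground_truth)
    if config is not None:
        paths["config"] = os.path.join(outdir, "config.json")
        config.to_json(paths["config"])
    return paths
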