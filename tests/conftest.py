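import numpy as np
import pandas as pd
import pytest

from excesscost.cost import ALL_SUBCATEGORIES


def make_episodes(rows):
    """Build an episode table from partial row dicts, filling sane defaults."""
    defaults = {
        "person_id": "P1",
        "episode_id": None,
        "age": 70,
        "sex": "female",
        "los_days": 5,
        "drg": "D001",
        "principal_dx": "R07",
        "additional_dx": [],
        "surgical": False,
        "admission_date": "2006-10-01",
    }
    out = []
    for i, row in enumerate(rows):
        rec = {**defaults, **row}
        if rec["episode_id"] is None:
            rec["episode_id"] = f"E{i:04d}"
        out.append(rec)
    df = pd.DataFrame(out)
    df["admission_date"] = pd.to_datetime(df["admission_date"])
    return df


def make_drg_ref(rows):
    """Build a DRG reference table; unspecified subcategories default to 0."""
    out = []
    for row in rows:
        rec = {"drg": "D001", "avg_overnight_los": 5.0, "cost_weight": 1.0}
        rec.update({k: 0.0 for k in ALL_SUBCATEGORIES})
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture
def rules():
    from excesscost.coding import load_complication_rules

    return load_complication_rules()


@pytest.fixture
def charlson_cfg():
    from excesscost.coding import load_charlson_config

    return load_charlson_config()


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
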