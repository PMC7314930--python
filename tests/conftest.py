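import math

import numpy as np
import pandas as pd
import pytest

from methpanel import simulate as sim
from methpanel.cohort import Cohort, SCHEMA_COLUMNS


@pytest.fixture(scope="session")
def training_cohort() -> Cohort:
    """Deterministic cohort realising the reported training-set counts."""
    return sim.reference_cohort("training")


@pytest.fixture(scope="session")
def validation_cohort() -> Cohort:
    return sim.reference_cohort("validation")


def make_record(sample_id="S1", group="control", stage=None, age=50, sex="male",
                location="unknown", size=math.nan, actb=(30.0, 30.0, 30.0),
                sept9=(math.nan,) * 3, sdc2=(math.nan,) * 3) -> dict:
    if stage is None:
        stage = "II" if group == "CRC" else "NA"
    row = {"sample_id": sample_id, "group": group, "stage": stage, "age": age,
           "sex": sex, "location": location, "tumor_size_cm": size}
    for name, cts in (("actb", actb), ("sept9", sept9), ("sdc2", sdc2)):
        for i in (1, 2, 3):
            row[f"{name}_ct_{i}"] = cts[i - 1]
    return row


def make_cohort(rows, label="test") -> Cohort:
    frame = pd.DataFrame(rows, columns=list(SCHEMA_COLUMNS))
    return Cohort(frame, label=label)


@pytest.fixture
def tiny_cohort() -> Cohort:
    rows = [
        make_record("P1", "CRC", sept9=(33.0, 33.5, 34.0), sdc2=(36.0, 36.5, math.nan)),
        make_record("P2", "CRC", sept9=(44.0, math.nan, math.nan)),
        make_record("N1", "control"),
        make_record("N2", "control", sept9=(40.0, 41.0, 42.0)),
        make_record("A1", "AA", sdc2=(38.0, 39.0, 40.0)),
    ]
    return make_cohort(rows)


def random_cohort(rng: np.random.Generator, n_per_group=(8, 3, 8)) -> Cohort:
    """Small random cohort exercising absent wells and mixed Ct levels."""
    rows = []
    for group, n in zip(("control", "AA", "CRC"), n_per_group):
        for i in range(n):
            def triplet(p_detect, lo, hi):
                return tuple(
                    float(rng.uniform(lo, hi)) if rng.random() < p_detect else math.nan
                    for _ in range(3))
            rows.append(make_record(
                f"{group}{i}", group,
                actb=triplet(0.95, 24.0, 43.0),
                sept9=triplet(rng.uniform(0.2, 0.9), 30.0, 44.9),
                sdc2=triplet(rng.uniform(0.2, 0.9), 32.0, 49.9),
            ))
    return make_cohort(rows)
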