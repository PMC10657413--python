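import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from syngrowth import MeasurementTable

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_table(rows, **metadata) -> MeasurementTable:
    """Build a MeasurementTable from (animal, group, day, volume[, weight]) tuples."""
    records = []
    for row in rows:
        animal, group, day, volume = row[:4]
        weight = row[4] if len(row) > 4 else np.nan
        records.append(
            {
                "animal_id": animal,
                "group": group,
                "day": day,
                "volume": volume,
                "body_weight": weight,
            }
        )
    return MeasurementTable.from_dataframe(pd.DataFrame(records), metadata)


def exponential_rows(animal, group, days, v0, rate, weight=20.0):
    return [(animal, group, d, v0 * np.exp(rate * d), weight) for d in days]


@pytest.fixture
def two_arm_table() -> MeasurementTable:
    """Noiseless two-arm study: vehicle grows at 0.30/day, treated at 0.15/day."""
    rows = []
    for i in range(3):
        rows += exponential_rows(f"v{i}", "vehicle", [0, 2, 4, 7], 30, 0.30)
        rows += exponential_rows(f"t{i}", "treated", [0, 2, 4, 7], 30, 0.15)
    return make_table(rows)
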