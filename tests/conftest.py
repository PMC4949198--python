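import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from wqagree import (
    AdjectiveRatings,
    MeasureTable,
    QBA_ADJECTIVES,
    QBAConfig,
    default_protocol,
)


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def qba_config(protocol) -> QBAConfig:
    return protocol.qba


def make_ratings(values, visit="farm01:2026-01-01", observer="A"):
    """AdjectiveRatings from a scalar, a sequence of 20, or a mapping."""
    if isinstance(values, dict):
        mapping = values
    elif np.isscalar(values):
        mapping = {a: float(values) for a in QBA_ADJECTIVES}
    else:
        mapping = dict(zip(QBA_ADJECTIVES, values))
    return AdjectiveRatings(visit_id=visit, observer_id=observer, values=mapping)


def make_table(value_a, value_bc, measure="m", kind="fraction", divisor=None):
    value_a = np.asarray(value_a, dtype=float)
    return MeasureTable(
        measure_id=measure,
        visit_ids=[f"farm{i:02d}:2026-01-01" for i in range(len(value_a))],
        value_a=value_a,
        value_bc=np.asarray(value_bc, dtype=float),
        kind=kind,
        scale_divisor=divisor,
    )
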