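import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from litmap.corpus import BibRecord
from litmap.grid import GridSpec, make_grid

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def box_grid():
    """6x6x6 all-in-mask box at 4 mm: the exact-arithmetic ALE fixture."""
    return make_grid(4.0, mask_source="box", box_shape=(6, 6, 6))


@pytest.fixture(scope="session")
def small_grid():
    """Small analytic ellipsoid mask (6 mm) for fast whole-pipeline runs."""
    return GridSpec(resolution_mm=6.0, semi_axes_mm=(40.0, 48.0, 40.0)).make()


def make_record(rid="1", abstract="", title="t", language="en",
                doc_type="Article", year=2020):
    return BibRecord(rid, title, abstract, language, doc_type, year)


@pytest.fixture
def five_records():
    """Hand-built fixture: terms 'alpha beta' and 'gamma delta' co-occur in
    exactly 3 of 5 abstracts."""
    return [
        make_record("1", "alpha beta with gamma delta here"),
        make_record("2", "alpha beta and then gamma delta"),
        make_record("3", "gamma delta precedes alpha beta"),
        make_record("4", "alpha beta alone in this one"),
        make_record("5", "nothing relevant at all today"),
    ]
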