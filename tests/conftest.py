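import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nafldscore import Cohort, DEFAULT_PANEL
from nafldscore.simulate import default_study_scenario, simulate_cohort_margins

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_cohort() -> Cohort:
    """Exact-count cohort reproducing the published per-locus group margins."""
    return simulate_cohort_margins(default_study_scenario(), seed=20180314)


def make_cohort(rows: list[dict]) -> Cohort:
    """Build a small cohort from partial row dicts (defaults filled in)."""
    defaults = {
        "group": "nafld",
        "age": 50.0,
        "sex": "male",
        "bmi": 28.0,
        "t2dm": "no",
        "rs738409": "CC",
        "rs58542926": "CC",
        "rs3750861": "CC",
        "rs4880": "CC",
        "rs13412852": "CC",
    }
    full = []
    for i, row in enumerate(rows):
        rec = {"subject_id": f"s{i:03d}", **defaults, **row}
        full.append(rec)
    return Cohort(DEFAULT_PANEL, pd.DataFrame(full))
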