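import math

import pandas as pd
import pytest

from kpsae.core_data import Dataset


def make_estimates(rows):
    """Direct-estimate frame from (method, point, sigma_or_ci) triples.

    Each row is (method, point, sigma) — the CI is reconstructed as
    point * exp(±1.96 sigma) so the consensus recovers sigma exactly —
    or (method, point, (lo, hi)) for explicit bounds.
    """
    out = []
    for method, point, spread in rows:
        if isinstance(spread, tuple):
            lo, hi = spread
        else:
            lo = point * math.exp(-1.96 * spread)
            hi = point * math.exp(1.96 * spread)
        out.append(
            {
                "region_id": "r01",
                "population": "FSW",
                "method": method,
                "point": float(point),
                "ci_lower": lo,
                "ci_upper": hi,
                "year": 2014,
            }
        )
    return pd.DataFrame(out)


@pytest.fixture
def tiny_dataset():
    """Two regions, one surveyed, with all five collections populated."""
    regions = pd.DataFrame(
        {"region_id": ["r01", "r02"], "name": ["Region 01", "Region 02"]}
    )
    denominators = pd.DataFrame(
        [
            {"region_id": "r01", "sex": "female", "age_band": "18-49", "year": 2014, "count": 10000},
            {"region_id": "r02", "sex": "female", "age_band": "18-49", "year": 2014, "count": 20000},
            {"region_id": "r01", "sex": "female", "age_band": "15-49", "year": 2021, "count": 12000},
            {"region_id": "r02", "sex": "female", "age_band": "15-49", "year": 2021, "count": 24000},
        ]
    )
    estimates = make_estimates(
        [("ss_pse", 200, 0.1), ("mapping", 260, 0.3), ("wisdom_of_crowds", 150, 0.8)]
    )
    program = pd.DataFrame(
        [
            {"source": "DATIM", "population": "FSW", "region_id": "r01",
             "fiscal_quarter": f"FY2020Q{q}", "count": c}
            for q, c in ((1, 60), (2, 70), (3, 80), (4, 90))
        ]
        + [
            {"source": "KP_STAR", "population": "FSW", "region_id": "r01",
             "fiscal_quarter": f"FY2020Q{q}", "count": c}
            for q, c in ((1, 65), (2, 75), (3, 85), (4, 95))
        ]
    )
    covariates = pd.DataFrame(
        [
            {"region_id": "r01", "variable": "hiv_prevalence", "sex_stratum": "all", "value": 20.0},
            {"region_id": "r02", "variable": "hiv_prevalence", "sex_stratum": "all", "value": 10.0},
            {"region_id": "r01", "variable": "population_density", "sex_stratum": "all", "value": 50.0},
            {"region_id": "r02", "variable": "population_density", "sex_stratum": "all", "value": 5.0},
        ]
    )
    return Dataset(
        regions=regions,
        denominators=denominators,
        direct_estimates=estimates,
        program_records=program,
        covariates=covariates,
    )
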