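import numpy as np
import pandas as pd
import pytest

from qcindex import SyntheticConfig, compute_qci, compute_ratios, generate
from qcindex.io import EPI_COLUMNS


def make_epi(measure_values: dict, location="A", year=2000, sex="both") -> pd.DataFrame:
    """One observation unit's EpiTable from a {measure: value} dict."""
    rows = [
        {
            "location": location,
            "location_level": "country",
            "year": year,
            "sex": sex,
            "age": "Age-standardized",
            "measure": m,
            "metric": "rate",
            "value": v,
            "lower": np.nan,
            "upper": np.nan,
        }
        for m, v in measure_values.items()
    ]
    return pd.DataFrame(rows, columns=EPI_COLUMNS)


@pytest.fixture
def toy_epi() -> pd.DataFrame:
    """Single unit with hand-checkable measures."""
    return make_epi(
        {"incidence": 10, "prevalence": 70, "deaths": 1, "DALYs": 35, "YLLs": 20, "YLDs": 15}
    )


@pytest.fixture(scope="session")
def default_run():
    """Full synthetic pipeline at generator defaults (shared across tests)."""
    cfg = SyntheticConfig()
    epi, truth = generate(cfg)
    ratios = compute_ratios(epi)
    result = compute_qci(ratios)
    return {"config": cfg, "epi": epi, "truth": truth, "ratios": ratios, "result": result}


@pytest.fixture(scope="session")
def symmetric_run():
    """Pipeline with no latent sex offset: male and female truly identical."""
    cfg = SyntheticConfig(sex_offset_sd=0.0)
    epi, truth = generate(cfg)
    ratios = compute_ratios(epi)
    result = compute_qci(ratios)
    return {"config": cfg, "epi": epi, "truth": truth, "ratios": ratios, "result": result}


@pytest.fixture(scope="session")
def small_ratio_pool() -> pd.DataFrame:
    """50 random complete ratio rows for PCA-level tests."""
    rng = np.random.default_rng(42)
    n = 50
    df = pd.DataFrame(
        {
            "location": [f"L{i:02d}" for i in range(n)],
            "year": 2010,
            "sex": "both",
            "r_pi": rng.lognormal(3.0, 0.4, n),
            "r_mi": rng.lognormal(-2.5, 0.6, n),
            "r_dp": rng.lognormal(-1.0, 0.5, n),
            "r_ly": rng.lognormal(0.0, 0.7, n),
        }
    )
    df["complete"] = True
    return df
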