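import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from marsflora.experiments import inclusion_sweep_trend
from marsflora.grids import GridSpec, PredictorStack, Raster
from marsflora.survey import SurveyTable


@pytest.fixture
def small_spec():
    return GridSpec(x_origin=127.0, y_origin=38.0, cell_size=0.01,
                    n_rows=10, n_cols=12)


@pytest.fixture
def small_raster(small_spec):
    rng = np.random.default_rng(7)
    return Raster(small_spec, rng.uniform(0, 1, small_spec.shape))


def make_table(records, source="train", crs="EPSG:4326"):
    """records: list of (species, x, y) or (species, x, y, endangered, endemic)."""
    rows = []
    for rec in records:
        sp, x, y = rec[:3]
        en = rec[3] if len(rec) > 3 else False
        em = rec[4] if len(rec) > 4 else False
        rows.append({"species_id": sp, "x": x, "y": y,
                     "endangered": en, "endemic": em, "source": source})
    return SurveyTable(pd.DataFrame(rows), crs=crs)


@pytest.fixture
def tiny_survey():
    return make_table([
        ("A", 127.10, 37.50), ("A", 127.30, 37.60), ("A", 127.32, 37.61),
        ("B", 127.80, 37.10), ("B", 127.81, 37.11),
        ("C", 128.00, 37.90),
    ])


@pytest.fixture(scope="session")
def sweep_result():
    """One shared 10-replicate minimum-record sweep on default synthetic
    communities (used by the trend and method-ordering checks)."""
    return inclusion_sweep_trend(range(10))
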