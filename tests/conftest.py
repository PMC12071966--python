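import numpy as np
import pytest
from hypothesis import settings

from exoenrich import datasets, rsm

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table_design():
    """The bundled 13-run medium-optimization design with responses."""
    return datasets.load_enrichment_design()


@pytest.fixture(scope="session")
def default_fits(table_design):
    """Per-response default-form surface fits on the bundled design."""
    return {
        name: rsm.fit_surface(table_design, name)
        for name in table_design.responses
    }


# Predictive columns of the printed design table, frozen for regression
# checks (integer column to the printed integer, 2-dp columns to 2 dp).
PREDICTED_CELL = np.array(
    [3420, 2941, 4089, 3610, 3854, 3176, 3042, 3988, 3515, 3515, 3515, 3515, 3515],
    dtype=float,
)
PREDICTED_EXOSOME = np.array(
    [74.88, 177.58, 37.92, 71.62, 27.03, 123.47, 156.28, 55.22,
     81.40, 81.40, 81.40, 81.40, 81.40]
)
PREDICTED_GLUCOSE = np.array(
    [75.79, 36.68, 99.05, 59.93, 95.52, 40.21, 51.42, 84.31,
     67.86, 67.86, 67.86, 67.86, 67.86]
)


@pytest.fixture(scope="session")
def predictive_columns():
    return {
        datasets.CELL: (PREDICTED_CELL, 1.0),
        datasets.EXOSOME: (PREDICTED_EXOSOME, 0.05),
        datasets.GLUCOSE: (PREDICTED_GLUCOSE, 0.05),
    }
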