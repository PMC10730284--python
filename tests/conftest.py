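import logging

import numpy as np
import pandas as pd
import pytest

from egsdisparity import (
    GeneratorConfig,
    SurveyDesign,
    build_cohort,
    generate_dataset,
    load_codemaps,
)
from egsdisparity.workflow import prepare_mediation_frame

logging.getLogger("egsdisparity").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def design():
    return SurveyDesign()


@pytest.fixture(scope="session")
def codemaps():
    return load_codemaps()


@pytest.fixture(scope="session")
def dataset():
    """A mid-sized synthetic dataset under the default structural model."""
    cfg = GeneratorConfig(n_discharges=20_000, seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def chole_cohort(dataset, codemaps, design):
    """Cholecystitis cohort with mediation covariates attached."""
    discharges, hospitals, _ = dataset
    co = build_cohort(discharges, codemaps["cholecystitis"])
    prepared, _, _ = prepare_mediation_frame(
        co, hospitals, design, codemaps["cholecystitis"]
    )
    return prepared


@pytest.fixture()
def toy_survey():
    """A printed 12-row, 3-stratum, 2-clusters-per-stratum design fixture.

    Small enough that every estimate can be reproduced by hand or by an
    independently coded linearization.
    """
    return pd.DataFrame({
        "y":           [1.0, 2.0, 3.0, 4.0, 5.0, 1.0, 2.0, 2.0, 4.0, 3.0, 0.0, 6.0],
        "discwt":      [1.0, 2.0, 1.0, 1.0, 2.0, 1.0, 1.0, 3.0, 1.0, 1.0, 2.0, 1.0],
        "stratum_id":  ["A", "A", "A", "A", "B", "B", "B", "B", "C", "C", "C", "C"],
        "hospital_id": ["a1", "a1", "a2", "a2", "b1", "b1", "b2", "b2",
                        "c1", "c1", "c2", "c2"],
    })


def srs_mean_se(y):
    """Textbook simple-random-sample mean and SE of the mean."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    return y.mean(), np.sqrt(y.var(ddof=1) / n)
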