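import numpy as np
import pandas as pd
import pytest

from gcompml import CohortTable


def build_cohort(y, z, covariates: dict, binary=()):
    return CohortTable(
        outcome=np.asarray(y), exposure=np.asarray(z),
        covariates=pd.DataFrame({k: np.asarray(v, dtype=float)
                                 for k, v in covariates.items()}),
        binary_covariates=tuple(binary),
    )


@pytest.fixture
def toy_cohort():
    """24 rows, one continuous covariate, mild confounding."""
    rng = np.random.default_rng(42)
    x = rng.normal(size=24)
    z = (rng.random(24) < 0.3 + 0.4 * (x > 0)).astype(int)
    y = (rng.random(24) < 0.3 + 0.3 * z + 0.2 * (x > 0)).astype(int)
    return build_cohort(y, z, {"X1": x})


@pytest.fixture
def stratified_cohort():
    """40 rows over the four (Z, X) cells of one binary covariate, with
    event counts chosen so every cell mixes both outcomes.

    Cell layout (10 rows each): (Z=0,X=0): 3 events; (Z=0,X=1): 6;
    (Z=1,X=0): 5; (Z=1,X=1): 8.  The exact standardization is
    0.5*(0.5-0.3) + 0.5*(0.8-0.6) = 0.2.
    """
    rows = []
    for z, x, events in ((0, 0, 3), (0, 1, 6), (1, 0, 5), (1, 1, 8)):
        for i in range(10):
            rows.append((1 if i < events else 0, z, x))
    y, z, x = map(np.array, zip(*rows))
    return build_cohort(y, z, {"X1": x}, binary=("X1",))
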