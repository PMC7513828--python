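import numpy as np
import pandas as pd
import pytest

from icmfate import (CircuitParams, GrowthConfig, run_batch)


@pytest.fixture(scope="session")
def params() -> CircuitParams:
    return CircuitParams()


@pytest.fixture(scope="session")
def small_config() -> GrowthConfig:
    """Cheap growth config for unit tests (not the study conditions)."""
    return GrowthConfig(target_size=12, n_initial=2, grn_on_size=6,
                        relax_hours=4.0)


@pytest.fixture(scope="session")
def wildtype_batch() -> pd.DataFrame:
    """100 wild-type embryos at the default study conditions.

    Session-scoped: the balanced-attractor and scaling comparisons both
    read from this batch.
    """
    return run_batch(range(1, 101))
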