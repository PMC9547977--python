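import numpy as np
import pandas as pd
import pytest

from kraswt.core_io import ExpressionMatrix
from kraswt.synthetic_data import SimConfig, generate_cohort, write_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic three-cancer-type cohort (shared, read-only)."""
    return generate_cohort(SimConfig())


@pytest.fixture(scope="session")
def cohort_dir(default_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    write_cohort(default_cohort, out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def make_counts(values, genes=None, samples=None) -> ExpressionMatrix:
    arr = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(arr, index=genes, columns=samples),
        scale="raw_counts")
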