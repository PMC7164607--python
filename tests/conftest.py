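import numpy as np
import pandas as pd
import pytest

from refstab import (
    CountSimSpec,
    ExpressionMatrix,
    LibraryMeta,
    make_fixture_suite,
    simulate_counts,
)


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    return make_fixture_suite(out, seed=42)


@pytest.fixture(scope="session")
def small_rpm_matrix():
    """A 50-gene RPM matrix on the 20-library design, with planted truth."""
    matrix, truth = simulate_counts(CountSimSpec(n_genes=50, seed=7))
    from refstab import to_rpm

    return to_rpm(matrix, "metadata"), truth


def toy_matrix(values, layer="normalized", library_ids=None):
    """Build an ExpressionMatrix from a dict gene -> list of values."""
    df = pd.DataFrame.from_dict(values, orient="index", dtype=float)
    if library_ids is None:
        library_ids = [f"S{i + 1}" for i in range(df.shape[1])]
    df.columns = library_ids
    return ExpressionMatrix(df, [], layer)


@pytest.fixture
def toy():
    return toy_matrix
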