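import numpy as np
import pytest

from beadprep import AssayMatrix, SimConfig, simulate_assay, toy_fixture
from beadprep.qc import impute_median, qc_filter


@pytest.fixture()
def toy():
    return toy_fixture()


@pytest.fixture(scope="session")
def small_sim():
    """Reduced-analyte synthetic dataset with the full sample design."""
    return simulate_assay(SimConfig(n_analytes=60, seed=7))


@pytest.fixture(scope="session")
def small_prepared(small_sim):
    """QC'd + imputed raw-scale matrix with its reference sample IDs."""
    matrix, _ = qc_filter(small_sim.matrix)
    imputed = impute_median(matrix)
    ref = [m.sample_id for m in small_sim.meta
           if m.group.value == "reference_pool" and m.sample_id in matrix.sample_ids]
    return imputed, ref


def make_matrix(values, scale_tag="raw", **kwargs):
    values = np.asarray(values, dtype=float)
    n, s = values.shape
    return AssayMatrix(
        analyte_ids=[f"A{i}" for i in range(n)],
        sample_ids=[f"S{j}" for j in range(s)],
        values=values,
        scale_tag=scale_tag,
        **kwargs,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
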