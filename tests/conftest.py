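import numpy as np
import pandas as pd
import pytest

from evproteo.datatypes import IntensityMatrix, SampleSheet


def make_matrix(values, protein_ids=None, sample_ids=None, is_log2=True):
    arr = np.asarray(values, dtype=float)
    protein_ids = protein_ids or [f"P{i}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or [f"S{j}" for j in range(arr.shape[1])]
    return IntensityMatrix(
        pd.DataFrame(arr, index=protein_ids, columns=sample_ids),
        is_log2=is_log2)


def make_sheet(assignments):
    """assignments: list of (sample_id, group, fraction)."""
    df = pd.DataFrame(assignments,
                      columns=["sample_id", "group", "fraction"])
    return SampleSheet(df.set_index("sample_id"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-spec synthetic dataset, preprocessed, shared by the
    slower integration-style tests."""
    from evproteo import preprocess
    from evproteo.synthetic import SimulationSpec, generate_dataset

    spec = SimulationSpec(seed=0)
    matrix, sheet, truth = generate_dataset(spec)
    filtered, _ = preprocess.filter_by_presence(matrix, sheet)
    imputed = preprocess.impute_missing_normal(filtered, seed=spec.seed)
    normalized = preprocess.quantile_normalize(imputed)
    return {"spec": spec, "raw": matrix, "sheet": sheet, "truth": truth,
            "normalized": normalized}
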