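import numpy as np
import pandas as pd
import pytest

from t21meta.studies import ExpressionStudy


def make_array_study(
    values: np.ndarray,
    n_case: int,
    n_control: int,
    study_id: str = "arr",
    genes=None,
) -> ExpressionStudy:
    genes = genes if genes is not None else [f"g{i}" for i in range(values.shape[0])]
    samples = [f"{study_id}_s{j}" for j in range(values.shape[1])]
    group = pd.Series(["case"] * n_case + ["control"] * n_control, index=samples)
    return ExpressionStudy(
        study_id, "array", pd.DataFrame(values, index=genes, columns=samples), group
    )


def make_count_study(
    counts: np.ndarray,
    n_case: int,
    n_control: int,
    study_id: str = "cnt",
    genes=None,
) -> ExpressionStudy:
    genes = genes if genes is not None else [f"g{i}" for i in range(counts.shape[0])]
    samples = [f"{study_id}_s{j}" for j in range(counts.shape[1])]
    group = pd.Series(["case"] * n_case + ["control"] * n_control, index=samples)
    return ExpressionStudy(
        study_id, "rnaseq", pd.DataFrame(counts, index=genes, columns=samples), group
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def null_array_study(rng):
    """2000 genes, 5 vs 5, pure Normal noise — no true effects."""
    vals = rng.normal(7.0, 1.5, 2000)[:, None] + rng.normal(0.0, 0.3, (2000, 10))
    return make_array_study(vals, 5, 5, study_id="null_arr")


# property tests run the same examples everywhere
from hypothesis import settings

settings.register_profile("default", derandomize=True)
settings.load_profile("default")
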