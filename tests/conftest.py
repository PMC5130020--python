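import numpy as np
import pandas as pd
import pytest

from amlmo import ExpressionMatrix, SampleDesign
from amlmo.simulate import generate_multiomic

_CLASS_OF = {
    "control": ("control", "none"),
    "MLP3-cl": ("cell_line", "MLP3"),
    "RF12-cl": ("cell_line", "RF12"),
    "RF26-cl": ("cell_line", "RF26"),
    "RF12-p": ("primary", "RF12"),
    "RF26-p": ("primary", "RF26"),
    "MLP3-ivp": ("ivp", "MLP3"),
}


def build_dataset(group_values: dict[str, np.ndarray], feature_ids=None, dataset_label="toy"):
    """Build an (ExpressionMatrix, SampleDesign) pair from per-material
    value arrays of shape (features, replicates)."""
    cols, data, rows = [], [], []
    for group, vals in group_values.items():
        vals = np.atleast_2d(np.asarray(vals, dtype=float))
        cls, line = _CLASS_OF[group]
        for r in range(vals.shape[1]):
            cols.append(f"{group}_{r + 1}")
            data.append(vals[:, r])
            rows.append((f"{group}_{r + 1}", cls, line, dataset_label, r + 1))
    n_feat = len(data[0])
    if feature_ids is None:
        feature_ids = [f"f{i + 1}" for i in range(n_feat)]
    matrix = ExpressionMatrix(
        pd.DataFrame(np.column_stack(data), index=feature_ids, columns=cols),
        dataset_label=dataset_label,
    )
    design = SampleDesign(
        pd.DataFrame(
            rows,
            columns=["sample_id", "material_class", "line", "dataset_label", "replicate_index"],
        )
    )
    return matrix, design


@pytest.fixture(scope="session")
def small_multiomic():
    """A fast full-design synthetic dataset with planted truth."""
    return generate_multiomic(
        n_transcripts=800, n_proteins=60, n_replicates=3, effect_log2=3.0,
        noise_sd=0.25, seed=7,
    )
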