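import math

import numpy as np
import pandas as pd
import pytest

from metalith.study_io import IntensityMatrix


def build_matrix(values, sample_meta=None, identified=None):
    """Assemble an IntensityMatrix from a dict {metabolite_id: [values]} or a
    DataFrame, with default factor metadata for quick test setup."""
    if isinstance(values, dict):
        values = pd.DataFrame(values)
    n = len(values)
    if values.index.dtype != object:
        values.index = [f"S{i + 1:03d}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "tissue": ["cerebellum"] * n,
            "genotype": ["WT"] * n,
            "treatment": ["control"] * n,
            "sex": ["F"] * n,
            "age": [14.0] * n,
            "weight": [25.0] * n,
        },
        index=values.index,
    )
    if sample_meta:
        for col, vals in sample_meta.items():
            meta[col] = vals
    ident = identified if identified is not None else [True] * values.shape[1]
    ann = pd.DataFrame(
        {"name": list(values.columns), "identified": ident},
        index=pd.Index(values.columns, name="metabolite_id"),
    )
    return IntensityMatrix(values=values.astype(float), samples=meta, annotations=ann)


@pytest.fixture
def two_group_matrix():
    """4 control + 4 lithium cerebellar WT samples, 3 metabolites, no MISSING."""
    rng = np.random.default_rng(42)
    vals = pd.DataFrame(
        rng.lognormal(mean=5.0, sigma=0.3, size=(8, 3)),
        columns=["m1", "m2", "m3"],
    )
    return build_matrix(
        vals, sample_meta={"treatment": ["control"] * 4 + ["lithium"] * 4}
    )


@pytest.fixture
def missing_cell_matrix():
    vals = pd.DataFrame(
        {"m1": [2.0, 3.0, math.nan], "m2": [1.0, 1.0, 4.0]},
    )
    return build_matrix(vals)
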