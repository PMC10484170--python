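import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from specsel.io_formats import ExpressionMatrix

GLOBAL_TEST_SEED = 20260926


def make_meta(sample_ids, experiment=None, study=None, tissue=None, treatment=None):
    n = len(sample_ids)
    return pd.DataFrame(
        {
            "run_id": sample_ids,
            "experiment_id": experiment if experiment is not None else sample_ids,
            "study_id": study if study is not None else ["s1"] * n,
            "tissue_label": tissue if tissue is not None else ["leaf"] * n,
            "treatment_label": treatment if treatment is not None else ["control"] * n,
        },
        index=sample_ids,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(GLOBAL_TEST_SEED)


@pytest.fixture
def small_matrix():
    samples = ["r1", "r2", "r3", "r4"]
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [10.0, 0.0, 5.0, 5.0]],
        index=["gA", "gB"],
        columns=samples,
    )
    meta = make_meta(
        samples,
        experiment=["e1", "e1", "e2", "e3"],
        treatment=["control", "control", "heat", "heat"],
    )
    return ExpressionMatrix(values, meta)


def random_expression_matrix(rng, n_genes=5, n_samples=4):
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"r{i}" for i in range(n_samples)]
    vals = pd.DataFrame(
        rng.gamma(2.0, 10.0, (n_genes, n_samples)), index=genes, columns=samples
    )
    treatments = rng.choice(["control", "heat", "cold"], n_samples)
    return ExpressionMatrix(vals, make_meta(samples, treatment=list(treatments)))
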