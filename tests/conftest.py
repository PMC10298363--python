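import numpy as np
import pandas as pd
import pytest

import switchquant as sq


@pytest.fixture
def config():
    return sq.AnalysisConfig()


@pytest.fixture
def tiny_cohort():
    """Hand-built 2-gene, 6-sample cohort with an obvious switch in G1.

    G1 has two isoforms that trade places between conditions; G2 has two
    isoforms with stable proportions.
    """
    samples = pd.DataFrame(
        {
            "condition": ["normal"] * 3 + ["cancer"] * 3,
            "cohort": "T",
        },
        index=pd.Index([f"s{i}" for i in range(1, 7)], name="sample_id"),
    )
    tpm = pd.DataFrame(
        {
            "s1": [80.0, 20.0, 50.0, 50.0],
            "s2": [75.0, 25.0, 60.0, 40.0],
            "s3": [85.0, 15.0, 55.0, 45.0],
            "s4": [20.0, 80.0, 52.0, 48.0],
            "s5": [25.0, 75.0, 58.0, 42.0],
            "s6": [15.0, 85.0, 50.0, 50.0],
        },
        index=pd.Index(["G1.T1", "G1.T2", "G2.T1", "G2.T2"],
                       name="transcript_id"),
    )
    annotation = pd.Series(
        ["G1", "G1", "G2", "G2"], index=tpm.index, name="gene_id"
    )
    tpm_m = sq.ExpressionMatrix(tpm, kind="tpm")
    counts_m = sq.ExpressionMatrix(tpm * 10, kind="counts")
    return counts_m, tpm_m, annotation, samples


@pytest.fixture
def random_matrix():
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.gamma(2.0, 10.0, size=(12, 8)),
        index=[f"tx{i}" for i in range(12)],
        columns=[f"s{j}" for j in range(8)],
    )
    return sq.ExpressionMatrix(values, kind="tpm")
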