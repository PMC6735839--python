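import numpy as np
import pandas as pd
import pytest

from lcv import CountMatrix, SampleMeta
from lcv.preprocess import CpmMatrix
from lcv.synthetic import SyntheticConfig, simulate_counts
from lcv.variability import SortedGeneFrame


@pytest.fixture(scope="session")
def small_dataset():
    """600 genes x 2 tissues x 12 samples, planted HV genes, fixed seed."""
    config = SyntheticConfig(n_genes=600, tissue_sizes=(12, 12), seed=7)
    counts, meta, annotation, truth = simulate_counts(config)
    return config, counts, meta, annotation, truth


@pytest.fixture()
def tiny_counts():
    df = pd.DataFrame(
        {
            "S1": [12, 0, 40, 3],
            "S2": [15, 1, 35, 2],
            "S3": [9, 0, 50, 4],
        },
        index=["G1", "G2", "G3", "G4"],
    )
    return CountMatrix(df)


@pytest.fixture()
def tiny_meta():
    return SampleMeta(
        pd.DataFrame(
            {
                "tissue": ["liver", "liver", "liver"],
                "sex": ["F", "male", "M"],
                "death_cause": ["traumatic injury"] * 3,
            },
            index=["S1", "S2", "S3"],
        )
    )


def make_frame(cv, medians=None, tissue="t"):
    """Build a SortedGeneFrame directly from a CV vector (test helper)."""
    cv = np.asarray(cv, dtype=float)
    n = len(cv)
    if medians is None:
        medians = np.arange(1.0, n + 1.0)
    return SortedGeneFrame(
        gene_ids=np.array([f"G{i:03d}" for i in range(n)], dtype=object),
        median_expression=np.asarray(medians, dtype=float),
        cv=cv,
        tissue=tissue,
    )


def make_cpm(values, gene_ids=None, tissue="t"):
    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"G{i:03d}" for i in range(values.shape[0])]
    df = pd.DataFrame(
        values, index=gene_ids, columns=[f"S{j}" for j in range(values.shape[1])]
    )
    return CpmMatrix(cpm=df, tissue=tissue)
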