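import numpy as np
import pandas as pd
import pytest

from synexpress import DatasetCollection, ExpressionDataset
from synexpress.simulate import GenomeSimConfig, simulate_genome_peaks_and_fasta


def make_dataset(ds_id: str, values: np.ndarray, genes, samples=None) -> ExpressionDataset:
    samples = samples or [f"S{i + 1}" for i in range(values.shape[1])]
    return ExpressionDataset(
        id=ds_id, values=pd.DataFrame(values, index=genes, columns=samples)
    )


@pytest.fixture
def random_collection():
    """Five random 10-gene x 8-sample datasets sharing one namespace."""
    rng = np.random.default_rng(11)
    genes = [f"G{i}" for i in range(10)]
    datasets = [
        make_dataset(f"DS{d}", rng.normal(8, 1, size=(10, 8)), genes) for d in range(5)
    ]
    return DatasetCollection(datasets)


@pytest.fixture(scope="session")
def genome_fixture():
    """Toy genome with planted TF peaks, mark peaks and promoter motifs."""
    return simulate_genome_peaks_and_fasta(GenomeSimConfig(seed=0))
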