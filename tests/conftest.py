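import numpy as np
import pandas as pd
import pytest

from modulonkit import generate_compendium
from modulonkit.qc import ExpressionCompendium, center_to_reference


@pytest.fixture(scope="session")
def small_compendium():
    """200 genes, 20 conditions x 3 replicates, 5 planted modules."""
    comp, truth = generate_compendium(
        n_genes=200, n_conditions=20, replicates_per_condition=3,
        k_modules=5, noise_sd=0.3, replicate_rho=0.9, seed=7,
    )
    return comp, truth


@pytest.fixture(scope="session")
def centered_small(small_compendium):
    comp, truth = small_compendium
    return center_to_reference(comp), truth


def toy_compendium(values: np.ndarray, meta_rows: list[dict]) -> ExpressionCompendium:
    """Build a compendium from raw values and metadata dicts (test helper)."""
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    data = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=list(meta.index),
    )
    return ExpressionCompendium(data=data, metadata=meta)


def make_meta(sample_id, project, condition, replicate_index, is_reference=False,
              mapped_reads=1_000_000, fastqc_pass=True):
    return {
        "sample_id": sample_id, "project": project, "condition": condition,
        "replicate_index": replicate_index, "is_reference": is_reference,
        "mapped_reads": mapped_reads, "fastqc_pass": fastqc_pass,
    }
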