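import numpy as np
import pytest

from lfqtier.io import LfqMatrix, SampleDesign
from lfqtier.synthetic_data import SimulationConfig, simulate_lfq


def make_matrix(intensities, sample_names=None, ids=None, genes=None,
                qc_flags=None):
    """Build a small LfqMatrix from a nested list (None = missing)."""
    arr = np.array(
        [[np.nan if v is None else float(v) for v in row]
         for row in intensities]
    )
    n = arr.shape[0]
    if sample_names is None:
        sample_names = [f"s{j}" for j in range(arr.shape[1])]
    return LfqMatrix(
        protein_ids=ids or [f"P{i}" for i in range(n)],
        gene_symbols=genes or [f"G{i}" for i in range(n)],
        intensities=arr,
        sample_names=sample_names,
        qc_flags=qc_flags,
    )


def make_design(n_bait, n_control, bait_prefix="b", control_prefix="c"):
    assignments = {}
    for i in range(n_bait):
        assignments[f"{bait_prefix}{i + 1}"] = ("bait", i + 1)
    for i in range(n_control):
        assignments[f"{control_prefix}{i + 1}"] = ("control", i + 1)
    return SampleDesign(assignments=assignments)


@pytest.fixture
def six_rep_design():
    """6 bait + 6 control replicates, the study's experimental layout."""
    return make_design(6, 6)


@pytest.fixture
def small_simulated():
    """One small seeded simulated experiment with ground truth."""
    config = SimulationConfig(
        n_proteins=300, n_enriched=20, seed=7, bait_protein=True
    )
    return simulate_lfq(config)
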