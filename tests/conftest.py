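import numpy as np
import pandas as pd
import pytest

from grnbench.data_io import EVIDENCE_FIELDS, ExpressionMatrix
from grnbench.workflow import benchmark_analysis


@pytest.fixture(scope="session")
def tooth_benchmark() -> dict:
    """One full pipeline run on the tooth-scale preset, shared by the
    end-to-end tests: simulate -> evidence integration -> preprocessing ->
    correlation/MI/DPI/tree networks -> path-tolerant evaluation with 1000
    node-label permutations (K = 7) -> perturbation fold-change analysis."""
    return benchmark_analysis(seed=7, K=7, n_permutations=1000, n_trees=100)


@pytest.fixture
def evidence_csv(tmp_path):
    """Factory writing an evidence CSV from a list of row dicts."""

    def write(rows, fields=EVIDENCE_FIELDS, name="evidence.csv"):
        path = tmp_path / name
        lines = [",".join(fields)]
        for row in rows:
            lines.append(",".join(str(row.get(f, "")) for f in fields))
        path.write_text("\n".join(lines) + "\n")
        return path

    return write


def full_row(**overrides) -> dict:
    row = {
        "regulator": "Pax9",
        "target": "Msx1",
        "perturbation": "loss",
        "effect": "down",
        "species": "mouse",
        "stage": "E13",
        "tissue_perturbed": "mesenchyme",
        "tissue_measured": "mesenchyme",
        "technique": "ISH",
        "molecule": "mRNA",
        "citation": "PMID:X",
    }
    row.update(overrides)
    return row


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 probes x 6 samples, two 3-replicate groups, hand-set values."""
    samples = [f"s{i}" for i in range(1, 7)]
    values = pd.DataFrame(
        {
            "s1": [5.0, 8.0, 9.0],
            "s2": [5.1, 8.1, 9.2],
            "s3": [4.9, 7.9, 8.8],
            "s4": [7.0, 8.0, 9.1],
            "s5": [7.1, 8.2, 8.9],
            "s6": [6.9, 7.8, 9.0],
        },
        index=["pA", "pB", "pC"],
    )
    metadata = pd.DataFrame(
        {
            "condition_class": ["genetic_perturbation"] * 3 + ["control"] * 3,
            "tissue": ["mesenchyme"] * 6,
            "stage": ["E13"] * 6,
            "perturbed_entity": ["GeneA"] * 3 + [""] * 3,
            "perturbation_direction": ["loss"] * 3 + [""] * 3,
            "replicate_group": ["pert"] * 3 + ["ctrl"] * 3,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    probe_genes = pd.Series(
        ["GeneA", "GeneB", "GeneC"], index=["pA", "pB", "pC"], name="gene"
    )
    return ExpressionMatrix(values, metadata, probe_genes)
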