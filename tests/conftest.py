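"""Shared fixtures: one full preset-study pipeline run reused across tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from organofit import synthetic_data as syn
from organofit.core_io import PipelineConfig
from organofit.workflow import run_pipeline

PRESET_SEED = 1


@pytest.fixture(scope="session")
def preset_study():
    """Simulated six-patient paired study with ground truth."""
    specs, params = syn.preset_study(seed=PRESET_SEED)
    matrix, truth, uni = syn.simulate_study(specs, params)
    return {
        "specs": specs,
        "params": params,
        "matrix": matrix,
        "truth": truth,
        "universe": uni,
    }


@pytest.fixture(scope="session")
def preset_run(preset_study):
    """The full pipeline executed once on the preset study."""
    uni = preset_study["universe"]
    params = preset_study["params"]
    result = run_pipeline(
        preset_study["matrix"],
        marker_panels=syn.marker_panel_sets(uni),
        gene_sets=syn.signature_sets(uni),
        centroids=syn.subtype_centroids(uni, params),
        config=PipelineConfig(seed=PRESET_SEED),
    )
    return result


@pytest.fixture(scope="session")
def preset_truth_aligned(preset_study, preset_run):
    """Truth cell table aligned to the QC-filtered pipeline matrix rows."""
    truth = preset_study["truth"]
    return truth.cells.set_index("barcode").loc[preset_run.matrix.barcodes]


@pytest.fixture()
def toy_matrix():
    """Tiny 4-cell x 6-gene matrix with two patients for I/O tests."""
    import scipy.sparse as sp

    from organofit.core_io import AnnotatedMatrix

    counts = sp.csr_matrix(
        np.array(
            [
                [5, 0, 1, 2, 0, 3],
                [0, 4, 2, 0, 1, 0],
                [1, 1, 0, 3, 2, 1],
                [2, 0, 0, 1, 4, 2],
            ]
        )
    )
    genes = pd.DataFrame(
        {
            "gene_id": [f"ENSG{i}" for i in range(6)],
            "symbol": [f"G{i}" for i in range(6)],
            "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2", "chr2"],
            "start": [100, 200, 300, 100, 200, 300],
        }
    )
    cells = pd.DataFrame(
        {
            "barcode": [f"BC{i}" for i in range(4)],
            "patient": ["P1", "P1", "P2", "P2"],
            "source": ["PBC", "BCO", "PBC", "BCO"],
        }
    )
    return AnnotatedMatrix(counts=counts, genes=genes, cells=cells)
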