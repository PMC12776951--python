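"""Shared fixtures: small synthetic samples generated at test time."""

import numpy as np
import pandas as pd
import pytest

from spikemap import domains, qc, synthetic


@pytest.fixture(scope="session")
def wt_sample():
    """One default wildtype W4 sample: (spec, polygons, cells, truth, counts, transcripts)."""
    spec = synthetic.default_spec("W4", "P1WT", seed=11)
    polygons, cells, truth = synthetic.build_spike_layout(spec)
    counts, transcripts = synthetic.sample_counts(polygons, cells, truth, spec)
    return spec, polygons, cells, truth, counts, transcripts


@pytest.fixture(scope="session")
def normalized_wt(wt_sample):
    """QC-filtered, blank-stripped, normalized wildtype sample."""
    spec, polygons, cells, truth, counts, _ = wt_sample
    filtered, cells_f, _ = qc.filter_cells(counts, cells)
    m = domains.normalize_counts(qc.strip_blanks(filtered))
    m.obs["sample_id"] = cells_f["sample_id"].loc[m.obs_names].to_numpy()
    return m, cells_f, truth


def make_normalized(stage, genotype, seed, scale=1):
    """Generate one sample and run it through QC + normalization."""
    spec = synthetic.default_spec(stage, genotype, seed=seed)
    if scale != 1:
        spec.cells_per_domain = {k: scale * v for k, v in spec.cells_per_domain.items()}
    polygons, cells, truth = synthetic.build_spike_layout(spec)
    counts, _ = synthetic.sample_counts(polygons, cells, truth, spec, emit_transcripts=False)
    filtered, cells_f, _ = qc.filter_cells(counts, cells)
    m = domains.normalize_counts(qc.strip_blanks(filtered))
    m.obs["sample_id"] = cells_f["sample_id"].loc[m.obs_names].to_numpy()
    return m, cells_f, truth


@pytest.fixture
def tiny_counts():
    """Hand-written 5-cell matrix with one blank gene, plus metadata."""
    from spikemap.io import counts_from_arrays

    X = np.array(
        [
            [5, 5, 0, 1],
            [20, 5, 0, 0],
            [14, 5, 5, 0],
            [50, 30, 20, 2],
            [10, 10, 10, 0],
        ],
        dtype=float,
    )
    adata = counts_from_arrays(X, [f"c{i}" for i in range(5)], ["A", "B", "C", "Blank-1"])
    cells = pd.DataFrame(
        {
            "center_x": np.arange(5.0),
            "center_y": np.arange(5.0),
            "volume": [600.0, 600.0, 450.0, 600.0, 600.0],
            "sample_id": "s1",
        },
        index=pd.Index([f"c{i}" for i in range(5)], name="cell_id"),
    )
    return adata, cells
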