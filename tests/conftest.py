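import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scbmm.core_io import CountMatrix, flag_mito_genes, lognormalize
from scbmm.synthetic_data import (
    DESpec,
    LRSpec,
    SimConfig,
    VelocitySpec,
    simulate_timecourse,
)


def make_count_matrix(
    counts: np.ndarray,
    timepoints=None,
    cell_types=None,
    clusters=None,
    gene_names=None,
    layers=None,
) -> CountMatrix:
    """Small dense-array constructor for hand-built fixtures."""
    n_cells, n_genes = counts.shape
    genes = list(gene_names) if gene_names is not None else [f"g{i}" for i in range(n_genes)]
    cells = [f"c{i}" for i in range(n_cells)]
    tps = list(timepoints) if timepoints is not None else ["D0"] * n_cells
    cm = CountMatrix(
        counts=sp.csr_matrix(counts),
        cell_meta=pd.DataFrame(
            {
                "timepoint": pd.Categorical(
                    tps, categories=sorted(set(tps), key=lambda s: int("".join(filter(str.isdigit, s)) or 0)), ordered=True
                ),
                "cell_type": list(cell_types) if cell_types is not None else [pd.NA] * n_cells,
                "cluster": list(clusters) if clusters is not None else [pd.NA] * n_cells,
            },
            index=pd.Index(cells, name="cell_id"),
        ),
        gene_meta=pd.DataFrame(
            {"is_mito": flag_mito_genes(genes)}, index=pd.Index(genes, name="gene_id")
        ),
        layers={k: sp.csr_matrix(v) for k, v in (layers or {}).items()},
    )
    return cm


@pytest.fixture(scope="session")
def small_timecourse():
    """A 3-timepoint, 3-type simulation with planted DE, LR and velocity truth."""
    cfg = SimConfig(
        timepoints=("D0", "D3", "D6"),
        cells_per_timepoint=(240, 240, 240),
        n_genes=400,
        cell_types=("A", "B", "C"),
        proportions=((1 / 3, 1 / 3, 1 / 3),) * 3,
        de_spec=(DESpec("A", "D3", 10, float(np.log(2)), "over"),),
        lr_spec=(
            LRSpec("Gene00001", "Gene00002", ["A"], ["B"], ["D3"]),
            LRSpec("Gene00003", "Gene00004", ["B"], ["C"], ["D0", "D3", "D6"]),
        ),
        velocity_spec=VelocitySpec(n_velocity_genes=12, noise_sd=0.1),
        seed=7,
    )
    matrices, truth = simulate_timecourse(cfg)
    return cfg, matrices, truth


@pytest.fixture()
def lognormed_timecourse(small_timecourse):
    from scbmm.pipeline import concat_timepoints

    _, matrices, truth = small_timecourse
    cm = concat_timepoints(matrices)
    lognormalize(cm)
    return cm, truth
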