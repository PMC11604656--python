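import numpy as np
import pandas as pd
import pytest

import spotclone as sc
from spotclone import io as scio
from spotclone import pipeline as pl
from spotclone import segmentation as seg


@pytest.fixture(scope="session")
def small_truth():
    """10×10 lattice, 120 genes (24 clone-informative at CN 4 vs 2)."""
    params = sc.SimulationParams(
        n_rows=10, n_cols=10, n_genes=120, contamination=0.1, seed=7
    )
    return sc.make_truth(params, n_informative=24)


@pytest.fixture(scope="session")
def small_prepared(small_truth):
    """QC-passed, normalized small sample plus its spot graph."""
    adata = sc.simulate_counts(small_truth)
    cfg = dict(scio.CONFIG_DEFAULTS)
    cfg.update(min_counts=1, min_genes=1, gene_filter_mode="spots", min_spots=1)
    prepared = pl.prepare_dataset(adata, cfg)
    graph = seg.build_spot_graph(prepared.obs)
    return prepared, graph


@pytest.fixture(scope="session")
def small_clone_map(small_truth, small_prepared):
    prepared, graph = small_prepared
    return sc.map_clones(
        prepared, small_truth.annotation, small_truth.profiles, graph, seed=0
    )


@pytest.fixture()
def hex_positions():
    lattice = sc.synthetic.hex_lattice(8, 8, 100.0)
    return lattice.set_index("spot_id")[["x_um", "y_um", "array_row", "array_col"]]
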