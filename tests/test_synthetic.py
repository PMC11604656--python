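"""Generators: lattice geometry, clone fields, counts, nuclei, FISH, structures."""

import numpy as np
import pandas as pd
import pytest

import spotclone as sc
from spotclone import synthetic as syn
from spotclone.segmentation import build_spot_graph


def test_half_split_partitions_columns():
    params = sc.SimulationParams(n_rows=4, n_cols=4, n_genes=10, seed=0)
    field = sc.generate_clone_field(params)
    a = field[field.clone == "A"]
    assert len(a) == 8 and set(a.array_col) == {0, 1}
    assert (field.clone == "B").sum() == 8


def test_half_split_clones_connected_under_hex_adjacency():
    params = sc.SimulationParams(n_rows=6, n_cols=8, n_genes=10, seed=0)
    field = sc.generate_clone_field(params).set_index("spot_id")
    graph = build_spot_graph(field)
    import networkx as nx

    for clone in ("A", "B"):
        sub = graph.subgraph(field.index[field.clone == clone])
        assert nx.is_connected(sub)


def test_blob_layout_deterministic_and_nonempty():
    params = sc.SimulationParams(n_rows=8, n_cols=8, n_genes=10, layout="blob", seed=3)
    f1 = sc.generate_clone_field(params)
    f2 = sc.generate_clone_field(params)
    pd.testing.assert_frame_equal(f1, f2)
    assert (f1.clone == "A").any() and (f1.clone == "B").any()


def test_blob_layout_is_spatially_coherent():
    """Adjacent spots share the clone label in >90% of pairs (smooth blobs)."""
    fracs = []
    for seed in range(20):
        params = sc.SimulationParams(
            n_rows=40, n_cols=40, n_genes=10, layout="blob", blob_smooth_um=300.0, seed=seed
        )
        field = sc.generate_clone_field(params).set_index("spot_id")
        graph = build_spot_graph(field)
        same = np.mean([field.clone[u] == field.clone[v] for u, v in graph.edges])
        fracs.append(same)
    assert np.mean(fracs) > 0.9


def test_lattice_geometry_offset_rows():
    lat = syn.hex_lattice(4, 4, 100.0)
    odd = lat[lat.array_row % 2 == 1]
    even = lat[lat.array_row % 2 == 0]
    assert np.allclose(odd.x_um.values % 100.0, 50.0)
    assert np.allclose(even.x_um.values % 100.0, 0.0)
    assert lat.spot_id.is_unique


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        sc.SimulationParams(n_rows=1, n_cols=4)
    with pytest.raises(ValueError):
        sc.SimulationParams(contamination=1.5)
    with pytest.raises(ValueError):
        sc.SimulationParams(nb_dispersion=0.0)
    with pytest.raises(ValueError):
        sc.SimulationParams(layout="stripes")


def _mean_ratio(truth, adata):
    informative = sorted(truth.informative_genes)
    sub = adata[:, informative]
    X = np.asarray(sub.X.todense(), dtype=float)
    is_a = (adata.obs["true_clone"] == "A").to_numpy()
    return X[is_a].mean() / X[~is_a].mean()


def test_counts_dosage_ratio_matches_closed_form():
    """CN 4 vs 2 without contamination doubles informative-gene means."""
    params = sc.SimulationParams(
        n_rows=40, n_cols=40, n_genes=300, contamination=0.0, seed=11
    )
    truth = sc.make_truth(params, n_informative=60)
    adata = sc.simulate_counts(truth)
    assert _mean_ratio(truth, adata) == pytest.approx(2.0, rel=0.1)


def test_counts_contamination_mixes_toward_neutral():
    """Mean contrast follows d·((1−c) + c/d); at c=1 the dosage cancels."""
    for c, expected in ((1.0, 1.0), (0.5, 1.5)):
        params = sc.SimulationParams(
            n_rows=40, n_cols=40, n_genes=300, contamination=c, seed=5
        )
        truth = sc.make_truth(params, n_informative=60)
        adata = sc.simulate_counts(truth)
        assert _mean_ratio(truth, adata) == pytest.approx(expected, rel=0.08)


def test_counts_poisson_limit_at_large_dispersion():
    params = sc.SimulationParams(
        n_rows=20,
        n_cols=20,
        n_genes=200,
        nb_dispersion=1e7,
        libsize_sd=0.0,
        gene_logmean_sd=0.0,
        baseline_mean=5.0,
        contamination=1.0,
        seed=2,
    )
    truth = sc.make_truth(params, n_informative=0)
    X = np.asarray(sc.simulate_counts(truth).X.todense(), dtype=float)
    ratio = X.var(axis=0, ddof=1) / X.mean(axis=0)
    assert np.mean(ratio) == pytest.approx(1.0, abs=0.05)


def test_counts_bit_reproducible():
    params = sc.SimulationParams(n_rows=4, n_cols=4, n_genes=30, seed=9)
    truth = sc.make_truth(params, n_informative=6)
    a1 = sc.simulate_counts(truth)
    a2 = sc.simulate_counts(truth)
    assert (a1.X != a2.X).nnz == 0


def test_nuclei_median_area_ratio():
    params = sc.SimulationParams(n_rows=20, n_cols=20, n_genes=10, seed=1)
    field = sc.generate_clone_field(params)
    nuc = sc.simulate_nuclei(
        field,
        density_per_mm2=2000.0,
        area_lognormal_params_per_clone={"A": (np.log(60.0), 0.3), "B": (np.log(40.0), 0.3)},
        seed=4,
    )
    assert len(nuc) > 2000
    med = nuc.groupby("true_clone")["area_um2"].median()
    assert med["A"] / med["B"] == pytest.approx(1.5, rel=0.1)


def test_nuclei_tiny_density_gives_empty_table():
    params = sc.SimulationParams(n_rows=3, n_cols=3, n_genes=10, seed=1)
    field = sc.generate_clone_field(params)
    nuc = sc.simulate_nuclei(
        field, 1e-9, {"A": (0.0, 0.1), "B": (0.0, 0.1)}, seed=0
    )
    assert len(nuc) == 0
    with pytest.raises(ValueError):
        sc.simulate_nuclei(field, -1.0, {"A": (0.0, 0.1), "B": (0.0, 0.1)})


def test_fish_counts_deterministic_limits():
    nuclei = pd.DataFrame(
        {
            "nucleus_id": [f"n{i}" for i in range(50)],
            "true_clone": ["A"] * 25 + ["B"] * 25,
        }
    )
    perfect = sc.simulate_fish_counts(nuclei, {"p": {"A": 2, "B": 2}}, 1.0, 0.0, seed=0)
    assert (perfect["count"] == 2).all()
    silent = sc.simulate_fish_counts(nuclei, {"p": {"A": 2, "B": 2}}, 0.0, 0.0, seed=0)
    assert (silent["count"] == 0).all()
    with pytest.raises(ValueError):
        sc.simulate_fish_counts(nuclei, {"p": {"A": 2, "B": 2}}, 1.5)


def test_fish_counts_binomial_means():
    nuclei = pd.DataFrame(
        {
            "nucleus_id": [f"n{i}" for i in range(4000)],
            "true_clone": ["A"] * 2000 + ["B"] * 2000,
        }
    )
    fish = sc.simulate_fish_counts(nuclei, {"p": {"A": 4, "B": 2}}, 0.9, 0.0, seed=1)
    merged = fish.merge(nuclei, on="nucleus_id")
    means = merged.groupby("true_clone")["count"].mean()
    assert means["A"] == pytest.approx(3.6, rel=0.05)
    assert means["B"] == pytest.approx(1.8, rel=0.05)


def test_structure_table_reproducible_and_filterable():
    tab1 = sc.simulate_structure_table(3, (np.log(40), 0.4), (np.log(8), 0.5), (50, 20), seed=3)
    tab2 = sc.simulate_structure_table(3, (np.log(40), 0.4), (np.log(8), 0.5), (50, 20), seed=3)
    pd.testing.assert_frame_equal(tab1, tab2)
    assert set(tab1["class"]) == {"cell", "microtube"}
    assert (tab1.groupby("crop_id").size() == 70).all()


def test_structure_table_small_cell_fraction_survives_filter():
    """~30% of cells below 10 µm² → the downstream filter keeps ~70%."""
    from spotclone.microtubes import filter_structures

    rng_med, sd = np.log(10.0 / np.exp(0.525 * 0.6)), 0.0
    # construct directly: 30% below threshold by mixing two point masses
    n = 3000
    rng = np.random.default_rng(0)
    areas = np.where(rng.uniform(size=n) < 0.3, 5.0, 20.0)
    tab = pd.DataFrame(
        {"sample_id": "S", "crop_id": "c0", "class": "cell", "area_um2": areas}
    )
    kept = filter_structures(tab)
    assert len(kept) / n == pytest.approx(0.7, abs=0.03)
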