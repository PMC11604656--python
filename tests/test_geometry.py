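"""Clone territories: connected components, alpha-shapes, nucleus assignment."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import spotclone as sc
from spotclone import geometry as geo


def test_lcc_examples():
    g = nx.Graph([(1, 2), (2, 3), (4, 5)])
    assert set(geo.largest_connected_component([1, 2, 3, 4, 5], g)) == {1, 2, 3}
    assert set(geo.largest_connected_component([4, 5], g)) == {4, 5}
    with pytest.raises(ValueError):
        geo.largest_connected_component([], g)


def test_lcc_tie_breaks_lexicographically():
    g = nx.Graph([(1, 2), (3, 4)])
    assert geo.largest_connected_component([1, 2, 3, 4], g) == [1, 2]


def test_lcc_matches_bfs_oracle_on_random_graphs():
    rng = np.random.default_rng(0)
    for trial in range(30):
        n = int(rng.integers(2, 50))
        g = nx.gnp_random_graph(n, 0.08, seed=trial)
        subset = [i for i in range(n) if rng.uniform() < 0.8]
        if not subset:
            continue
        result = set(geo.largest_connected_component(subset, g))
        # BFS oracle over the induced subgraph
        subset_set = set(subset)
        seen, best = set(), set()
        for start in subset:
            if start in seen:
                continue
            comp, frontier = {start}, [start]
            while frontier:
                u = frontier.pop()
                for v in g.neighbors(u):
                    if v in subset_set and v not in comp:
                        comp.add(v)
                        frontier.append(v)
            seen |= comp
            if len(comp) > len(best):
                best = comp
        assert len(result) == len(best)


def test_concave_hull_convex_limit_unit_square():
    square = [(0, 0), (1, 0), (1, 1), (0, 1)]
    hull = geo.concave_hull(square, alpha=1e-9)
    assert hull.area == pytest.approx(1.0, abs=1e-9)


def test_concave_hull_tighter_than_convex_on_l_shape():
    rng = np.random.default_rng(1)
    pts = np.vstack(
        [
            rng.uniform([0, 0], [3, 1], (300, 2)),
            rng.uniform([0, 0], [1, 3], (300, 2)),
        ]
    )
    concave = geo.concave_hull(pts, alpha=1.0 / 0.5)
    convex = geo.concave_hull(pts, alpha=0.0)
    assert concave.area < convex.area
    # zero-alpha shape coincides with the convex hull
    assert convex.area == pytest.approx(convex.convex_hull.area, rel=1e-9)


def test_concave_hull_degenerate_inputs():
    with pytest.raises(ValueError):
        geo.concave_hull([(0, 0), (1, 1)], alpha=0.1)
    with pytest.raises(ValueError, match="collinear|degenerate"):
        geo.concave_hull([(0, 0), (1, 1), (2, 2), (3, 3)], alpha=0.1)
    with pytest.raises(ValueError, match="no triangle"):
        geo.concave_hull([(0, 0), (1, 0), (0, 1)], alpha=1e9)


def test_territory_hull_contains_all_spot_centers(small_clone_map, small_prepared):
    prepared, graph = small_prepared
    positions = prepared.obs[["x_um", "y_um"]]
    terrs = geo.build_territories(small_clone_map.frame["clone"], positions, graph)
    import shapely

    for t in terrs.values():
        pts = shapely.points(
            positions.loc[t.spots, "x_um"].to_numpy(),
            positions.loc[t.spots, "y_um"].to_numpy(),
        )
        assert shapely.covers(t.hull.buffer(1e-9), pts).all()


def test_assign_nuclei_basic_rules():
    from shapely.geometry import Polygon

    terrs = {
        "A": geo.CloneTerritory("A", [], Polygon([(0, 0), (10, 0), (10, 10), (0, 10)]), 1.0),
        "B": geo.CloneTerritory("B", [], Polygon([(20, 0), (30, 0), (30, 10), (20, 10)]), 1.0),
    }
    nuclei = pd.DataFrame(
        {
            "nucleus_id": ["in_a", "boundary_a", "outside"],
            "x_um": [5.0, 10.0, 15.0],
            "y_um": [5.0, 5.0, 5.0],
            "area_um2": [40.0, 40.0, 40.0],
        }
    )
    out = geo.assign_nuclei(nuclei, terrs)
    assert list(out["clone"]) == ["A", "A", "unassigned"]  # boundary inclusive


def test_assign_nuclei_overlap_warns_unassigned():
    from shapely.geometry import Polygon

    sq = Polygon([(0, 0), (10, 0), (10, 10), (0, 10)])
    terrs = {
        "A": geo.CloneTerritory("A", [], sq, 1.0),
        "B": geo.CloneTerritory("B", [], sq, 1.0),
    }
    nuclei = pd.DataFrame(
        {"nucleus_id": ["n0"], "x_um": [5.0], "y_um": [5.0], "area_um2": [30.0]}
    )
    with pytest.warns(UserWarning, match="multiple"):
        out = geo.assign_nuclei(nuclei, terrs)
    assert out["clone"][0] == "unassigned"


def test_nucleus_assignment_recovery_and_translation_invariance(
    small_truth, small_clone_map, small_prepared
):
    prepared, graph = small_prepared
    positions = prepared.obs[["x_um", "y_um"]]
    nuclei = sc.simulate_nuclei(
        small_truth.clone_field,
        density_per_mm2=1500.0,
        area_lognormal_params_per_clone={"A": (np.log(60), 0.3), "B": (np.log(40), 0.3)},
        seed=2,
    )
    terrs = geo.build_territories(small_clone_map.frame["clone"], positions, graph)
    assigned = geo.assign_nuclei(nuclei, terrs)
    ok = assigned["clone"].isin(["A", "B"])
    accuracy = (assigned.loc[ok, "clone"] == assigned.loc[ok, "true_clone"]).mean()
    assert accuracy >= 0.9

    shifted_positions = positions + np.array([1000.0, -500.0])
    shifted_nuclei = nuclei.assign(
        x_um=nuclei["x_um"] + 1000.0, y_um=nuclei["y_um"] - 500.0
    )
    terrs_shifted = geo.build_territories(
        small_clone_map.frame["clone"], shifted_positions, graph
    )
    assigned_shifted = geo.assign_nuclei(shifted_nuclei, terrs_shifted)
    assert (assigned_shifted["clone"] == assigned["clone"]).all()


def test_compare_nuclear_area_exact_small_case():
    nuclei = pd.DataFrame(
        {
            "nucleus_id": list("abcdef"),
            "x_um": 0.0,
            "y_um": 0.0,
            "area_um2": [40.0, 50.0, 60.0, 10.0, 20.0, 30.0],
            "clone": ["A"] * 3 + ["B"] * 3,
        }
    )
    res = sc.compare_nuclear_area(nuclei)
    # all A > all B: exact two-sided p = 2 / C(6,3) = 0.1
    assert res["p_two_sided"] == pytest.approx(0.1, abs=1e-9)
    assert res["median_A"] == 50.0 and res["median_B"] == 20.0
    with pytest.raises(ValueError, match="no assigned"):
        sc.compare_nuclear_area(nuclei[nuclei.clone == "A"])
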