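"""Clone territories and nucleus-to-clone assignment.

Per-spot clone labels from clustering are somewhat noisy; to obtain
contiguous tissue areas per clone we keep the largest connected component
of each clone's spots on the spot graph and outline it with an
alpha-shape (concave hull).  Nucleus centroids are then assigned to the
clone whose territory contains them, giving per-clone nuclear-morphology
statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

from .stats import mann_whitney_u

__all__ = [
    "CloneTerritory",
    "largest_connected_component",
    "concave_hull",
    "build_territories",
    "assign_nuclei",
    "compare_nuclear_area",
    "default_alpha",
]


@dataclass
class CloneTerritory:
    """Largest connected clone region with its concave-hull outline."""

    clone: str
    spots: list
    hull: Polygon | MultiPolygon
    alpha: float


def largest_connected_component(spot_subset, graph: nx.Graph) -> list:
    """Maximal connected component of the induced subgraph.

    Ties in component size are broken by the smallest lexicographic spot
    id, making the choice deterministic.
    """
    spot_subset = list(spot_subset)
    if not spot_subset:
        raise ValueError("empty spot subset")
    missing = [s for s in spot_subset if s not in graph]
    if missing:
        raise ValueError(f"spots not in graph: {missing[:3]}...")
    sub = graph.subgraph(spot_subset)
    components = [sorted(c, key=str) for c in nx.connected_components(sub)]
    components.sort(key=lambda c: (-len(c), str(c[0])))
    return components[0]


def _circumradius(pa, pb, pc) -> float:
    a = np.linalg.norm(pb - pc)
    b = np.linalg.norm(pa - pc)
    c = np.linalg.norm(pa - pb)
    area = abs(
        (pb[0] - pa[0]) * (pc[1] - pa[1]) - (pc[0] - pa[0]) * (pb[1] - pa[1])
    ) / 2.0
    if area == 0:
        return np.inf
    return a * b * c / (4.0 * area)


def concave_hull(points_um, alpha: float) -> Polygon | MultiPolygon:
    """Alpha-shape of a point cloud.

    Delaunay triangles are kept iff their circumradius ≤ 1/alpha and the
    union of kept triangles is returned; alpha → 0 recovers the convex
    hull.  Raises for fewer than 3 points, collinear input, or an alpha so
    large that no triangle survives.
    """
    pts = np.asarray(points_um, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points for a hull")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    try:
        tri = Delaunay(pts)
    except Exception as err:  # all points collinear
        raise ValueError("degenerate point cloud (collinear?)") from err
    max_r = np.inf if alpha == 0 else 1.0 / alpha
    kept = []
    for simplex in tri.simplices:
        pa, pb, pc = pts[simplex]
        if _circumradius(pa, pb, pc) <= max_r:
            kept.append(Polygon([pa, pb, pc]))
    if not kept:
        raise ValueError(
            f"alpha={alpha} leaves no triangle (1/alpha={max_r:.3g} below the "
            "smallest circumradius); decrease alpha"
        )
    hull = unary_union(kept)
    if isinstance(hull, Polygon):
        return hull
    if isinstance(hull, MultiPolygon):
        return hull
    raise ValueError("alpha-shape degenerated to a non-areal geometry")


def default_alpha(positions: pd.DataFrame) -> float:
    """1 / (1.5 × minimum centre spacing): keeps hex-adjacent triangles,
    drops triangles spanning holes."""
    xy = positions[["x_um", "y_um"]].to_numpy(dtype=float)
    d, _ = cKDTree(xy).query(xy, k=2)
    spacing = float(d[:, 1].min())
    if spacing <= 0:
        raise ValueError("coincident spot centres")
    return 1.0 / (1.5 * spacing)


def build_territories(
    clone_labels: pd.Series,
    positions: pd.DataFrame,
    graph: nx.Graph,
    alpha: float | None = None,
) -> dict[str, CloneTerritory]:
    """Largest connected component + concave hull for each clone label."""
    if alpha is None:
        alpha = default_alpha(positions)
    territories = {}
    for clone in sorted(clone_labels.unique()):
        spots = clone_labels.index[clone_labels == clone]
        lcc = largest_connected_component(spots, graph)
        hull = concave_hull(positions.loc[lcc, ["x_um", "y_um"]].to_numpy(), alpha)
        territories[str(clone)] = CloneTerritory(str(clone), lcc, hull, alpha)
    return territories


def assign_nuclei(
    nuclei: pd.DataFrame, territories: dict[str, CloneTerritory]
) -> pd.DataFrame:
    """Assign each nucleus to the clone whose territory contains its centroid.

    Boundary points count as inside.  A centroid inside multiple hulls is
    left unassigned (with a warning), as is one outside all hulls.
    """
    points = shapely.points(nuclei["x_um"].to_numpy(), nuclei["y_um"].to_numpy())
    inside = {
        clone: shapely.covers(t.hull, points) for clone, t in territories.items()
    }
    mat = np.column_stack(list(inside.values()))
    clones = np.array(list(inside.keys()))
    n_hit = mat.sum(axis=1)
    assignment = np.full(len(nuclei), "unassigned", dtype=object)
    unique_hits = n_hit == 1
    assignment[unique_hits] = clones[mat[unique_hits].argmax(axis=1)]
    n_ambiguous = int((n_hit > 1).sum())
    if n_ambiguous:
        warnings.warn(
            f"{n_ambiguous} nuclei fall inside multiple clone territories; left unassigned"
        )
    out = nuclei.copy()
    out["clone"] = assignment
    return out


def compare_nuclear_area(nuclei: pd.DataFrame) -> dict:
    """Two-sided Mann-Whitney comparison of nuclear areas between clones.

    A smaller-nucleus ancestral clone (more diploid cells) versus a
    larger-nucleus polyploid-enriched daughter clone shows up as a shifted
    area distribution.
    """
    areas = {
        c: nuclei.loc[nuclei["clone"] == c, "area_um2"].to_numpy() for c in ("A", "B")
    }
    for c, vals in areas.items():
        if len(vals) == 0:
            raise ValueError(f"clone {c} has no assigned nuclei")
    mw = mann_whitney_u(areas["A"], areas["B"], alternative="two_sided")
    return {
        "median_A": float(np.median(areas["A"])),
        "median_B": float(np.median(areas["B"])),
        "n_A": int(len(areas["A"])),
        "n_B": int(len(areas["B"])),
        "U": mw["U"],
        "p_two_sided": mw["p"],
    }
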