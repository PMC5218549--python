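"""Row-standardized spatial weight matrices from Delaunay triangulation.

Parcel coordinates (decimal degrees) are projected to planar kilometres
with an equirectangular projection about the centroid latitude, the
points are Delaunay-triangulated, and two owners are neighbours iff they
share a triangle edge.  Each row of the resulting n×n weight matrix W is
standardized to sum to one, so w_ij = 1/|N(i)| for neighbours j of i.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from scipy.spatial import Delaunay, QhullError

EARTH_RADIUS_KM = 6371.0088

#: Deterministic jitter applied to coincident points (km).
COINCIDENT_JITTER_KM = 1e-6
JITTER_SEED = 20170106


@dataclass
class WeightMatrix:
    """Sparse row-standardized spatial dependence matrix with metadata."""

    n: int
    neighbors: list[np.ndarray]
    w: sp.csr_matrix
    coords: np.ndarray  # planar km, shape (n, 2)
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Check the structural invariants of a valid W."""
        if self.w.shape != (self.n, self.n):
            raise ValueError("W shape mismatch")
        if np.abs(self.w.diagonal()).max() != 0:
            raise ValueError("nonzero diagonal")
        rowsum = np.asarray(self.w.sum(axis=1)).ravel()
        if np.abs(rowsum - 1.0).max() > 1e-12:
            raise ValueError("rows not standardized to 1")
        for i, nb in enumerate(self.neighbors):
            for j in nb:
                if i not in self.neighbors[j]:
                    raise ValueError("asymmetric neighbour relation")


def project_coordinates(
    coords: np.ndarray, max_span_deg: float = 10.0, override: bool = False
) -> tuple[np.ndarray, dict]:
    """Project lon/lat degrees to planar x/y kilometres.

    Equirectangular about the centroid: adequate for study regions of a
    few degrees.  Raises if the extent exceeds ``max_span_deg`` unless
    ``override`` is set.
    """
    coords = np.asarray(coords, dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    lon, lat = coords[:, 0], coords[:, 1]
    span = max(np.ptp(lon), np.ptp(lat)) if len(coords) else 0.0
    if span > max_span_deg and not override:
        raise ValueError(
            f"coordinate span {span:.2f} deg exceeds {max_span_deg} deg; "
            "equirectangular distortion may be severe (use override=True)"
        )
    lon0, lat0 = lon.mean(), lat.mean()
    ky = EARTH_RADIUS_KM * np.pi / 180.0
    kx = ky * np.cos(np.deg2rad(lat0))
    xy = np.column_stack([(lon - lon0) * kx, (lat - lat0) * ky])
    meta = {
        "projection": "equirectangular",
        "centroid_lon": float(lon0),
        "centroid_lat": float(lat0),
        "span_deg": float(span),
    }
    return xy, meta


def delaunay_neighbors(xy: np.ndarray, jitter_seed: int = JITTER_SEED) -> list[np.ndarray]:
    """Neighbour lists from the Delaunay triangulation of planar points.

    i and j are neighbours iff they are vertices of a common triangle
    edge.  Coincident points receive a deterministic 1e-6 km jitter so
    the triangulation is well defined.
    """
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    if n < 3:
        raise ValueError("at least 3 points required for a triangulation")
    _, first = np.unique(xy, axis=0, return_index=True)
    if len(first) < n:
        dup = np.setdiff1d(np.arange(n), first)
        rng = np.random.default_rng(jitter_seed)
        xy = xy.copy()
        xy[dup] += rng.normal(scale=COINCIDENT_JITTER_KM, size=(len(dup), 2))
    try:
        tri = Delaunay(xy)
    except QhullError as exc:  # all points collinear, etc.
        raise ValueError(f"degenerate point configuration: {exc}") from exc
    sets: list[set[int]] = [set() for _ in range(n)]
    for simplex in tri.simplices:
        for a in simplex:
            for b in simplex:
                if a != b:
                    sets[int(a)].add(int(b))
    if any(len(s) == 0 for s in sets):
        raise ValueError("triangulation left a point without neighbours")
    return [np.array(sorted(s), dtype=np.int64) for s in sets]


def row_standardize(neighbors: list[np.ndarray]) -> sp.csr_matrix:
    """Build W with w_ij = 1/|N(i)| for neighbours j of i, else 0."""
    n = len(neighbors)
    indptr = np.zeros(n + 1, dtype=np.int64)
    indices, data = [], []
    for i, nb in enumerate(neighbors):
        if len(nb) == 0:
            raise ValueError(f"row {i} has no neighbours")
        indices.append(nb)
        data.append(np.full(len(nb), 1.0 / len(nb)))
        indptr[i + 1] = indptr[i] + len(nb)
    w = sp.csr_matrix(
        (np.concatenate(data), np.concatenate(indices), indptr), shape=(n, n)
    )
    w.sort_indices()
    return w


def build_weights(coords: np.ndarray, already_planar: bool = False, **proj_kw) -> WeightMatrix:
    """Project lon/lat, triangulate, and row-standardize in one call."""
    coords = np.asarray(coords, dtype=float)
    if already_planar:
        xy, meta = coords, {"projection": "none"}
    else:
        xy, meta = project_coordinates(coords, **proj_kw)
    neighbors = delaunay_neighbors(xy)
    w = row_standardize(neighbors)
    wm = WeightMatrix(n=len(xy), neighbors=neighbors, w=w, coords=xy, meta=meta)
    counts = np.array([len(nb) for nb in neighbors])
    mean_dist = _mean_neighbor_distances(wm)
    wm.meta.update(
        min_neighbors=int(counts.min()),
        max_neighbors=int(counts.max()),
        mean_neighbor_distance_km_min=float(mean_dist.min()),
        mean_neighbor_distance_km_max=float(mean_dist.max()),
    )
    return wm


def _mean_neighbor_distances(wm: WeightMatrix) -> np.ndarray:
    """Per-row mean Euclidean distance (km) to Delaunay neighbours."""
    out = np.empty(wm.n)
    for i, nb in enumerate(wm.neighbors):
        d = np.linalg.norm(wm.coords[nb] - wm.coords[i], axis=1)
        out[i] = d.mean()
    return out


def neighbor_stats(wm: WeightMatrix) -> dict:
    """Neighbour-count and neighbour-distance summary of a W matrix."""
    counts = np.array([len(nb) for nb in wm.neighbors])
    mean_dist = _mean_neighbor_distances(wm)
    return {
        "n": wm.n,
        "min_neighbors": int(counts.min()),
        "max_neighbors": int(counts.max()),
        "mean_neighbors": float(counts.mean()),
        "mean_neighbor_distance_km_min": float(mean_dist.min()),
        "mean_neighbor_distance_km_max": float(mean_dist.max()),
        "mean_neighbor_distance_km": float(mean_dist.mean()),
    }


def save_weights(wm: WeightMatrix, path: str | Path) -> None:
    """Write W (<stem>.mtx), neighbour list CSV, coords, and stats JSON."""
    path = Path(path)
    mmwrite(str(path.with_suffix(".mtx")), wm.w, precision=17)
    coo = wm.w.tocoo()
    pd.DataFrame({"i": coo.row, "j": coo.col, "w_ij": coo.data}).to_csv(
        path.with_suffix(".neighbors.csv"), index=False
    )
    pd.DataFrame(wm.coords, columns=["x_km", "y_km"]).to_csv(
        path.with_suffix(".coords.csv"), index=False
    )
    with open(path.with_suffix(".stats.json"), "w") as fh:
        json.dump({**wm.meta, **neighbor_stats(wm)}, fh, indent=2)


def load_weights(path: str | Path) -> WeightMatrix:
    """Load a WeightMatrix written by :func:`save_weights`."""
    path = Path(path)
    w = sp.csr_matrix(mmread(str(path.with_suffix(".mtx"))))
    w.sort_indices()
    coords = pd.read_csv(path.with_suffix(".coords.csv")).to_numpy(dtype=float)
    n = w.shape[0]
    neighbors = [w.indices[w.indptr[i]: w.indptr[i + 1]].astype(np.int64) for i in range(n)]
    meta = {}
    stats_path = path.with_suffix(".stats.json")
    if stats_path.exists():
        with open(stats_path) as fh:
            meta = json.load(fh)
    return WeightMatrix(n=n, neighbors=neighbors, w=w, coords=coords, meta=meta)
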