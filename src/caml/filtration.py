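"""Filtered simplicial complexes from labeled 3D point clouds.

A filtration assigns to each simplex sigma a scale value g(sigma) that is
monotone under inclusion, so the sublevel snapshots Delta^r = {sigma :
g(sigma) <= r} form a nested family of simplicial complexes.  Two
constructions are provided:

* the Vietoris-Rips filtration, where g of a simplex is the maximum pairwise
  distance (diameter) of its vertices, truncated at a dimension bound and a
  distance cap;
* the bipartite filtration on two disjoint point sets, containing vertices
  and only the cross edges (never a 2-simplex), which isolates the
  inter-molecular interactions between a protein-side and a ligand-side
  atom group.

Vertices are born at scale 0.  All thresholds are closed (<=).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .simplicial_core import SimplicialComplex

Simplex = Tuple[int, ...]


@dataclass
class PointCloud:
    """3D coordinates (angstrom) with a per-point element/category label."""

    coordinates: np.ndarray
    labels: Sequence[str]

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        self.labels = list(self.labels)
        if len(self.labels) != len(self.coordinates):
            raise ValueError("labels and coordinates length mismatch")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.coordinates)


def read_xyz(path) -> PointCloud:
    """Read a labeled point cloud in plain XYZ format."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError("empty XYZ file")
    n = int(lines[0].split()[0])
    coords, labels = [], []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        labels.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    if len(coords) != n:
        raise ValueError(f"XYZ header promises {n} atoms, found {len(coords)}")
    return PointCloud(np.array(coords), labels)


def write_xyz(path, cloud: PointCloud, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(cloud)}\n{comment}\n")
        for lab, (x, y, z) in zip(cloud.labels, cloud.coordinates):
            fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")


class Filtration:
    """Simplices with monotone scale values, sorted by (value, dim, lex)."""

    def __init__(
        self,
        simplices: Iterable[Tuple[Sequence[int], float]],
        max_dimension: int,
        cap: float,
        vertices: Sequence[int] | None = None,
        validate: bool = True,
    ):
        items = [(tuple(sorted(s)), float(v)) for s, v in simplices]
        items.sort(key=lambda sv: (sv[1], len(sv[0]), sv[0]))
        self.simplices: List[Tuple[Simplex, float]] = items
        self.max_dimension = int(max_dimension)
        self.cap = float(cap)
        self._values: Dict[Simplex, float] = {s: v for s, v in items}
        if vertices is None:
            vertices = sorted({v for s, _ in items for v in s})
        self.vertices: Tuple[int, ...] = tuple(sorted(vertices))
        if validate:
            self._check_monotone()

    def _check_monotone(self) -> None:
        for s, v in self.simplices:
            if len(s) == 1:
                continue
            for i in range(len(s)):
                face = s[:i] + s[i + 1 :]
                fv = self._values.get(face)
                if fv is None:
                    raise ValueError(f"boundary face {face} of {s} missing")
                if fv > v + 1e-12:
                    raise ValueError(f"monotonicity violated at {s}")

    def value(self, simplex: Sequence[int]) -> float:
        return self._values[tuple(sorted(simplex))]

    def __len__(self) -> int:
        return len(self.simplices)

    def complex_at(self, r: float) -> SimplicialComplex:
        return complex_at(self, r)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("simplex\tvalue\n")
            for s, v in self.simplices:
                fh.write(",".join(map(str, s)) + f"\t{v:.6f}\n")


def rips_filtration(points: PointCloud, max_dim: int, cap: float) -> Filtration:
    """Vietoris-Rips filtration: flag complex with diameter values, up to cap.

    A simplex on vertex set U (|U| <= max_dim + 1) enters at the maximum
    pairwise distance within U, provided that value is <= cap; vertices enter
    at 0.
    """
    if len(points) == 0:
        raise ValueError("empty point cloud")
    if cap <= 0:
        raise ValueError("cap must be positive")
    n = len(points)
    dist = squareform(pdist(points.coordinates)) if n > 1 else np.zeros((1, 1))
    simplices: List[Tuple[Simplex, float]] = [((i,), 0.0) for i in range(n)]
    # neighbor lists restricted to higher indices give each clique once
    nbrs = [
        [j for j in range(i + 1, n) if dist[i, j] <= cap] for i in range(n)
    ]
    frontier: List[Tuple[Simplex, float]] = [((i,), 0.0) for i in range(n)]
    for _ in range(max_dim):
        nxt: List[Tuple[Simplex, float]] = []
        for simplex, value in frontier:
            last = simplex[-1]
            for v in nbrs[last]:
                ok = True
                new_val = value
                for u in simplex:
                    d = dist[u, v]
                    if d > cap:
                        ok = False
                        break
                    if d > new_val:
                        new_val = d
                if ok:
                    nxt.append((simplex + (v,), new_val))
        simplices.extend(nxt)
        frontier = nxt
        if not frontier:
            break
    return Filtration(simplices, max_dimension=max_dim, cap=cap,
                      vertices=range(n), validate=False)


def bipartite_filtration(set_a: PointCloud, set_b: PointCloud, cap: float) -> Filtration:
    """Vertices of both sets at 0; only cross edges (a, b) at their distance.

    Vertex indices: 0..|A|-1 for set A, then |A|..|A|+|B|-1 for set B.  No
    simplex of dimension >= 2 is ever created.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    na, nb = len(set_a), len(set_b)
    simplices: List[Tuple[Simplex, float]] = [((i,), 0.0) for i in range(na + nb)]
    if na and nb:
        cross = np.linalg.norm(
            set_a.coordinates[:, None, :] - set_b.coordinates[None, :, :], axis=2
        )
        for i in range(na):
            for j in range(nb):
                d = float(cross[i, j])
                if d <= cap:
                    simplices.append(((i, na + j), d))
    return Filtration(simplices, max_dimension=1, cap=cap,
                      vertices=range(na + nb), validate=False)


def complex_at(filt: Filtration, r: float) -> SimplicialComplex:
    """Snapshot Delta^r = {sigma : g(sigma) <= r}; r must not exceed the cap."""
    if r > filt.cap:
        raise ValueError(f"r={r} beyond filtration cap {filt.cap}")
    faces = [s for s, v in filt.simplices if v <= r]
    vertices = filt.vertices if r >= 0 else ()
    return SimplicialComplex(vertices, faces)


def restrict(filt: Filtration, w: Iterable[int]) -> Filtration:
    """Induced filtration on the vertex subset w; values are unchanged."""
    wset = set(w)
    unknown = wset - set(filt.vertices)
    if unknown:
        raise ValueError(f"unknown vertices in restriction: {sorted(unknown)}")
    kept = [(s, v) for s, v in filt.simplices if set(s) <= wset]
    return Filtration(kept, max_dimension=filt.max_dimension, cap=filt.cap,
                      vertices=sorted(wset), validate=False)
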