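"""Finite abstract simplicial complexes and Stanley-Reisner invariants.

A simplicial complex on a finite vertex set is a downward-closed family of
non-empty vertex subsets (faces) that contains every singleton.  Attached to
it are the classical invariants of combinatorial commutative algebra: the
f-vector (face counts by dimension), the h-vector (numerator coefficients of
the Hilbert series of the Stanley-Reisner ring k[Delta]), the Stanley-Reisner
ideal I(Delta) generated by the minimal non-faces, the facet prime ideals
P_sigma = (x_i : x_i not in sigma), and the Krull dimension dim(Delta) + 1.

Faces are stored as canonically sorted tuples of 0-based vertex indices;
vertex labels (any orderable hashable) are mapped to indices at construction.
The empty face is never stored but f_{-1} = 1 is honoured in all formulas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Dict, FrozenSet, Iterable, List, Sequence, Tuple

Face = Tuple[int, ...]

_BRUTE_FORCE_GUARD = 20


class SimplicialComplex:
    """Downward-closed face family on an ordered finite vertex set."""

    def __init__(self, vertices: Sequence, faces: Iterable[Iterable]):
        self.vertices: Tuple = tuple(sorted(set(vertices)))
        self._index: Dict = {v: i for i, v in enumerate(self.vertices)}
        face_set = set()
        for f in faces:
            idx = tuple(sorted(self._index[v] for v in f))
            if not idx:
                continue
            if len(set(idx)) != len(idx):
                raise ValueError(f"face with repeated vertices: {tuple(f)}")
            face_set.add(idx)
        for i in range(len(self.vertices)):
            face_set.add((i,))
        # enforce downward closure
        for face in list(face_set):
            for k in range(1, len(face)):
                for sub in combinations(face, k):
                    face_set.add(sub)
        self.faces: FrozenSet[Face] = frozenset(face_set)

    # -- basic structure -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def dim(self) -> int:
        if not self.faces:
            return -1
        return max(len(f) for f in self.faces) - 1

    def has_face(self, face: Iterable) -> bool:
        try:
            idx = tuple(sorted(self._index[v] for v in face))
        except KeyError:
            return False
        return idx in self.faces

    def faces_by_dim(self) -> List[List[Face]]:
        """Faces grouped by dimension, each group sorted lexicographically."""
        out: List[List[Face]] = [[] for _ in range(self.dim + 1)]
        for f in self.faces:
            out[len(f) - 1].append(f)
        for group in out:
            group.sort()
        return out

    def labels(self, face: Face) -> Tuple:
        return tuple(self.vertices[i] for i in face)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SimplicialComplex)
            and self.vertices == other.vertices
            and self.faces == other.faces
        )

    def __repr__(self) -> str:
        return (
            f"SimplicialComplex(n_vertices={self.n_vertices}, "
            f"n_faces={len(self.faces)}, dim={self.dim})"
        )

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "vertices": list(self.vertices),
                "facets": [list(self.labels(f)) for f in sorted(facets(self))],
            }
        )

    @classmethod
    def from_json(cls, doc: str) -> "SimplicialComplex":
        data = json.loads(doc)
        return make_complex_from_facets(
            [tuple(f) for f in data["facets"]], vertices=data["vertices"]
        )


@dataclass(frozen=True)
class SquarefreeMonomialIdeal:
    """Squarefree monomial ideal given by inclusion-minimal generators.

    Generators are vertex-index subsets; a squarefree monomial (identified
    with its support) lies in the ideal iff its support contains a generator.
    """

    ambient_vertices: Tuple
    generators: FrozenSet[Face]

    def __post_init__(self):
        gens = sorted(self.generators, key=lambda g: (len(g), g))
        for a, b in combinations(gens, 2):
            if set(a) <= set(b) or set(b) <= set(a):
                raise ValueError("generators must be pairwise incomparable")

    @property
    def is_zero(self) -> bool:
        return not self.generators

    def contains(self, support: Iterable[int]) -> bool:
        s = set(support)
        return any(set(g) <= s for g in self.generators)

    def __str__(self) -> str:
        if self.is_zero:
            return "(0)"
        gens = sorted(self.generators, key=lambda g: (len(g), g))
        terms = ["*".join(f"x{i + 1}" for i in g) for g in gens]
        return "(" + ", ".join(terms) + ")"


# -- construction --------------------------------------------------------


def make_complex_from_facets(
    facet_list: Iterable[Iterable], vertices: Sequence | None = None
) -> SimplicialComplex:
    """Downward closure of a set of candidate facets.

    Dominated and duplicate members are absorbed; the facets of the result
    are exactly the inclusion-maximal members of the input.
    """
    facet_list = [tuple(f) for f in facet_list]
    if not facet_list:
        raise ValueError("empty complex")
    if vertices is None:
        vertices = sorted({v for f in facet_list for v in f})
    return SimplicialComplex(vertices, facet_list)


def facets(cx: SimplicialComplex) -> set:
    """Inclusion-maximal faces, as sorted index tuples."""
    by_dim = cx.faces_by_dim()
    out = set()
    face_set = cx.faces
    for dim, group in enumerate(by_dim):
        for face in group:
            if dim == cx.dim:
                out.add(face)
                continue
            covered = False
            others = set(range(cx.n_vertices)) - set(face)
            for v in others:
                if tuple(sorted(face + (v,))) in face_set:
                    covered = True
                    break
            if not covered:
                out.add(face)
    return out


def facet_labels(cx: SimplicialComplex) -> set:
    return {cx.labels(f) for f in facets(cx)}


# -- f / h vectors and Hilbert function ----------------------------------


def f_vector(cx: SimplicialComplex) -> Tuple[int, ...]:
    """(f_0, ..., f_{d-1}); entry i counts i-dimensional faces."""
    counts = [0] * (cx.dim + 1)
    for f in cx.faces:
        counts[len(f) - 1] += 1
    return tuple(counts)


def h_from_f(f: Sequence[int], d: int) -> Tuple[int, ...]:
    """h-vector from the f-vector: h_j = sum_i (-1)^{j-i} C(d-i, j-i) f_{i-1}."""
    if len(f) != d:
        raise ValueError(f"expected f-vector of length d={d}, got {len(f)}")
    fm = (1,) + tuple(f)  # fm[i] = f_{i-1}
    return tuple(
        sum((-1) ** (j - i) * comb(d - i, j - i) * fm[i] for i in range(j + 1))
        for j in range(d + 1)
    )


def f_from_h(h: Sequence[int], d: int) -> Tuple[int, ...]:
    """Inverse transform: f_{j-1} = sum_i C(d-i, j-i) h_i, j = 1..d."""
    if len(h) != d + 1:
        raise ValueError(f"expected h-vector of length d+1={d + 1}, got {len(h)}")
    return tuple(
        sum(comb(d - i, j - i) * h[i] for i in range(j + 1)) for j in range(1, d + 1)
    )


def hilbert_dimensions(cx: SimplicialComplex, max_degree: int) -> Tuple[int, ...]:
    """dim_k k[Delta]_t for t = 0..max_degree, by direct monomial counting.

    A degree-t monomial survives in k[Delta] iff its support is a face; there
    are C(t-1, |F|-1) monomials of degree t with support exactly F.  This is
    the brute-force counterpart of the rational Hilbert-series form and is
    used as its oracle in tests.
    """
    if max_degree < 0:
        raise ValueError("max_degree must be >= 0")
    out = [1]
    for t in range(1, max_degree + 1):
        out.append(sum(comb(t - 1, len(f) - 1) for f in cx.faces))
    return tuple(out)


def hilbert_series_coefficients(
    h: Sequence[int], d: int, max_degree: int
) -> Tuple[int, ...]:
    """Power-series expansion of (h_0 + h_1 s + ... + h_d s^d) / (1-s)^d."""
    # 1/(1-s)^d has coefficients C(t+d-1, d-1)
    out = []
    for t in range(max_degree + 1):
        if d == 0:
            out.append(h[0] if t == 0 else 0)
            continue
        out.append(
            sum(h[j] * comb(t - j + d - 1, d - 1) for j in range(min(t, d) + 1))
        )
    return tuple(out)


# -- Stanley-Reisner ideals ----------------------------------------------


def stanley_reisner_generators(cx: SimplicialComplex) -> SquarefreeMonomialIdeal:
    """Minimal non-faces of Delta, generating I(Delta).

    The full simplex has the zero ideal (no non-faces).
    """
    gens = []
    n = cx.n_vertices
    # a minimal non-face has all proper subsets as faces, hence size <= dim+2
    for size in range(2, min(n, cx.dim + 2) + 1):
        for cand in combinations(range(n), size):
            if cand in cx.faces:
                continue
            if all(sub in cx.faces for sub in combinations(cand, size - 1)):
                gens.append(cand)
    return SquarefreeMonomialIdeal(cx.vertices, frozenset(gens))


def facet_prime_ideal(facet: Iterable, cx: SimplicialComplex) -> SquarefreeMonomialIdeal:
    """P_sigma = (x_i : x_i not in sigma) for a facet sigma of Delta."""
    idx = tuple(sorted(cx._index[v] for v in facet))
    if idx not in facets(cx):
        raise ValueError(f"{tuple(facet)} is not a facet of the complex")
    missing = frozenset((i,) for i in range(cx.n_vertices) if i not in idx)
    return SquarefreeMonomialIdeal(cx.vertices, missing)


def check_primary_decomposition(cx: SimplicialComplex) -> bool:
    """Verify I(Delta) = intersection of the facet ideals P_sigma, by brute force.

    Checks every squarefree monomial: membership in I(Delta) (support is a
    non-face) must coincide with membership in all P_sigma (support not
    contained in sigma).  Always true for a valid complex; a False return
    signals an implementation bug.
    """
    n = cx.n_vertices
    if n > _BRUTE_FORCE_GUARD:
        raise ValueError(f"brute-force guard exceeded: {n} > {_BRUTE_FORCE_GUARD}")
    facet_sets = [set(f) for f in facets(cx)]
    for size in range(1, n + 1):
        for support in combinations(range(n), size):
            in_ideal = support not in cx.faces
            in_all_primes = all(not set(support) <= fs for fs in facet_sets)
            if in_ideal != in_all_primes:
                return False
    return True


def krull_dimension(cx: SimplicialComplex) -> int:
    """Krull dimension of k[Delta], equal to dim(Delta) + 1."""
    return cx.dim + 1
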