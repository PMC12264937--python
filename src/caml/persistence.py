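"""Facet persistence barcodes and persistent Stanley-Reisner invariants.

Given a filtration Delta^r, a simplex sigma is a *facet* of the snapshot
exactly while g(sigma) <= r and no cofacet has entered yet; the interval
[birth, death) during which its facet prime ideal P_sigma belongs to the
primary decomposition of I(Delta^r) is one bar of the facet persistence
barcode.  The facet persistence Betti number beta_i^{r,r'} counts the
i-dimensional facet ideals common to the snapshots at scales r and r'.

The persistent graded Betti numbers refine Hochster's formula: for the
inclusion Delta^r -> Delta^{r'},

    beta_{i,i+j}^{r,r'} = sum over W subset V, |W| = i+j of
                          rank( H~_{j-1}(Delta_W^r) -> H~_{j-1}(Delta_W^{r'}) )

computed here over the rationals with exact arithmetic.  At r = r' this is
the classical Hochster formula, and the persistent h- and f-vectors built
from it coincide with the classical ones.

All homology-based operations carry brute-force vertex guards: they are
exponential-time oracles meant for small complexes, not production paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from . import _exactla
from .filtration import Filtration, complex_at, restrict
from .simplicial_core import SimplicialComplex

HOMOLOGY_GUARD = 16
GRADED_BETTI_GUARD = 12


def _binom(a: int, b: int) -> int:
    """Binomial with the conventions C(a, 0) = 1 (any a) and C(a, b) = 0 for a < b."""
    if b == 0:
        return 1
    if b < 0 or a < b or a < 0:
        return 0
    return math.comb(a, b)


# -- facet persistence ---------------------------------------------------


@dataclass(frozen=True)
class FacetBar:
    """One facet-ideal persistence interval [birth, death)."""

    dimension: int
    birth: float
    death: float  # math.inf when no cofacet enters within the cap
    witness: Tuple[int, ...]

    def alive_on(self, r: float, r_prime: float) -> bool:
        return self.birth <= r and self.death > r_prime


@dataclass
class FacetBarcode:
    bars: List[FacetBar]
    cap: float

    def by_dimension(self, dim: int) -> List[FacetBar]:
        return [b for b in self.bars if b.dimension == dim]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("dimension\tbirth\tdeath\twitness\n")
            for b in sorted(self.bars, key=lambda b: (b.dimension, b.birth, b.witness)):
                death = "inf" if math.isinf(b.death) else f"{b.death:.6f}"
                fh.write(
                    f"{b.dimension}\t{b.birth:.6f}\t{death}\t"
                    + ",".join(map(str, b.witness))
                    + "\n"
                )


def facet_barcode(filt: Filtration, up_to_dim: int) -> FacetBarcode:
    """Facet persistence bars for all simplices of dimension <= up_to_dim.

    A simplex is born at its own value and dies when its first cofacet
    enters (min cofacet value); by monotonicity this equals the first time
    any strict superset is present.  Simplices covered at their own birth
    value produce no bar.  The filtration must track one dimension above
    ``up_to_dim`` so cofacets are visible; deaths beyond the cap are +inf.
    """
    if filt.max_dimension < up_to_dim + 1:
        raise ValueError(
            f"filtration max_dimension={filt.max_dimension} too small for "
            f"facet bars up to dimension {up_to_dim} (need >= {up_to_dim + 1})"
        )
    death: Dict[Tuple[int, ...], float] = {}
    for simplex, value in filt.simplices:
        if len(simplex) < 2 or len(simplex) - 2 > up_to_dim:
            continue
        for i in range(len(simplex)):
            face = simplex[:i] + simplex[i + 1 :]
            if value < death.get(face, math.inf):
                death[face] = value
    bars = []
    for simplex, value in filt.simplices:
        if len(simplex) - 1 > up_to_dim:
            continue
        d = death.get(simplex, math.inf)
        if d > value:
            bars.append(FacetBar(len(simplex) - 1, value, d, simplex))
    return FacetBarcode(bars, cap=filt.cap)


def facet_persistence_betti(bc: FacetBarcode, i: int, r: float, r_prime: float) -> int:
    """beta_i^{r,r'} = number of i-facets of Delta^r still facets of Delta^{r'}."""
    if r > r_prime:
        raise ValueError("need r <= r_prime")
    if r_prime > bc.cap:
        raise ValueError(f"r'={r_prime} beyond barcode cap {bc.cap}")
    return sum(1 for b in bc.bars if b.dimension == i and b.alive_on(r, r_prime))


@dataclass
class PersistenceSummary:
    """Grid-sampled facet Betti numbers and their average rates."""

    grid: Tuple[float, ...]
    beta: Dict[int, Tuple[int, ...]]
    beta_rate: Dict[int, Tuple[float, ...]]
    f_rate: Tuple[Tuple[float, ...], ...] = ()


def summarize_on_grid(
    bc: FacetBarcode,
    f_by_r: Mapping[float, Sequence[int]] | None = None,
    grid: Sequence[float] = (),
    dims: Sequence[int] | None = None,
) -> PersistenceSummary:
    """Sample beta_i^{r,r} and the rates beta_i^{r,r}/r (and f^{r,r}/r) on a grid."""
    grid = tuple(float(r) for r in grid)
    if any(r <= 0 for r in grid):
        raise ValueError("grid values must be positive (rates divide by r)")
    if any(b >= a for a, b in zip(grid[1:], grid)):
        raise ValueError("grid must be strictly increasing")
    if dims is None:
        dims = sorted({b.dimension for b in bc.bars}) or [0]
    beta = {
        i: tuple(facet_persistence_betti(bc, i, r, r) for r in grid) for i in dims
    }
    beta_rate = {
        i: tuple(v / r for v, r in zip(beta[i], grid)) for i in dims
    }
    f_rate: Tuple[Tuple[float, ...], ...] = ()
    if f_by_r is not None:
        f_rate = tuple(
            tuple(x / r for x in f_by_r[r]) for r in grid
        )
    return PersistenceSummary(grid, beta, beta_rate, f_rate)


# -- exact (persistent) homology ranks -----------------------------------


def _boundary_vectors(
    faces_p: List[Tuple[int, ...]],
    faces_p1: List[Tuple[int, ...]],
) -> List[List[int]]:
    """Boundary of each (p+1)-face as a vector in the given p-face basis."""
    index = {f: k for k, f in enumerate(faces_p)}
    vecs = []
    for tau in faces_p1:
        vec = [0] * len(faces_p)
        for i in range(len(tau)):
            face = tau[:i] + tau[i + 1 :]
            vec[index[face]] += (-1) ** i
        vecs.append(vec)
    return vecs


def _faces_of_card(cx: SimplicialComplex, card: int) -> List[Tuple[int, ...]]:
    return sorted(f for f in cx.faces if len(f) == card)


def reduced_homology_rank(cx: SimplicialComplex, p: int) -> int:
    """dim of the p-th reduced simplicial homology over Q.

    Uses boundary-matrix ranks including the augmentation map C_0 -> k, so
    two isolated points have reduced H_0 of rank 1.
    """
    if cx.n_vertices > HOMOLOGY_GUARD:
        raise ValueError(f"homology guard exceeded: {cx.n_vertices} > {HOMOLOGY_GUARD}")
    if p < 0:
        return 0
    faces_p = _faces_of_card(cx, p + 1)
    if not faces_p:
        return 0
    faces_p1 = _faces_of_card(cx, p + 2)
    if p == 0:
        rank_dp = 1 if faces_p else 0  # augmentation row of ones
    else:
        faces_pm1 = _faces_of_card(cx, p)
        # rank of d_p equals rank of its transpose (boundary vectors as rows)
        rank_dp = _exactla.rank(_boundary_vectors(faces_pm1, faces_p))
    rank_dp1 = _exactla.rank(_boundary_vectors(faces_p, faces_p1))
    return len(faces_p) - rank_dp - rank_dp1


def persistent_homology_rank(
    filt: Filtration, p: int, r: float, r_prime: float
) -> int:
    """Rank of H~_p(Delta^r) -> H~_p(Delta^{r'}) induced by inclusion.

    Computed as rank[B_p(Delta^{r'}) | Z_p(Delta^r)] - rank B_p(Delta^{r'})
    in the p-chain basis of Delta^{r'}, over Q.
    """
    if r > r_prime:
        raise ValueError("need r <= r_prime")
    if len(filt.vertices) > HOMOLOGY_GUARD:
        raise ValueError(
            f"homology guard exceeded: {len(filt.vertices)} > {HOMOLOGY_GUARD}"
        )
    if p < 0:
        return 0
    cx_r = complex_at(filt, r)
    cx_rp = complex_at(filt, r_prime)
    faces_p_L = _faces_of_card(cx_rp, p + 1)
    if not faces_p_L:
        return 0
    index_L = {f: k for k, f in enumerate(faces_p_L)}
    faces_p_K = _faces_of_card(cx_r, p + 1)
    if not faces_p_K:
        return 0
    # cycles of Delta^r, embedded into the chain basis of Delta^{r'}
    if p == 0:
        dp_K = [[1] * len(faces_p_K)]
    else:
        faces_pm1_K = _faces_of_card(cx_r, p)
        # rows = equations indexed by (p-1)-faces: transpose boundary vectors
        cols = _boundary_vectors(faces_pm1_K, faces_p_K)
        dp_K = [list(row) for row in zip(*cols)] if cols else []
    kernel = _exactla.kernel_basis(dp_K, len(faces_p_K))
    z_vecs = []
    for vec in kernel:
        out = [0] * len(faces_p_L)
        for f, x in zip(faces_p_K, vec):
            out[index_L[f]] = x
        z_vecs.append(out)
    b_vecs = _boundary_vectors(faces_p_L, _faces_of_card(cx_rp, p + 2))
    rank_b = _exactla.rank(b_vecs)
    rank_bz = _exactla.rank(b_vecs + z_vecs)
    return rank_bz - rank_b


# -- persistent graded Betti numbers and h/f-vectors ---------------------


def persistent_graded_betti(
    filt: Filtration, i: int, j: int, r: float, r_prime: float
) -> int:
    """beta_{i,i+j}^{r,r'}: persistent Hochster sum over |W| = i+j subsets.

    ``i`` is the homological index (>= 1) and ``j`` the degree offset
    (>= 1); the total degree is i + j.  At r = r' this is Hochster's
    formula for the classical graded Betti number beta_{i,i+j}(k[Delta^r]).
    """
    n = len(filt.vertices)
    if n > GRADED_BETTI_GUARD:
        raise ValueError(f"graded Betti guard exceeded: {n} > {GRADED_BETTI_GUARD}")
    if i < 1 or j < 1:
        raise ValueError("need i >= 1 and j >= 1")
    size = i + j
    if size > n:
        return 0
    total = 0
    for w in combinations(filt.vertices, size):
        total += persistent_homology_rank(restrict(filt, w), j - 1, r, r_prime)
    return total


@dataclass
class GradedBettiTable:
    """beta_{i,j}^{r,r'} values keyed by (i, total degree j, r, r')."""

    entries: Dict[Tuple[int, int, float, float], int] = field(default_factory=dict)

    def beta(self, i: int, j_total: int, r: float, r_prime: float) -> int:
        return self.entries.get((i, j_total, r, r_prime), 0)


def graded_betti_table(
    filt: Filtration, r: float, r_prime: float, max_total_degree: int | None = None
) -> GradedBettiTable:
    """All persistent graded Betti numbers up to a total degree (default |V|)."""
    n = len(filt.vertices)
    jmax = n if max_total_degree is None else min(max_total_degree, n)
    table = GradedBettiTable()
    table.entries[(0, 0, r, r_prime)] = 1
    for total in range(2, jmax + 1):
        for i in range(1, total):
            val = persistent_graded_betti(filt, i, total - i, r, r_prime)
            if val:
                table.entries[(i, total, r, r_prime)] = val
    return table


def persistent_h_vector(
    filt: Filtration, r: float, r_prime: float
) -> Tuple[int, ...]:
    """(h_0^{r,r'}, ..., h_d^{r,r'}) with d = dim(Delta^{r'}) + 1.

    h_m = sum_{j=0}^m C(n-d+m-j-1, m-j) * sum_{i=0}^j (-1)^i beta_{i,j}^{r,r'},
    reading the second Betti index as total degree (beta_{0,0} = 1, zero for
    0 < j <= i) and with the convention C(a, 0) = 1, C(a, b) = 0 for a < b.
    At r = r' this reproduces the classical h-vector of Delta^r.
    """
    n = len(filt.vertices)
    d = complex_at(filt, r_prime).dim + 1
    if d <= 0:
        raise ValueError("empty snapshot at r'")
    table = graded_betti_table(filt, r, r_prime, max_total_degree=d)
    out = []
    for m in range(d + 1):
        h_m = 0
        for j in range(m + 1):
            alt = sum((-1) ** i * table.beta(i, j, r, r_prime) for i in range(j + 1))
            if j == 0:
                alt = 1
            h_m += _binom(n - d + m - j - 1, m - j) * alt
        out.append(h_m)
    return tuple(out)


def persistent_f_vector(
    filt: Filtration, r: float, r_prime: float
) -> Tuple[int, ...]:
    """(f_0^{r,r'}, ..., f_{d-1}^{r,r'}) via f_{m-1} = sum_i C(d-i, m-i) h_i.

    At r = r' this equals the classical f-vector of the snapshot Delta^r.
    """
    h = persistent_h_vector(filt, r, r_prime)
    d = len(h) - 1
    return tuple(
        sum(_binom(d - i, m - i) * h[i] for i in range(m + 1)) for m in range(1, d + 1)
    )
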