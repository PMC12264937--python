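"""Exact linear algebra over the rationals for small boundary matrices.

Matrices are lists of rows of :class:`fractions.Fraction` (or ints).  All
homology ranks in this package go through these routines so that results are
field-characteristic-0 exact; the brute-force guards elsewhere keep every
matrix tiny, so plain Gaussian elimination is more than fast enough.
"""

from __future__ import annotations

from fractions import Fraction
from typing import List, Sequence


def _echelonize(mat: List[List[Fraction]]) -> int:
    """Reduce ``mat`` in place to row echelon form; return its rank."""
    if not mat or not mat[0]:
        return 0
    n_rows, n_cols = len(mat), len(mat[0])
    rank = 0
    for col in range(n_cols):
        pivot = None
        for row in range(rank, n_rows):
            if mat[row][col] != 0:
                pivot = row
                break
        if pivot is None:
            continue
        mat[rank], mat[pivot] = mat[pivot], mat[rank]
        inv = Fraction(1, 1) / mat[rank][col]
        mat[rank] = [x * inv for x in mat[rank]]
        for row in range(n_rows):
            if row != rank and mat[row][col] != 0:
                factor = mat[row][col]
                mat[row] = [a - factor * b for a, b in zip(mat[row], mat[rank])]
        rank += 1
        if rank == n_rows:
            break
    return rank


def rank(matrix: Sequence[Sequence[int]]) -> int:
    """Rank of a matrix with integer (or Fraction) entries, over Q."""
    mat = [[Fraction(x) for x in row] for row in matrix]
    return _echelonize(mat)


def kernel_basis(matrix: Sequence[Sequence[int]], n_cols: int) -> List[List[Fraction]]:
    """Basis of the null space of ``matrix`` (rows = equations, n_cols unknowns).

    Returns basis vectors as length-``n_cols`` lists; the empty matrix has the
    full space as kernel.
    """
    mat = [[Fraction(x) for x in row] for row in matrix]
    if not mat:
        return [[Fraction(int(i == j)) for j in range(n_cols)] for i in range(n_cols)]
    _echelonize(mat)
    pivots = []
    for row in mat:
        for j, x in enumerate(row):
            if x != 0:
                pivots.append(j)
                break
    pivot_set = set(pivots)
    free = [j for j in range(n_cols) if j not in pivot_set]
    basis = []
    for f in free:
        vec = [Fraction(0)] * n_cols
        vec[f] = Fraction(1)
        for row, p in zip(mat, pivots):
            vec[p] = -row[f]
        basis.append(vec)
    return basis
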