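"""Deterministic synthetic inputs: the C60 fullerene worked example, random
binding-pocket-like complexes, and regression datasets with known signal.

The C60 molecule (60 carbon atoms on a truncated icosahedron, 12 pentagons
and 20 hexagons) is built parametrically from its two bond lengths - single
(pentagon-hexagon) bonds of 1.453 A and double (hexagon-hexagon) bonds of
1.367 A - so both lengths are exact by construction: truncating a regular
icosahedron of edge a = 2*single + double at fraction t = single/a places
the pentagon edges at t*a = single and the hexagon-hexagon edges at
(1 - 2t)*a = double.

Synthetic pockets emulate the geometry the featurizer sees in real
structures (a ligand blob surrounded by a protein shell, optionally with a
metal ion) but not chemistry: no bonds, no realistic residue geometry.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, Tuple

import numpy as np

from .filtration import PointCloud
from .structures import (
    LIGAND_ELEMENTS,
    METAL_ELEMENTS,
    PROTEIN_ELEMENTS,
    RESIDUE_CATEGORIES,
    Atom,
    MolecularComplex,
)

GOLDEN = (1 + np.sqrt(5)) / 2

C60_SINGLE_BOND = 1.453  # pentagon-hexagon bonds, 60 of them
C60_DOUBLE_BOND = 1.367  # hexagon-hexagon bonds, 30 of them

_LIGAND_WEIGHTS = dict(
    C=0.45, H=0.15, O=0.15, N=0.12, S=0.03, P=0.02, F=0.03, Cl=0.03, Br=0.01, I=0.01
)
_PROTEIN_WEIGHTS = dict(C=0.60, N=0.16, O=0.20, S=0.04)


def _icosahedron(edge: float) -> np.ndarray:
    """Vertices of a regular icosahedron with the given edge length."""
    pts = []
    for a in (-1.0, 1.0):
        for b in (-GOLDEN, GOLDEN):
            pts += [(0, a, b), (a, b, 0), (b, 0, a)]
    verts = np.array(pts)
    return verts * (edge / 2.0)  # canonical coordinates have edge length 2


def make_c60(
    single_bond: float = C60_SINGLE_BOND, double_bond: float = C60_DOUBLE_BOND
) -> PointCloud:
    """C60 point cloud by truncation of a regular icosahedron.

    Each of the 30 icosahedron edges carries two atoms at fractions t and
    1 - t with t = single/(2*single + double); the 60 atoms realize exactly
    30 pairs at the double-bond length and 60 pairs at the single-bond
    length, each atom having two single bonds and one double bond.
    """
    if single_bond <= 0 or double_bond <= 0:
        raise ValueError("bond lengths must be positive")
    a = 2 * single_bond + double_bond
    t = single_bond / a
    verts = _icosahedron(a)
    n = len(verts)
    edges = [
        (i, j)
        for i, j in combinations(range(n), 2)
        if abs(np.linalg.norm(verts[i] - verts[j]) - a) < 1e-9 * a
    ]
    assert len(edges) == 30
    points = []
    for i, j in edges:
        u, v = verts[i], verts[j]
        points.append(u + t * (v - u))
        points.append(u + (1 - t) * (v - u))
    return PointCloud(np.array(points), ["C"] * len(points))


def c60_bond_counts(cloud: PointCloud, tol: float = 1e-3) -> Dict[str, int]:
    """Count atom pairs at the single/double bond lengths (fixture self-check)."""
    from scipy.spatial.distance import pdist

    d = pdist(cloud.coordinates)
    return {
        "double": int(np.sum(np.abs(d - C60_DOUBLE_BOND) < tol)),
        "single": int(np.sum(np.abs(d - C60_SINGLE_BOND) < tol)),
    }


def _random_unit(rng: np.random.Generator, size: int = 1) -> np.ndarray:
    v = rng.normal(size=(size, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def make_synthetic_pocket(
    n_protein: int, n_ligand: int, with_metal: bool, seed: int
) -> MolecularComplex:
    """Random binding-pocket-like complex, reproducible per seed.

    Ligand atoms are uniform in a 5 A ball at the origin; protein atoms lie
    in a shell chosen so that every one survives the 12 A pocket cutoff;
    with ``with_metal`` one metal ion is placed within 15 A of the ligand.
    """
    if n_ligand < 1:
        raise ValueError("need at least one ligand atom")
    if n_protein < 0:
        raise ValueError("n_protein must be >= 0")
    rng = np.random.default_rng(seed)
    residue_codes = sorted(RESIDUE_CATEGORIES)

    lig_elements = list(_LIGAND_WEIGHTS)
    lig_p = np.array(list(_LIGAND_WEIGHTS.values()))
    lig_xyz = _random_unit(rng, n_ligand) * (5.0 * rng.random(n_ligand) ** (1 / 3))[:, None]
    atoms = [
        Atom(el, xyz, "", "ligand")
        for el, xyz in zip(rng.choice(lig_elements, n_ligand, p=lig_p), lig_xyz)
    ]

    prot_elements = list(_PROTEIN_WEIGHTS)
    prot_p = np.array(list(_PROTEIN_WEIGHTS.values()))
    placed = 0
    while placed < n_protein:
        pos = _random_unit(rng)[0] * rng.uniform(2.0, 11.5)
        dmin = np.min(np.linalg.norm(lig_xyz - pos, axis=1))
        if 1.5 <= dmin <= 11.5:
            atoms.append(
                Atom(
                    rng.choice(prot_elements, p=prot_p),
                    pos,
                    rng.choice(residue_codes),
                    "protein",
                )
            )
            placed += 1

    if with_metal:
        while True:
            anchor = lig_xyz[rng.integers(n_ligand)]
            pos = anchor + _random_unit(rng)[0] * rng.uniform(2.0, 10.0)
            dmin = np.min(np.linalg.norm(lig_xyz - pos, axis=1))
            if 1.5 <= dmin <= 15.0:
                atoms.append(Atom(rng.choice(list(METAL_ELEMENTS)), pos, "", "metal"))
                break

    return MolecularComplex(atoms, identifier=f"synthetic-{seed}")


def make_regression_dataset(
    n_samples: int,
    seed: int,
    sigma: float = 0.5,
    scheme: str = "ES",
) -> Tuple[np.ndarray, np.ndarray, Dict]:
    """Labeled descriptor matrix with a known sparse linear signal.

    Features are the full descriptors of seeded random pockets of varying
    size; labels are a fixed sparse linear combination of eight standardized
    high-variance feature columns plus Gaussian noise of scale ``sigma``.
    The generating indices, weights and noise scale are returned in the
    metadata dict.
    """
    if n_samples < 10:
        raise ValueError("need n_samples >= 10")
    from .featurize import featurize_complex

    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_samples):
        pocket = make_synthetic_pocket(
            n_protein=int(rng.integers(20, 41)),
            n_ligand=int(rng.integers(5, 11)),
            with_metal=False,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rows.append(featurize_complex(pocket, scheme=scheme, has_metal=False))
    X = np.stack(rows)

    variances = X.var(axis=0)
    order = np.lexsort((np.arange(len(variances)), -variances))
    idx = np.sort(order[:8])
    weights = np.array([1.0, -0.8, 0.8, 0.6, -0.6, 0.5, -0.4, 0.4])
    sel = X[:, idx]
    standardized = (sel - sel.mean(axis=0)) / sel.std(axis=0)
    y = standardized @ weights + rng.normal(0.0, sigma, size=n_samples)
    info = {
        "feature_indices": idx.tolist(),
        "weights": weights.tolist(),
        "sigma": sigma,
        "standardized": True,
        "scheme": scheme,
    }
    return X, y, info
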