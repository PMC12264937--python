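"""Element- and category-specific persistent commutative-algebra descriptors.

A pocket-filtered molecular complex is decomposed into pairwise atom groups:

* P-L: protein element (C/N/O/S) or residue category (H/U/N/P) against one
  of ten ligand elements (C/N/O/S/P/F/Cl/Br/I/H) - 40 pairs;
* M-P: metal element (Zn/Mg/Mn/Ca/Na/Fe/Ni) against the protein tags - 28;
* M-L: metal element against ligand elements - 70 (138 in total for
  metalloprotein complexes).

Each pair yields two filtered complexes - a Vietoris-Rips filtration on the
union of the two clouds and a bipartite filtration on the pair - and for
every grid scale r (1 to 12 A for P-L, 1 to 15 A for metal pairs, step
0.5 A) four statistics: the facet persistence Betti numbers beta_0^{r,r},
beta_1^{r,r} and their average rates beta/r.  Concatenation over the pair
list in a fixed order gives the final descriptor; empty groups contribute
zero blocks at fixed offsets, so the vector length depends only on
(scheme, has_metal).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .filtration import PointCloud, bipartite_filtration, rips_filtration
from .persistence import facet_barcode, facet_persistence_betti
from .structures import (
    CATEGORY_TAGS,
    LIGAND_ELEMENTS,
    METAL_ELEMENTS,
    PROTEIN_ELEMENTS,
    MolecularComplex,
    pocket_atoms,
    residue_category,
)

GRID_PL: Tuple[float, ...] = tuple(1.0 + 0.5 * k for k in range(23))  # 1.0 .. 12.0
GRID_METAL: Tuple[float, ...] = tuple(1.0 + 0.5 * k for k in range(29))  # 1.0 .. 15.0
STATS = ("beta0", "beta1", "beta0_rate", "beta1_rate")
CONSTRUCTIONS = ("rips_union", "bipartite")


@dataclass(frozen=True)
class PairSpec:
    """One atom-group pairing: (protein-or-metal tag, partner tag, class)."""

    side_a: str
    side_b: str
    interaction: str  # "P-L" | "M-P" | "M-L"

    @property
    def grid(self) -> Tuple[float, ...]:
        return GRID_PL if self.interaction == "P-L" else GRID_METAL


def enumerate_pairs(scheme: str = "ES", has_metal: bool = False) -> List[PairSpec]:
    """Deterministic product-order pair list: P-L, then M-P, then M-L."""
    scheme = scheme.upper()
    if scheme not in ("ES", "CS"):
        raise ValueError(f"unknown scheme {scheme!r} (expected 'ES' or 'CS')")
    protein_tags = PROTEIN_ELEMENTS if scheme == "ES" else CATEGORY_TAGS
    pairs = [PairSpec(p, l, "P-L") for p in protein_tags for l in LIGAND_ELEMENTS]
    if has_metal:
        pairs += [PairSpec(m, p, "M-P") for m in METAL_ELEMENTS for p in protein_tags]
        pairs += [PairSpec(m, l, "M-L") for m in METAL_ELEMENTS for l in LIGAND_ELEMENTS]
    return pairs


def _protein_cloud(mc: MolecularComplex, tag: str, scheme: str) -> PointCloud:
    atoms = [
        a
        for a in mc.by_role("protein")
        if a.element in PROTEIN_ELEMENTS
        and (a.element == tag if scheme == "ES" else residue_category(a.residue_name) == tag)
    ]
    return PointCloud(mc.coords(atoms), [a.element for a in atoms])


def group_atoms(
    mc: MolecularComplex, spec: PairSpec, scheme: str = "ES"
) -> Tuple[PointCloud, PointCloud]:
    """The two labeled point clouds selected by a pair spec (may be empty)."""
    scheme = scheme.upper()
    if spec.interaction == "P-L":
        side_a = _protein_cloud(mc, spec.side_a, scheme)
        lig = [a for a in mc.by_role("ligand") if a.element == spec.side_b]
        side_b = PointCloud(mc.coords(lig), [a.element for a in lig])
    elif spec.interaction == "M-P":
        met = [a for a in mc.by_role("metal") if a.element == spec.side_a]
        side_a = PointCloud(mc.coords(met), [a.element for a in met])
        side_b = _protein_cloud(mc, spec.side_b, scheme)
    elif spec.interaction == "M-L":
        met = [a for a in mc.by_role("metal") if a.element == spec.side_a]
        side_a = PointCloud(mc.coords(met), [a.element for a in met])
        lig = [a for a in mc.by_role("ligand") if a.element == spec.side_b]
        side_b = PointCloud(mc.coords(lig), [a.element for a in lig])
    else:
        raise ValueError(f"unknown interaction class {spec.interaction!r}")
    return side_a, side_b


def _barcode_stats(bc, grid: Sequence[float]) -> np.ndarray:
    out = np.empty(len(grid) * len(STATS))
    for t, r in enumerate(grid):
        b0 = facet_persistence_betti(bc, 0, r, r)
        b1 = facet_persistence_betti(bc, 1, r, r)
        out[4 * t : 4 * t + 4] = (b0, b1, b0 / r, b1 / r)
    return out


def pair_features(
    a: PointCloud, b: PointCloud, grid: Sequence[float], max_dim: int = 2
) -> np.ndarray:
    """Feature segment for one pair: rips-union block then bipartite block."""
    seg_len = len(grid) * len(STATS)
    cap = float(grid[-1])
    blocks = []
    # Rips on the union of the two clouds
    n_union = len(a) + len(b)
    if n_union == 0:
        blocks.append(np.zeros(seg_len))
    else:
        union = PointCloud(
            np.vstack([a.coordinates, b.coordinates]), list(a.labels) + list(b.labels)
        )
        filt = rips_filtration(union, max_dim=max_dim, cap=cap)
        blocks.append(_barcode_stats(facet_barcode(filt, up_to_dim=1), grid))
    # bipartite on (a, b)
    if n_union == 0:
        blocks.append(np.zeros(seg_len))
    else:
        filt = bipartite_filtration(a, b, cap=cap)
        # no 2-simplex ever exists in a bipartite filtration, so dimension-1
        # cofacets are trivially tracked
        filt.max_dimension = 2
        blocks.append(_barcode_stats(facet_barcode(filt, up_to_dim=1), grid))
    return np.concatenate(blocks)


@dataclass
class FeatureSchema:
    """Fixed descriptor layout for a (scheme, has_metal) configuration."""

    scheme: str
    has_metal: bool
    pairs: List[PairSpec] = field(default_factory=list)

    def __post_init__(self):
        if not self.pairs:
            self.pairs = enumerate_pairs(self.scheme, self.has_metal)

    @property
    def n_features(self) -> int:
        return sum(
            len(p.grid) * len(STATS) * len(CONSTRUCTIONS) for p in self.pairs
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "scheme": self.scheme,
                "has_metal": self.has_metal,
                "stats": STATS,
                "constructions": CONSTRUCTIONS,
                "grid_pl": GRID_PL,
                "grid_metal": GRID_METAL,
                "pairs": [[p.side_a, p.side_b, p.interaction] for p in self.pairs],
                "n_features": self.n_features,
            }
        )

    @property
    def schema_id(self) -> str:
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]


def featurize_complex(
    mc: MolecularComplex,
    scheme: str = "ES",
    has_metal: bool | None = None,
    pocket_filter: bool = True,
    max_dim: int = 2,
) -> np.ndarray:
    """Full descriptor vector for one (pocket-filtered) molecular complex."""
    if not mc.by_role("ligand"):
        raise ValueError("no ligand atoms in complex")
    if pocket_filter:
        mc = pocket_atoms(mc)
    if has_metal is None:
        has_metal = mc.has_metal
    schema = FeatureSchema(scheme.upper(), has_metal)
    segments = []
    for spec in schema.pairs:
        a, b = group_atoms(mc, spec, scheme)
        segments.append(pair_features(a, b, spec.grid, max_dim=max_dim))
    return np.concatenate(segments)


class CamlFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer: molecular complexes -> descriptor matrix.

    Parameters
    ----------
    scheme : {"ES", "CS"}
        Element-specific or category-specific protein-side grouping.
    has_metal : bool
        Include the metal interaction blocks (fixes the output width).
    pocket_filter : bool
        Apply the 12/15 A binding-pocket cutoffs before featurization.
    max_dim : int
        Rips dimension bound; 2 suffices for dimension-0/1 facet statistics.
    """

    def __init__(
        self,
        scheme: str = "ES",
        has_metal: bool = False,
        pocket_filter: bool = True,
        max_dim: int = 2,
    ):
        self.scheme = scheme
        self.has_metal = has_metal
        self.pocket_filter = pocket_filter
        self.max_dim = max_dim

    def fit(self, X: Sequence[MolecularComplex], y=None) -> "CamlFeaturizer":
        schema = FeatureSchema(self.scheme.upper(), self.has_metal)
        self.schema_ = schema
        self.n_features_out_ = schema.n_features
        return self

    def transform(self, X: Sequence[MolecularComplex]) -> np.ndarray:
        if not hasattr(self, "schema_"):
            self.fit(X)
        return np.stack(
            [
                featurize_complex(
                    mc,
                    scheme=self.scheme,
                    has_metal=self.has_metal,
                    pocket_filter=self.pocket_filter,
                    max_dim=self.max_dim,
                )
                for mc in X
            ]
        )
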