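# Methods

## Persistent Stanley–Reisner invariants

`caml` works with finite abstract simplicial complexes stored as
downward-closed sets of canonically sorted vertex-index tuples. The
classical layer (`simplicial_core`) computes facets, f- and h-vectors, the
Hilbert function of the Stanley–Reisner ring by direct monomial counting,
the ideal of minimal non-faces, facet prime ideals and Krull dimension.
Monomials are represented by their supports (vertex subsets); there is no
symbolic-algebra dependency, so all counting is exact and field-independent.

The persistent layer (`persistence`) is built on two constructions:

**Facet persistence barcodes.** In a filtration with monotone values
g(σ), a simplex is a facet of the snapshot Δʳ from its own birth g(σ)
until the first cofacet enters, so its bar is [g(σ), min_τ g(τ)) over
cofacets τ. Monotonicity guarantees that the minimum over cofacets equals
the minimum over all strict supersets, so a filtration that tracks one
dimension above the bars requested suffices; `facet_barcode` enforces this
precondition. A simplex covered at its own birth value (e.g. the edges of
an equilateral triangle under the Rips diameter rule) is never a facet of
any snapshot and produces no bar: death must be strictly later than birth.
Deaths beyond the filtration cap are +inf ("inf" in TSV exports).
Distance comparisons are exact floating-point; no rounding is applied
inside the library, and tests that rely on ties use coordinates whose
distances are bit-identical by symmetry.

**Persistent graded Betti numbers.** For r ≤ r′,
β_{i,i+j}^{r,r′} sums, over all vertex subsets W of size i+j, the rank of
the map H̃_{j−1}(Δ_Wʳ) → H̃_{j−1}(Δ_Wʳ′) induced by inclusion. The rank is
computed as rank[B | Z] − rank B, where B spans the (j−1)-boundaries of the
larger snapshot and Z the (j−1)-cycles of the smaller one, both expressed
in the chain basis of the larger snapshot; reduced homology includes the
augmentation map, so isolated points behave correctly at j = 1. All ranks
are taken over the rationals with exact Fraction arithmetic — the field k
is arbitrary of characteristic 0, and the tiny matrix sizes under the
brute-force guards (16 vertices for homology, 12 for the Hochster sum)
make exactness essentially free. These operations are oracles by design:
they scale exponentially and refuse larger inputs with explicit errors.

**Persistent h- and f-vectors.** With n = |V| and d = dim(Δʳ′) + 1,

    h_m^{r,r′} = Σ_{j=0}^m C(n−d+m−j−1, m−j) Σ_{i=0}^j (−1)^i β_{i,j}^{r,r′}

reading the second Betti index as *total* degree (β_{0,0} = 1; zero for
0 < j ≤ i), with the binomial conventions C(a, 0) = 1 for every a
(including a = −1, which carries the full-simplex case n = d) and
C(a, b) = 0 for a < b. This is the K-polynomial/Hilbert-series numerator
relation, so at r = r′ the persistent h-vector equals the classical one
and the derived persistent f-vector coincides with the face counts of the
snapshot — an identity the test suite checks on randomized filtrations.
The same convention resolves the edge cases the defining formula leaves
open; the r = r′ coincidence is the validation criterion for the choice.

## Filtrations

Vietoris–Rips filtrations use the diameter rule (simplex value = maximum
pairwise distance) with a closed threshold g(σ) ≤ r, a dimension bound and
a distance cap; vertices are born at 0. Bipartite filtrations on two
disjoint clouds contain all vertices and only the cross edges — no
2-simplex ever forms, which models inter-molecular contacts without
intra-molecular clutter. Restriction to a vertex subset keeps values
unchanged and commutes with taking snapshots; for Rips this equals the
Rips filtration of the sub-cloud (flag locality), which the tests verify.

For facet statistics of dimensions 0 and 1 the featurizer builds Rips
complexes to dimension 2 (cofacet visibility for edges); the C60
demonstration uses dimension 3 so that 2-dimensional facet bars are also
meaningful.

## Molecular descriptors

Pocket extraction keeps every ligand atom, protein atoms whose minimum
atom–atom distance to the ligand is ≤ 12 Å, and metal ions within 15 Å
(closed thresholds, matching the filtration convention; atom–atom minimum
distance is used rather than a centroid rule). Protein atoms outside
{C, N, O, S} — hydrogens in particular — are ignored by the featurizer;
the ligand alphabet is {C, N, O, S, P, F, Cl, Br, I, H} and the metal
alphabet {Zn, Mg, Mn, Ca, Na, Fe, Ni}. Waters are dropped at parse time,
and only the first alternate location of a PDB atom is kept, for
deterministic parsing of real-world files.

Pair enumeration is a fixed product order (P–L block, then M–P, then M–L;
protein tags × partner tags in declared alphabet order), so descriptor
layout is a pure function of (scheme, has_metal): 40 pairs without metals,
138 with. Each pair contributes, for both the Rips-union and the bipartite
construction, four statistics per grid point — β₀^{r,r}, β₁^{r,r} and the
rates β/r — on the 23-point 1–12 Å grid (P–L) or the 29-point 1–15 Å grid
(metal pairs, following the wider metal collection cutoff). Both
constructions are emitted because each captures a different reading of the
interaction geometry (intra-group packing vs pure cross-contacts); the
cost of carrying both is small and ablation is straightforward. Empty atom
groups contribute all-zero blocks at fixed offsets. The category-specific
scheme replaces only the protein-side element tags with the four residue
categories (hydrophobic 9, uncharged 6, negative 2, positive 3 residues);
ligand and metal blocks are recomputed rather than shared with the ES
descriptor — identical by construction, but keeping the two schemes
self-contained.

## Regression head

`ConsensusGradientBoostingRegressor` averages independently seeded
scikit-learn `GradientBoostingRegressor` fits; repetition k uses
`random_state + k`, so the whole model is deterministic given one seed.
The full-scale defaults are 20,000 trees (30,000 for external
transformer-embedding descriptors), depth 7, minimum split 5, learning
rate 0.002, √-feature subsampling, subsample 0.8, 20 repetitions.
Consensus across *models* (ES, CS, external embeddings) is an explicit
element-wise mean (`consensus`), separate from the within-model repetition
average. External protein/ligand sequence embeddings (1280- and 512-dim)
are consumed as ready-made CSV feature columns; no embedding computation
happens in this package.

The reduced preset (200 trees, learning rate 0.05, 2 repetitions) exists
because a 200-tree ensemble at learning rate 0.002 would have total
shrinkage 0.4 and be deliberately underfit; raising the rate makes the
small ensemble a sensible regressor for examples and tests. pK_d labels
convert to kcal/mol by 1.3633 where benchmark comparisons require energies;
metalloprotein-style evaluations keep raw pK_d.

## Synthetic data

`make_c60` constructs the fullerene parametrically: a regular icosahedron
with edge a = 2·single + double is truncated at fraction t = single/a,
placing two atoms on each of the 30 edges. The pentagon edges then have
length t·a = single (adjacent icosahedron edges subtend 60°) and the
hexagon–hexagon edges (1−2t)·a = double, so both bond lengths are exact by
construction, for any parameter pair. Self-checks: 30/60 bond counts,
three neighbors per atom, 12 pentagons and 20 hexagons in the bond graph.
With the default bond lengths the hexagon second-neighbor distance is
2.4426 Å (law of cosines at 120°) and the pentagon diagonal φ·1.453 =
2.3510 Å.

`make_synthetic_pocket` emulates only the *geometry* the featurizer sees:
ligand atoms uniform in a 5 Å ball, protein atoms rejection-sampled in a
shell 1.5–11.5 Å from the ligand (so every generated atom survives the
pocket cutoff), element frequencies roughly biomolecular (C-dominated),
residues uniform over the 20 standard codes, optionally one metal ion
within 15 Å. It has no bonds, no residue geometry and no chemistry, so
tests passing on it validate the descriptor pipeline's combinatorics,
invariances and determinism — not predictive performance on real
complexes. `make_regression_dataset` labels such pockets with a fixed
sparse linear signal on eight standardized high-variance descriptor
columns plus Gaussian noise (σ = 0.5 by default; the generating indices,
weights and σ are returned as metadata), giving a recoverable ground truth
for end-to-end model checks: at σ = 0 the pipeline reaches held-out
Pearson correlation > 0.95 with the reduced preset at n = 200, and
permuted labels stay near 0.

## Problem sizes and limitations

The exact-homology operations are enumeration oracles with hard guards;
production featurization never calls them. Randomized algebraic checks in
the test suite run on complexes of up to 8 vertices and filtrations of 3–6
points (100 of each), where exhaustive subset sums remain cheap; the
barcode oracle uses clouds of up to 12 points. Descriptor extraction on
realistic pockets (tens of atoms per element group) takes tens of
milliseconds per complex. Known limitations: no alpha/Čech complexes, no
sparse Rips approximation for very large groups, no protonation or bond
perception in structure parsing, and the benchmark-scale experiments
(external PDBbind-v2016 and metalloprotein sets, 20×20,000-tree fits) are
an external-data workflow, not shipped computations.
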