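"""Facet barcodes, persistent homology ranks, persistent graded Betti numbers."""

import math

import numpy as np
import pytest

from caml import (
    PointCloud,
    complex_at,
    f_vector,
    facet_barcode,
    facet_persistence_betti,
    facets,
    make_complex_from_facets,
    persistent_f_vector,
    persistent_graded_betti,
    persistent_h_vector,
    persistent_homology_rank,
    reduced_homology_rank,
    restrict,
    rips_filtration,
    summarize_on_grid,
)
from caml.persistence import FacetBarcode

from conftest import random_rips

SQRT2 = math.sqrt(2)


def two_point_filtration(d=2.0, max_dim=2):
    cloud = PointCloud(np.array([[0.0, 0, 0], [d, 0, 0]]), ["C", "C"])
    return rips_filtration(cloud, max_dim=max_dim, cap=3.0)


class TestFacetBarcode:
    def test_two_points(self):
        bc = facet_barcode(two_point_filtration(), up_to_dim=1)
        d0 = bc.by_dimension(0)
        d1 = bc.by_dimension(1)
        assert [(b.birth, b.death) for b in d0] == [(0.0, 2.0), (0.0, 2.0)]
        assert len(d1) == 1 and d1[0].birth == 2.0 and math.isinf(d1[0].death)

    def test_equilateral_edges_never_facets(self, equilateral_cloud):
        # edges and the 2-simplex share the diameter value, so no edge is
        # ever a facet of any snapshot
        filt = rips_filtration(equilateral_cloud, max_dim=3, cap=2.0)
        bc = facet_barcode(filt, up_to_dim=2)
        assert len(bc.by_dimension(0)) == 3
        assert all(b.death == SQRT2 for b in bc.by_dimension(0))
        assert bc.by_dimension(1) == []
        d2 = bc.by_dimension(2)
        assert len(d2) == 1 and d2[0].birth == SQRT2 and math.isinf(d2[0].death)

    def test_c60_barcode(self, c60_filtration):
        bc = facet_barcode(c60_filtration, up_to_dim=2)
        d0 = bc.by_dimension(0)
        assert len(d0) == 60
        assert all(abs(b.death - 1.367) < 1e-3 for b in d0)
        double = [b for b in bc.by_dimension(1) if abs(b.birth - 1.367) < 1e-3]
        single = [b for b in bc.by_dimension(1) if abs(b.birth - 1.453) < 1e-3]
        assert len(double) == 30
        assert all(abs(b.death - 2.443) < 1e-3 for b in double)
        assert len(single) == 60
        # single bonds die on the pentagon diagonal, phi * 1.453
        phi = (1 + math.sqrt(5)) / 2
        assert all(abs(b.death - phi * 1.453) < 1e-3 for b in single)

    def test_cofacet_visibility_required(self):
        filt = two_point_filtration(max_dim=1)
        with pytest.raises(ValueError, match="max_dimension"):
            facet_barcode(filt, up_to_dim=1)

    def test_tsv_export(self, tmp_path):
        bc = facet_barcode(two_point_filtration(), up_to_dim=1)
        path = tmp_path / "bars.tsv"
        bc.write_tsv(path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == ["dimension", "birth", "death", "witness"]
        assert len(lines) == 4 and lines[-1].split("\t")[2] == "inf"


class TestFacetPersistenceBetti:
    def test_c60_values(self, c60_filtration):
        bc = facet_barcode(c60_filtration, up_to_dim=2)
        assert facet_persistence_betti(bc, 1, 1.4, 2.0) == 30
        assert facet_persistence_betti(bc, 0, 1.0, 1.5) == 0

    def test_triangle_two_simplex(self, equilateral_cloud):
        filt = rips_filtration(equilateral_cloud, max_dim=3, cap=2.0)
        bc = facet_barcode(filt, up_to_dim=2)
        assert facet_persistence_betti(bc, 2, SQRT2, SQRT2) == 1

    def test_reversed_interval_rejected(self, c60_filtration):
        bc = facet_barcode(c60_filtration, up_to_dim=1)
        with pytest.raises(ValueError):
            facet_persistence_betti(bc, 0, 2.0, 1.0)

    def test_matches_snapshot_intersection(self):
        """Bars reproduce |P_i(D^r) n P_i(D^r')| from facet enumeration."""
        rng = np.random.default_rng(8)
        for _ in range(5):
            filt = random_rips(rng, 8, max_dim=3)
            bc = facet_barcode(filt, up_to_dim=2)
            grid = np.linspace(0.05, filt.cap, 4)
            for r in grid:
                for rp in grid[grid >= r]:
                    fr = facets(complex_at(filt, r))
                    frp = facets(complex_at(filt, rp))
                    both = fr & frp
                    for i in range(3):
                        expected = sum(1 for f in both if len(f) - 1 == i)
                        assert facet_persistence_betti(bc, i, r, rp) == expected

    def test_monotone_in_r_prime(self, c60_filtration):
        bc = facet_barcode(c60_filtration, up_to_dim=1)
        values = [facet_persistence_betti(bc, 1, 1.5, rp) for rp in (1.5, 2.0, 2.5, 3.0)]
        assert values == sorted(values, reverse=True)


class TestSummary:
    def test_c60_grid_points(self, c60_filtration):
        bc = facet_barcode(c60_filtration, up_to_dim=1)
        s = summarize_on_grid(bc, grid=[1.0])
        assert s.beta[0] == (60,) and s.beta_rate[0] == (60.0,)
        # at r=1.4 only the 30 double-bond edges have been born
        s2 = summarize_on_grid(bc, grid=[1.4])
        assert s2.beta[1] == (30,) and s2.beta_rate[1] == (30 / 1.4,)
        # at r=2.0 all 90 bonds are facets (first triangle closes at 2.351)
        s3 = summarize_on_grid(bc, grid=[2.0])
        assert s3.beta[1] == (90,) and s3.beta_rate[1] == (45.0,)

    def test_empty_barcode(self):
        s = summarize_on_grid(FacetBarcode([], cap=5.0), grid=[1.0, 2.0])
        assert s.beta == {0: (0, 0)}

    def test_nonpositive_grid_rejected(self, c60_filtration):
        bc = facet_barcode(c60_filtration, up_to_dim=1)
        with pytest.raises(ValueError, match="positive"):
            summarize_on_grid(bc, grid=[0.0, 1.0])

    def test_f_rates(self, c60_filtration):
        bc = facet_barcode(c60_filtration, up_to_dim=1)
        f_by_r = {2.0: f_vector(complex_at(c60_filtration, 2.0))}
        s = summarize_on_grid(bc, f_by_r=f_by_r, grid=[2.0])
        assert s.f_rate[0][0] == f_by_r[2.0][0] / 2.0


class TestHomologyRanks:
    @pytest.mark.parametrize(
        "facet_list,p,expected",
        [
            ([(1, 2), (2, 3), (1, 3)], 1, 1),
            ([(1,), (2,)], 0, 1),
            ([(1, 2, 3)], 1, 0),
            ([(1, 2, 3)], 0, 0),
        ],
    )
    def test_reduced_homology(self, facet_list, p, expected):
        assert reduced_homology_rank(make_complex_from_facets(facet_list), p) == expected

    def test_guard(self):
        cx = make_complex_from_facets([tuple(range(17))])
        with pytest.raises(ValueError, match="guard"):
            reduced_homology_rank(cx, 0)

    def test_merging_component_dies(self):
        filt = two_point_filtration(d=1.0)
        assert persistent_homology_rank(filt, 0, 0.5, 1.5) == 0
        assert persistent_homology_rank(filt, 0, 0.5, 0.5) == 1

    def test_square_cycle_persists(self):
        sq = PointCloud(np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float), ["C"] * 4)
        filt = rips_filtration(sq, max_dim=2, cap=1.3)
        assert persistent_homology_rank(filt, 1, 1.0, 1.2) == 1


class TestGradedBetti:
    def test_two_isolated_points(self):
        filt = two_point_filtration(d=9.0)  # edge beyond cap: never born
        assert persistent_graded_betti(filt, 1, 1, 0.5, 0.5) == 1

    def test_hollow_triangle_static(self, equilateral_cloud):
        # max_dim=1 keeps the 2-simplex out: the snapshot is the hollow triangle
        filt = rips_filtration(equilateral_cloud, max_dim=1, cap=2.0)
        assert persistent_graded_betti(filt, 1, 2, 1.5, 1.5) == 1
        assert persistent_graded_betti(filt, 1, 1, 1.5, 1.5) == 0

    def test_merging_map_has_rank_zero(self):
        filt = two_point_filtration(d=1.0)
        assert persistent_graded_betti(filt, 1, 1, 0.5, 1.5) == 0

    def test_hochster_at_equal_scales(self):
        """Persistent graded Betti at r=r' equals the classical Hochster sums."""
        from itertools import combinations

        rng = np.random.default_rng(9)
        for _ in range(5):
            filt = random_rips(rng, 5, max_dim=3)
            r = float(rng.uniform(0.2, filt.cap))
            n = len(filt.vertices)
            for total in range(2, n + 1):
                for i in range(1, total):
                    j = total - i
                    expected = 0
                    for w in combinations(filt.vertices, total):
                        cx_w = complex_at(restrict(filt, w), r)
                        if j == 1:
                            b0 = reduced_homology_rank(cx_w, 0) + 1
                            expected += b0 - 1
                        else:
                            expected += reduced_homology_rank(cx_w, j - 1)
                    assert persistent_graded_betti(filt, i, j, r, r) == expected

    def test_boundary_relation_full_vertex_set(self):
        """beta_{i,|V|}^{r,r'} equals the persistent rank in dimension |V|-i-1."""
        rng = np.random.default_rng(10)
        for _ in range(5):
            filt = random_rips(rng, 5, max_dim=4)
            n = len(filt.vertices)
            r = float(rng.uniform(0.3, filt.cap))
            rp = float(rng.uniform(r, filt.cap))
            for i in range(1, n):
                assert persistent_graded_betti(filt, i, n - i, r, rp) == (
                    persistent_homology_rank(filt, n - i - 1, r, rp)
                )


class TestPersistentHF:
    def test_hollow_triangle(self, equilateral_cloud):
        filt = rips_filtration(equilateral_cloud, max_dim=1, cap=2.0)
        assert persistent_h_vector(filt, 1.5, 1.5) == (1, 1, 1)
        assert persistent_f_vector(filt, 1.5, 1.5) == (3, 3)

    def test_full_simplex(self, equilateral_cloud):
        filt = rips_filtration(equilateral_cloud, max_dim=3, cap=2.0)
        assert persistent_h_vector(filt, 1.5, 1.5) == (1, 0, 0, 0)
        assert persistent_f_vector(filt, 1.5, 1.5) == (3, 3, 1)

    def test_isolated_points(self):
        cloud = PointCloud(np.array([[0, 0, 0], [9, 0, 0], [0, 9, 0]], float), ["C"] * 3)
        filt = rips_filtration(cloud, max_dim=2, cap=3.0)
        assert persistent_h_vector(filt, 0.5, 0.5) == (1, 2)
        assert persistent_f_vector(filt, 0.5, 0.5) == (3,)

    def test_two_points_before_edge(self):
        filt = two_point_filtration(d=1.0)
        assert persistent_f_vector(filt, 0.5, 0.5) == (2,)

    def test_coincides_with_classical_f(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            filt = random_rips(rng, 6, max_dim=3)
            for r in np.linspace(0.2, filt.cap, 3):
                assert persistent_f_vector(filt, r, r) == f_vector(complex_at(filt, r))
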