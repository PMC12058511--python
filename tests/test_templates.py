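"""Tessellation generator, simple-template derivation, and outline projection."""

import networkx as nx
import numpy as np
import pytest

from lecmech import (
    PuzzleParams,
    derive_simple_tessellation,
    generate_puzzle_tessellation,
    project_outlines_to_cylinder,
)
from lecmech.curves import signed_curvature_ring, smooth_ring
from lecmech.templates import (
    TessellationError,
    boundary_total_curvature,
    cells_per_circumference,
)


class TestPuzzleGenerator:
    def test_partition_invariants(self, puzzle_default, default_domain):
        # disjoint interiors + full coverage -> area conservation within 0.5%
        total = puzzle_default.total_area
        assert total == pytest.approx(default_domain.lateral_area, rel=5e-3)
        assert nx.is_connected(puzzle_default.adjacency)

    def test_interior_junctions_are_tricellular(self, puzzle_default):
        degs = puzzle_default.interior_junction_degrees
        assert len(degs) > 0
        assert np.all(degs == 3)
        assert len(puzzle_default.tricellular_points) == len(degs)

    def test_deterministic_for_fixed_seed(self, default_domain):
        params = PuzzleParams(rng_seed=7)
        a = generate_puzzle_tessellation(default_domain, params)
        b = generate_puzzle_tessellation(default_domain, params)
        assert all(np.array_equal(x, y) for x, y in zip(a.cells, b.cells))

    def test_lobed_boundaries_have_both_curvature_signs(self, puzzle_default):
        for ring in puzzle_default.cells:
            kappa = signed_curvature_ring(smooth_ring(ring, 1.0))
            assert (kappa > 1e-4).any() and (kappa < -1e-4).any()

    def test_amplitude_zero_is_simple(self, default_domain):
        tess = generate_puzzle_tessellation(
            default_domain, PuzzleParams(lobe_amplitude=0.0, rng_seed=0)
        )
        # straight-edged: total turning equals the lobed template's floor
        lobed = generate_puzzle_tessellation(
            default_domain, PuzzleParams(rng_seed=0)
        )
        assert boundary_total_curvature(tess) < 0.25 * boundary_total_curvature(
            lobed
        )
        # fixed point of straightening (up to vertex resampling)
        simple = derive_simple_tessellation(tess)
        assert np.allclose(np.sort(simple.areas), np.sort(tess.areas), rtol=1e-6)
        assert np.allclose(
            np.sort(simple.perimeters), np.sort(tess.perimeters), rtol=1e-6
        )

    def test_infeasible_packing_raises(self, default_domain):
        with pytest.raises(TessellationError, match="packing"):
            generate_puzzle_tessellation(
                default_domain, PuzzleParams(n_cells=2)
            )
        with pytest.raises(TessellationError):
            generate_puzzle_tessellation(
                default_domain, PuzzleParams(n_cells=3000)
            )

    def test_excessive_amplitude_raises_with_diagnostic(self, default_domain):
        with pytest.raises(TessellationError, match="amplitude"):
            generate_puzzle_tessellation(
                default_domain,
                PuzzleParams(lobe_amplitude=25.0, lobe_wavelength=8.0),
            )

    def test_three_cells_per_circumference(self, default_domain):
        vals = [
            cells_per_circumference(
                generate_puzzle_tessellation(
                    default_domain, PuzzleParams(rng_seed=s)
                )
            )
            for s in range(3)
        ]
        assert 2.5 <= np.mean(vals) <= 3.5


class TestSimpleDerivation:
    def test_adjacency_preserved_exactly(self, puzzle_default):
        simple = derive_simple_tessellation(puzzle_default)
        assert simple.n_cells == puzzle_default.n_cells
        assert set(map(frozenset, simple.adjacency.edges)) == set(
            map(frozenset, puzzle_default.adjacency.edges)
        )

    def test_perimeters_do_not_increase(self, puzzle_default):
        simple = derive_simple_tessellation(puzzle_default)
        assert np.all(simple.perimeters <= puzzle_default.perimeters + 1e-9)

    def test_total_area_conserved(self, puzzle_default, default_domain):
        simple = derive_simple_tessellation(puzzle_default)
        assert simple.total_area == pytest.approx(
            default_domain.lateral_area, rel=5e-3
        )

    def test_straight_segments_between_junctions(self, puzzle_default):
        simple = derive_simple_tessellation(puzzle_default)
        for b in simple.borders:
            assert len(b.coords) == 2


class TestProjection:
    def _rect_tiling(self, domain, nx_=3, nz_=4):
        P, L = domain.circumference, domain.axial_length
        outs = []
        for i in range(nx_):
            for j in range(nz_):
                x0, x1 = i * P / nx_, (i + 1) * P / nx_
                z0, z1 = j * L / nz_, (j + 1) * L / nz_
                outs.append(
                    np.array([[x0, z0], [x1, z0], [x1, z1], [x0, z1]])
                )
        return outs

    def test_identity_projection_preserves_areas(self, default_domain):
        outs = self._rect_tiling(default_domain)
        tess = project_outlines_to_cylinder(outs, default_domain, 0)
        expected = default_domain.lateral_area / len(outs)
        assert np.allclose(tess.areas, expected)

    def test_smoothing_reduces_total_curvature_monotonically(
        self, puzzle_default, default_domain
    ):
        cells = list(puzzle_default.cells)
        prev = np.inf
        for k in (0, 1, 3, 6):
            tess = project_outlines_to_cylinder(cells, default_domain, k)
            cur = boundary_total_curvature(tess)
            assert cur <= prev + 1e-9
            prev = cur

    def test_gap_raises_listing_cells(self, default_domain):
        outs = self._rect_tiling(default_domain)
        P, L = default_domain.circumference, default_domain.axial_length
        outs[0] = np.array([[2.0, 2.0], [P / 3, 0], [P / 3, L / 4], [0, L / 4]])
        with pytest.raises(TessellationError, match="gap"):
            project_outlines_to_cylinder(outs, default_domain, 0)
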