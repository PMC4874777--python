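"""Boundary extraction, coordinate systems, normalization, profiles."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from tauseq import geometry as geo
from tauseq import synthetic as syn


def chord_curve(profile: geo.DensityProfile) -> np.ndarray:
    """Analytic Y-density of a uniform cylinder with the |Z|<=0.5 slab."""
    y = profile.centers
    c = np.minimum(0.5, np.sqrt(np.clip(1 - y**2, 0.0, None)))
    return c / (c * np.diff(profile.edges)).sum()


class TestBoundaryExtraction:
    def test_recovers_synthetic_outline(self, straight_cell):
        img, px, origin = syn.phase_image(straight_cell)
        b = geo.extract_boundary(img, pixel_um=px)
        truth = Polygon(straight_cell.boundary).exterior
        verts = b.vertices + origin
        import shapely

        d_fwd = shapely.distance(truth, shapely.points(verts)).max()
        extr = Polygon(verts).exterior
        d_rev = shapely.distance(
            extr, shapely.points(straight_cell.boundary)
        ).max()
        assert max(d_fwd, d_rev) < 0.5 * px

    def test_constant_image_errors(self):
        with pytest.raises(ValueError):
            geo.extract_boundary(np.ones((60, 60)))

    def test_contrast_inversion_symmetric(self, straight_cell):
        img, px, _ = syn.phase_image(straight_cell)
        b1 = geo.extract_boundary(img, pixel_um=px)
        b2 = geo.extract_boundary(-img, pixel_um=px, invert=True)
        assert np.allclose(b1.vertices, b2.vertices)


class TestCoordinateSystem:
    def test_poles_and_length_on_straight_cell(self, straight_cell, straight_cs):
        cs = straight_cs
        true_poles = np.array([[1.5, 0.0], [-1.5, 0.0]])
        err = min(
            np.linalg.norm(cs.poles - true_poles, axis=1).max(),
            np.linalg.norm(cs.poles - true_poles[::-1], axis=1).max(),
        )
        assert err < 0.02 * straight_cell.length
        assert cs.length == pytest.approx(3.0, rel=0.02)
        assert len(cs.centerline) == 101
        assert cs.n_ribs == 100

    def test_equal_arc_sides(self, straight_cs):
        for side in (straight_cs.side1, straight_cs.side2):
            seg = np.linalg.norm(np.diff(side, axis=0), axis=1)
            assert seg.std() / seg.mean() < 0.05

    def test_circle_is_degenerate(self):
        th = np.linspace(0, 2 * math.pi, 200, endpoint=False)
        b = geo.CellBoundary(np.column_stack([np.cos(th), np.sin(th)]))
        with pytest.raises(ValueError, match="degenerate"):
            geo.build_coordinate_system(b)

    def test_bent_cell_centerline_curvature(self):
        spec = syn.CellSimSpec(
            length_um=(3.0, 0.0), width_um=(1.0, 0.0), bend_curvature=0.25,
            n_cells=1, seed=2,
        )
        cell = syn.simulate_cells(spec)[0]
        cs = geo.build_coordinate_system(geo.CellBoundary(cell.boundary))
        cl = cs.centerline[25:76]        # central half, away from caps
        A = np.column_stack([cl[:, 0], cl[:, 1], np.ones(len(cl))])
        sol, *_ = np.linalg.lstsq(A, (cl**2).sum(axis=1), rcond=None)
        cx, cy = sol[0] / 2, sol[1] / 2
        R = math.sqrt(sol[2] + cx * cx + cy * cy)
        assert 1.0 / R == pytest.approx(0.25, rel=0.10)

    def test_few_vertices_rejected(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        with pytest.raises(ValueError):
            geo.build_coordinate_system(geo.CellBoundary(sq))


class TestQC:
    def _cs(self, L1, L2, area):
        base = geo.coordinate_system_from_ground_truth(
            np.column_stack([np.linspace(0, 3, 50), np.zeros(50)]),
            np.full(50, 0.5),
        )
        return geo.CellCoordinateSystem(
            side1=base.side1, side2=base.side2, centerline=base.centerline,
            half_widths=base.half_widths, L1=L1, L2=L2, area=area,
        )

    def test_area_threshold(self):
        ok, reason = geo.qc_filter_cell(self._cs(3.0, 3.0, 3.5))
        assert not ok and "area" in reason
        ok, _ = geo.qc_filter_cell(self._cs(3.0, 3.0, 3.0))
        assert ok  # boundary equality passes

    def test_asymmetry_threshold(self):
        ok, reason = geo.qc_filter_cell(self._cs(1.0, 1.3, 2.0))
        assert not ok and "asymmetry" in reason
        ok, _ = geo.qc_filter_cell(self._cs(1.0, 1.2, 2.0))
        assert ok

    def test_symmetric_small_cell_passes(self):
        ok, reason = geo.qc_filter_cell(self._cs(2.0, 2.0, 2.0))
        assert ok and reason == "ok"


class TestNormalization:
    def test_centerline_point_maps_to_zero_y(self, straight_cs):
        locs = np.array([[0.0, 0.0, 0.0]]) * 1000.0
        out = geo.normalize_localizations(straight_cs, locs)
        assert abs(out.Y[0]) < 1e-6

    def test_boundary_point_at_midcell(self, straight_cs):
        locs = np.array([[0.0, 0.5, 0.0], [0.0, -0.5, 0.0]]) * 1000.0
        out = geo.normalize_localizations(straight_cs, locs)
        assert np.allclose(np.abs(out.Y), 1.0, atol=0.01)
        assert np.sign(out.Y[0]) != np.sign(out.Y[1])

    def test_pole_tip_maps_to_x_extreme(self, straight_cs):
        locs = np.array([[1.5, 0.0, 0.0], [-1.5, 0.0, 0.0]]) * 1000.0
        out = geo.normalize_localizations(straight_cs, locs)
        assert set(np.round(out.X, 2)) <= {0.0, 1.0}

    def test_z_scaled_by_local_radius(self, straight_cs):
        locs = np.array([[0.0, 0.0, 0.25]]) * 1000.0
        out = geo.normalize_localizations(straight_cs, locs)
        assert out.Z[0] == pytest.approx(0.5, abs=0.01)

    def test_outlier_flagging(self, straight_cs):
        locs = np.array([[0.0, 0.55, 0.0], [0.0, 0.7, 0.0]]) * 1000.0
        out = geo.normalize_localizations(straight_cs, locs)
        assert not out.outlier[0] and out.outlier[1]

    def test_roundtrip_of_planted_points(self, straight_cell, straight_cs):
        # plant points at known normalized coordinates away from the poles,
        # convert to physical, and recover through the full pipeline
        rng = np.random.default_rng(6)
        Xn = rng.uniform(0.25, 0.75, 200)
        Yn = rng.uniform(-0.9, 0.9, 200)
        Zn = rng.uniform(-0.9, 0.9, 200)
        x = (Xn - 0.5) * 3.0
        y = Yn * 0.5
        z = Zn * 0.5
        locs = np.column_stack([x, y, z]) * 1000.0
        out = geo.normalize_localizations(straight_cs, locs)
        # pole ordering (X direction) and in-plane handedness (Y sign) are
        # a per-cell convention; compare up to the global flip
        x_err = min(
            np.abs(out.X - Xn).max(), np.abs(out.X - (1 - Xn)).max()
        )
        y_err = min(
            np.abs(out.Y - Yn).max(), np.abs(out.Y + Yn).max()
        )
        assert x_err < 0.03
        assert y_err < 0.03
        assert np.abs(out.Z - Zn).max() < 0.03


@pytest.fixture(scope="module")
def uniform_norm(straight_cell, straight_cs):
    pat = syn.LocalizationPattern("uniform_volume", 100_000, 0.0, 3)
    locs = syn.simulate_localizations(straight_cell, pat)
    return geo.normalize_localizations(straight_cs, locs)


class TestProfiles:
    def test_uniform_profile_matches_chord_curve(self, uniform_norm):
        prof = geo.density_profile(uniform_norm)
        assert np.abs(prof.density - chord_curve(prof)).max() < 0.05

    def test_membrane_shell_selected_y_above_threshold(self, straight_cell,
                                                       straight_cs):
        pat = syn.LocalizationPattern("membrane_shell", 20_000, 0.0, 4)
        locs = syn.simulate_localizations(straight_cell, pat)
        out = geo.normalize_localizations(straight_cs, locs)
        sel = out[(out.Z.abs() <= 0.5) & (out.X.between(0.1, 0.9))]
        assert len(sel) > 0
        assert sel.Y.abs().min() >= math.sqrt(1 - 0.25) - 5e-3

    def test_empty_profile_warns(self, straight_cs):
        empty = pd.DataFrame({"X": [], "Y": [], "Z": []})
        with pytest.warns(UserWarning):
            prof = geo.density_profile(empty)
        assert prof.n_selected == 0

    def test_profile_counts_are_selection(self, uniform_norm):
        prof = geo.density_profile(uniform_norm, normalize=False)
        sel = uniform_norm[
            (uniform_norm.Z.abs() <= 0.5) & (uniform_norm.X.between(0.1, 0.9))
        ]
        in_range = sel[sel.Y.abs() <= 1.0]
        assert prof.counts.sum() == len(in_range)


class TestCrossSection:
    def test_symmetry(self, straight_cell, straight_cs):
        pat = syn.LocalizationPattern("uniform_volume", 40_000, 0.0, 7)
        locs = syn.simulate_localizations(straight_cell, pat)
        norm = geo.normalize_localizations(straight_cs, locs)
        H, _, _ = geo.average_cross_section(norm, axis="short", n_bins=20)
        flipped = H[::-1, :]
        diff = np.abs(H - flipped)
        assert diff.mean() < 3 * math.sqrt(H.mean() + 1)

    def test_counts_conserved(self, straight_cs, straight_cell):
        pat = syn.LocalizationPattern("uniform_volume", 5000, 0.0, 9)
        locs = syn.simulate_localizations(straight_cell, pat)
        norm = geo.normalize_localizations(straight_cs, locs)
        H, _, _ = geo.average_cross_section(
            norm, axis="long", x_window=(0.1, 0.9), n_bins=25
        )
        sel = norm[(norm.X >= 0.1) & (norm.X <= 0.9) & (norm.Y.abs() <= 1.2)]
        assert H.sum() == len(sel)

    def test_empty_selection_zero_image(self, straight_cs):
        df = pd.DataFrame({"X": [0.5], "Y": [0.0], "Z": [0.9]})
        H, _, _ = geo.average_cross_section(
            df, axis="short", slice_halfwidth=0.1, slice_coord="Z"
        )
        assert H.sum() == 0


class TestMEI:
    def test_flat_profile_unity(self):
        edges = np.linspace(-1, 1, 41)
        flat = geo.DensityProfile(
            edges=edges, counts=np.full(40, 10), density=np.full(40, 0.5),
            n_selected=400, z_halfwidth=0.5, x_window=(0.1, 0.9),
        )
        assert geo.membrane_enrichment_index(flat) == pytest.approx(1.0)

    def test_membrane_shell_infinite(self, straight_cell, straight_cs):
        pat = syn.LocalizationPattern("membrane_shell", 10_000, 0.0, 5)
        locs = syn.simulate_localizations(straight_cell, pat)
        norm = geo.normalize_localizations(straight_cs, locs)
        prof = geo.density_profile(norm)
        assert math.isinf(geo.membrane_enrichment_index(prof))

    def test_uniform_matches_analytic_and_stable_across_seeds(
        self, straight_cell, straight_cs
    ):
        meis = []
        for seed in (11, 12, 13):
            pat = syn.LocalizationPattern("uniform_volume", 250_000, 0.0, seed)
            locs = syn.simulate_localizations(straight_cell, pat)
            prof = geo.density_profile(
                geo.normalize_localizations(straight_cs, locs)
            )
            meis.append(geo.membrane_enrichment_index(prof))
        # analytic value from the chord curve on the same binning
        prof0 = geo.density_profile(
            geo.normalize_localizations(
                straight_cs,
                syn.simulate_localizations(
                    straight_cell,
                    syn.LocalizationPattern("uniform_volume", 250_000, 0.0, 14),
                ),
            )
        )
        analytic = geo.DensityProfile(
            edges=prof0.edges, counts=prof0.counts,
            density=chord_curve(prof0), n_selected=prof0.n_selected,
            z_halfwidth=0.5, x_window=(0.1, 0.9),
        )
        target = geo.membrane_enrichment_index(analytic)
        for m in meis:
            assert m == pytest.approx(target, abs=0.05)
        assert (max(meis) - min(meis)) / np.mean(meis) < 0.02
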