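"""Quantification operators: overlaps, linearity, classification, lobes, MT."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lecmech.metrics import (
    UNCLASSIFIABLE,
    CellMaskPair,
    ClassifierThresholds,
    JunctionProfile,
    OutlineCurve,
    classify_junction,
    count_lobes,
    junction_linearity_index,
    measure_overlap,
    mt_anchoring,
    tabulate_junction_frequencies,
)

PX = 0.1


def _rect_pair(overlap_um=3.0, height_um=10.0):
    H, W = int(height_um / PX), int(37 / PX)
    a = np.zeros((H, W), bool)
    b = np.zeros((H, W), bool)
    a[:, : int(20 / PX)] = True
    b[:, int((20 - overlap_um) / PX) :] = True
    return CellMaskPair(a, b, PX)


class TestMeasureOverlap:
    def test_rectangular_strip(self):
        m = measure_overlap(_rect_pair())
        assert m.area == pytest.approx(30.0, abs=0.2)
        assert m.mean_width == pytest.approx(3.0, abs=PX)

    def test_disjoint_masks_flagged(self):
        a = np.zeros((50, 50), bool)
        b = np.zeros((50, 50), bool)
        a[:, :20] = True
        b[:, 30:] = True
        m = measure_overlap(CellMaskPair(a, b, PX))
        assert m.disjoint and m.area == 0.0 and not m.width_defined
        assert np.isnan(m.mean_width)

    def test_symmetric_in_mask_order(self):
        p = _rect_pair(2.4)
        m1 = measure_overlap(p)
        m2 = measure_overlap(CellMaskPair(p.mask_b, p.mask_a, PX))
        assert m1.area == m2.area
        assert m1.mean_width == pytest.approx(m2.mean_width, abs=1e-9)

    def test_rotation_by_90_degrees(self):
        p = _rect_pair(2.7)
        m1 = measure_overlap(p)
        m2 = measure_overlap(
            CellMaskPair(np.rot90(p.mask_a), np.rot90(p.mask_b), PX)
        )
        assert m2.area == m1.area
        assert m2.mean_width == pytest.approx(m1.mean_width, abs=PX)

    def test_width_cap_excludes_samples(self):
        m = measure_overlap(_rect_pair(5.0, height_um=30.0), width_cap=4.0)
        assert not m.width_defined  # every sample exceeds the cap
        assert m.n_capped > 0
        m2 = measure_overlap(_rect_pair(3.0, height_um=30.0), width_cap=4.0)
        assert m2.width_defined and m2.n_capped == 0


class TestLinearityIndex:
    def test_straight_segment(self):
        assert junction_linearity_index(np.array([[0, 0], [7.3, 0]])) == 1.0

    def test_semicircle(self):
        th = np.linspace(0, np.pi, 400)
        arc = np.column_stack([np.cos(th), np.sin(th)])
        assert junction_linearity_index(arc) == pytest.approx(
            np.pi / 2, rel=1e-4
        )

    def test_sine_path_matches_dense_arclength_oracle(self):
        x = np.linspace(0, 10, 200)
        path = np.column_stack([x, np.sin(x)])
        xd = np.linspace(0, 10, 20000)
        dense = np.column_stack([xd, np.sin(xd)])
        arc = np.linalg.norm(np.diff(dense, axis=0), axis=1).sum()
        oracle = arc / np.linalg.norm(dense[-1] - dense[0])
        assert junction_linearity_index(path) == pytest.approx(
            oracle, rel=1e-3
        )

    def test_closed_loop_raises(self):
        th = np.linspace(0, 2 * np.pi, 50)
        loop = np.column_stack([np.cos(th), np.sin(th)])
        with pytest.raises(ValueError, match="chord"):
            junction_linearity_index(loop)

    @given(
        angle=st.floats(0, 2 * np.pi),
        scale=st.floats(0.1, 50),
        dx=st.floats(-100, 100),
    )
    def test_invariant_under_rigid_motion_and_scaling(self, angle, scale, dx):
        x = np.linspace(0, 5, 60)
        path = np.column_stack([x, np.sin(1.3 * x)])
        R = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        moved = scale * path @ R.T + np.array([dx, -2.0])
        assert junction_linearity_index(moved) == pytest.approx(
            junction_linearity_index(path), rel=1e-9
        )


class TestClassifier:
    CASES = [
        (JunctionProfile((0.9, 0.9), 0.8, True), "double"),
        (JunctionProfile((0.0, 0.0), 0.7, True), "button"),
        (JunctionProfile((0.9, 0.9), 0.0, False, 0.95), "zipper"),
        (JunctionProfile((0.7, 0.05), 0.0, False, 0.4), "lyve1neg_curvilinear"),
        (JunctionProfile((0.7, 0.05), 0.8, True), "curvilinear"),
        (JunctionProfile((0.05, 0.05), 2.5, True), UNCLASSIFIABLE),
        (JunctionProfile((0.05, 0.05), 0.0, False, 0.2), UNCLASSIFIABLE),
    ]

    @pytest.mark.parametrize("profile,expected", CASES)
    def test_rule_table(self, profile, expected):
        call = classify_junction(profile)
        assert call.label == expected
        assert call.rule_trace  # trace always recorded

    @given(
        c1=st.floats(0, 1),
        c2=st.floats(0, 1),
        neck=st.floats(0, 5),
        lobe=st.booleans(),
        whole=st.floats(0, 1),
    )
    def test_total_deterministic_function(self, c1, c2, neck, lobe, whole):
        p = JunctionProfile((c1, c2), neck, lobe, whole)
        a = classify_junction(p)
        b = classify_junction(p)
        assert a.label == b.label
        assert a.label in (
            "button",
            "curvilinear",
            "double",
            "lyve1neg_curvilinear",
            "zipper",
            UNCLASSIFIABLE,
        )

    def test_thresholds_are_configurable(self):
        p = JunctionProfile((0.2, 0.2), 0.8, True)
        strict = classify_junction(p, ClassifierThresholds(border_min=0.15))
        assert strict.label == "double"
        assert classify_junction(p).label == "button"


class TestTabulation:
    def test_percentages(self):
        labels = ["button"] * 2 + ["double"] * 8
        tab = tabulate_junction_frequencies(labels)
        assert tab.loc["pooled", "button"] == pytest.approx(20.0)
        assert tab.loc["pooled", "double"] == pytest.approx(80.0)

    def test_single_label_is_point_mass(self):
        tab = tabulate_junction_frequencies(["zipper"] * 5)
        assert tab.loc["pooled", "zipper"] == 100.0
        assert tab.loc["pooled", "button"] == 0.0

    def test_unclassifiable_reported_separately(self):
        labels = ["button"] * 4 + [UNCLASSIFIABLE]
        tab = tabulate_junction_frequencies(labels)
        assert tab.loc["pooled", "button"] == 100.0
        assert tab.loc["pooled", "n_unclassifiable"] == 1

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        labels = list(
            rng.choice(["button", "double", "zipper"], size=60, p=[0.2, 0.5, 0.3])
        )
        t1 = tabulate_junction_frequencies(labels)
        rng.shuffle(labels)
        t2 = tabulate_junction_frequencies(labels)
        assert t1.loc["pooled"].equals(t2.loc["pooled"])

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            tabulate_junction_frequencies([])

    def test_grouped_weighted_mean(self):
        labels = ["button"] * 2 + ["double"] * 2 + ["double"] * 4
        groups = ["m1"] * 4 + ["m2"] * 4
        tab = tabulate_junction_frequencies(labels, groups)
        assert tab.loc["m1", "button"] == pytest.approx(50.0)
        assert tab.loc["group_mean", "button"] == pytest.approx(25.0)


class TestLobeCounting:
    def test_circle_has_no_lobes(self):
        th = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        circle = 10 * np.column_stack([np.cos(th), np.sin(th)])
        assert count_lobes(circle) == 0

    def test_ellipse_has_no_lobes(self):
        th = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        ell = np.column_stack([10 * np.cos(th), 5 * np.sin(th)])
        assert count_lobes(ell) == 0

    def test_rosette_matches_analytic_curvature_oracle(self, rosette):
        # oracle: sign changes of the analytic curvature of r=R(1+a sin 5θ)
        th = np.linspace(0, 2 * np.pi, 20000, endpoint=False)
        R, a, k = 10.0, 0.3, 5
        r = R * (1 + a * np.sin(k * th))
        rp = R * a * k * np.cos(k * th)
        rpp = -R * a * k * k * np.sin(k * th)
        kappa = (r * r + 2 * rp * rp - r * rpp) / (r * r + rp * rp) ** 1.5
        n_convex_arcs = int(np.sum(np.diff((kappa > 0).astype(int)) == 1))
        assert n_convex_arcs == 5
        assert count_lobes(rosette) == 5

    def test_monotone_in_amplitude_threshold(self, rosette):
        counts = [count_lobes(rosette, amplitude_min=a) for a in (0.5, 2, 5, 20)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_rigid_motion_invariance(self, rosette):
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        assert count_lobes(rosette @ R.T + 40.0) == count_lobes(rosette)

    def test_self_intersecting_raises(self):
        bow = np.array([[0, 0], [2, 2], [2, 0], [0, 2.0]])
        with pytest.raises(ValueError, match="self-intersect"):
            count_lobes(bow)


class TestMtAnchoring:
    def test_all_endpoints_concave(self, rosette):
        oc = OutlineCurve(rosette)
        ring, kappa, _ = oc.curvature_samples()
        pts = ring[kappa < 0][:20]
        r = mt_anchoring(oc, pts)
        assert r.fraction_concave == 1.0 and r.fraction_convex == 0.0

    def test_density_is_count_over_arclength(self, rosette):
        oc = OutlineCurve(rosette)
        ring, kappa, _ = oc.curvature_samples()
        pts = ring[kappa < 0][:10]
        r = mt_anchoring(oc, pts)
        assert r.density_concave == pytest.approx(10 / r.arc_concave)

    def test_far_endpoints_rejected(self, rosette):
        oc = OutlineCurve(rosette)
        ring, kappa, _ = oc.curvature_samples()
        pts = np.vstack([ring[kappa < 0][:5], [[200.0, 200.0]]])
        r = mt_anchoring(oc, pts, capture_distance=2.0)
        assert r.n_rejected == 1 and r.n_assigned == 5

    def test_fractions_sum_to_one(self, rosette):
        oc = OutlineCurve(rosette)
        ring, _, _ = oc.curvature_samples()
        r = mt_anchoring(oc, ring[::7])
        assert r.fraction_concave + r.fraction_convex == pytest.approx(1.0)
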