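"""Synthetic-data generators: reproducibility and generator–estimator loops."""

import numpy as np
import pytest

from lecmech.metrics import classify_junction, count_lobes, measure_overlap, mt_anchoring
from lecmech.synth import (
    DEFAULT_FRAC_CONCAVE,
    JunctionMixConfig,
    OverlapGenConfig,
    gen_junction_dataset,
    gen_lobed_outlines,
    gen_mt_endpoints,
    gen_overlap_pairs,
)


class TestOverlapGenerator:
    def test_deterministic_per_seed(self):
        cfg = OverlapGenConfig(n=3, rng_seed=11)
        p1, t1 = gen_overlap_pairs(cfg)
        p2, t2 = gen_overlap_pairs(cfg)
        assert all(
            np.array_equal(a.mask_a, b.mask_a)
            and np.array_equal(a.mask_b, b.mask_b)
            for a, b in zip(p1, p2)
        )
        assert t1.equals(t2)

    def test_zero_sd_gives_equal_widths(self):
        cfg = OverlapGenConfig(
            n=4, width_mean=2.0, width_sd=0.0, area_mean=80.0, area_sd=0.0
        )
        pairs, truth = gen_overlap_pairs(cfg)
        widths = [measure_overlap(p).mean_width for p in pairs]
        assert np.all(np.abs(np.diff(widths)) <= cfg.pixel_size)
        assert np.allclose(truth.width_true, 2.0)

    def test_generator_estimator_loop_control(self):
        # measured means must track the realized ground truth within 3 s.e.m.
        cfg = OverlapGenConfig.preset("control", rng_seed=3)
        pairs, truth = gen_overlap_pairs(cfg)
        meas_w = np.array([measure_overlap(p).mean_width for p in pairs])
        meas_a = np.array([measure_overlap(p).area for p in pairs])
        sem_w = cfg.width_sd / np.sqrt(cfg.n)
        assert abs(np.nanmean(meas_w) - truth.width_true.mean()) < 3 * sem_w
        assert abs(np.mean(meas_a) - truth.area_true.mean()) < 0.05 * truth.area_true.mean()

    def test_unknown_preset_raises(self):
        with pytest.raises(ValueError, match="preset"):
            OverlapGenConfig.preset("nope")

    def test_preset_parameters(self):
        c = OverlapGenConfig.preset("fluid_injected")
        assert (c.width_mean, c.width_sd) == (1.7, 0.7)
        assert (c.area_mean, c.area_sd) == (83.4, 52.0)
        assert c.n == 35
        t = OverlapGenConfig.preset("tem")
        assert (t.width_mean, t.width_sd, t.n) == (1.8, 0.9, 34)
        assert t.area_mean is None


class TestJunctionGenerator:
    def test_zero_noise_classifies_perfectly(self):
        profiles, labels = gen_junction_dataset(
            JunctionMixConfig(noise=0.0, n=400, rng_seed=2)
        )
        calls = [classify_junction(p).label for p in profiles]
        assert calls == labels

    def test_single_category_point_mass(self):
        mix = {k: 0.0 for k in JunctionMixConfig().proportions}
        mix["zipper"] = 1.0
        profiles, labels = gen_junction_dataset(
            JunctionMixConfig(proportions=mix, n=50, rng_seed=0)
        )
        assert set(labels) == {"zipper"}

    def test_deterministic(self):
        cfg = JunctionMixConfig(n=100, rng_seed=9)
        p1, l1 = gen_junction_dataset(cfg)
        p2, l2 = gen_junction_dataset(cfg)
        assert l1 == l2 and p1 == p2

    def test_bad_proportions_raise(self):
        bad = dict(JunctionMixConfig().proportions)
        bad["button"] = 0.5
        with pytest.raises(ValueError, match="sum to 1"):
            JunctionMixConfig(proportions=bad)


class TestLobedOutlines:
    def test_truth_counts_recovered_exactly(self):
        outlines, truth = gen_lobed_outlines(15, (0, 3, 5, 7), seed=4)
        assert [count_lobes(o) for o in outlines] == truth

    def test_reproducible(self):
        o1, t1 = gen_lobed_outlines(5, (0, 5), seed=1)
        o2, t2 = gen_lobed_outlines(5, (0, 5), seed=1)
        assert t1 == t2
        assert all(np.array_equal(a.points, b.points) for a, b in zip(o1, o2))

    def test_k_one_rejected(self):
        with pytest.raises(ValueError):
            gen_lobed_outlines(3, (1,), seed=0)


class TestMtEndpoints:
    def test_fraction_one_all_concave(self, rosette):
        pts, classes = gen_mt_endpoints(rosette, 1.0, 40, seed=0)
        assert set(classes) == {"concave"}
        r = mt_anchoring(rosette, pts)
        assert r.fraction_concave > 0.9  # jitter can flip a boundary point

    def test_recovery_within_three_sem(self, rosette):
        frac = 0.75
        n = 500
        pts, _ = gen_mt_endpoints(rosette, frac, n, seed=3)
        r = mt_anchoring(rosette, pts)
        sem = np.sqrt(frac * (1 - frac) / n)
        assert abs(r.fraction_concave - frac) < 3 * sem

    def test_symmetric_half_split(self, rosette):
        pts, classes = gen_mt_endpoints(rosette, 0.5, 100, seed=5)
        assert classes.count("concave") == 50

    def test_default_fraction_from_measured_counts(self):
        assert DEFAULT_FRAC_CONCAVE == pytest.approx(156 / 212)

    def test_missing_class_raises(self):
        th = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        circle = 10 * np.column_stack([np.cos(th), np.sin(th)])
        with pytest.raises(ValueError, match="concave"):
            gen_mt_endpoints(circle, 0.5, 10, seed=0)
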