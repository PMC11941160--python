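import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from yeastfish.exceptions import ConfigurationError
from yeastfish.optics import OpticsConfig, psf_sigma
from yeastfish.simimages import Ellipse, NOISELESS, SceneCell, render_field
from yeastfish.spots import (
    DetectionConfig,
    ThresholdSuggestion,
    _local_maxima,
    assign_spots,
    counts_to_table,
    detect_spots,
    log_filter,
    suggest_threshold,
)


def _single_spot_stack(z=16.0, y=40.0, x=45.0, amp=100.0, noise_sd=10.0, seed=0,
                       shape=(100, 100)):
    cell = SceneCell(
        1, "G1", Ellipse((shape[0] // 2, shape[1] // 2), (30, 30), 0.0),
        spots={"Cy3": np.array([[z, y, x, amp, 0.0]])},
    )
    f = render_field([cell], noise=NOISELESS, shape=shape)
    rng = np.random.default_rng(seed)
    return f.stacks["Cy3"] + rng.normal(0, noise_sd, f.stacks["Cy3"].shape)


class TestDetectSpots:
    def test_constant_stack_yields_nothing(self):
        cfg = DetectionConfig(threshold=1.0)
        assert detect_spots(np.full((32, 50, 50), 7.0), cfg) == []

    def test_single_spot_localised(self):
        stack = _single_spot_stack(amp=100.0, noise_sd=10.0)  # SNR 10
        # threshold between the noise response ceiling (~22 at sd 10) and
        # the spot response (~48)
        cfg = DetectionConfig(channel="Cy3", threshold=30.0)
        spots = detect_spots(stack, cfg)
        assert len(spots) == 1
        s = spots[0]
        assert abs(s.y - 40.0) < 1.0 and abs(s.x - 45.0) < 1.0
        assert abs(s.z - 16.0) < 1.0

    def test_two_separated_spots(self):
        sxy, _ = psf_sigma(OpticsConfig(), "Cy3")
        d = 5 * sxy
        cell = SceneCell(
            1, "G1", Ellipse((50, 50), (30, 30), 0.0),
            spots={"Cy3": np.array([
                [16.0, 50.0, 50.0, 120.0, 0.0],
                [16.0, 50.0 + d, 50.0, 120.0, 0.0],
            ])},
        )
        f = render_field([cell], noise=NOISELESS, shape=(100, 100))
        spots = detect_spots(f.stacks["Cy3"], DetectionConfig(channel="Cy3", threshold=10.0))
        assert len(spots) == 2

    def test_raising_threshold_never_adds_spots(self):
        stack = _single_spot_stack(noise_sd=10.0)
        counts = [
            len(detect_spots(stack, DetectionConfig(channel="Cy3", threshold=t)))
            for t in (24.0, 32.0, 45.0, 80.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_translation_equivariance(self):
        stack = _single_spot_stack(noise_sd=0.0)
        shifted = np.roll(stack, (7, 5), axis=(1, 2))
        cfg = DetectionConfig(channel="Cy3", threshold=20.0)
        a = detect_spots(stack, cfg)
        b = detect_spots(shifted, cfg)
        assert len(a) == len(b) == 1
        assert b[0].y - a[0].y == pytest.approx(7.0, abs=0.05)
        assert b[0].x - a[0].x == pytest.approx(5.0, abs=0.05)

    def test_empty_stack_raises(self):
        with pytest.raises(ValueError):
            detect_spots(np.empty((0, 4, 4)), DetectionConfig())

    def test_matches_bruteforce_oracle_on_small_stack(self):
        """Well-separated spots on a <=32^3 stack: detections match a
        voxel-threshold + connected-components oracle."""
        cell = SceneCell(
            1, "G1", Ellipse((16, 16), (12, 12), 0.0),
            spots={"Cy3": np.array([
                [10.0, 10.0, 10.0, 150.0, 0.0],
                [20.0, 22.0, 20.0, 150.0, 0.0],
            ])},
        )
        f = render_field([cell], noise=NOISELESS, shape=(32, 32))
        stack = f.stacks["Cy3"]
        cfg = DetectionConfig(channel="Cy3", threshold=15.0)
        detections = detect_spots(stack, cfg)
        resp = log_filter(stack, cfg)
        comp, n = ndimage.label(resp >= cfg.threshold)
        assert len(detections) == n == 2
        centers = ndimage.center_of_mass(resp, comp, range(1, n + 1))
        for c in centers:
            assert any(
                np.hypot(s.y - c[1], s.x - c[2]) < 1.5 and abs(s.z - c[0]) < 2
                for s in detections
            )


class TestSuggestThreshold:
    def test_bimodal_splits_the_modes(self, rng):
        responses = np.concatenate([
            rng.normal(1.0, 0.2, 100), rng.normal(50.0, 2.0, 20)
        ])
        s = suggest_threshold(responses)
        assert 2.0 < s.threshold < 45.0
        assert s.confident

    def test_identical_candidates_flagged(self):
        s = suggest_threshold([5.0] * 20)
        assert s.threshold == 5.0
        assert not s.confident

    def test_monotone_curve_returns_flagged_knee(self, rng):
        s = suggest_threshold(np.linspace(1, 100, 200))
        assert isinstance(s, ThresholdSuggestion)
        assert not s.confident
        assert 1 <= s.threshold <= 100

    def test_too_few_candidates_raise(self):
        with pytest.raises(ValueError):
            suggest_threshold([1.0] * 5)

    def test_auto_threshold_recovers_truth_count(self, noisy_field):
        """On a rendered field, the plateau threshold yields a total count
        within 5% of the rendered truth."""
        stack = noisy_field.stacks["Cy3"]
        cfg = DetectionConfig(channel="Cy3", threshold=0.0, optics=noisy_field.optics)
        resp = log_filter(stack, cfg)
        vals = [resp[z, y, x] for z, y, x in _local_maxima(resp, cfg.min_separation_px)]
        s = suggest_threshold(vals)
        n = len(detect_spots(stack, DetectionConfig(
            channel="Cy3", threshold=s.threshold, optics=noisy_field.optics)))
        n_truth = len(noisy_field.truth_spots)
        assert abs(n - n_truth) <= max(1, 0.05 * n_truth)


class TestAssignment:
    def test_spot_at_centroid_and_background(self):
        mask = np.zeros((20, 20), dtype=int)
        mask[5:10, 5:10] = 3
        from yeastfish.spots import Spot

        inside = Spot("Cy3", 1.0, 7.0, 7.0, 10.0, 1.0, 1.0, 5.0)
        outside = Spot("Cy3", 1.0, 15.0, 15.0, 10.0, 1.0, 1.0, 5.0)
        counts, assigned = assign_spots([inside, outside], mask)
        assert counts == {3: 1}
        assert assigned[0].cell_id == 3 and assigned[1].cell_id is None

    def test_counts_to_table_rows_and_zero_cells(self):
        assignments = {"Cy3": {1: 2, 2: 0}, "Cy5": {1: 1, 2: 0}}
        t = counts_to_table(assignments, {"Cy3": "CLB1", "Cy5": "CLB2"})
        assert len(t) == 4
        zero_rows = t[(t.cell_id == 2)]
        assert (zero_rows["count"] == 0).all()

    def test_counts_to_table_bud_links_sum(self):
        assignments = {"Cy3": {1: 4, 2: 3}}
        t = counts_to_table(assignments, {"Cy3": "CLB1"}, bud_links={2: 1})
        by_comp = t.set_index("compartment")["count"]
        assert by_comp["mother"] + by_comp["bud"] == by_comp["whole"] == 7

    def test_unmapped_channel_raises(self):
        with pytest.raises(ConfigurationError):
            counts_to_table({"Cy3": {1: 1}}, {"Cy5": "CLB2"})
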