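import numpy as np
import pytest

from yeastfish.cellgeom import (
    CellRecord,
    DapiFeatures,
    build_records,
    count_spbs,
    dapi_features,
    link_buds,
    size_distribution,
)
from yeastfish.phaserule import UNASSIGNED, classify_all, classify_rule


def _point_source_stack(points, shape=(8, 60, 60), amp=200.0, sigma=1.0):
    stack = np.zeros(shape)
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    for z, y, x in points:
        stack += amp * np.exp(
            -0.5 * (((zz - z) / 1.2) ** 2 + ((yy - y) / sigma) ** 2 + ((xx - x) / sigma) ** 2)
        )
    return stack


def _disk_mask(shape=(60, 60), center=(30, 30), r=20, label=1):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    mask = np.zeros(shape, dtype=np.int32)
    mask[(yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r * r] = label
    return mask


class TestCountSpbs:
    def test_two_point_sources(self):
        mask = _disk_mask()
        stack = _point_source_stack([(4, 26, 26), (4, 34, 34)])
        count, raw, flagged = count_spbs(stack, mask, 1)
        assert (count, raw, flagged) == (2, 2, False)

    def test_no_signal_gives_zero(self):
        count, raw, flagged = count_spbs(np.zeros((8, 60, 60)), _disk_mask(), 1)
        assert (count, raw) == (0, 0)

    def test_three_sources_capped_and_flagged(self):
        mask = _disk_mask()
        stack = _point_source_stack([(4, 22, 30), (4, 30, 22), (4, 38, 38)])
        count, raw, flagged = count_spbs(stack, mask, 1)
        assert (count, raw, flagged) == (2, 3, True)


def _two_cell_mask(area_a=900, area_b=200, gap=1):
    """Two squares of given areas, nearly touching."""
    side_a = int(np.sqrt(area_a))
    side_b = int(np.sqrt(area_b))
    h = side_a + 10
    w = side_a + side_b + gap + 10
    mask = np.zeros((h, w), dtype=np.int32)
    mask[5 : 5 + side_a, 5 : 5 + side_a] = 1
    x0 = 5 + side_a + gap
    mask[5 : 5 + side_b, x0 : x0 + side_b] = 2
    return mask


def _records_from_mask(mask):
    return build_records(mask)


class TestLinkBuds:
    def test_small_touching_cell_becomes_bud(self):
        records = _records_from_mask(_two_cell_mask(900, 200))
        by_id = {r.cell_id: r for r in records}
        assert by_id[2].is_bud and by_id[2].mother_id == 1
        assert by_id[1].bud_id == 2 and not by_id[1].is_bud

    def test_isolated_cell_not_linked(self):
        mask = _disk_mask()
        (r,) = _records_from_mask(mask)
        assert not r.is_bud and r.mother_id is None

    def test_similar_sizes_not_linked(self):
        records = _records_from_mask(_two_cell_mask(900, 784))
        assert all(not r.is_bud for r in records)

    def test_every_bud_has_exactly_one_mother(self, noiseless_field):
        records = build_records(noiseless_field.label_mask)
        for r in records:
            if r.is_bud:
                assert r.mother_id is not None
                mother = next(m for m in records if m.cell_id == r.mother_id)
                assert not mother.is_bud
                assert mother.area_px >= r.area_px / 0.5


def _nucleus_stack(blobs, shape=(8, 80, 80), sigma=4.0, amp=100.0):
    stack = np.zeros(shape)
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    for (y, x, sy, sx) in blobs:
        stack += amp * np.exp(
            -0.5 * (((zz - 4) / 2.0) ** 2 + ((yy - y) / sy) ** 2 + ((xx - x) / sx) ** 2)
        )
    return stack


class TestDapiFeatures:
    def test_single_round_blob(self):
        mask = _disk_mask(shape=(80, 80), center=(40, 40), r=25)
        stack = _nucleus_stack([(40, 40, 4, 4)])
        d = dapi_features(stack, mask, 1)
        assert d.n_blobs == 1
        assert d.elongation == pytest.approx(1.0, abs=0.25)
        assert not d.crosses_neck

    def test_divided_nucleus_two_blobs(self):
        mask = _two_cell_mask(900, 400, gap=2)
        ya, xa = 5 + 15, 5 + 15  # mother center
        yb, xb = 5 + 10, 5 + 30 + 2 + 10  # bud center
        stack = _nucleus_stack([(ya, xa, 4, 4), (yb, xb, 3, 3)], shape=(8, 45, 67))
        d = dapi_features(stack, mask, 1, mother_link=2)
        assert d.n_blobs == 2

    def test_stretched_nucleus_crosses_neck(self):
        mask = _two_cell_mask(900, 400, gap=2)
        # chain of blobs from mother into bud
        blobs = [(20, x, 3, 3) for x in range(20, 45, 4)]
        stack = _nucleus_stack(blobs, shape=(8, 45, 67))
        d = dapi_features(stack, mask, 1, mother_link=2)
        assert d.crosses_neck

    def test_no_signal_flagged(self):
        d = dapi_features(np.zeros((8, 60, 60)), _disk_mask(), 1)
        assert d.flagged and d.n_blobs == 0

    def test_invariant_to_translation_and_rotation(self):
        mask = _disk_mask(shape=(80, 80), center=(35, 35), r=22)
        stack = _nucleus_stack([(35, 35, 5, 3)])
        base = dapi_features(stack, mask, 1)
        shifted = dapi_features(
            np.roll(stack, (6, 9), axis=(1, 2)), np.roll(mask, (6, 9), axis=(0, 1)), 1
        )
        rotated = dapi_features(
            np.rot90(stack, axes=(1, 2)).copy(), np.rot90(mask).copy(), 1
        )
        for other in (shifted, rotated):
            assert other.n_blobs == base.n_blobs
            assert other.elongation == pytest.approx(base.elongation, rel=0.05)


def _record(**kw):
    defaults = dict(cell_id=1, area_px=500.0, area_um2=8.0, centroid=(0.0, 0.0))
    defaults.update(kw)
    return CellRecord(**defaults)


class TestClassifyRule:
    def test_g2_two_spbs_budded_nucleus_in_mother(self):
        r = _record(bud_id=2, spb_count=2, dapi=DapiFeatures(n_blobs=1))
        assert classify_rule(r) == "G2"

    def test_g1_one_spb_unbudded_round_nucleus(self):
        r = _record(spb_count=1, dapi=DapiFeatures(n_blobs=1))
        assert classify_rule(r) == "G1"

    def test_s_budded_one_spb(self):
        r = _record(bud_id=2, spb_count=1, dapi=DapiFeatures(n_blobs=1))
        assert classify_rule(r) == "S"

    def test_early_m_crossing_nucleus(self):
        r = _record(bud_id=2, spb_count=1,
                    dapi=DapiFeatures(n_blobs=1, crosses_neck=True))
        assert classify_rule(r) == "Early-M"

    def test_late_m_divided_nucleus(self):
        r = _record(bud_id=2, spb_count=1, dapi=DapiFeatures(n_blobs=2))
        assert classify_rule(r) == "Late-M"

    def test_bud_mirrors_mother(self):
        mother = _record(cell_id=1, bud_id=2, spb_count=1,
                         dapi=DapiFeatures(n_blobs=2), phase="Late-M")
        bud = _record(cell_id=2, is_bud=True, mother_id=1)
        assert classify_rule(bud, mother) == "Late-M-Bud"

    def test_unbudded_two_spbs_unassigned(self):
        r = _record(spb_count=2, dapi=DapiFeatures(n_blobs=1))
        assert classify_rule(r) == UNASSIGNED

    def test_missing_features_unassigned(self):
        r = _record(spb_count=1, dapi=DapiFeatures(flagged=True))
        assert classify_rule(r) == UNASSIGNED

    def test_order_independent(self, noiseless_field):
        f = noiseless_field
        records = build_records(f.label_mask, f.stacks["SPB"], f.stacks["DAPI"], f.optics)
        a = {r.cell_id: r.phase for r in classify_all(records)}
        records2 = build_records(f.label_mask, f.stacks["SPB"], f.stacks["DAPI"], f.optics)
        b = {r.cell_id: r.phase for r in classify_all(list(reversed(records2)))}
        assert a == b


def test_rule_matches_truth_on_noiseless_field(noiseless_field):
    f = noiseless_field
    records = build_records(f.label_mask, f.stacks["SPB"], f.stacks["DAPI"], f.optics)
    classify_all(records)
    truth = f.truth_objects.set_index("label")["phase"]
    assert all(r.phase == truth.loc[r.cell_id] for r in records)


class TestSizeDistribution:
    def test_identical_strains_ratio_one(self, rng):
        areas = rng.uniform(400, 900, 500)
        out = size_distribution({"WT": areas, "x": areas.copy()})
        row = out[out.strain_id == "x"].iloc[0]
        assert row.median_ratio == pytest.approx(1.0)

    def test_scaled_strain_ratio(self, rng):
        areas = rng.uniform(400, 900, 500)
        out = size_distribution({"WT": areas, "big": areas * 1.2})
        assert out[out.strain_id == "big"].iloc[0].median_ratio == pytest.approx(1.2)

    def test_ten_percent_shift_is_significant(self, rng):
        areas = rng.normal(650, 80, 2000)
        out = size_distribution({"WT": areas, "clb6D": areas * 1.1})
        assert out[out.strain_id == "clb6D"].iloc[0].mw_p < 1e-6

    def test_single_strain_raises(self):
        with pytest.raises(ValueError):
            size_distribution({"WT": [1, 2, 3]})
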