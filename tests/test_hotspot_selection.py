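"""Brown-mark detection, density estimation and penalty-driven selection."""

import numpy as np
import pytest

from ki67hotspot import (
    DensityMap,
    FieldGeometry,
    PenaltyParams,
    ScalarPlane,
    SpecimenMap,
    density_map,
    immunopositive_marks,
    penalty,
    select_fields,
)
from ki67hotspot.hotspot_selection import calibrate_rho


def _full_map(shape):
    return SpecimenMap(np.ones(shape, bool), working_downsample=8)


class TestImmunopositiveMarks:
    def test_constant_plane_has_no_marks(self):
        u = ScalarPlane(np.full((32, 32), 5.0))
        assert immunopositive_marks(u, _full_map((32, 32))).sum() == 0

    def test_single_deep_pit_gives_one_mark(self):
        yy, xx = np.mgrid[:64, :64]
        # u high (brown) at the pit => plane = -depth bump in u
        u = 10.0 - 5.0 * np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / 18.0)
        marks = immunopositive_marks(ScalarPlane(-u), _full_map((64, 64)),
                                     h_frac=0.1)
        from skimage.measure import label
        assert label(marks, connectivity=2).max() == 1
        assert marks[32, 32]

    def test_shallow_pit_suppressed(self):
        yy, xx = np.mgrid[:64, :64]
        # broad basin of depth 5 sets the dynamic range (h = 0.5);
        # the narrow pit of depth 0.4 < h must be suppressed
        u = (10.0
             - 5.0 * np.exp(-((yy - 16) ** 2 + (xx - 16) ** 2) / 800.0)
             - 0.4 * np.exp(-((yy - 48) ** 2 + (xx - 48) ** 2) / 8.0))
        marks = immunopositive_marks(ScalarPlane(-u), _full_map((64, 64)),
                                     h_frac=0.1)
        assert not marks[44:53, 44:53].any()

    def test_empty_specimen_map_gives_no_marks(self):
        u = ScalarPlane(np.random.default_rng(0).random((16, 16)))
        specimen = SpecimenMap(np.zeros((16, 16), bool))
        assert immunopositive_marks(u, specimen).sum() == 0


class TestDensityMap:
    def test_no_marks_zero_map(self):
        d = density_map(np.zeros((64, 64), bool), FieldGeometry(112, 84))
        assert d.mark_count == 0
        assert d.values == pytest.approx(0.0)

    def test_single_interior_mark_sums_to_one(self):
        marks = np.zeros((64, 64), bool)
        marks[32, 32] = True
        d = density_map(marks, FieldGeometry(112, 84))
        assert d.mark_count == 1
        assert d.values.sum() == pytest.approx(1.0, abs=1e-6)

    def test_two_separated_clusters_make_two_equal_maxima(self):
        marks = np.zeros((96, 96), bool)
        marks[20, 20] = marks[21, 22] = True
        marks[70, 70] = marks[71, 72] = True
        d = density_map(marks, FieldGeometry(112, 84))
        assert d.values[20, 21] == pytest.approx(d.values[70, 71], rel=1e-9)
        assert d.values.sum() == pytest.approx(4.0, abs=1e-6)


class TestPenalty:
    def test_empty_selection_gives_one(self):
        assert penalty((5, 5), [], PenaltyParams(0.2), fov_width=10) == 1.0

    def test_single_neighbor_at_one_fov(self):
        val = penalty((0, 0), [(0, 10)], PenaltyParams(0.2), fov_width=10)
        assert val == pytest.approx(0.8)

    def test_two_neighbors_at_one_and_two_fov(self):
        val = penalty((0, 0), [(0, 10), (0, 20)], PenaltyParams(0.2),
                      fov_width=10)
        assert val == pytest.approx(0.7)

    def test_never_exceeds_one_and_floors_at_zero(self):
        near = [(0, 1)] * 20
        assert penalty((0, 0), near, PenaltyParams(0.5), fov_width=10) == 0.0

    def test_decreases_as_selected_field_approaches(self):
        far = penalty((0, 0), [(0, 40)], PenaltyParams(0.2), 10)
        close = penalty((0, 0), [(0, 12)], PenaltyParams(0.2), 10)
        assert close < far < 1.0

    def test_coincident_center_rejected(self):
        with pytest.raises(ValueError):
            penalty((3, 3), [(3, 3)], PenaltyParams(0.2), 10)


def _single_peak_setup(shape=(128, 128)):
    rng = np.random.default_rng(42)
    marks = np.zeros(shape, bool)
    rr = rng.normal(64, 5, 120).astype(int).clip(0, shape[0] - 1)
    cc = rng.normal(64, 5, 120).astype(int).clip(0, shape[1] - 1)
    marks[rr, cc] = True
    d = density_map(marks, FieldGeometry(64, 48))
    return d, _full_map(shape)


def mean_pairwise_distance(selection):
    cen = selection.centers()
    n = len(cen)
    dists = [np.hypot(*(cen[i] - cen[j]))
             for i in range(n) for j in range(i + 1, n)]
    return float(np.mean(dists))


class TestSelectFields:
    def test_zero_rho_packs_fields_around_single_peak(self):
        d, spec = _single_peak_setup()
        sel = select_fields(d, spec, n=10, params=PenaltyParams(0.0),
                            fov=FieldGeometry(64, 48), stride=2)
        assert len(sel) == 10
        assert all(np.hypot(f.center[0] - 64, f.center[1] - 64) < 30
                   for f in sel.fields)

    def test_dispersion_grows_with_rho(self):
        d, spec = _single_peak_setup()
        packed = select_fields(d, spec, n=10, params=PenaltyParams(0.0),
                               fov=FieldGeometry(64, 48), stride=2)
        spread = select_fields(d, spec, n=10, params=PenaltyParams(0.2),
                               fov=FieldGeometry(64, 48), stride=2)
        assert mean_pairwise_distance(spread) > mean_pairwise_distance(packed)

    def test_two_equal_hotspots_get_one_field_each(self):
        marks = np.zeros((160, 160), bool)
        rng = np.random.default_rng(1)
        for center in ((40, 40), (120, 120)):
            rr = rng.normal(center[0], 3, 60).astype(int)
            cc = rng.normal(center[1], 3, 60).astype(int)
            marks[rr.clip(0, 159), cc.clip(0, 159)] = True
        d = density_map(marks, FieldGeometry(64, 48))
        sel = select_fields(d, _full_map((160, 160)), n=2,
                            params=PenaltyParams(0.2),
                            fov=FieldGeometry(64, 48), stride=2)
        centers = sel.centers()
        d1 = min(np.hypot(*(c - (40, 40))) for c in centers)
        d2 = min(np.hypot(*(c - (120, 120))) for c in centers)
        assert d1 < 15 and d2 < 15

    def test_selected_fields_respect_overlap_and_coverage_rules(
            self, pipeline_result):
        sel = pipeline_result.selection
        spec = pipeline_result.specimen
        fh = sel.fov.height_px // 8
        fw = sel.fov.width_px // 8
        centers = sel.centers()
        for i, (r, c) in enumerate(centers):
            window = spec.mask[int(r - fh / 2):int(r + fh / 2),
                               int(c - fw / 2):int(c + fw / 2)]
            assert window.mean() >= 0.75   # 0.8 rule minus rounding slack
            for j in range(i + 1, len(centers)):
                dr = abs(centers[j][0] - r)
                dc = abs(centers[j][1] - c)
                overlap = (max(0, fh - dr) * max(0, fw - dc)) / (fh * fw)
                assert overlap <= 0.5 + 1e-9

    def test_scores_are_non_increasing(self, pipeline_result):
        scores = [f.score for f in pipeline_result.selection.fields]
        assert all(a >= b - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_no_tissue_returns_empty_selection_with_warning(self):
        d = density_map(np.zeros((64, 64), bool), FieldGeometry(64, 48))
        with pytest.warns(UserWarning):
            sel = select_fields(d, SpecimenMap(np.zeros((64, 64), bool)),
                                fov=FieldGeometry(64, 48))
        assert len(sel) == 0


class TestCalibrateRho:
    def _case(self):
        from ki67hotspot.concordance_stats import ObserverFieldSet
        d, spec = _single_peak_setup()
        ref = ObserverFieldSet([(64.0, 64.0, 20.0)], "ref")
        return [(d, spec, ref)]

    def test_single_value_grid_returns_it(self):
        rho, curve = calibrate_rho(self._case(), rho_grid=[0.3], n=3,
                                   fov=FieldGeometry(64, 48), stride=2)
        assert rho == 0.3 and len(curve) == 1

    def test_curve_length_matches_grid(self):
        grid = [0.1, 0.2, 0.3]
        _, curve = calibrate_rho(self._case(), rho_grid=grid, n=3,
                                 fov=FieldGeometry(64, 48), stride=2)
        assert [rec["rho"] for rec in curve] == grid

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            calibrate_rho(self._case(), rho_grid=[])
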