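"""Repeatability/variability statistics, AHA labelling, 2SD segmentation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from raffmap.phantoms import LesionSpec, make_sax_phantom
from raffmap.stats import (
    RoiSample,
    aha16_label,
    bullseye_summary,
    cv_percent,
    pearson_and_bland_altman,
    precision_reproducibility_intersubject,
    scar_mask_2sd,
    segment_table_from_maps,
)


class TestCv:
    def test_examples(self):
        assert cv_percent([100, 100, 100]) == 0.0
        assert cv_percent([95, 100, 105]) == pytest.approx(5.0)

    @given(scale=hst.floats(0.1, 1000.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, scale):
        base = np.array([70.0, 80.0, 90.0])
        assert cv_percent(scale * base) == pytest.approx(cv_percent(base), rel=1e-9)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            cv_percent([5.0])
        with pytest.raises(ValueError):
            cv_percent([-1.0, 1.0])


def _hier_table(rng, n_subj=7, n_rep=3, mean=79.1, cv_between=0.10, cv_within=0.01):
    rows = []
    for seg in range(1, 17):
        sl = "basal" if seg <= 6 else ("mid" if seg <= 12 else "apical")
        for subj in range(n_subj):
            mu = mean * (1 + rng.normal(0, cv_between))
            for rep in range(n_rep):
                rows.append(dict(subject=subj, repetition=rep, slice=sl,
                                 segment=seg,
                                 mean_ms=mu * (1 + rng.normal(0, cv_within)),
                                 sd_ms=0.076 * mu))
    return pd.DataFrame(rows)


class TestHierarchicalCvs:
    def test_identical_values_give_zero(self):
        rows = [dict(subject=s, repetition=r, slice="mid", segment=7,
                     mean_ms=80.0, sd_ms=5.0)
                for s in range(3) for r in range(2)]
        rep = precision_reproducibility_intersubject(pd.DataFrame(rows))
        assert rep.loc[7, "wcv_bar"] == 0.0
        assert rep.loc[7, "cv_bar"] == 0.0
        assert rep.loc[7, "wcv"] == pytest.approx(100 * 5.0 / 80.0)

    def test_recovers_generative_cvs(self):
        rep = precision_reproducibility_intersubject(
            _hier_table(np.random.default_rng(123)))
        assert rep["cv_bar"].mean() == pytest.approx(10.0, abs=3.0)
        assert rep["wcv_bar"].mean() == pytest.approx(1.0, abs=0.5)
        assert rep["wcv"].mean() == pytest.approx(7.6, abs=0.5)

    def test_single_subject_rejected(self):
        rows = [dict(subject=0, repetition=r, slice="mid", segment=7,
                     mean_ms=80.0, sd_ms=5.0) for r in range(3)]
        with pytest.raises(ValueError, match="subjects"):
            precision_reproducibility_intersubject(pd.DataFrame(rows))

    def test_missing_cells_reported(self):
        t = _hier_table(np.random.default_rng(0))
        t = t[~((t.subject == 2) & (t.repetition == 1))]
        with pytest.raises(ValueError, match=r"\(2, 1\)"):
            precision_reproducibility_intersubject(t)


class TestAgreement:
    def test_identity_pairs(self):
        out = pearson_and_bland_altman([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert out["r2"] == pytest.approx(1.0)
        assert out["bias"] == 0.0
        assert out["loa_low"] == out["loa_high"] == 0.0

    def test_constant_shift(self):
        x = np.array([101.7, 250.0, 400.0, 550.8])
        out = pearson_and_bland_altman(x, x - 156.4)
        assert out["r2"] == pytest.approx(1.0)
        assert out["bias"] == pytest.approx(-156.4)
        assert out["slope"] == pytest.approx(1.0)

    def test_independent_draws_have_low_r2(self):
        rng = np.random.default_rng(8)
        out = pearson_and_bland_altman(rng.normal(size=100), rng.normal(size=100))
        assert out["r2"] < 0.1

    def test_loa_width(self):
        rng = np.random.default_rng(1)
        x = rng.normal(100, 10, 200)
        y = x + rng.normal(0, 2, 200)
        out = pearson_and_bland_altman(x, y)
        sd = np.std(y - x, ddof=1)
        assert out["loa_high"] - out["loa_low"] == pytest.approx(2 * 1.96 * sd)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_and_bland_altman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestScar2Sd:
    def test_threshold_arithmetic(self):
        rng = np.random.default_rng(0)
        remote_vals = rng.normal(50.0, 5.0, 10_000)
        img = np.concatenate([remote_vals, [61.0, 59.0]]).reshape(1, -1)
        remote = np.zeros_like(img, dtype=bool)
        remote[0, :10_000] = True
        thr = remote_vals.mean() + 2 * remote_vals.std(ddof=1)
        mask = scar_mask_2sd(img, remote)
        assert mask[0, -2] == (61.0 > thr)
        assert not mask[0, -1]

    def test_uniform_image_warns_and_empty(self):
        img = np.full((8, 8), 42.0)
        with pytest.warns(UserWarning, match="degenerate"):
            mask = scar_mask_2sd(img, np.ones_like(img, dtype=bool))
        assert not mask.any()

    def test_empty_remote_rejected(self):
        with pytest.raises(ValueError):
            scar_mask_2sd(np.ones((4, 4)), np.zeros((4, 4), dtype=bool))


@pytest.fixture(scope="module")
def sax():
    return make_sax_phantom(grid_size=96, radii=(13.0, 22.0))


class TestAha16:
    @pytest.mark.parametrize("level,expected", [
        ("basal", set(range(1, 7))), ("mid", set(range(7, 13))),
        ("apical", set(range(13, 17))),
    ])
    def test_exact_partition(self, sax, level, expected):
        lab = aha16_label(sax.myocardium_mask, sax.lv_center, sax.rv_insertion, level)
        assert set(np.unique(lab[sax.myocardium_mask])) == expected
        assert np.array_equal(lab > 0, sax.myocardium_mask)

    def test_rotating_insertion_permutes_mid_labels(self, sax):
        c = sax.lv_center[0]
        r_out = 22.0

        def insertion(angle_deg):
            a = math.radians(angle_deg)
            return (c - r_out * math.sin(a), c + r_out * math.cos(a))

        lab0 = aha16_label(sax.myocardium_mask, sax.lv_center, insertion(120.0), "mid")
        lab1 = aha16_label(sax.myocardium_mask, sax.lv_center, insertion(180.0), "mid")
        m = sax.myocardium_mask
        # +60 deg CCW rotation of the origin shifts every sector down one
        assert np.array_equal((lab1[m] - 7) % 6, (lab0[m] - 8) % 6)

    def test_chirality_flag_mirrors_labels(self, sax):
        lab_ccw = aha16_label(sax.myocardium_mask, sax.lv_center,
                              sax.rv_insertion, "mid")
        lab_cw = aha16_label(sax.myocardium_mask, sax.lv_center,
                             sax.rv_insertion, "mid", counterclockwise=False)
        m = sax.myocardium_mask
        assert set(np.unique(lab_cw[m])) == set(range(7, 13))
        assert not np.array_equal(lab_cw[m], lab_ccw[m])

    def test_insertion_at_center_rejected(self, sax):
        with pytest.raises(ValueError, match="angle"):
            aha16_label(sax.myocardium_mask, sax.lv_center, sax.lv_center, "mid")


class TestBullseye:
    def _table(self, value=79.1):
        rows = []
        for seg in range(1, 17):
            sl = "basal" if seg <= 6 else ("mid" if seg <= 12 else "apical")
            rows.append(dict(subject=1, repetition=1, slice=sl, segment=seg,
                             mean_ms=value, sd_ms=5.0))
        return pd.DataFrame(rows)

    def test_uniform_table(self):
        rep = bullseye_summary(self._table(79.1))
        assert rep["global_mean"] == pytest.approx(79.1)
        assert rep["per_slice"] == {"basal": pytest.approx(79.1),
                                    "mid": pytest.approx(79.1),
                                    "apical": pytest.approx(79.1)}

    def test_grand_mean_conserved(self):
        t = self._table()
        t["mean_ms"] = np.linspace(60, 95, 16)
        rep = bullseye_summary(t)
        assert rep["global_mean"] == pytest.approx(t["mean_ms"].mean(), abs=1e-12)

    def test_plot_written(self, tmp_path):
        out = tmp_path / "bullseye.png"
        bullseye_summary(self._table(), plot_path=out)
        assert out.exists() and out.stat().st_size > 0


def test_segment_table_from_maps_aggregates_means():
    sax = make_sax_phantom(grid_size=96, radii=(13.0, 22.0))
    lab = aha16_label(sax.myocardium_mask, sax.lv_center, sax.rv_insertion, "mid")
    t = segment_table_from_maps(sax.maps.traff2_map, None, lab,
                                subject=1, repetition=1, slice_level="mid")
    assert set(t["segment"]) == set(range(7, 13))
    assert np.allclose(t["mean_ms"], 79.1)


def test_roi_sample_summary():
    roi = RoiSample(values=[78.0, 80.0, 82.0], label="vial 1")
    assert roi.mean == pytest.approx(80.0)
    assert roi.sd == pytest.approx(2.0)
    with pytest.raises(ValueError):
        RoiSample(values=[])
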