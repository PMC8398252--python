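import numpy as np
import pytest

import ecgbeats as eb
from ecgbeats.features import (
    FEATURE_GROUPS,
    FEATURE_NAMES,
    FRAGMENT_LEN,
    HID,
    LOD,
    dwt_features,
    morph_features,
    segment,
)


# ---------------------------------------------------------------------------
# independent direct-convolution DWT oracle
# ---------------------------------------------------------------------------

def _oracle_dwt_level(x, filt):
    """One analysis level: symmetric extension by len(filt)-1, full
    convolution, dyadic downsampling of the fully-overlapped outputs."""
    m = len(filt) - 1
    ext = np.concatenate([x[:m][::-1], x, x[-m:][::-1]])
    full = np.convolve(ext, filt, mode="full")
    return full[m + 1 :: 2][: (len(x) - 1) // 2 + 3]


def oracle_wavedec4(x):
    a = np.asarray(x, dtype=float)
    details = []
    for _ in range(4):
        details.append(_oracle_dwt_level(a, HID))
        a = _oracle_dwt_level(a, LOD)
    d1, d2, d3, d4 = details
    return a, d4, d3


class TestSegmentation:
    def test_middle_peak_only_is_eligible(self):
        rec = eb.EcgRecord("r", np.zeros(1000), 360.0)
        frags = segment(rec, [100, 400, 700])
        assert len(frags) == 1
        assert frags[0].r_index_in_record == 400

    def test_window_arithmetic(self):
        rec = eb.EcgRecord("r", np.arange(1000, dtype=float), 360.0)
        frag = segment(rec, [100, 400, 700])[0]
        assert frag.hb.size == FRAGMENT_LEN
        assert frag.hb[0] == 350 and frag.hb[-1] == 500
        assert frag.hb[50] == 400  # R is the 51st sample

    def test_peak_too_close_to_edge_skipped(self):
        rec = eb.EcgRecord("r", np.zeros(1000), 360.0)
        frags = segment(rec, [5, 30, 400, 700])
        # 30 has a previous and next peak but only 30 samples of history
        assert [f.r_index_in_record for f in frags] == [400]

    def test_empty_rpeaks_gives_empty_list(self):
        rec = eb.EcgRecord("r", np.zeros(1000), 360.0)
        assert segment(rec, []) == []

    def test_rr_intervals_in_seconds(self):
        rec = eb.EcgRecord("r", np.zeros(2000), 360.0)
        frag = segment(rec, [200, 560, 1000])[0]
        assert frag.rr_pre == pytest.approx(360 / 360.0)
        assert frag.rr_pos == pytest.approx(440 / 360.0)


class TestMorphFeatures:
    def test_symmetric_rr_gives_zero_hrv(self, fragment_factory):
        m = morph_features(fragment_factory(np.zeros(151)), 0.8, 0.8)
        assert m.hrv_loc == 0.0

    def test_flat_central_window_gives_zero_dif(self, fragment_factory):
        hb = np.ones(151)
        hb[20:101] = 0.0
        m = morph_features(fragment_factory(hb))
        assert m.dif == 0.0

    def test_ratio_lr_hand_computed(self, fragment_factory):
        hb = np.empty(151)
        hb[:50] = 1.0   # hb(1..50)
        hb[50] = 5.0    # hb(51), excluded from both sums
        hb[51:] = 2.0   # hb(52..151)
        m = morph_features(fragment_factory(hb))
        assert m.ratio_lr == pytest.approx(50 / 200)

    def test_ratio_ud_uses_magnitude_of_negative_sum(self, fragment_factory):
        hb = np.zeros(151)
        hb[:10] = 2.0    # positive area 20
        hb[60:70] = -1.0  # negative area -10
        m = morph_features(fragment_factory(hb))
        assert m.ratio_ud == pytest.approx(2.0)
        assert m.ratio_ud > 0

    def test_dif_window_is_81_samples_about_r(self, fragment_factory):
        hb = np.zeros(151)
        hb[20] = -1.0   # first sample inside hb(21..101)
        hb[100] = 2.0   # last sample inside
        hb[101] = 50.0  # just outside: must not count
        hb[19] = -50.0
        m = morph_features(fragment_factory(hb))
        assert m.dif == pytest.approx(3.0)

    def test_one_sided_fragment_stays_finite(self, fragment_factory):
        m = morph_features(fragment_factory(np.abs(np.random.default_rng(0).normal(size=151))))
        assert np.isfinite(m.ratio_ud)
        assert np.isfinite(m.ratio_lr)

    def test_nonpositive_rr_rejected(self, fragment_factory):
        with pytest.raises(ValueError):
            morph_features(fragment_factory(np.zeros(151)), rr_pre=0.0, rr_pos=0.8)


class TestDwtFeatures:
    def test_level_lengths_and_total(self, fragment_factory):
        w = dwt_features(fragment_factory(np.random.default_rng(1).normal(size=151)))
        assert (len(w.a4), len(w.d4), len(w.d3)) == (14, 14, 23)
        assert len(w.a4) + len(w.d4) + len(w.d3) == 51

    def test_length_recurrence(self):
        # per-level output length floor((n-1)/2) + 3 from 151
        n = 151
        lengths = []
        for _ in range(4):
            n = (n - 1) // 2 + 3
            lengths.append(n)
        assert lengths == [78, 41, 23, 14]

    def test_zero_fragment_gives_zero_coefficients(self, fragment_factory):
        w = dwt_features(fragment_factory(np.zeros(151)))
        assert not np.any(w.a4) and not np.any(w.d4) and not np.any(w.d3)

    def test_matches_direct_convolution_oracle(self, random_fragments):
        worst = 0.0
        for hb in random_fragments:
            w = dwt_features(hb)
            a4, d4, d3 = oracle_wavedec4(hb)
            worst = max(
                worst,
                np.max(np.abs(w.a4 - a4)),
                np.max(np.abs(w.d4 - d4)),
                np.max(np.abs(w.d3 - d3)),
            )
        assert worst < 1e-10

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            dwt_features(np.zeros(150))


class TestBuildVector:
    def test_layout_and_length(self, fragment_factory):
        frag = fragment_factory(np.random.default_rng(2).normal(size=151))
        m = morph_features(frag)
        w = dwt_features(frag)
        v = eb.build_vector(m, w, label="N")
        assert v.values.size == 56
        assert v.values[0] == m.rr_pre
        assert v.values[1] == m.hrv_loc
        assert v.values[5] == w.a4[0]   # a4 block starts at 5
        assert v.values[19] == w.d3[0]  # d3 block
        assert v.values[42] == w.d4[0]  # d4 block
        assert v.label == "N"

    def test_zero_inputs_give_zero_vector(self):
        m = eb.MorphFeatures(0.0, 0.0, 0.0, 0.0, 0.0)
        w = eb.WaveletFeatures(np.zeros(14), np.zeros(14), np.zeros(23))
        v = eb.build_vector(m, w)
        assert not np.any(v.values)
        assert v.values.size == 56

    def test_group_slices_cover_all_columns(self):
        covered = sorted(
            i for lo, hi in FEATURE_GROUPS.values() for i in range(lo, hi)
        )
        assert covered == list(range(56))
        assert FEATURE_NAMES[:5] == ("rr_pre", "hrv_loc", "ratio_lr", "ratio_ud", "dif")


class TestScaleCovariance:
    def test_scaling_fragment_scales_dif_and_wavelets_only(self, fragment_factory):
        rng = np.random.default_rng(3)
        hb = rng.standard_normal(151)
        c = 3.7
        m1, m2 = (
            morph_features(fragment_factory(h)) for h in (hb, c * hb)
        )
        w1, w2 = dwt_features(hb), dwt_features(c * hb)
        assert m2.dif == pytest.approx(c * m1.dif)
        assert m2.ratio_lr == pytest.approx(m1.ratio_lr)
        assert m2.ratio_ud == pytest.approx(m1.ratio_ud)
        np.testing.assert_allclose(w2.a4, c * w1.a4, rtol=1e-12, atol=1e-14)
        np.testing.assert_allclose(w2.d3, c * w1.d3, rtol=1e-12, atol=1e-14)


class TestExtractFeatures:
    def test_one_vector_per_eligible_beat(self, default_synth):
        rec = default_synth.record
        labels = list(default_synth.classes)
        vecs = eb.extract_features(rec, default_synth.rpeaks, labels)
        frags = segment(rec, default_synth.rpeaks, labels)
        assert len(vecs) == len(frags)
        assert all(v.values.size == 56 for v in vecs)
        assert all(v.label in eb.CLASS_ORDER for v in vecs)

    def test_csv_round_trip(self, tmp_path, default_synth):
        vecs = eb.extract_features(
            default_synth.record, default_synth.rpeaks, list(default_synth.classes)
        )[:20]
        path = tmp_path / "f.csv"
        from ecgbeats.features import read_feature_csv, write_feature_csv

        write_feature_csv(vecs, path)
        back = read_feature_csv(path)
        assert len(back) == len(vecs)
        np.testing.assert_allclose(back[0].values, vecs[0].values, rtol=1e-12)
        assert [v.label for v in back] == [v.label for v in vecs]
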