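import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hypervoc.vowelspace import (
    FormantTrack,
    VowelToken,
    exclude_high_f0,
    hz_to_bark,
    mid_window_mean,
    point_vowel_means,
    speaker_vsa,
    vsa,
    vsa_difference,
)

from conftest import shoelace_area

IDS_MEANS = {"i": (453.0, 1972.0), "ɑ": (656.0, 1383.0), "u": (430.0, 934.0)}
ADS_MEANS = {"i": (472.0, 1904.0), "ɑ": (661.0, 1307.0), "u": (473.0, 1032.0)}


def make_token(f0=200.0, speaker="s1", register="IDS", vowel="i",
               f1=450.0, f2=1900.0, token_id=""):
    return VowelToken(speaker_id=speaker, register=register, vowel=vowel,
                      median_f0=f0, point_f1=f1, point_f2=f2, token_id=token_id)


class TestF0Exclusion:
    def test_boundary_is_strictly_exceeding(self):
        tokens = [make_token(f0) for f0 in (200.0, 350.0, 351.0)]
        kept, excluded = exclude_high_f0(tokens)
        assert [t.median_f0 for t in kept] == [200.0, 350.0]
        assert [t.median_f0 for t in excluded] == [351.0]

    def test_no_exclusions_when_all_below(self):
        tokens = [make_token(f0) for f0 in (180.0, 349.9, 350.0)]
        kept, excluded = exclude_high_f0(tokens)
        assert excluded == [] and len(kept) == 3

    def test_custom_threshold(self):
        tokens = [make_token(f0) for f0 in (200.0, 300.0)]
        kept, _ = exclude_high_f0(tokens, threshold=250.0)
        assert [t.median_f0 for t in kept] == [200.0]

    def test_partition_exhaustive_and_monotone_in_threshold(self, rng):
        tokens = [make_token(float(f0)) for f0 in rng.uniform(100, 500, 200)]
        prev_excluded = -1
        for thr in (400.0, 350.0, 300.0, 250.0):
            kept, excluded = exclude_high_f0(tokens, thr)
            assert len(kept) + len(excluded) == len(tokens)
            assert set(id(t) for t in kept) | set(id(t) for t in excluded) == set(
                id(t) for t in tokens
            )
            assert len(excluded) >= prev_excluded  # lowering never shrinks
            prev_excluded = len(excluded)


class TestMidWindow:
    def test_constant_track_for_any_fraction(self):
        track = FormantTrack(times=np.linspace(0, 0.2, 17),
                             f1=np.full(17, 500.0), f2=np.full(17, 1500.0))
        for fraction in (0.1, 0.4, 0.7, 1.0):
            assert mid_window_mean(track, fraction) == (500.0, 1500.0)

    def test_index_selection_matches_timestamp_rule(self):
        f1 = np.array([100, 100, 100, 400, 400, 400, 400, 400, 100, 100, 100], float)
        track = FormantTrack(times=np.linspace(0, 1, 11), f1=f1, f2=f1 * 3)
        got_f1, got_f2 = mid_window_mean(track, 0.4)
        assert got_f1 == pytest.approx(400.0)
        assert got_f2 == pytest.approx(1200.0)

    def test_single_sample_fallback(self):
        track = FormantTrack(times=np.array([0.05]), f1=np.array([480.0]),
                             f2=np.array([1700.0]))
        assert mid_window_mean(track) == (480.0, 1700.0)

    def test_sparse_track_falls_back_to_nearest_midpoint(self):
        # no sample inside the mid-40% window -> nearest to midpoint used
        track = FormantTrack(times=np.array([0.0, 0.05, 0.96, 1.0]),
                             f1=np.array([100.0, 200.0, 300.0, 400.0]),
                             f2=np.array([1000.0, 1100.0, 1200.0, 1300.0]))
        assert mid_window_mean(track, 0.4) == (200.0, 1100.0)

    def test_windowing_reduces_coarticulation_bias(self, rng):
        # linear ramps into a steady state: mid-window mean is closer
        # to the steady state than the full-duration mean
        for _ in range(50):
            steady = rng.uniform(300, 800)
            locus = steady + rng.choice([-1, 1]) * rng.uniform(50, 200)
            d = rng.uniform(0.1, 0.3)
            t = np.arange(0, d, 0.005)
            ramp = 0.25 * d
            vals = np.full_like(t, steady)
            vals[t < ramp] = locus + (steady - locus) * t[t < ramp] / ramp
            off = t > d - ramp
            vals[off] = locus + (steady - locus) * (d - t[off]) / ramp
            track = FormantTrack(times=t, f1=vals, f2=vals * 2 + 500)
            windowed = mid_window_mean(track, 0.4)[0]
            full = float(vals.mean())
            assert abs(windowed - steady) < abs(full - steady)

    def test_invalid_fraction(self):
        track = FormantTrack(times=np.array([0.0, 0.1]),
                             f1=np.array([500.0, 500.0]), f2=np.array([1500.0, 1500.0]))
        with pytest.raises(ValueError):
            mid_window_mean(track, 0.0)


class TestVSA:
    def test_ids_grand_means(self):
        assert vsa(IDS_MEANS) == pytest.approx(112_130.5)

    def test_ads_grand_means(self):
        assert vsa(ADS_MEANS) == pytest.approx(82_105.5)

    def test_collinear_points_give_zero(self):
        assert vsa({"i": (100, 100), "ɑ": (200, 200), "u": (300, 300)}) == 0.0

    def test_matches_shoelace_oracle_on_random_triangles(self, rng):
        for _ in range(1000):
            pts = rng.uniform(200, 2500, size=(3, 2))
            means = {"i": tuple(pts[0]), "ɑ": tuple(pts[1]), "u": tuple(pts[2])}
            expected = shoelace_area(pts)
            if expected == 0.0:
                continue
            assert abs(vsa(means) - expected) / expected < 1e-9

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(-1e4, 1e4), st.floats(-1e4, 1e4))
    def test_translation_invariance(self, dx, dy):
        shifted = {v: (f1 + dx, f2 + dy) for v, (f1, f2) in IDS_MEANS.items()}
        assert vsa(shifted) == pytest.approx(vsa(IDS_MEANS), rel=1e-6, abs=1e-3)

    def test_label_permutation_invariance(self):
        rotated = {"i": IDS_MEANS["ɑ"], "ɑ": IDS_MEANS["u"], "u": IDS_MEANS["i"]}
        assert vsa(rotated) == pytest.approx(vsa(IDS_MEANS))

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.1, 5.0))
    def test_quadratic_scaling(self, c):
        scaled = {v: (c * f1, c * f2) for v, (f1, f2) in IDS_MEANS.items()}
        assert vsa(scaled) == pytest.approx(c * c * vsa(IDS_MEANS), rel=1e-9)

    def test_missing_vowel_errors(self):
        with pytest.raises(ValueError, match="missing point vowels"):
            vsa({"i": (1, 2), "u": (3, 4)})


class TestBark:
    def test_reference_values(self):
        assert hz_to_bark(1960.0) == pytest.approx(12.875, abs=5e-4)
        assert hz_to_bark(1000.0) == pytest.approx(8.527, abs=5e-4)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(1.0, 20000.0), st.floats(0.01, 5000.0))
    def test_strictly_increasing(self, f, step):
        assert hz_to_bark(f + step) > hz_to_bark(f)

    def test_nonpositive_frequency_errors(self):
        with pytest.raises(ValueError):
            hz_to_bark(0.0)


class TestMeansAndDifference:
    def _tokens(self):
        toks = []
        for vowel, (f1, f2) in ADS_MEANS.items():
            toks.append(make_token(vowel=vowel, f1=f1, f2=f2, register="ADS"))
        for vowel, (f1, f2) in IDS_MEANS.items():
            toks.append(make_token(vowel=vowel, f1=f1, f2=f2, register="IDS"))
        return toks

    def test_single_token_means_equal_tokens(self):
        means = point_vowel_means(self._tokens(), "s1", "IDS")
        assert means == {v: pytest.approx(m) for v, m in IDS_MEANS.items()}

    def test_two_token_mean(self):
        toks = [make_token(vowel="i", f1=440.0, f2=1900.0),
                make_token(vowel="i", f1=466.0, f2=2000.0),
                make_token(vowel="ɑ", f1=650.0, f2=1300.0),
                make_token(vowel="u", f1=430.0, f2=900.0)]
        means = point_vowel_means(toks, "s1", "IDS")
        assert means["i"] == pytest.approx((453.0, 1950.0))

    def test_open_vowel_alias(self):
        tok = make_token(vowel="a")
        assert tok.vowel == "ɑ"

    def test_bark_converts_each_token_before_averaging(self):
        toks = [make_token(vowel="i", f1=400.0, f2=1000.0),
                make_token(vowel="i", f1=500.0, f2=1960.0),
                make_token(vowel="ɑ", f1=650.0, f2=1300.0),
                make_token(vowel="u", f1=430.0, f2=900.0)]
        means = point_vowel_means(toks, "s1", "IDS", scale="bark")
        expected_f2 = (hz_to_bark(1000.0) + hz_to_bark(1960.0)) / 2
        assert means["i"][1] == pytest.approx(expected_f2)
        # converting the averaged Hz value instead would differ (concavity)
        assert means["i"][1] != pytest.approx(hz_to_bark(1480.0), abs=1e-3)

    def test_missing_category_names_the_vowel(self):
        toks = [make_token(vowel="i"), make_token(vowel="ɑ")]
        with pytest.raises(ValueError, match="/u/"):
            point_vowel_means(toks, "s1", "IDS")

    def test_difference_is_signed_and_exact(self):
        toks = self._tokens()
        ids = speaker_vsa(toks, "s1", "IDS")
        ads = speaker_vsa(toks, "s1", "ADS")
        d = vsa_difference(ids, ads)
        assert d.difference == pytest.approx(112_130.5 - 82_105.5)
        # swapped registers preserve a negative difference
        flipped = vsa_difference(
            speaker_vsa([make_token(vowel=v, f1=f1, f2=f2, register="IDS")
                         for v, (f1, f2) in ADS_MEANS.items()], "s1", "IDS"),
            speaker_vsa([make_token(vowel=v, f1=f1, f2=f2, register="ADS")
                         for v, (f1, f2) in IDS_MEANS.items()], "s1", "ADS"),
        )
        assert flipped.difference == pytest.approx(-(112_130.5 - 82_105.5))

    def test_scale_mismatch_errors(self):
        toks = self._tokens()
        ids = speaker_vsa(toks, "s1", "IDS", scale="bark")
        ads = speaker_vsa(toks, "s1", "ADS", scale="hz")
        with pytest.raises(ValueError, match="scale mismatch"):
            vsa_difference(ids, ads)

    def test_equal_areas_give_zero(self):
        toks = self._tokens()
        ids = speaker_vsa(
            [make_token(vowel=v, f1=f1, f2=f2, register="IDS")
             for v, (f1, f2) in ADS_MEANS.items()], "s1", "IDS")
        ads = speaker_vsa(toks, "s1", "ADS")
        assert vsa_difference(ids, ads).difference == pytest.approx(0.0)
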