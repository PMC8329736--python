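import numpy as np
import pytest

from hypervoc.analysis import run_study
from hypervoc.config import StudyConfig
from hypervoc.simulate import (
    SimulationConfig,
    calibrate_probs,
    expected_score,
    simulate_study,
    simulate_tokens,
    simulate_vocalizations,
    speaker_profile,
)
from hypervoc.transcribe import parse_transcription
from hypervoc.vowelspace import exclude_high_f0, speaker_vsa
from hypervoc.wcm import score_vocalization


def noiseless_config(**kw):
    defaults = dict(
        between_sd_f1=0.0, between_sd_f2=0.0, ids_jitter_f1=0.0, ids_jitter_f2=0.0,
        within_sd_f1=0.0, within_sd_f2=0.0, ramp_fraction=0.0, f0_exceed_rate=0.0,
        resid_sd=0.0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestAcousticGenerator:
    def test_expansion_scales_area_quadratically(self, rng):
        cfg = noiseless_config(expansion_factor=1.36)
        profile = speaker_profile(cfg, "s1", rng)
        assert profile.vsa_ids == pytest.approx(1.36**2 * profile.vsa_ads, rel=1e-12)

    def test_zero_noise_pipeline_recovers_truth_exactly(self, rng):
        cfg = noiseless_config(tokens_per_vowel=3)
        profile = speaker_profile(cfg, "s1", rng)
        tokens = []
        for register in ("IDS", "ADS"):
            tokens += simulate_tokens(cfg, "s1", register, rng,
                                      means=profile.means[register])
        kept, excluded = exclude_high_f0(tokens)
        assert excluded == []
        ids = speaker_vsa(kept, "s1", "IDS")
        ads = speaker_vsa(kept, "s1", "ADS")
        assert ids.area == pytest.approx(profile.vsa_ids, rel=1e-9)
        assert ads.area == pytest.approx(profile.vsa_ads, rel=1e-9)

    def test_ramped_tracks_still_unbiased_in_window(self, rng):
        # ramps cover 25% at each edge; the mid-40% window sees only steady state
        cfg = noiseless_config(ramp_fraction=0.25, tokens_per_vowel=2)
        profile = speaker_profile(cfg, "s1", rng)
        tokens = simulate_tokens(cfg, "s1", "ADS", rng, means=profile.means["ADS"])
        ads = speaker_vsa(tokens, "s1", "ADS")
        assert ads.area == pytest.approx(profile.vsa_ads, rel=1e-6)

    def test_f0_exceedance_rate(self, rng):
        cfg = SimulationConfig(f0_exceed_rate=0.2, tokens_per_vowel=334)
        tokens = simulate_tokens(cfg, "s1", "IDS", rng)
        _, excluded = exclude_high_f0(tokens)
        n = len(tokens)
        rate = len(excluded) / n
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(rate - 0.2) < 3 * se

    def test_track_structure(self, rng):
        cfg = SimulationConfig(tokens_per_vowel=1)
        tok = simulate_tokens(cfg, "s1", "IDS", rng)[0]
        assert tok.track is not None
        assert len(tok.track) >= 3
        assert np.all(np.diff(tok.track.times) > 0)


class TestVocalizationGenerator:
    def test_target_zero_scores_zero(self, inventory):
        for text in simulate_vocalizations(0.0, 50, SimulationConfig(), 3):
            assert score_vocalization(parse_transcription(text, inventory)).total == 0

    def test_pure_trill_scores_exactly_three(self, inventory):
        cfg = SimulationConfig(feature_probs={"trill": 1.0})
        for text in simulate_vocalizations(3.0, 50, cfg, 3):
            s = score_vocalization(parse_transcription(text, inventory))
            assert s.total == 3
            assert s.breakdown["trill"] == 3

    def test_empirical_mean_matches_closed_form(self, inventory, rng):
        target = 1.23
        n = 4000
        texts = simulate_vocalizations(target, n, SimulationConfig(), 11)
        scores = np.array(
            [score_vocalization(parse_transcription(t, inventory)).total for t in texts]
        )
        se = scores.std(ddof=1) / np.sqrt(n)
        assert abs(scores.mean() - target) < 3 * se

    def test_calibration_hits_target_exactly_in_expectation(self):
        base = SimulationConfig().feature_probs
        for target in (0.3, 1.23, 2.13, 4.69):
            probs = calibrate_probs(target, base)
            assert expected_score(probs) == pytest.approx(target, abs=1e-9)

    def test_unreachable_target_errors(self):
        with pytest.raises(ValueError, match="unreachable"):
            simulate_vocalizations(500.0, 1, SimulationConfig(), 0)

    def test_corpus_mean_converges_with_n(self, inventory):
        # LLN: deviation shrinks as the corpus grows
        cfg = SimulationConfig()
        devs = []
        for n in (50, 3200):
            texts = simulate_vocalizations(1.5, n, cfg, 5)
            scores = [
                score_vocalization(parse_transcription(t, inventory)).total
                for t in texts
            ]
            devs.append(abs(np.mean(scores) - 1.5))
        assert devs[1] < max(devs[0], 0.1)


class TestStudyGenerator:
    def test_ground_truth_consistent_with_profiles(self):
        ds = simulate_study(SimulationConfig(n_dyads=4, tokens_per_vowel=2,
                                             vocalizations_per_infant=5), 9)
        for p in ds.profiles:
            t = ds.truth[p.speaker_id]
            assert t["difference"] == pytest.approx(p.vsa_ids - p.vsa_ads)

    def test_round_trips_pipeline_without_errors(self, inventory):
        ds = simulate_study(SimulationConfig(n_dyads=6, tokens_per_vowel=4,
                                             vocalizations_per_infant=8), 13)
        vocs = [
            parse_transcription(t, inventory, subject_id=s)
            for s, _, t in ds.transcriptions
        ]
        res = run_study(ds.tokens, vocs, StudyConfig(scales=("hz", "bark")))
        assert res.audit["vocalizations_scored"] == len(vocs)
        assert res.scales["hz"].paired_test.n == 6

    def test_null_expansion_gives_centered_slope_and_diff(self, inventory):
        # beta_true = 0 and no expansion: fitted slopes center on zero
        cfg = SimulationConfig(n_dyads=12, tokens_per_vowel=4,
                               vocalizations_per_infant=8,
                               expansion_factor=1.0, beta_true=0.0)
        slopes = []
        for rep in range(12):
            ds = simulate_study(cfg, 300 + rep)
            vocs = [
                parse_transcription(t, inventory, subject_id=s)
                for s, _, t in ds.transcriptions
            ]
            res = run_study(ds.tokens, vocs, StudyConfig())
            slopes.append(res.scales["hz"].regression.beta)
        slopes = np.array(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean()) < 3 * se + 1e-12

    def test_slope_recovery_low_noise(self, inventory):
        cfg = SimulationConfig(n_dyads=60, within_sd_f1=5.0, within_sd_f2=5.0,
                               tokens_per_vowel=8, vocalizations_per_infant=15,
                               resid_sd=0.1)
        betas = []
        for rep in range(5):
            ds = simulate_study(cfg, 700 + rep)
            vocs = [
                parse_transcription(t, inventory, subject_id=s)
                for s, _, t in ds.transcriptions
            ]
            res = run_study(ds.tokens, vocs, StudyConfig())
            betas.append(res.scales["hz"].regression.beta)
        assert np.mean(betas) == pytest.approx(cfg.beta_true, rel=0.15)

    def test_determinism_same_seed_same_dataset(self):
        cfg = SimulationConfig(n_dyads=3, tokens_per_vowel=2,
                               vocalizations_per_infant=4)
        a = simulate_study(cfg, 77)
        b = simulate_study(cfg, 77)
        assert a.transcriptions == b.transcriptions
        assert [t.median_f0 for t in a.tokens] == [t.median_f0 for t in b.tokens]
        assert a.truth == b.truth
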