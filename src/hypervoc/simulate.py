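"""Synthetic parent-infant study generator.

Generates the two inputs the analysis pipeline consumes — a parent
vowel-token table (with formant tracks) and an infant transcription
corpus — with the statistical structure the analysis assumes, so that
every stage, and the headline association between parental vowel-space
expansion and infant vocalization complexity, can be tested end to end
without any recordings.

Acoustic model
--------------
Each speaker's ADS point-vowel means are drawn around configurable
anchors (defaulting to published grand means for Swedish parents) with
between-speaker spread; the same speaker's IDS triangle is the ADS
triangle expanded linearly about its centroid by ``expansion_factor``
(area therefore scales with the factor squared), plus register-specific
jitter.  Tokens get steady-state formants around the speaker mean,
linear coarticulation ramps from a neutral locus at both edges of the
track, and a median f0 drawn to straddle the 350 Hz exclusion ceiling
at a configurable rate.

Complexity model
----------------
Infant vocalizations are built from a zero-complexity CV.CV frame into
which independent Bernoulli "features" inject exactly one scoring
parameter each (a trill onset, a liquid onset, a cluster, a final
consonant, a third syllable, non-initial stress, ...).  The expected
score under given feature probabilities has a closed form (the one
coupled term — the extra cluster arising when two or more sound-class
onsets co-occur in the same run — is handled by inclusion–exclusion),
so probabilities can be calibrated exactly to any reachable target
mean.  Each infant's target is ``intercept + beta_true × (true VSA
difference) + noise``, which makes the fitted regression slope an
estimate of ``beta_true``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .vowelspace import POINT_VOWELS, FormantTrack, VowelToken, vsa

__all__ = [
    "SimulationConfig",
    "SpeakerProfile",
    "SyntheticDataset",
    "expected_score",
    "calibrate_probs",
    "simulate_tokens",
    "simulate_vocalizations",
    "simulate_study",
    "speaker_profile",
]

#: Anchor ADS grand means (F1, F2) in Hz for /i/, /ɑ/, /u/.
ADS_ANCHORS = {"i": (472.0, 1904.0), "ɑ": (661.0, 1307.0), "u": (473.0, 1032.0)}

# Zero-complexity building material: phones that earn no sound-class points.
_ZERO_CONSONANTS = ("m", "n", "p", "b", "t", "d")
_ZERO_VOWELS = ("a", "e", "o", "ɛ")
_LFR_VOWELS = ("yː", "øː", "ʉː")

#: WCM features the generator can inject, with the onset symbol used by
#: the sound-class features (run order is fixed for determinism).
_CLASS_FEATURES = (
    ("trill", "r", 3),
    ("liquid", "l", 1),
    ("fricative", "s", 1),
    ("velar", "k", 1),
    ("voiced_fricative", "v", 2),  # fricative + voiced fricative
)
_STRUCT_FEATURES = ("polysyllabic", "stress", "final_consonant", "cluster", "lfr_vowel")

FEATURES = tuple(name for name, _, _ in _CLASS_FEATURES) + _STRUCT_FEATURES

_DEFAULT_FEATURE_PROBS = {
    "trill": 0.12,
    "liquid": 0.30,
    "fricative": 0.30,
    "velar": 0.25,
    "voiced_fricative": 0.10,
    "polysyllabic": 0.25,
    "stress": 0.20,
    "final_consonant": 0.30,
    "cluster": 0.20,
    "lfr_vowel": 0.08,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-generator parameters (all frequencies in Hz)."""

    n_dyads: int = 19
    ads_means: dict = field(default_factory=lambda: dict(ADS_ANCHORS))
    between_sd_f1: float = 60.0
    between_sd_f2: float = 150.0
    ids_jitter_f1: float = 30.0
    ids_jitter_f2: float = 75.0
    within_sd_f1: float = 60.0
    within_sd_f2: float = 170.0
    tokens_per_vowel: int = 20
    expansion_factor: float = 1.36  # linear, about the ADS-triangle centroid
    f0_exceed_rate: float = 0.10  # fraction of tokens with median f0 > 350 Hz
    f0_low_range: tuple[float, float] = (170.0, 345.0)
    f0_high_range: tuple[float, float] = (355.0, 450.0)
    ramp_fraction: float = 0.25  # coarticulated edge fraction at each end
    locus: tuple[float, float] = (500.0, 1500.0)  # ramp origin (F1, F2)
    sample_step: float = 0.00625  # seconds between formant samples
    duration_range: tuple[float, float] = (0.08, 0.25)
    beta_true: float = 8e-6  # points per Hz² of VSA difference
    intercept: float = 1.0  # points
    resid_sd: float = 0.42  # subject-level noise on expected mean score
    vocalizations_per_infant: int = 30
    feature_probs: dict = field(
        default_factory=lambda: dict(_DEFAULT_FEATURE_PROBS)
    )

    def __post_init__(self) -> None:
        for name, value in (
            ("between_sd_f1", self.between_sd_f1),
            ("between_sd_f2", self.between_sd_f2),
            ("within_sd_f1", self.within_sd_f1),
            ("within_sd_f2", self.within_sd_f2),
            ("resid_sd", self.resid_sd),
        ):
            if value < 0:
                raise ValueError(f"{name} must be ≥ 0")
        if not self.expansion_factor > 0:
            raise ValueError("expansion_factor must be positive")
        if not 0 <= self.f0_exceed_rate <= 1:
            raise ValueError("f0_exceed_rate must be in [0, 1]")
        if not 0 <= self.ramp_fraction < 0.5:
            raise ValueError("ramp_fraction must be in [0, 0.5)")
        unknown = set(self.feature_probs) - set(FEATURES)
        if unknown:
            raise ValueError(f"unknown feature probabilities {sorted(unknown)}")
        for name, p in self.feature_probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"feature probability {name}={p} outside [0, 1]")


@dataclass(frozen=True)
class SpeakerProfile:
    """Ground-truth per-speaker vowel means and areas."""

    speaker_id: str
    means: dict  # register -> vowel -> (F1, F2)
    vsa_ids: float
    vsa_ads: float

    @property
    def difference(self) -> float:
        return self.vsa_ids - self.vsa_ads


@dataclass(frozen=True)
class SyntheticDataset:
    tokens: list
    transcriptions: list  # (subject_id, vocalization_id, string)
    profiles: list
    truth: dict  # speaker_id -> {vsa_ids, vsa_ads, difference, expected_wcm}
    config: SimulationConfig
    seed: int


def _expand_about_centroid(means: dict, factor: float) -> dict:
    pts = np.array([means[v] for v in POINT_VOWELS])
    centroid = pts.mean(axis=0)
    expanded = centroid + factor * (pts - centroid)
    return {v: tuple(expanded[k]) for k, v in enumerate(POINT_VOWELS)}


def speaker_profile(
    config: SimulationConfig, speaker_id: str, rng: np.random.Generator
) -> SpeakerProfile:
    """Draw one speaker's true ADS and IDS point-vowel mean triangles."""
    ads = {
        v: (
            m[0] + rng.normal(0, config.between_sd_f1),
            m[1] + rng.normal(0, config.between_sd_f2),
        )
        for v, m in config.ads_means.items()
    }
    ids = _expand_about_centroid(ads, config.expansion_factor)
    ids = {
        v: (
            m[0] + rng.normal(0, config.ids_jitter_f1),
            m[1] + rng.normal(0, config.ids_jitter_f2),
        )
        for v, m in ids.items()
    }
    return SpeakerProfile(
        speaker_id=speaker_id,
        means={"ADS": ads, "IDS": ids},
        vsa_ids=vsa(ids),
        vsa_ads=vsa(ads),
    )


def _draw_track(
    config: SimulationConfig,
    steady_f1: float,
    steady_f2: float,
    rng: np.random.Generator,
) -> FormantTrack:
    d = rng.uniform(*config.duration_range)
    times = np.arange(0.0, d + 1e-12, config.sample_step)
    if len(times) < 3:
        times = np.linspace(0.0, d, 3)
    r = config.ramp_fraction

    def shape(steady: float, locus: float) -> np.ndarray:
        vals = np.full_like(times, steady)
        if r > 0:
            edge = r * d
            onset = times < edge
            vals[onset] = locus + (steady - locus) * (times[onset] / edge)
            offset = times > d - edge
            vals[offset] = locus + (steady - locus) * ((d - times[offset]) / edge)
        return np.maximum(vals, 50.0)

    return FormantTrack(times=times, f1=shape(steady_f1, config.locus[0]),
                        f2=shape(steady_f2, config.locus[1]))


def simulate_tokens(
    config: SimulationConfig,
    speaker_id: str,
    register: str,
    seed: int | np.random.Generator,
    means: dict | None = None,
) -> list[VowelToken]:
    """Generate one speaker/register's vowel tokens.

    ``means`` (vowel → (F1, F2)) defaults to a fresh speaker profile's
    means for the register, drawn from the same generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if means is None:
        means = speaker_profile(config, speaker_id, rng).means[register]
    tokens = []
    for vowel in POINT_VOWELS:
        mf1, mf2 = means[vowel]
        for k in range(config.tokens_per_vowel):
            f1 = max(mf1 + rng.normal(0, config.within_sd_f1), 100.0)
            f2 = max(mf2 + rng.normal(0, config.within_sd_f2), 300.0)
            if rng.uniform() < config.f0_exceed_rate:
                f0 = rng.uniform(*config.f0_high_range)
            else:
                f0 = rng.uniform(*config.f0_low_range)
            tokens.append(
                VowelToken(
                    speaker_id=speaker_id,
                    register=register,
                    vowel=vowel,
                    median_f0=float(f0),
                    track=_draw_track(config, f1, f2, rng),
                    token_id=f"{speaker_id}_{register}_{vowel}_{k}",
                )
            )
    return tokens


# --------------------------------------------------------------------
# Infant corpus generation


def expected_score(probs: dict) -> float:
    """Closed-form expected WCM-SE score under the feature model.

    Every feature contributes its point value times its probability;
    additionally, when at least two sound-class onsets are active they
    form a consonant run, earning one extra cluster point with
    probability P(≥2 active) = 1 − Π(1−pᵢ) − Σᵢ pᵢ Πⱼ≠ᵢ(1−pⱼ).
    """
    p = {name: probs.get(name, 0.0) for name in FEATURES}
    e = sum(points * p[name] for name, _, points in _CLASS_FEATURES)
    e += sum(p[name] for name in _STRUCT_FEATURES)
    class_p = [p[name] for name, _, _ in _CLASS_FEATURES]
    none_active = float(np.prod([1 - q for q in class_p]))
    one_active = sum(
        q * float(np.prod([1 - r for j, r in enumerate(class_p) if j != i]))
        for i, q in enumerate(class_p)
    )
    e += 1 - none_active - one_active
    return e


def calibrate_probs(target: float, base_probs: dict) -> dict:
    """Scale ``base_probs`` by a common factor so the expected score hits ``target``.

    Raises if the target is negative or unreachable (above the score
    expectation with every feature probability saturated at 1).
    """
    if target < 0:
        raise ValueError("target expected score must be ≥ 0")
    if target == 0:
        return {name: 0.0 for name in FEATURES}
    active = {n: q for n, q in base_probs.items() if q > 0}
    if not active:
        raise ValueError("no feature has positive base probability")
    lam_hi = 1.0 / min(active.values())  # every active feature saturated

    def probs_at(lam: float) -> dict:
        return {n: min(1.0, lam * q) for n, q in base_probs.items()}

    e_max = expected_score(probs_at(lam_hi))
    if target > e_max + 1e-12:
        raise ValueError(
            f"target {target} unreachable (maximum expected score {e_max:.3f} "
            "under these base probabilities)"
        )
    if abs(target - e_max) <= 1e-12:
        return probs_at(lam_hi)
    lam = brentq(lambda l: expected_score(probs_at(l)) - target, 0.0, lam_hi)
    return probs_at(lam)


def _one_vocalization(probs: dict, rng: np.random.Generator) -> str:
    on = {name: rng.uniform() < probs.get(name, 0.0) for name in FEATURES}
    zc = lambda: str(rng.choice(_ZERO_CONSONANTS))
    zv = lambda: str(rng.choice(_ZERO_VOWELS))

    onset1 = zc() + zc() if on["cluster"] else zc()
    run = "".join(sym for name, sym, _ in _CLASS_FEATURES if on[name])
    onset2 = run if run else zc()
    v2 = str(rng.choice(_LFR_VOWELS)) if on["lfr_vowel"] else zv()

    syllables = [onset1 + zv(), onset2 + v2]
    if on["polysyllabic"]:
        syllables.append(zc() + zv())
    if on["final_consonant"]:
        syllables[-1] += zc()
    if on["stress"]:
        syllables[1] = "ˈ" + syllables[1]
    return ".".join(syllables)


def simulate_vocalizations(
    target_expected_score: float,
    n: int,
    config: SimulationConfig,
    seed: int | np.random.Generator,
) -> list[str]:
    """Generate ``n`` transcription strings with expected score ``target_expected_score``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = calibrate_probs(target_expected_score, config.feature_probs)
    return [_one_vocalization(probs, rng) for _ in range(n)]


def simulate_study(config: SimulationConfig, seed: int) -> SyntheticDataset:
    """Generate a full synthetic study: token table, corpora and ground truth."""
    rng = np.random.default_rng(seed)
    tokens: list[VowelToken] = []
    transcriptions: list[tuple[str, str, str]] = []
    profiles: list[SpeakerProfile] = []
    truth: dict[str, dict] = {}
    width = max(2, len(str(config.n_dyads)))
    for d in range(config.n_dyads):
        sid = f"dyad{d:0{width}d}"
        profile = speaker_profile(config, sid, rng)
        profiles.append(profile)
        for register in ("IDS", "ADS"):
            tokens.extend(
                simulate_tokens(config, sid, register, rng, means=profile.means[register])
            )
        target = (
            config.intercept
            + config.beta_true * profile.difference
            + rng.normal(0, config.resid_sd)
        )
        target = max(target, 0.0)
        for vid, text in enumerate(
            simulate_vocalizations(target, config.vocalizations_per_infant, config, rng)
        ):
            transcriptions.append((sid, f"{sid}_v{vid:03d}", text))
        truth[sid] = {
            "vsa_ids": profile.vsa_ids,
            "vsa_ads": profile.vsa_ads,
            "difference": profile.difference,
            "expected_wcm": target,
        }
    return SyntheticDataset(
        tokens=tokens,
        transcriptions=transcriptions,
        profiles=profiles,
        truth=truth,
        config=config,
        seed=seed,
    )
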