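"""Vowel space area (VSA) from point-vowel formant measurements.

The vowel space is the triangle spanned by a speaker's mean (F1, F2)
for the point vowels /i/, /ɑ/ and /u/.  Its area is

    VSA = |iF1·(ɑF2 − uF2) + ɑF1·(uF2 − iF2) + uF1·(iF2 − ɑF2)| / 2

in Hz² (or Bark² after per-token conversion).  Hyperarticulation in
infant-directed speech (IDS) relative to adult-directed speech (ADS) is
the signed per-speaker difference VSA_IDS − VSA_ADS.

Token processing follows the acoustic-reliability conventions of the
IDS literature: tokens whose median fundamental frequency exceeds
350 Hz are excluded (formant estimates degrade at high f0), and each
token's formants are averaged over the middle 40% of the vowel's
duration to reduce the influence of coarticulated edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "POINT_VOWELS",
    "FormantTrack",
    "VowelToken",
    "SpeakerVSA",
    "VSADifference",
    "exclude_high_f0",
    "mid_window_mean",
    "hz_to_bark",
    "point_vowel_means",
    "vsa",
    "speaker_vsa",
    "vsa_difference",
]

POINT_VOWELS = ("i", "ɑ", "u")
REGISTERS = ("IDS", "ADS")

_VOWEL_ALIASES = {"a": "ɑ"}  # the open point vowel appears as both /a/ and /ɑ/

F0_MAX_DEFAULT = 350.0  # Hz; median f0 above this → token excluded
MID_WINDOW_FRACTION = 0.4  # central fraction of the vowel used for averaging


@dataclass(frozen=True)
class FormantTrack:
    """Time-stamped F1/F2 samples over one vowel token."""

    times: np.ndarray
    f1: np.ndarray
    f2: np.ndarray
    f0: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f1 = np.asarray(self.f1, dtype=float)
        f2 = np.asarray(self.f2, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "f1", f1)
        object.__setattr__(self, "f2", f2)
        if self.f0 is not None:
            object.__setattr__(self, "f0", np.asarray(self.f0, dtype=float))
        if t.ndim != 1 or len(t) < 1:
            raise ValueError("track must hold at least one sample")
        if len(f1) != len(t) or len(f2) != len(t):
            raise ValueError("times, f1 and f2 must have equal length")
        if self.f0 is not None and len(self.f0) != len(t):
            raise ValueError("f0 track length mismatch")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(f1 <= 0) or np.any(f2 <= 0):
            raise ValueError("formant frequencies must be positive")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class VowelToken:
    """One vowel production by one speaker in one register."""

    speaker_id: str
    register: str
    vowel: str
    median_f0: float
    track: FormantTrack | None = None
    point_f1: float | None = None
    point_f2: float | None = None
    token_id: str = ""

    def __post_init__(self) -> None:
        if self.register not in REGISTERS:
            raise ValueError(f"register must be one of {REGISTERS}, got {self.register!r}")
        vowel = _VOWEL_ALIASES.get(self.vowel, self.vowel)
        object.__setattr__(self, "vowel", vowel)
        if vowel not in POINT_VOWELS:
            raise ValueError(f"vowel must be a point vowel {POINT_VOWELS}, got {vowel!r}")
        if not self.median_f0 > 0:
            raise ValueError("median_f0 must be positive")
        if self.track is None and (self.point_f1 is None or self.point_f2 is None):
            raise ValueError("token needs a formant track or point F1/F2 estimates")


@dataclass(frozen=True)
class SpeakerVSA:
    """Per-speaker, per-register point-vowel means and triangle area."""

    speaker_id: str
    register: str
    means: dict[str, tuple[float, float]]  # vowel -> (F1, F2)
    area: float
    n_tokens: dict[str, int]
    scale: str  # "hz" | "bark"


@dataclass(frozen=True)
class VSADifference:
    speaker_id: str
    vsa_ids: float
    vsa_ads: float
    difference: float
    scale: str


def exclude_high_f0(
    tokens: list[VowelToken], threshold: float = F0_MAX_DEFAULT
) -> tuple[list[VowelToken], list[VowelToken]]:
    """Partition tokens into (kept, excluded) by the median-f0 ceiling.

    A token is excluded when its median f0 strictly exceeds ``threshold``
    (a median of exactly 350 Hz is kept at the default).
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    kept = [t for t in tokens if t.median_f0 <= threshold]
    excluded = [t for t in tokens if t.median_f0 > threshold]
    return kept, excluded


def mid_window_mean(
    track: FormantTrack, fraction: float = MID_WINDOW_FRACTION
) -> tuple[float, float]:
    """Mean (F1, F2) over the central ``fraction`` of the track's duration.

    Samples are selected by timestamp: with onset t0 and duration d, the
    closed window is [t0 + (1−fraction)/2·d, t0 + (1+fraction)/2·d].  If
    no sample falls inside (sparse or single-sample tracks), the sample
    nearest the temporal midpoint is used.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    t = track.times
    t0, t1 = t[0], t[-1]
    lo = t0 + (1 - fraction) / 2 * (t1 - t0)
    hi = t0 + (1 + fraction) / 2 * (t1 - t0)
    inside = (t >= lo) & (t <= hi)
    if not inside.any():
        mid = (t0 + t1) / 2
        inside = np.zeros(len(t), dtype=bool)
        inside[np.argmin(np.abs(t - mid))] = True
    return float(track.f1[inside].mean()), float(track.f2[inside].mean())


def hz_to_bark(f):
    """Convert frequency in Hz to the Bark auditory scale.

    Uses z = 26.81·f/(1960 + f) − 0.53 with the standard edge
    corrections (z < 2: z + 0.15·(2 − z); z > 20.1: z + 0.22·(z − 20.1)).
    Strictly increasing in f.  Accepts scalars or arrays.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    z = 26.81 * f / (1960.0 + f) - 0.53
    z = np.where(z < 2.0, z + 0.15 * (2.0 - z), z)
    z = np.where(z > 20.1, z + 0.22 * (z - 20.1), z)
    return float(z) if z.ndim == 0 else z


def _token_estimate(token: VowelToken, fraction: float) -> tuple[float, float]:
    if token.track is not None:
        return mid_window_mean(token.track, fraction)
    return float(token.point_f1), float(token.point_f2)


def point_vowel_means(
    tokens: list[VowelToken],
    speaker_id: str,
    register: str,
    scale: str = "hz",
    fraction: float = MID_WINDOW_FRACTION,
) -> dict[str, tuple[float, float]]:
    """Per-vowel mean (F1, F2) for one speaker and register.

    Each token contributes its mid-window mean (or its supplied point
    estimate); on the Bark scale each token is converted *before*
    averaging.  Raises if any point vowel has no token.
    """
    if scale not in ("hz", "bark"):
        raise ValueError(f"scale must be 'hz' or 'bark', got {scale!r}")
    per_vowel: dict[str, list[tuple[float, float]]] = {v: [] for v in POINT_VOWELS}
    for tok in tokens:
        if tok.speaker_id != speaker_id or tok.register != register:
            continue
        est = _token_estimate(tok, fraction)
        if scale == "bark":
            est = (hz_to_bark(est[0]), hz_to_bark(est[1]))
        per_vowel[tok.vowel].append(est)
    for vowel, ests in per_vowel.items():
        if not ests:
            raise ValueError(
                f"speaker {speaker_id!r} register {register}: no tokens for vowel /{vowel}/"
            )
    return {
        v: tuple(np.asarray(ests).mean(axis=0)) for v, ests in per_vowel.items()
    }


def vsa(means: dict[str, tuple[float, float]]) -> float:
    """Triangle area spanned by the /i/, /ɑ/, /u/ mean (F1, F2) points.

    Collinear (degenerate) configurations give 0.
    """
    missing = set(POINT_VOWELS) - set(means)
    if missing:
        raise ValueError(f"missing point vowels: {sorted(missing)}")
    i_f1, i_f2 = means["i"]
    a_f1, a_f2 = means["ɑ"]
    u_f1, u_f2 = means["u"]
    return abs(i_f1 * (a_f2 - u_f2) + a_f1 * (u_f2 - i_f2) + u_f1 * (i_f2 - a_f2)) / 2.0


def speaker_vsa(
    tokens: list[VowelToken],
    speaker_id: str,
    register: str,
    scale: str = "hz",
    fraction: float = MID_WINDOW_FRACTION,
) -> SpeakerVSA:
    """Point-vowel means plus area for one speaker/register (post-exclusion tokens)."""
    means = point_vowel_means(tokens, speaker_id, register, scale, fraction)
    n_tokens = {v: 0 for v in POINT_VOWELS}
    for tok in tokens:
        if tok.speaker_id == speaker_id and tok.register == register:
            n_tokens[tok.vowel] += 1
    return SpeakerVSA(
        speaker_id=speaker_id,
        register=register,
        means=means,
        area=vsa(means),
        n_tokens=n_tokens,
        scale=scale,
    )


def vsa_difference(ids: SpeakerVSA, ads: SpeakerVSA) -> VSADifference:
    """Signed hyperarticulation measure VSA_IDS − VSA_ADS for one speaker."""
    if ids.speaker_id != ads.speaker_id:
        raise ValueError("VSA difference requires the same speaker in both registers")
    if ids.scale != ads.scale:
        raise ValueError(f"scale mismatch: {ids.scale} vs {ads.scale}")
    if (ids.register, ads.register) != ("IDS", "ADS"):
        raise ValueError("arguments must be the IDS and ADS summaries, in that order")
    return VSADifference(
        speaker_id=ids.speaker_id,
        vsa_ids=ids.area,
        vsa_ads=ads.area,
        difference=ids.area - ads.area,
        scale=ids.scale,
    )
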