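import numpy as np
import pytest

from hypervoc.phones import default_inventory


@pytest.fixture(scope="session")
def inventory():
    return default_inventory()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


# ---------------------------------------------------------------------
# Independent flat-recount oracle for WCM-SE, working directly on the
# canonical transcription string (no shared code with the scorer).

_VELAR = set("kgŋɧ")
_LIQUID = set("lɭɹ")
_FRICATIVE = set("fvsʐʁʂʝhɧɕ")
_VOICED_FRIC = set("vʐʁʝ")
_TRILL = set("rʀ")
_CONSONANTS = (
    set("pbtdkgmnrfvsʂhjl")
    | {"ʈ", "ɖ", "ɳ", "ŋ", "ʀ", "ɾ", "ʐ", "ʝ", "ʁ", "ɧ", "ɕ", "ɹ", "ɭ"}
)
_VOWELS = set("iyʉueøoɛœɔaɑæəɪʏʊɵ")
_LFR_BASE = set("yøʉ")


def wcm_oracle(canonical: str) -> int:
    """Brute-force WCM-SE recount over a canonical transcription string."""
    syllables = canonical.split(".")
    total = 0
    if len(syllables) > 2:
        total += 1
    stress_idx = next(
        (i for i, s in enumerate(syllables) if s.startswith("ˈ")), None
    )
    if stress_idx is not None and stress_idx > 0:
        total += 1

    # flatten to phone-level flags; ː merges into the preceding char
    flags = []  # 'c' consonant-like, 'v' vowel-like, 'x' indeterminate
    chars = []
    for ch in canonical:
        if ch in ".ˈ":
            continue
        if ch == "ː":
            chars[-1] = chars[-1] + "ː"
            continue
        if ch in _CONSONANTS or ch == "C":
            flags.append("c")
        elif ch in _VOWELS or ch == "V":
            flags.append("v")
        else:
            flags.append("x")
        chars.append(ch)

    if flags and flags[-1] == "c":
        total += 1

    run = 0
    for f in flags:
        if f == "c":
            run += 1
        else:
            if run >= 2:
                total += 1
            run = 0
    if run >= 2:
        total += 1

    for sym in chars:
        base = sym.rstrip("ː")
        total += base in _VELAR
        total += base in _LIQUID
        total += base in _FRICATIVE
        total += base in _VOICED_FRIC
        total += 3 * (base in _TRILL)
        total += sym.endswith("ː") and base in _LFR_BASE
    return total


def random_transcription(rng: np.random.Generator, inventory) -> str:
    """Random syllabified transcription over the full inventory alphabet."""
    cons = sorted(inventory.consonants()) + ["C"]
    vows = sorted(v for v in inventory.vowels() if not v.endswith("ː")) + ["V"]
    n_syll = int(rng.integers(1, 5))
    stress_at = int(rng.integers(0, n_syll)) if rng.uniform() < 0.5 else None
    parts = []
    for i in range(n_syll):
        syl = ""
        for _ in range(int(rng.integers(0, 3))):
            syl += str(rng.choice(cons))
        if rng.uniform() < 0.1:
            syl += "□"
        nucleus = str(rng.choice(vows))
        if nucleus != "V" and rng.uniform() < 0.3:
            nucleus += "ː"
        syl += nucleus
        for _ in range(int(rng.integers(0, 3))):
            syl += str(rng.choice(cons))
        if i == stress_at:
            syl = "ˈ" + syl
        parts.append(syl)
    return ".".join(parts)


def shoelace_area(points) -> float:
    """Generic polygon shoelace area, independent of the VSA formula."""
    pts = list(points)
    n = len(pts)
    acc = 0.0
    for k in range(n):
        x1, y1 = pts[k]
        x2, y2 = pts[(k + 1) % n]
        acc += x1 * y2 - x2 * y1
    return abs(acc) / 2.0
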