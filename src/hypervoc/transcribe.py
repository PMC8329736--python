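"""Parsing of IPA-like infant-vocalization transcriptions.

Transcription dialect
---------------------
* Phones are single Unicode IPA symbols from a :class:`~hypervoc.phones.PhoneInventory`,
  plus the placeholders ``C`` (unidentifiable consonant-like segment),
  ``V`` (vowel-like) and ``□`` (indeterminate).
* ``.`` separates syllables.
* ``ˈ`` before a syllable marks it as carrying primary stress; the ASCII
  apostrophe ``'`` is accepted as an alias.
* A grave or acute accent diacritic on a vowel (``à``, ``á``, combining
  or precomposed) marks that vowel's syllable as stressed; it is
  normalized to the ``ˈ`` notation on output.
* ``ː`` (ASCII ``:`` accepted) attaches to the preceding phone and marks
  it long.

If a transcription contains no syllable delimiters but more than one
vowel nucleus, it is syllabified deterministically by vowel nuclei with
onset maximization: every consonant run between two nuclei joins the
onset of the following syllable.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass

from .phones import (
    LENGTH_MARK,
    Phone,
    PhoneInventory,
    classify_phone,
    default_inventory,
)

__all__ = [
    "ParseError",
    "Syllable",
    "Vocalization",
    "parse_transcription",
    "count_syllables",
    "transcription_agreement",
]

_STRESS = "ˈ"
_SYLLABLE_SEP = "."
_COMBINING_ACCENTS = {"̀", "́"}  # grave, acute
_CHAR_ALIASES = {
    ":": LENGTH_MARK,
    "'": _STRESS,
    "ʼ": _STRESS,
    "ɡ": "g",  # IPA script g
    "☐": "□",
}


class ParseError(ValueError):
    """A transcription could not be parsed.

    Attributes
    ----------
    position:
        0-based index of the offending character in the normalized input,
        or ``None`` for structural errors.
    """

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message if position is None else f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Syllable:
    phones: tuple[Phone, ...]
    stressed: bool = False

    def __post_init__(self) -> None:
        if not self.phones:
            raise ValueError("syllable must contain at least one phone")


@dataclass(frozen=True)
class Vocalization:
    """A parsed, silence-bounded infant vocalization."""

    syllables: tuple[Syllable, ...]
    raw: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not self.syllables:
            raise ValueError("vocalization must contain at least one syllable")
        if sum(s.stressed for s in self.syllables) > 1:
            raise ValueError("at most one primary stress per vocalization")

    @property
    def phones(self) -> tuple[Phone, ...]:
        return tuple(p for s in self.syllables for p in s.phones)

    @property
    def stress_index(self) -> int | None:
        """Index of the stressed syllable, or None if stress is unmarked."""
        for i, s in enumerate(self.syllables):
            if s.stressed:
                return i
        return None

    def canonical(self) -> str:
        """Serialize to the canonical dialect (``ˈ`` stress, ``.`` boundaries)."""
        parts = []
        for syl in self.syllables:
            body = "".join(p.symbol for p in syl.phones)
            parts.append(_STRESS + body if syl.stressed else body)
        return _SYLLABLE_SEP.join(parts)


def _normalize(text: str) -> str:
    text = unicodedata.normalize("NFD", text)
    return "".join(_CHAR_ALIASES.get(ch, ch) for ch in text)


def parse_transcription(
    text: str,
    inventory: PhoneInventory | None = None,
    subject_id: str = "",
) -> Vocalization:
    """Parse a transcription string into a :class:`Vocalization`.

    Raises
    ------
    ParseError
        On an empty input, a symbol outside the inventory, a dangling
        stress mark or length mark, or duplicated primary stress.
    """
    if inventory is None:
        inventory = default_inventory()
    if not text or not text.strip():
        raise ParseError("empty transcription")

    norm = _normalize(text.strip())

    phones: list[Phone] = []  # phones of the current syllable
    syllables: list[Syllable] = []
    stress_next = False  # a ˈ seen, applies to the syllable being opened
    current_stressed = False
    accent_phone_index: int | None = None  # flat index of accent-marked vowel
    saw_delimiter = False
    n_stressed = 0
    flat_count = 0  # phones emitted so far across closed syllables

    def close_syllable(pos: int) -> None:
        nonlocal phones, current_stressed, n_stressed, flat_count
        if not phones:
            raise ParseError("empty syllable", pos)
        if current_stressed:
            n_stressed += 1
            if n_stressed > 1:
                raise ParseError("more than one primary stress", pos)
        syllables.append(Syllable(tuple(phones), stressed=current_stressed))
        flat_count += len(phones)
        phones = []
        current_stressed = False

    for i, ch in enumerate(norm):
        if ch.isspace():
            continue
        if ch == _SYLLABLE_SEP:
            saw_delimiter = True
            close_syllable(i)
            stress_next = False
            continue
        if ch == _STRESS:
            if phones:
                close_syllable(i)
            stress_next = True
            continue
        if ch in _COMBINING_ACCENTS:
            if not phones:
                raise ParseError("accent diacritic with no preceding vowel", i)
            current_stressed = True
            accent_phone_index = flat_count + len(phones) - 1
            continue
        if ch == LENGTH_MARK:
            if not phones:
                raise ParseError("length mark with no preceding phone", i)
            prev = phones[-1]
            if prev.symbol.endswith(LENGTH_MARK):
                raise ParseError("duplicated length mark", i)
            try:
                phones[-1] = classify_phone(prev.symbol + LENGTH_MARK, inventory)
            except KeyError:
                raise ParseError(
                    f"length mark not applicable to {prev.symbol!r}", i
                ) from None
            continue
        if stress_next and not phones:
            current_stressed = True
            stress_next = False
        try:
            phones.append(classify_phone(ch, inventory))
        except KeyError:
            raise ParseError(f"unknown symbol {ch!r}", i) from None

    if stress_next and not phones:
        raise ParseError("stress mark with no following syllable", len(norm) - 1)
    if not phones and not syllables:
        raise ParseError("no phones in transcription")
    if phones:
        close_syllable(len(norm))

    voc = Vocalization(tuple(syllables), raw=text, subject_id=subject_id)

    if not saw_delimiter and any(
        sum(p.is_vocalic for p in s.phones) > 1 for s in voc.syllables
    ):
        voc = _resyllabify(voc, accent_phone_index)
    return voc


def _resyllabify(voc: Vocalization, accent_phone_index: int | None) -> Vocalization:
    """Split undelimited multi-nucleus chunks at vowel nuclei (onset maximization).

    Every non-nucleus run between two nuclei attaches to the following
    syllable's onset; trailing material stays with the last syllable.
    Stress marked on a chunk stays on the sub-syllable holding the
    accented vowel, or on the chunk's first sub-syllable for a ``ˈ`` mark.
    """
    out: list[Syllable] = []
    offset = 0  # flat phone index of the current chunk's first phone
    for syl in voc.syllables:
        nuclei = [i for i, p in enumerate(syl.phones) if p.is_vocalic]
        if len(nuclei) <= 1:
            out.append(syl)
            offset += len(syl.phones)
            continue
        starts = [0] + [n + 1 for n in nuclei[:-1]]  # consonants go rightward
        bounds = starts + [len(syl.phones)]
        target: int | None = None
        if syl.stressed:
            target = 0
            if (
                accent_phone_index is not None
                and offset <= accent_phone_index < offset + len(syl.phones)
            ):
                local = accent_phone_index - offset
                for si in range(len(starts)):
                    if bounds[si] <= local < bounds[si + 1]:
                        target = si
                        break
        for si in range(len(starts)):
            out.append(
                Syllable(tuple(syl.phones[bounds[si] : bounds[si + 1]]), stressed=si == target)
            )
        offset += len(syl.phones)
    return Vocalization(tuple(out), raw=voc.raw, subject_id=voc.subject_id)


def count_syllables(voc: Vocalization) -> int:
    """Number of syllables in a parsed vocalization."""
    return len(voc.syllables)


def transcription_agreement(a: str, b: str) -> float:
    """Percent character agreement between two transcriptions of one vocalization.

    Defined as 100 × (matched characters under an optimal global
    alignment, i.e. the longest common subsequence) divided by the length
    of the longer string.  Symmetric; 100 iff the strings are identical.
    """
    if not a or not b:
        raise ValueError("transcriptions must be non-empty")
    if a == b:
        return 100.0
    # LCS dynamic program over characters
    m, n = len(a), len(b)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [0] * (n + 1)
        ai = a[i - 1]
        for j in range(1, n + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = cur[j - 1] if cur[j - 1] >= prev[j] else prev[j]
        prev = cur
    return 100.0 * prev[n] / max(m, n)
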