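"""Phone inventory and sound-class classification.

A :class:`PhoneInventory` maps IPA symbols to a category (consonant or
vowel) and to the set of complexity-relevant sound classes used by the
WCM-SE scorer (velar, liquid, fricative, voiced fricative, trill, long
front rounded vowel).  The default inventory covers the Swedish phoneme
set used for transcribing infant vocalizations and ships as editable
package data (``data/phone_inventory.tsv``).

Three placeholder symbols are always available regardless of the
inventory file: ``C`` (a segment judged consonant-like but not
identifiable), ``V`` (vowel-like), and ``□`` (indeterminate).  These
carry no sound classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "Phone",
    "PhoneInventory",
    "CONSONANT",
    "VOWEL",
    "UNKNOWN_CONSONANT",
    "UNKNOWN_VOWEL",
    "INDETERMINATE",
    "SOUND_CLASSES",
    "LENGTH_MARK",
    "default_inventory",
    "classify_phone",
]

CONSONANT = "consonant"
VOWEL = "vowel"
UNKNOWN_CONSONANT = "unknown-consonant"
UNKNOWN_VOWEL = "unknown-vowel"
INDETERMINATE = "indeterminate"

#: Sound classes that earn WCM-SE points.
SOUND_CLASSES = frozenset(
    {
        "velar",
        "liquid",
        "fricative",
        "voiced-fricative",
        "trill",
        "long-front-rounded-vowel",
    }
)

LENGTH_MARK = "ː"

_PLACEHOLDER_CATEGORY = {
    "C": UNKNOWN_CONSONANT,
    "V": UNKNOWN_VOWEL,
    "□": INDETERMINATE,
}

_VOWEL_ONLY_CLASSES = {"long-front-rounded-vowel"}


@dataclass(frozen=True)
class Phone:
    """One transcribed segment.

    Attributes
    ----------
    symbol:
        The IPA symbol, including a trailing length mark where present.
    category:
        ``consonant``, ``vowel``, ``unknown-consonant``, ``unknown-vowel``
        or ``indeterminate``.
    classes:
        The WCM-SE sound classes the phone belongs to.  Empty for
        placeholder categories.
    """

    symbol: str
    category: str
    classes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.category in (UNKNOWN_CONSONANT, UNKNOWN_VOWEL, INDETERMINATE):
            if self.classes:
                raise ValueError(
                    f"placeholder phone {self.symbol!r} cannot carry sound classes"
                )
        unknown = set(self.classes) - SOUND_CLASSES
        if unknown:
            raise ValueError(f"unknown sound classes {sorted(unknown)}")
        for cls in self.classes:
            if cls in _VOWEL_ONLY_CLASSES and self.category != VOWEL:
                raise ValueError(f"class {cls!r} requires a vowel, got {self.category}")
            if cls not in _VOWEL_ONLY_CLASSES and self.category != CONSONANT:
                raise ValueError(f"class {cls!r} requires a consonant, got {self.category}")

    @property
    def long(self) -> bool:
        return self.symbol.endswith(LENGTH_MARK)

    @property
    def is_consonantal(self) -> bool:
        """True for known and unknown consonants (cluster/coda membership)."""
        return self.category in (CONSONANT, UNKNOWN_CONSONANT)

    @property
    def is_vocalic(self) -> bool:
        """True for known and unknown vowels (syllable-nucleus membership)."""
        return self.category in (VOWEL, UNKNOWN_VOWEL)


class PhoneInventory:
    """Symbol → (category, sound classes) lookup table.

    Parameters
    ----------
    entries:
        Mapping from symbol to ``(category, classes)``.  Long-vowel
        symbols (base + ``ː``) may be listed explicitly; otherwise a long
        vowel falls back to its base symbol's entry.
    """

    def __init__(self, entries: dict[str, tuple[str, frozenset[str]]]):
        for sym, (cat, classes) in entries.items():
            if cat not in (CONSONANT, VOWEL):
                raise ValueError(f"symbol {sym!r}: invalid category {cat!r}")
            bad = set(classes) - SOUND_CLASSES
            if bad:
                raise ValueError(f"symbol {sym!r}: unknown classes {sorted(bad)}")
        self._entries = dict(entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhoneInventory":
        """Load an inventory from a tab-separated file.

        Expected columns: symbol, category, classes (comma-separated,
        possibly empty), notes (ignored).  Lines starting with ``#`` and
        the header line are skipped.
        """
        entries: dict[str, tuple[str, frozenset[str]]] = {}
        text = Path(path).read_text(encoding="utf-8")
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "symbol":  # header
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
            symbol = fields[0].strip()
            category = fields[1].strip()
            raw_classes = fields[2].strip() if len(fields) > 2 else ""
            classes = frozenset(c.strip() for c in raw_classes.split(",") if c.strip())
            if symbol in entries and entries[symbol][0] != category:
                raise ValueError(
                    f"{path}:{lineno}: symbol {symbol!r} redefined with a conflicting category"
                )
            entries[symbol] = (category, classes)
        return cls(entries)

    def __contains__(self, symbol: str) -> bool:
        try:
            self.lookup(symbol)
        except KeyError:
            return False
        return True

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()

    def lookup(self, symbol: str) -> tuple[str, frozenset[str]]:
        """Resolve a symbol, falling back from ``Xː`` to ``X`` for vowels."""
        if symbol in _PLACEHOLDER_CATEGORY:
            return _PLACEHOLDER_CATEGORY[symbol], frozenset()
        entry = self._entries.get(symbol)
        if entry is not None:
            return entry
        if symbol.endswith(LENGTH_MARK):
            base = self._entries.get(symbol[: -len(LENGTH_MARK)])
            if base is not None:
                return base
        raise KeyError(symbol)

    def base_symbols(self) -> set[str]:
        """Inventory symbols without an attached length mark."""
        return {s for s in self._entries if not s.endswith(LENGTH_MARK)}

    def consonants(self) -> set[str]:
        return {s for s, (c, _) in self._entries.items() if c == CONSONANT}

    def vowels(self) -> set[str]:
        return {s for s, (c, _) in self._entries.items() if c == VOWEL}


def default_inventory() -> PhoneInventory:
    """The packaged Swedish infant-transcription inventory."""
    ref = resources.files("hypervoc").joinpath("data/phone_inventory.tsv")
    with resources.as_file(ref) as path:
        return PhoneInventory.from_tsv(path)


def classify_phone(symbol: str, inventory: PhoneInventory) -> Phone:
    """Build a :class:`Phone` for ``symbol`` using ``inventory``.

    Raises
    ------
    KeyError
        If the symbol is neither in the inventory nor a placeholder.
    """
    category, classes = inventory.lookup(symbol)
    return Phone(symbol=symbol, category=category, classes=classes)
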