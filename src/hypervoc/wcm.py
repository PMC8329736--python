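"""Word Complexity Measure for Swedish (WCM-SE) scoring.

A vocalization earns points over ten complexity parameters in three
domains:

==================  =========================  =================
Domain              Parameter                  Points
==================  =========================  =================
Word patterns       >2 syllables               1 per vocalization
                    Non-initial stress         1 per vocalization
Syllable structure  Word-final consonant       1 per vocalization
                    Consonant cluster          1 per occurrence
Sound classes       Velar consonant            1 per occurrence
                    Liquid                     1 per occurrence
                    Fricative                  1 per occurrence
                    Voiced fricative           1 per occurrence
                    Trill                      3 per occurrence
                    Long front rounded vowel   1 per occurrence
==================  =========================  =================

A phone belonging to several sound classes earns points for each of
them ([v] is both a fricative and a voiced fricative, 2 points; [ɧ] is
both velar and a fricative).  A consonant cluster is a maximal run of
two or more consecutive consonants anywhere in the vocalization,
ignoring syllable boundaries, counting once per run (set
``tautosyllabic_clusters=True`` to count runs within syllables only).
Placeholder consonants (``C``) count for syllable structure (clusters,
final-consonant position) but earn no sound-class points; the
indeterminate placeholder counts for nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .transcribe import Vocalization

__all__ = [
    "PARAMETERS",
    "TRILL_POINTS",
    "WCMScore",
    "SubjectWCMSummary",
    "score_vocalization",
    "score_corpus",
    "subject_mean",
]

#: The ten complexity parameters, in report order.
PARAMETERS = (
    "polysyllabic",
    "non-initial-stress",
    "word-final-consonant",
    "consonant-cluster",
    "velar",
    "liquid",
    "fricative",
    "voiced-fricative",
    "trill",
    "long-front-rounded-vowel",
)

#: Points per occurrence; all parameters are worth 1 except the trill.
TRILL_POINTS = 3

_SOUND_CLASS_PARAMS = (
    "velar",
    "liquid",
    "fricative",
    "voiced-fricative",
    "trill",
    "long-front-rounded-vowel",
)


@dataclass(frozen=True)
class WCMScore:
    """Total WCM-SE points for one vocalization, with the per-parameter split."""

    total: int
    breakdown: dict[str, int]

    def __post_init__(self) -> None:
        if self.total != sum(self.breakdown.values()):
            raise ValueError("total must equal the sum of the breakdown")
        if self.breakdown.get("trill", 0) % TRILL_POINTS != 0:
            raise ValueError(f"trill points must be a multiple of {TRILL_POINTS}")
        for param in ("polysyllabic", "non-initial-stress", "word-final-consonant"):
            if self.breakdown.get(param, 0) not in (0, 1):
                raise ValueError(f"{param} is a 0/1 parameter")


@dataclass(frozen=True)
class SubjectWCMSummary:
    subject_id: str
    n_vocalizations: int
    mean_score: float
    excluded: bool = False
    exclusion_reason: str | None = None


def _cluster_occurrences(voc: Vocalization, tautosyllabic: bool) -> int:
    """Count maximal runs of ≥2 consonantal phones (C placeholder included)."""
    if tautosyllabic:
        groups: Iterable = (syl.phones for syl in voc.syllables)
    else:
        groups = (voc.phones,)
    n = 0
    for phones in groups:
        run = 0
        for p in phones:
            if p.is_consonantal:
                run += 1
            else:
                if run >= 2:
                    n += 1
                run = 0
        if run >= 2:
            n += 1
    return n


def score_vocalization(
    voc: Vocalization, *, tautosyllabic_clusters: bool = False
) -> WCMScore:
    """Score one parsed vocalization.

    A zero total is a valid outcome (e.g. /ˈma.ma/).  Non-initial stress
    requires an explicit stress mark; the long-front-rounded class
    requires the length mark.
    """
    breakdown = {param: 0 for param in PARAMETERS}

    if len(voc.syllables) > 2:
        breakdown["polysyllabic"] = 1
    if voc.stress_index is not None and voc.stress_index > 0:
        breakdown["non-initial-stress"] = 1
    if voc.phones[-1].is_consonantal:
        breakdown["word-final-consonant"] = 1
    breakdown["consonant-cluster"] = _cluster_occurrences(voc, tautosyllabic_clusters)

    for phone in voc.phones:
        for cls in phone.classes:
            points = TRILL_POINTS if cls == "trill" else 1
            breakdown[cls] += points

    return WCMScore(total=sum(breakdown.values()), breakdown=breakdown)


def score_corpus(
    vocalizations: Sequence[Vocalization], *, tautosyllabic_clusters: bool = False
) -> list[WCMScore]:
    """Order-preserving scoring of a corpus."""
    return [
        score_vocalization(v, tautosyllabic_clusters=tautosyllabic_clusters)
        for v in vocalizations
    ]


def subject_mean(subject_id: str, scores: Sequence[WCMScore]) -> SubjectWCMSummary:
    """Arithmetic mean of per-vocalization totals for one subject."""
    if not scores:
        raise ValueError(f"subject {subject_id!r}: no scores to average")
    total = sum(s.total for s in scores)
    return SubjectWCMSummary(
        subject_id=subject_id,
        n_vocalizations=len(scores),
        mean_score=total / len(scores),
    )
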