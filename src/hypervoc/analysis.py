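"""Group-level statistics: register comparison and the complexity regression.

Two questions are answered, mirroring the study design this package
reproduces:

1. Are vowels hyperarticulated in infant-directed speech?  Per-speaker
   vowel space areas are compared between registers with a two-tailed
   paired-samples t-test.
2. Does a parent's articulatory adaptation (VSA_IDS − VSA_ADS) predict
   the phonetic complexity of their infant's vocalizations?  Ordinary
   least squares of per-subject mean WCM-SE score on the VSA difference,
   with an F-test of the slope, optionally after excluding outlying
   subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .config import StudyConfig
from .transcribe import Vocalization
from .vowelspace import (
    VowelToken,
    VSADifference,
    exclude_high_f0,
    speaker_vsa,
    vsa_difference,
)
from .wcm import SubjectWCMSummary, WCMScore, score_vocalization, subject_mean

__all__ = [
    "PipelineError",
    "PairedTestResult",
    "RegressionResult",
    "ScaleResult",
    "StudyResult",
    "paired_t_test",
    "exclude_outliers",
    "fit_regression",
    "predicted_increase",
    "run_study",
]


class PipelineError(RuntimeError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n: int


@dataclass(frozen=True)
class RegressionResult:
    beta: float
    intercept: float
    F: float
    df: tuple[int, int]
    r_squared: float
    p: float
    n: int


@dataclass(frozen=True)
class ScaleResult:
    """Results of both analysis arms on one frequency scale."""

    scale: str
    paired_test: PairedTestResult
    regression: RegressionResult
    differences: list[VSADifference]
    predicted_increase: float | None = None
    predicted_delta: float | None = None


@dataclass(frozen=True)
class StudyResult:
    scales: dict[str, ScaleResult]
    wcm_summaries: list[SubjectWCMSummary]
    outliers: list[SubjectWCMSummary]
    excluded_token_ids: list[str]
    audit: dict[str, int]


def paired_t_test(a, b) -> PairedTestResult:
    """Classical two-tailed paired-samples t-test.

    Raises on fewer than two pairs or zero-variance differences (the
    degenerate case a = b + constant has an undefined t statistic).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D sequences")
    n = len(a)
    if n < 2:
        raise ValueError("paired t-test needs at least two pairs")
    if np.var(a - b) == 0:
        raise ValueError("differences have zero variance; t is undefined")
    res = stats.ttest_rel(a, b)
    return PairedTestResult(
        t=float(res.statistic),
        df=n - 1,
        p=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        n=n,
    )


def exclude_outliers(
    summaries: list[SubjectWCMSummary],
    policy: str = "z",
    k: float = 3.0,
    cutoff: float | None = None,
) -> tuple[list[SubjectWCMSummary], list[SubjectWCMSummary]]:
    """Partition subject summaries into (kept, excluded) by mean score.

    Policies
    --------
    ``none``
        Nothing excluded.
    ``absolute``
        Exclude subjects with mean score > ``cutoff``.
    ``z`` (default)
        Leave-one-out criterion: a subject is excluded when its mean
        score deviates from the mean of the *other* subjects by more
        than ``k`` of their standard deviations.
    """
    if policy == "none":
        return list(summaries), []
    kept: list[SubjectWCMSummary] = []
    excluded: list[SubjectWCMSummary] = []
    if policy == "absolute":
        if cutoff is None:
            raise ValueError("absolute policy requires a cutoff")
        for s in summaries:
            if s.mean_score > cutoff:
                excluded.append(
                    replace(s, excluded=True, exclusion_reason=f"mean score > {cutoff}")
                )
            else:
                kept.append(s)
        return kept, excluded
    if policy == "z":
        values = np.array([s.mean_score for s in summaries], dtype=float)
        for idx, s in enumerate(summaries):
            rest = np.delete(values, idx)
            if len(rest) < 2 or rest.std(ddof=1) == 0:
                kept.append(s)
                continue
            z = abs(s.mean_score - rest.mean()) / rest.std(ddof=1)
            if z > k:
                excluded.append(
                    replace(
                        s,
                        excluded=True,
                        exclusion_reason=f"leave-one-out |z| = {z:.2f} > {k}",
                    )
                )
            else:
                kept.append(s)
        return kept, excluded
    raise ValueError(f"unknown outlier policy {policy!r}")


def fit_regression(x, y) -> RegressionResult:
    """OLS of y on x with intercept, F-test of the slope, and R²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = len(x)
    if n < 3:
        raise ValueError("regression needs at least three observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is not identifiable")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        beta=float(model.params[1]),
        intercept=float(model.params[0]),
        F=float(model.fvalue),
        df=(1, n - 2),
        r_squared=float(model.rsquared),
        p=float(model.f_pvalue),
        n=n,
    )


def predicted_increase(beta: float, delta: float) -> float:
    """Model-predicted change in mean WCM-SE for a ``delta`` change in VSA difference."""
    return beta * delta


def run_study(
    tokens: list[VowelToken],
    vocalizations: list[Vocalization],
    config: StudyConfig | None = None,
) -> StudyResult:
    """Run the full two-arm analysis and return an auditable result.

    Acoustic arm: f0 exclusion → mid-window formant means → per-speaker
    point-vowel means → VSA per register → paired t-test on areas.
    Complexity arm: per-vocalization WCM-SE → per-subject means →
    outlier policy → OLS of mean score on VSA difference.  Speaker IDs
    in the token table and subject IDs in the transcription corpus
    identify the same dyad.
    """
    if config is None:
        config = StudyConfig()
    audit: dict[str, int] = {}

    # --- acoustic arm ------------------------------------------------
    kept_tokens, excluded_tokens = exclude_high_f0(tokens, config.f0_max)
    audit["tokens_read"] = len(tokens)
    audit["tokens_kept"] = len(kept_tokens)
    audit["tokens_excluded_f0"] = len(excluded_tokens)

    speakers = sorted({t.speaker_id for t in kept_tokens})

    # --- complexity arm ----------------------------------------------
    by_subject: dict[str, list[WCMScore]] = {}
    for voc in vocalizations:
        by_subject.setdefault(voc.subject_id, []).append(
            score_vocalization(voc, tautosyllabic_clusters=config.tautosyllabic_clusters)
        )
    audit["vocalizations_scored"] = len(vocalizations)
    summaries = [subject_mean(sid, scores) for sid, scores in sorted(by_subject.items())]
    kept_summaries, outliers = exclude_outliers(
        summaries, policy=config.outlier_policy, k=config.outlier_k,
        cutoff=config.outlier_cutoff,
    )
    audit["subjects_scored"] = len(summaries)
    audit["subjects_excluded_outlier"] = len(outliers)
    mean_by_subject = {s.subject_id: s.mean_score for s in kept_summaries}

    scale_results: dict[str, ScaleResult] = {}
    for scale in config.scales:
        diffs: list[VSADifference] = []
        for spk in speakers:
            try:
                ids = speaker_vsa(kept_tokens, spk, "IDS", scale, config.window_fraction)
                ads = speaker_vsa(kept_tokens, spk, "ADS", scale, config.window_fraction)
            except ValueError as exc:
                raise PipelineError("speaker_vsa", str(exc)) from exc
            diffs.append(vsa_difference(ids, ads))
        try:
            paired = paired_t_test(
                [d.vsa_ids for d in diffs], [d.vsa_ads for d in diffs]
            )
        except ValueError as exc:
            raise PipelineError("paired_t_test", str(exc)) from exc

        pairs = [
            (d.difference, mean_by_subject[d.speaker_id])
            for d in diffs
            if d.speaker_id in mean_by_subject
        ]
        try:
            regression = fit_regression(
                [p[0] for p in pairs], [p[1] for p in pairs]
            )
        except ValueError as exc:
            raise PipelineError("fit_regression", str(exc)) from exc

        pred = None
        if scale == "hz":
            pred = predicted_increase(regression.beta, config.predicted_delta)
        scale_results[scale] = ScaleResult(
            scale=scale,
            paired_test=paired,
            regression=regression,
            differences=diffs,
            predicted_increase=pred,
            predicted_delta=config.predicted_delta if scale == "hz" else None,
        )

    return StudyResult(
        scales=scale_results,
        wcm_summaries=summaries,
        outliers=outliers,
        excluded_token_ids=[t.token_id for t in excluded_tokens],
        audit=audit,
    )
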