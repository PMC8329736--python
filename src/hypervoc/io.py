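"""File formats: token tables, formant tracks, transcription corpora, reports.

Primary formats are plain text: a CSV token table (one row per vowel
token, formants either inline as ``f1``/``f2`` columns or referenced as
a per-token track CSV of ``time,f1,f2[,f0]`` rows), a UTF-8 TSV
transcription table (``subject_id``, ``vocalization_id``,
``transcription``), and a JSON study report.  Optional readers accept
Praat TextGrid interval tiers and ELAN EAF annotation tiers, mapping
one non-empty annotation to one vocalization.

Readers validate row by row and collect rejects with row numbers
instead of failing fast, so a corpus with a few bad rows still yields
the good ones plus an audit trail.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from lxml import etree

from .analysis import StudyResult
from .phones import PhoneInventory
from .transcribe import ParseError, Vocalization, parse_transcription
from .vowelspace import FormantTrack, VowelToken

__all__ = [
    "ReadReport",
    "read_token_table",
    "read_track",
    "read_transcriptions",
    "read_textgrid_annotations",
    "read_eaf_annotations",
    "write_tokens",
    "write_transcriptions",
    "write_report",
    "study_result_to_dict",
]

TOKEN_COLUMNS = ("speaker_id", "register", "vowel", "median_f0")


@dataclass
class ReadReport:
    """Audit of a row-validated read: counts plus per-row error messages."""

    n_read: int = 0
    n_accepted: int = 0
    errors: list[str] = field(default_factory=list)

    def reject(self, row: int, message: str) -> None:
        self.errors.append(f"row {row}: {message}")


def read_track(path: str | Path) -> FormantTrack:
    """Read one formant track CSV (columns time, f1, f2, optional f0)."""
    df = pd.read_csv(path)
    missing = {"time", "f1", "f2"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing track columns {sorted(missing)}")
    f0 = df["f0"].to_numpy(float) if "f0" in df.columns else None
    return FormantTrack(
        times=df["time"].to_numpy(float),
        f1=df["f1"].to_numpy(float),
        f2=df["f2"].to_numpy(float),
        f0=f0,
    )


def read_token_table(
    path: str | Path,
) -> tuple[list[VowelToken], ReadReport]:
    """Read a vowel-token CSV into typed tokens plus a validation report.

    Each row needs ``speaker_id, register, vowel, median_f0`` and either
    numeric ``f1``/``f2`` columns or a ``track_file`` path (relative to
    the table's directory).  Invalid rows are rejected with row-numbered
    messages; an empty or column-less file is a hard error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except (pd.errors.EmptyDataError, OSError) as exc:
        raise ValueError(f"{path}: unreadable token table: {exc}") from exc
    missing = set(TOKEN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        raise ValueError(f"{path}: token table has no rows")

    report = ReadReport(n_read=len(df))
    tokens: list[VowelToken] = []
    for idx, row in df.iterrows():
        rowno = idx + 2  # 1-based, after header
        try:
            median_f0 = float(row["median_f0"])
        except (TypeError, ValueError):
            report.reject(rowno, f"non-numeric median_f0 {row['median_f0']!r}")
            continue
        track = None
        point_f1 = point_f2 = None
        track_file = row.get("track_file")
        if isinstance(track_file, str) and track_file.strip():
            try:
                track = read_track(path.parent / track_file.strip())
            except (ValueError, OSError) as exc:
                report.reject(rowno, f"bad track file: {exc}")
                continue
        else:
            try:
                point_f1 = float(row["f1"])
                point_f2 = float(row["f2"])
            except (TypeError, ValueError, KeyError):
                report.reject(rowno, "needs numeric f1/f2 or a track_file")
                continue
        try:
            token = VowelToken(
                speaker_id=str(row["speaker_id"]),
                register=str(row["register"]),
                vowel=str(row["vowel"]),
                median_f0=median_f0,
                track=track,
                point_f1=point_f1,
                point_f2=point_f2,
                token_id=str(row.get("token_id", "") or f"{path.stem}:{rowno}"),
            )
        except ValueError as exc:
            report.reject(rowno, str(exc))
            continue
        tokens.append(token)
    report.n_accepted = len(tokens)
    return tokens, report


def read_transcriptions(
    path: str | Path,
    inventory: PhoneInventory | None = None,
) -> tuple[list[Vocalization], ReadReport]:
    """Read and parse a transcription TSV; collect per-row parse errors."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except (pd.errors.EmptyDataError, OSError) as exc:
        raise ValueError(f"{path}: unreadable transcription table: {exc}") from exc
    missing = {"subject_id", "transcription"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    report = ReadReport(n_read=len(df))
    out: list[Vocalization] = []
    for idx, row in df.iterrows():
        rowno = idx + 2
        text = row["transcription"]
        if not isinstance(text, str) or not text.strip():
            report.reject(rowno, "empty transcription")
            continue
        try:
            out.append(
                parse_transcription(text, inventory, subject_id=str(row["subject_id"]))
            )
        except ParseError as exc:
            report.reject(rowno, str(exc))
    report.n_accepted = len(out)
    return out, report


# --------------------------------------------------------------------
# Optional annotation-tool readers

_TG_INTERVAL = re.compile(
    r'intervals\s*\[\d+\]\s*:?\s*'
    r'xmin\s*=\s*([\d.eE+-]+)\s*'
    r'xmax\s*=\s*([\d.eE+-]+)\s*'
    r'text\s*=\s*"((?:[^"]|"")*)"',
)


def read_textgrid_annotations(path: str | Path, tier: str | None = None) -> list[str]:
    """Non-empty interval texts from a Praat TextGrid (long text format).

    ``tier`` selects an interval tier by name; by default the first
    interval tier is used.
    """
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    # split into tiers on 'item [k]:' headers
    chunks = re.split(r"item\s*\[\d+\]\s*:", text)[1:]
    if not chunks:
        raise ValueError(f"{path}: no tiers found (is this a long-format TextGrid?)")
    for chunk in chunks:
        name_m = re.search(r'name\s*=\s*"((?:[^"]|"")*)"', chunk)
        if tier is not None and (name_m is None or name_m.group(1) != tier):
            continue
        if 'class = "IntervalTier"' not in chunk.replace("  ", " "):
            continue
        texts = [
            m.group(3).replace('""', '"').strip() for m in _TG_INTERVAL.finditer(chunk)
        ]
        return [t for t in texts if t]
    raise ValueError(f"{path}: interval tier {tier!r} not found")


def read_eaf_annotations(path: str | Path, tier: str | None = None) -> list[str]:
    """Non-empty annotation values from an ELAN EAF file, in document order."""
    tree = etree.parse(str(path))
    tiers = tree.findall(".//TIER")
    if tier is not None:
        tiers = [t for t in tiers if t.get("TIER_ID") == tier]
    if not tiers:
        raise ValueError(f"{path}: annotation tier {tier!r} not found")
    out = []
    for t in tiers[:1]:
        for ann in t.findall(".//ANNOTATION_VALUE"):
            if ann.text and ann.text.strip():
                out.append(ann.text.strip())
    return out


# --------------------------------------------------------------------
# Writers


def write_tokens(tokens: list[VowelToken], out_dir: str | Path) -> Path:
    """Write a token table (and per-token track CSVs) under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tracks_dir = out_dir / "tracks"
    rows = []
    for tok in tokens:
        row = {
            "speaker_id": tok.speaker_id,
            "register": tok.register,
            "vowel": tok.vowel,
            "median_f0": tok.median_f0,
            "token_id": tok.token_id,
        }
        if tok.track is not None:
            tracks_dir.mkdir(exist_ok=True)
            rel = f"tracks/{tok.token_id}.csv"
            pd.DataFrame(
                {"time": tok.track.times, "f1": tok.track.f1, "f2": tok.track.f2}
            ).to_csv(out_dir / rel, index=False)
            row["track_file"] = rel
        else:
            row["f1"] = tok.point_f1
            row["f2"] = tok.point_f2
        rows.append(row)
    table = out_dir / "tokens.csv"
    pd.DataFrame(rows).to_csv(table, index=False)
    return table


def write_transcriptions(
    transcriptions: list[tuple[str, str, str]], path: str | Path
) -> Path:
    """Write (subject_id, vocalization_id, transcription) rows as TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        transcriptions, columns=["subject_id", "vocalization_id", "transcription"]
    ).to_csv(path, sep="\t", index=False)
    return path


def study_result_to_dict(result: StudyResult) -> dict:
    """JSON-ready dict: full-precision numbers plus display-rounded fields."""
    out: dict = {"scales": {}, "audit": dict(result.audit)}
    for scale, res in result.scales.items():
        t = res.paired_test
        r = res.regression
        entry = {
            "paired_test": {
                "t": t.t,
                "df": t.df,
                "p": t.p,
                "p_display": round(t.p, 3),
                "mean_ids": t.mean_a,
                "mean_ads": t.mean_b,
                "sd_ids": t.sd_a,
                "sd_ads": t.sd_b,
                "n": t.n,
            },
            "regression": {
                "beta": r.beta,
                "intercept": r.intercept,
                "F": r.F,
                "df": list(r.df),
                "r_squared": r.r_squared,
                "p": r.p,
                "p_display": round(r.p, 3),
                "n": r.n,
            },
            "differences": [
                {
                    "speaker_id": d.speaker_id,
                    "vsa_ids": d.vsa_ids,
                    "vsa_ads": d.vsa_ads,
                    "difference": d.difference,
                }
                for d in res.differences
            ],
        }
        if res.predicted_increase is not None:
            entry["predicted_increase"] = {
                "delta": res.predicted_delta,
                "value": res.predicted_increase,
                "display": round(res.predicted_increase, 2),
            }
        out["scales"][scale] = entry
    out["subjects"] = [
        {
            "subject_id": s.subject_id,
            "n_vocalizations": s.n_vocalizations,
            "mean_score": s.mean_score,
        }
        for s in result.wcm_summaries
    ]
    out["outliers"] = [
        {
            "subject_id": s.subject_id,
            "mean_score": s.mean_score,
            "reason": s.exclusion_reason,
        }
        for s in result.outliers
    ]
    out["excluded_token_ids"] = list(result.excluded_token_ids)
    return out


def write_report(
    result: StudyResult, path: str | Path, fmt: str = "json"
) -> Path:
    """Write a study report; JSON is lossless, CSV is a per-subject flat view."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = study_result_to_dict(result)
    if fmt == "json":
        path.write_text(
            json.dumps(data, sort_keys=True, indent=2, ensure_ascii=False) + "\n",
            encoding="utf-8",
        )
        return path
    if fmt == "csv":
        rows = []
        hz = data["scales"].get("hz") or next(iter(data["scales"].values()))
        diff_by_spk = {d["speaker_id"]: d for d in hz["differences"]}
        scores = {s["subject_id"]: s["mean_score"] for s in data["subjects"]}
        for spk in sorted(set(diff_by_spk) | set(scores)):
            d = diff_by_spk.get(spk, {})
            rows.append(
                {
                    "subject_id": spk,
                    "vsa_ids": d.get("vsa_ids"),
                    "vsa_ads": d.get("vsa_ads"),
                    "vsa_difference": d.get("difference"),
                    "mean_wcm": scores.get(spk),
                }
            )
        summary = {
            "subject_id": "__summary__",
            "vsa_ids": hz["paired_test"]["mean_ids"],
            "vsa_ads": hz["paired_test"]["mean_ads"],
            "vsa_difference": hz["paired_test"]["mean_ids"] - hz["paired_test"]["mean_ads"],
            "mean_wcm": None,
        }
        pd.DataFrame(rows + [summary]).to_csv(path, index=False)
        return path
    raise ValueError(f"unknown report format {fmt!r}")
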