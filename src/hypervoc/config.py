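"""Study configuration: the analysis constants, surfaced and validated.

All conventions the analysis depends on live here with their standard
values as defaults: the 350 Hz median-f0 ceiling, the mid-40% formant
window, the frequency scale(s), and the subject outlier policy.  A
config can be loaded from YAML; unknown keys are rejected so that typos
fail loudly rather than silently falling back to defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["StudyConfig"]

SCHEMA_VERSION = 1

_VALID_SCALES = ("hz", "bark")
_VALID_POLICIES = ("none", "absolute", "z")


@dataclass(frozen=True)
class StudyConfig:
    """Parameters governing a full study run.

    Attributes
    ----------
    f0_max:
        Median-f0 ceiling in Hz; tokens strictly above it are excluded.
    window_fraction:
        Central fraction of each vowel's duration used for formant
        averaging (0.4 = the mid 40%).
    scales:
        Frequency scales to analyse; ``("hz",)`` or ``("hz", "bark")``.
    outlier_policy / outlier_k / outlier_cutoff:
        Subject-level mean-score exclusion rule; see
        :func:`hypervoc.analysis.exclude_outliers`.
    predicted_delta:
        VSA-difference step (Hz²) for the predicted-increase report.
    tautosyllabic_clusters:
        Count consonant clusters within syllables only.
    seed:
        Seed recorded in reports for provenance; simulation entry points
        take their own explicit seed.
    """

    f0_max: float = 350.0
    window_fraction: float = 0.4
    scales: tuple[str, ...] = ("hz",)
    outlier_policy: str = "z"
    outlier_k: float = 3.0
    outlier_cutoff: float | None = None
    predicted_delta: float = 10_000.0
    tautosyllabic_clusters: bool = False
    seed: int | None = None
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if not self.f0_max > 0:
            raise ValueError("f0_max must be positive")
        if not 0 < self.window_fraction <= 1:
            raise ValueError("window_fraction must be in (0, 1]")
        object.__setattr__(self, "scales", tuple(s.lower() for s in self.scales))
        for scale in self.scales:
            if scale not in _VALID_SCALES:
                raise ValueError(f"unknown scale {scale!r}; valid: {_VALID_SCALES}")
        if self.outlier_policy not in _VALID_POLICIES:
            raise ValueError(
                f"unknown outlier policy {self.outlier_policy!r}; valid: {_VALID_POLICIES}"
            )
        if self.outlier_policy == "absolute" and self.outlier_cutoff is None:
            raise ValueError("absolute outlier policy requires outlier_cutoff")
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"config schema_version {self.schema_version} not supported "
                f"(expected {SCHEMA_VERSION})"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "scales" in raw and isinstance(raw["scales"], list):
            raw["scales"] = tuple(raw["scales"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scales"] = list(self.scales)
        return d
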