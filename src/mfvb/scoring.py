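"""Composite 0-100 Mental Fitness Vocal Biomarker (MFVB) score.

Each of the eight vocal features is normalized against a reference
distribution summarized by its 25th/75th percentiles, oriented so that
higher always means better mental fitness, mapped through the standard
normal CDF onto [0, 100], and the eight subscores are averaged.  The score
is a closed-form deterministic function of the feature vector — no learned
models anywhere.

The published description states only that normalized features are
averaged; the exact normalization is not public.  The form used here is a
robust z-score built from the published quartiles (midpoint as center,
IQR/1.349 as a normal-consistent spread) pushed through the normal CDF.
It uses exactly the published quartiles, is smooth and bounded, and puts a
feature sitting at its reference band edge at subscore 25 or 75 by
construction.  Absolute scores from other implementations need not match;
orderings, monotonicity and the 0-69 / 70-79 / 80-100 category logic do.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields as dc_fields
from importlib import resources

# IQR of a standard normal: Phi^-1(0.75) - Phi^-1(0.25)
_NORMAL_IQR = 1.3489795003921634

MFVB_CATEGORIES = ("excellent", "good", "pay_attention")

FEATURE_NAMES = (
    "jitter_pct",
    "shimmer_pct",
    "pitch_variability_oct",
    "energy_variability_db",
    "vowel_space_mhz2",
    "phonation_duration_ms",
    "speech_rate_wpm",
    "pause_duration_s",
)


@dataclass(frozen=True)
class FeatureVector:
    """The eight vocal features, in their reporting units.

    jitter_pct, shimmer_pct: cycle-to-cycle period/amplitude variation (%);
    pitch_variability_oct: SD of log2 F0 over voiced frames (octaves);
    energy_variability_db: SD of frame energy over speech frames (dB);
    vowel_space_mhz2: mean squared F1-F2 separation, scaled to "MHz^2";
    phonation_duration_ms: mean phonation-segment duration (msec);
    speech_rate_wpm: estimated words per minute;
    pause_duration_s: median inter-phonation gap (sec).
    """

    jitter_pct: float
    shimmer_pct: float
    pitch_variability_oct: float
    energy_variability_db: float
    vowel_space_mhz2: float
    phonation_duration_ms: float
    speech_rate_wpm: float
    pause_duration_s: float

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{f.name} must be finite and >= 0, got {v!r}")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass(frozen=True)
class QuartileEntry:
    q25: float
    q75: float
    direction: str  # '+' worsens with depression severity, '-' improves

    def __post_init__(self) -> None:
        if not self.q25 < self.q75:
            raise ValueError(f"require q25 < q75, got ({self.q25}, {self.q75})")
        if self.direction not in ("+", "-"):
            raise ValueError(f"direction must be '+' or '-', got {self.direction!r}")


class ReferenceQuartiles:
    """Per-feature reference bands and depression-correlation directions."""

    def __init__(self, entries: dict[str, QuartileEntry]):
        missing = set(FEATURE_NAMES) - set(entries)
        if missing:
            raise ValueError(f"missing reference entries for: {sorted(missing)}")
        self.entries = dict(entries)

    @classmethod
    def from_dict(cls, payload: dict) -> "ReferenceQuartiles":
        feats = payload.get("features", payload)
        return cls({
            name: QuartileEntry(float(spec["q25"]), float(spec["q75"]),
                                str(spec["direction"]))
            for name, spec in feats.items()
        })

    @classmethod
    def from_json(cls, path) -> "ReferenceQuartiles":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def default(cls) -> "ReferenceQuartiles":
        text = (resources.files("mfvb") / "data" / "reference_quartiles.json").read_text()
        return cls.from_dict(json.loads(text))

    def __getitem__(self, name: str) -> QuartileEntry:
        return self.entries[name]


@dataclass(frozen=True)
class MFVBResult:
    score: float
    category: str
    subscores: dict[str, float]
    timestamp: float | None = None
    partial: bool = False  # True when scored from a feature subset


def _norm_cdf(z: float) -> float:
    return 0.5 * math.erfc(-z / math.sqrt(2.0))


def feature_subscore(x: float, ref: QuartileEntry) -> float:
    """Map one feature value to a [0, 100] subscore.

    Robust z uses the band midpoint and IQR-derived spread; the sign is
    flipped for features that worsen with depression so that a higher
    subscore always means better fitness.  At the band midpoint the
    subscore is exactly 50; at the adverse band edge it is 25.
    """
    if not math.isfinite(x):
        raise ValueError(f"feature value must be finite, got {x!r}")
    center = 0.5 * (ref.q25 + ref.q75)
    spread = (ref.q75 - ref.q25) / _NORMAL_IQR
    z = (x - center) / spread
    if ref.direction == "+":
        z = -z
    return 100.0 * _norm_cdf(z)


def compose_mfvb(subscores: dict[str, float]) -> float:
    """Average the per-feature subscores into the 0-100 composite score."""
    if not subscores:
        raise ValueError("cannot compose a score from zero subscores")
    vals = list(subscores.values())
    return sum(vals) / len(vals)


def categorize(score: float) -> str:
    """Map a score to its display category.

    Boundaries are treated as half-open real intervals: [80, 100] is
    excellent, [70, 80) is good, [0, 70) is pay_attention.  Display
    rounding is a presentation concern and plays no role here.
    """
    if not (0.0 <= score <= 100.0):
        raise ValueError(f"score must lie in [0, 100], got {score!r}")
    if score >= 80.0:
        return "excellent"
    if score >= 70.0:
        return "good"
    return "pay_attention"


def score_features(
    features: FeatureVector | dict[str, float],
    reference: ReferenceQuartiles | None = None,
    timestamp: float | None = None,
    *,
    allow_partial: bool = False,
) -> MFVBResult:
    """Full scoring pipeline: normalize, average, categorize.

    With ``allow_partial`` a dict missing some features is scored from the
    mean of the available subscores and flagged; by default all eight
    features are required.
    """
    reference = reference or ReferenceQuartiles.default()
    if isinstance(features, FeatureVector):
        values = features.as_dict()
    else:
        values = dict(features)
        unknown = set(values) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature(s): {sorted(unknown)}")
        missing = set(FEATURE_NAMES) - set(values)
        if missing and not allow_partial:
            raise ValueError(
                f"missing feature(s): {sorted(missing)}; pass allow_partial=True "
                "to score from the available subset"
            )
    subscores = {
        name: feature_subscore(x, reference[name]) for name, x in values.items()
    }
    score = compose_mfvb(subscores)
    return MFVBResult(
        score=score,
        category=categorize(score),
        subscores=subscores,
        timestamp=timestamp,
        partial=len(subscores) < len(FEATURE_NAMES),
    )
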