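"""Synthetic speech-like audio with known ground truth.

Renders glottal-pulse trains whose cycle-level perturbations are calibrated
so the *measured* local jitter/shimmer statistics match the requested
percentages, filters them through vocal-tract resonators, and assembles
phonation/pause utterances that emulate 30-second voice-journaling
recordings.  Everything is returned alongside exact per-cycle ground truth
so the acoustic extractors can be validated by parameter recovery.

Perturbation law: periods are T_i = (1/f0)(1 + e_i) with e_i independent
zero-mean Gaussians.  The local jitter statistic mean|dT|/mean(T) of such a
sequence has expectation 2*sigma/sqrt(pi), so sigma = (pct/100)*sqrt(pi)/2
makes the realized statistic target the request; amplitudes analogously.
The goal is analyzability, not naturalness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .audio import AudioBuffer

# Phonation target RMS before loudness modulation; pauses sit this many dB
# below it.  The final utterance is peak-normalized, which preserves all
# relative levels.
_BASE_RMS = 0.01
_PAUSE_REL_DB = -45.0
_PEAK_NORM = 0.9

# Gaps shorter than this are articulatory, not pauses, when computing the
# analytically expected pause-duration feature.
DEFAULT_MIN_PAUSE_S = 0.1


@dataclass(frozen=True)
class VoiceSpec:
    """Ground-truth generative parameters for one phonation stretch."""

    f0_hz: float = 120.0
    jitter_pct: float = 0.0
    shimmer_pct: float = 0.0
    formants: tuple[tuple[float, float], ...] = ((500.0, 80.0), (1100.0, 120.0))
    energy_mod_db: float = 0.0
    energy_mod_timescale_s: float = 2.0
    sample_rate_hz: int = 16000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (50.0 < self.f0_hz < 500.0):
            raise ValueError(f"f0 must lie in (50, 500) Hz, got {self.f0_hz}")
        if self.jitter_pct < 0 or self.shimmer_pct < 0:
            raise ValueError("jitter/shimmer percentages must be >= 0")
        if len(self.formants) < 2:
            raise ValueError("at least two formants (F1, F2) required")
        centers = [f for f, _ in self.formants]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("formant centers must be strictly increasing")
        if self.sample_rate_hz < 8000:
            raise ValueError("sample rate must be >= 8000 Hz")
        if self.energy_mod_db < 0:
            raise ValueError("energy modulation SD must be >= 0")


@dataclass(frozen=True)
class PlanSegment:
    kind: str  # 'phonation' | 'pause'
    duration_s: float
    spec: VoiceSpec | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("phonation", "pause"):
            raise ValueError(f"segment kind must be phonation|pause, got {self.kind!r}")
        if self.duration_s <= 0:
            raise ValueError("segment durations must be positive")


@dataclass(frozen=True)
class UtterancePlan:
    segments: tuple[PlanSegment, ...]
    base_spec: VoiceSpec = VoiceSpec()
    seed: int = 0

    def __post_init__(self) -> None:
        if not any(s.kind == "phonation" for s in self.segments):
            raise ValueError("plan must contain at least one phonation segment")

    @property
    def duration_s(self) -> float:
        return sum(s.duration_s for s in self.segments)


@dataclass
class GroundTruth:
    """Exact per-cycle and per-segment truth for an assembled utterance."""

    period_sequence: np.ndarray            # concatenated cycle durations (s)
    amplitude_sequence: np.ndarray         # matching cycle amplitudes
    run_lengths: list[int]                 # cycles per phonation segment
    segment_table: list[tuple[str, float, float]]  # (kind, start_s, end_s)
    expected_features: dict[str, float] = field(default_factory=dict)

    @property
    def phonation_segments(self):
        return [(a, b) for k, a, b in self.segment_table if k == "phonation"]

    @property
    def pause_segments(self):
        return [(a, b) for k, a, b in self.segment_table if k == "pause"]


def _formant_filter(x: np.ndarray, formants, fs: int) -> np.ndarray:
    """Cascade of two-pole resonators at the given (center, bandwidth) Hz."""
    y = x
    for fc, bw in formants:
        r = math.exp(-math.pi * bw / fs)
        theta = 2.0 * math.pi * fc / fs
        a = [1.0, -2.0 * r * math.cos(theta), r * r]
        y = lfilter([1.0 - r], a, y)
    return y


def _loudness_envelope_db(
    n: int, fs: int, sd_db: float, timescale_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth Gaussian dB modulation, marginal SD sd_db, clipped at 2 SD."""
    if sd_db == 0.0:
        return np.zeros(n)
    dt = 0.2
    m = max(int(math.ceil(n / fs / dt)) + 2, 3)
    a = math.exp(-dt / timescale_s)
    g = np.empty(m)
    g[0] = rng.standard_normal()
    innov = rng.standard_normal(m - 1) * math.sqrt(1.0 - a * a)
    for i in range(1, m):
        g[i] = a * g[i - 1] + innov[i - 1]
    g = np.clip(g * sd_db, -2.0 * sd_db, 2.0 * sd_db)
    t = np.arange(n) / fs
    return np.interp(t, np.arange(m) * dt, g)


def _render_core(spec: VoiceSpec, duration_s: float, rng: np.random.Generator):
    """Unnormalized glottal-pulse render; returns (samples, periods, amps)."""
    fs = spec.sample_rate_hz
    t0 = 1.0 / spec.f0_hz
    if duration_s < 5.0 * t0:
        raise ValueError(
            f"duration {duration_s:.3f} s holds fewer than 5 periods at "
            f"f0={spec.f0_hz:.1f} Hz; need at least {5 * t0:.3f} s"
        )
    sigma_j = (spec.jitter_pct / 100.0) * math.sqrt(math.pi) / 2.0
    sigma_s = (spec.shimmer_pct / 100.0) * math.sqrt(math.pi) / 2.0

    times = [0.0]
    while True:
        e = sigma_j * rng.standard_normal()
        period = t0 * float(np.clip(1.0 + e, 0.5, 1.5))
        if times[-1] + period >= duration_s:
            break
        times.append(times[-1] + period)
    times = np.asarray(times)
    pulse_amps = 1.0 + sigma_s * rng.standard_normal(times.size)
    pulse_amps = np.clip(pulse_amps, 0.1, None)

    n = int(round(duration_s * fs))
    x = np.zeros(n)
    # split each pulse over two samples to keep sub-sample timing
    idx = times * fs
    lo = np.floor(idx).astype(int)
    frac = idx - lo
    np.add.at(x, lo, pulse_amps * (1.0 - frac))
    hi = np.minimum(lo + 1, n - 1)
    np.add.at(x, hi, pulse_amps * frac)

    y = _formant_filter(x, spec.formants, fs)
    rms = float(np.sqrt(np.mean(y**2)))
    y *= _BASE_RMS / max(rms, 1e-12)

    env_db = _loudness_envelope_db(n, fs, spec.energy_mod_db,
                                   spec.energy_mod_timescale_s, rng)
    y *= 10.0 ** (env_db / 20.0)

    gains = 10.0 ** (np.interp(times, np.arange(n) / fs, env_db) / 20.0)
    cycle_amps = pulse_amps * gains
    # cycle i spans marks i..i+1: one amplitude per period
    periods = np.diff(times)
    return y, periods, cycle_amps[:-1]


def render_pulse_train(spec: VoiceSpec, duration_s: float):
    """Render one continuous phonation; returns (AudioBuffer, periods, amps).

    Deterministic for a fixed spec (seed included).  With zero jitter and
    shimmer every returned period is exactly 1/f0 and every amplitude is
    constant (up to the loudness envelope, if requested).
    """
    rng = np.random.default_rng(spec.seed)
    y, periods, amps = _render_core(spec, duration_s, rng)
    peak = float(np.max(np.abs(y)))
    y *= _PEAK_NORM / max(peak, 1e-12)
    return AudioBuffer(y, spec.sample_rate_hz), periods, amps


def _weighted_log2_sd(f0s, durations) -> float:
    w = np.asarray(durations, dtype=float)
    w = w / w.sum()
    lf = np.log2(np.asarray(f0s, dtype=float))
    mu = float(np.sum(w * lf))
    return float(math.sqrt(np.sum(w * (lf - mu) ** 2)))


def synthesize_utterance(
    plan: UtterancePlan, min_pause_s: float = DEFAULT_MIN_PAUSE_S
):
    """Assemble a phonation/pause utterance; returns (AudioBuffer, GroundTruth).

    Pauses carry low-level Gaussian noise (not digital silence) so
    voice-activity thresholding is exercised realistically.  The ground
    truth records the exact segment table, the per-cycle period and
    amplitude sequences, and the features the plan determines analytically:
    median pause duration (over gaps of at least ``min_pause_s``), mean
    phonation duration, and the duration-weighted pitch variability of the
    piecewise-constant F0 plan.
    """
    fs = plan.base_spec.sample_rate_hz
    children = np.random.SeedSequence(plan.seed).spawn(len(plan.segments))
    pieces: list[np.ndarray] = []
    periods: list[np.ndarray] = []
    amps: list[np.ndarray] = []
    run_lengths: list[int] = []
    table: list[tuple[str, float, float]] = []
    f0s: list[float] = []
    phon_durs: list[float] = []
    pause_rms = _BASE_RMS * 10.0 ** (_PAUSE_REL_DB / 20.0)

    t = 0.0
    for seg, ss in zip(plan.segments, children):
        rng = np.random.default_rng(ss)
        if seg.kind == "phonation":
            spec = seg.spec or plan.base_spec
            if spec.sample_rate_hz != fs:
                raise ValueError("all segments must share one sample rate")
            y, p, a = _render_core(spec, seg.duration_s, rng)
            pieces.append(y)
            periods.append(p)
            amps.append(a)
            run_lengths.append(p.size)
            f0s.append(spec.f0_hz)
            phon_durs.append(seg.duration_s)
        else:
            n = int(round(seg.duration_s * fs))
            pieces.append(rng.normal(0.0, pause_rms, size=n))
        table.append((seg.kind, t, t + seg.duration_s))
        t += seg.duration_s

    samples = np.concatenate(pieces)
    peak = float(np.max(np.abs(samples)))
    samples *= _PEAK_NORM / max(peak, 1e-12)

    expected: dict[str, float] = {}
    real_pauses = [d for k, a, b in table if k == "pause"
                   for d in [b - a] if d >= min_pause_s]
    if real_pauses:
        expected["pause_duration_s"] = float(np.median(real_pauses))
    expected["phonation_duration_ms"] = 1000.0 * float(np.mean(phon_durs))
    if len(f0s) >= 2:
        expected["pitch_variability_oct"] = _weighted_log2_sd(f0s, phon_durs)

    truth = GroundTruth(
        period_sequence=np.concatenate(periods) if periods else np.empty(0),
        amplitude_sequence=np.concatenate(amps) if amps else np.empty(0),
        run_lengths=run_lengths,
        segment_table=table,
        expected_features=expected,
    )
    return AudioBuffer(samples, fs), truth


# Vowel-like (F1, F2) targets with roughly 640-665 Hz separation, cycled
# through phonation segments to exercise the vowel-space feature.
_VOWEL_INVENTORY = (
    ((500.0, 80.0), (1140.0, 120.0)),
    ((550.0, 85.0), (1215.0, 120.0)),
    ((450.0, 80.0), (1095.0, 110.0)),
    ((600.0, 90.0), (1260.0, 130.0)),
    ((480.0, 80.0), (1130.0, 120.0)),
)


def journal_plan(
    duration_s: float = 30.0,
    seed: int = 0,
    base_spec: VoiceSpec | None = None,
) -> UtterancePlan:
    """A voice-journaling-like utterance plan.

    Speech comes in bursts of 3-5 syllable-scale phonation segments
    separated by short articulatory gaps, with longer pauses between
    bursts.  Per-syllable fundamental frequency is drawn log-normally
    around the base F0 and vowel targets cycle through a small inventory,
    so all eight extracted features take realistic values.  Defaults are
    tuned so each feature lands near the midpoint of its reference
    interquartile band.
    """
    base = base_spec or VoiceSpec(
        f0_hz=120.0, jitter_pct=6.3, shimmer_pct=4.2, energy_mod_db=8.2
    )
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x9A7)))
    segments: list[PlanSegment] = []
    t = 0.0
    vowel_i = 0
    while t < duration_s:
        burst = int(rng.integers(3, 6))
        for k in range(burst):
            syl = float(rng.uniform(0.19, 0.305))
            f0 = float(base.f0_hz * 2.0 ** rng.normal(0.0, 0.215))
            f0 = float(np.clip(f0, 70.0, 300.0))
            spec = replace(base, f0_hz=f0,
                           formants=_VOWEL_INVENTORY[vowel_i % len(_VOWEL_INVENTORY)])
            segments.append(PlanSegment("phonation", syl, spec))
            t += syl
            vowel_i += 1
            if k < burst - 1:
                gap = float(rng.uniform(0.055, 0.08))
                segments.append(PlanSegment("pause", gap))
                t += gap
            if t >= duration_s:
                break
        if t >= duration_s:
            break
        pause = float(rng.uniform(0.32, 0.60))
        segments.append(PlanSegment("pause", pause))
        t += pause
    # never end on a pause
    while segments and segments[-1].kind == "pause":
        segments.pop()
    return UtterancePlan(tuple(segments), base_spec=base, seed=seed)
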