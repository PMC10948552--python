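"""Classical-DSP extraction of the eight MFVB vocal features.

Frame-level analysis (energy, autocorrelation F0, LPC formants) in the
style of Praat/openSMILE, cycle-level period and amplitude tracking via
LPC inverse filtering, energy-based voice-activity segmentation, and the
eight summary features:

    jitter_pct              100 * mean|dT| / mean(T)   (local jitter)
    shimmer_pct             100 * mean|dA| / mean(A)   (local shimmer)
    pitch_variability_oct   SD of log2(F0) over voiced frames
    energy_variability_db   SD of frame energy (dB) over speech frames
    vowel_space_mhz2        mean (F2 - F1)^2 / 1e6 over voiced frames
    phonation_duration_ms   mean phonation-segment duration
    speech_rate_wpm         syllable-nuclei estimate / 1.5 * 60 / duration
    pause_duration_s        median inter-phonation gap

No learned models anywhere; every threshold is configurable with
documented defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_toeplitz
from scipy.signal import find_peaks, hilbert, lfilter, medfilt, resample_poly

from .audio import AudioBuffer
from .scoring import FeatureVector


class NoVoiceError(ValueError):
    """The audio contains no detectable voiced speech."""


class FeatureError(ValueError):
    """One or more features could not be computed from this audio."""

    def __init__(self, failures: dict[str, str]):
        self.failures = dict(failures)
        details = "; ".join(f"{k}: {v}" for k, v in failures.items())
        super().__init__(f"uncomputable feature(s): {details}")


@dataclass(frozen=True)
class AcousticsConfig:
    """All extraction thresholds; defaults are Praat-like conventions."""

    frame_len_s: float = 0.04
    hop_s: float = 0.01
    f0_min_hz: float = 60.0
    f0_max_hz: float = 400.0
    voicing_threshold: float = 0.45      # normalized autocorrelation
    voicing_energy_offset_db: float = 15.0  # above the noise floor
    # voice-activity segmentation (fine RMS envelope)
    env_window_s: float = 0.015
    env_hop_s: float = 0.0025
    vad_offset_db: float = 10.0          # detection threshold above floor
    boundary_refine_db: float = 6.0      # below local level, for edges
    min_phonation_s: float = 0.05
    min_pause_s: float = 0.10
    merge_gap_s: float = 0.03
    # formant analysis
    formant_fs_hz: int = 10000
    preemphasis: float = 0.97
    max_formant_bw_hz: float = 400.0
    # cycle-level whitening (period/amplitude tracking)
    whitening_resonators: int = 2
    whitening_maxiter: int = 300
    # rate estimation
    words_per_syllable: float = 1.5
    nuclei_min_sep_s: float = 0.18
    nuclei_smooth_s: float = 0.12
    # substituted when an utterance contains no pause at all
    default_pause_s: float = 0.10


@dataclass
class FrameTrack:
    """Per-frame intermediate quantities plus a fine VAD envelope."""

    frame_times: np.ndarray
    energy_db: np.ndarray
    f0_hz: np.ndarray          # NaN where unvoiced
    voiced: np.ndarray
    f1_hz: np.ndarray          # NaN where unavailable
    f2_hz: np.ndarray
    env_times: np.ndarray
    env_db: np.ndarray
    sample_rate_hz: int
    duration_s: float

    @property
    def n_voiced(self) -> int:
        return int(np.sum(self.voiced))


@dataclass
class PeriodSequence:
    """Consecutive pitch periods and matching cycle amplitudes.

    ``run_lengths`` partitions the cycles into contiguous voiced runs;
    first-difference statistics never straddle a run boundary.
    """

    periods_s: np.ndarray
    amplitudes: np.ndarray
    run_lengths: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.periods_s = np.asarray(self.periods_s, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.periods_s.size != self.amplitudes.size:
            raise ValueError("periods and amplitudes must have equal length")
        if np.any(self.periods_s <= 0):
            raise ValueError("periods must be positive")
        if not self.run_lengths:
            self.run_lengths = [self.periods_s.size]
        if sum(self.run_lengths) != self.periods_s.size:
            raise ValueError("run lengths must partition the cycle sequence")

    def _runs(self, values: np.ndarray):
        i = 0
        for n in self.run_lengths:
            yield values[i:i + n]
            i += n


@dataclass
class SegmentSet:
    """Phonation intervals and the qualifying gaps (pauses) between them."""

    phonation_segments: list[tuple[float, float]]
    pauses: list[tuple[float, float]]


# ---------------------------------------------------------------------------
# frame-level analysis
# ---------------------------------------------------------------------------

def _frame_matrix(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    n_frames = 1 + (x.size - frame_len) // hop
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def _lpc(x: np.ndarray, order: int) -> np.ndarray:
    """Autocorrelation-method LPC; returns the full A(z) coefficient vector."""
    r = np.correlate(x, x, mode="full")[x.size - 1 : x.size + order]
    r = r.copy()
    r[0] *= 1.0 + 1e-9  # tiny ridge for numerical safety
    if r[0] <= 0:
        raise np.linalg.LinAlgError("degenerate autocorrelation")
    a = solve_toeplitz((r[:-1], r[:-1]), -r[1:])
    return np.concatenate(([1.0], a))


def _formants_from_lpc(a: np.ndarray, fs: float, max_bw: float):
    roots = np.roots(a)
    roots = roots[np.imag(roots) > 1e-6]
    freqs = np.angle(roots) * fs / (2.0 * math.pi)
    bws = -np.log(np.maximum(np.abs(roots), 1e-12)) * fs / math.pi
    keep = (freqs > 90.0) & (freqs < fs / 2.0 - 50.0) & (bws < max_bw)
    fr = np.sort(freqs[keep])
    if fr.size >= 2:
        return float(fr[0]), float(fr[1])
    return math.nan, math.nan


def track_frames(
    audio: AudioBuffer,
    frame_len_s: float | None = None,
    hop_s: float | None = None,
    config: AcousticsConfig | None = None,
) -> FrameTrack:
    """Per-frame energy, autocorrelation F0 with voicing, and LPC F1/F2."""
    cfg = config or AcousticsConfig()
    if frame_len_s is not None or hop_s is not None:
        from dataclasses import replace
        cfg = replace(cfg, frame_len_s=frame_len_s or cfg.frame_len_s,
                      hop_s=hop_s or cfg.hop_s)
    fs = audio.sample_rate_hz
    if fs < 8000:
        raise ValueError(f"sample rate {fs} Hz below 8 kHz; formant analysis "
                         "is unreliable — resample first")
    x = audio.samples
    frame_len = int(round(cfg.frame_len_s * fs))
    hop = int(round(cfg.hop_s * fs))
    if x.size < frame_len:
        raise ValueError("audio shorter than one analysis frame")

    frames = _frame_matrix(x, frame_len, hop)
    n_frames = frames.shape[0]
    times = (np.arange(n_frames) * hop + frame_len / 2) / fs
    energy_db = 20.0 * np.log10(np.sqrt(np.mean(frames**2, axis=1)) + 1e-10)
    noise_floor = float(np.percentile(energy_db, 5))

    # F0 from the normalized autocorrelation of the Hilbert envelope: the
    # envelope follows glottal-pulse positions, so the periodicity peak
    # survives the formant-phase decorrelation that high jitter causes in
    # the raw waveform
    env = np.abs(hilbert(x))
    env_frames = _frame_matrix(env, frame_len, hop)
    centered = env_frames - env_frames.mean(axis=1, keepdims=True)
    nfft = 1 << int(np.ceil(np.log2(2 * frame_len)))
    spec = np.fft.rfft(centered, n=nfft, axis=1)
    ac = np.fft.irfft(spec * np.conj(spec), axis=1)[:, :frame_len]
    ac0 = np.maximum(ac[:, 0], 1e-20)
    ac_norm = ac / ac0[:, None]

    lag_min = max(2, int(math.floor(fs / cfg.f0_max_hz)))
    lag_max = min(frame_len - 2, int(math.ceil(fs / cfg.f0_min_hz)))
    f0 = np.full(n_frames, math.nan)
    voiced = np.zeros(n_frames, dtype=bool)
    # continuous speech has no quiet frames, so the floor estimate can sit
    # at the speech level itself; cap the gate relative to the peak too
    gate = min(noise_floor + cfg.voicing_energy_offset_db,
               float(energy_db.max()) - 30.0)
    energetic = energy_db > gate
    for i in np.nonzero(energetic)[0]:
        seg = ac_norm[i, lag_min:lag_max + 1]
        peaks, _ = find_peaks(seg)
        if peaks.size == 0:
            continue
        best = float(seg[peaks].max())
        if best < cfg.voicing_threshold:
            continue
        # prefer the smallest lag among near-best peaks (octave-error guard)
        lag = lag_min + int(peaks[np.nonzero(seg[peaks] >= 0.9 * best)[0][0]])
        y0, y1, y2 = ac_norm[i, lag - 1], ac_norm[i, lag], ac_norm[i, lag + 1]
        denom = y0 - 2.0 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
        lag_f = lag + float(np.clip(shift, -0.5, 0.5))
        voiced[i] = True
        f0[i] = fs / lag_f

    # remove isolated octave errors without disturbing genuine contours
    vi = np.nonzero(voiced)[0]
    if vi.size >= 5:
        f0[vi] = medfilt(f0[vi], kernel_size=5)

    f1, f2 = _formant_track(x, fs, times, voiced, cfg)

    env_win = max(4, int(round(cfg.env_window_s * fs)))
    env_hop = max(1, int(round(cfg.env_hop_s * fs)))
    if x.size >= env_win:
        env_frames = _frame_matrix(x, env_win, env_hop)
        env_rms = np.sqrt(np.mean(env_frames**2, axis=1))
        env_times = (np.arange(env_frames.shape[0]) * env_hop + env_win / 2) / fs
    else:
        env_rms = np.array([np.sqrt(np.mean(x**2))])
        env_times = np.array([x.size / 2 / fs])
    env_db = 20.0 * np.log10(env_rms + 1e-10)

    return FrameTrack(times, energy_db, f0, voiced, f1, f2,
                      env_times, env_db, fs, audio.duration_s)


def _formant_track(x, fs, frame_times, voiced, cfg: AcousticsConfig):
    """LPC F1/F2 on voiced frames, at a 10 kHz analysis rate."""
    n = frame_times.size
    f1 = np.full(n, math.nan)
    f2 = np.full(n, math.nan)
    if not voiced.any():
        return f1, f2
    g = math.gcd(cfg.formant_fs_hz, fs)
    xd = resample_poly(x, cfg.formant_fs_hz // g, fs // g)
    fsd = cfg.formant_fs_hz
    xd = np.append(xd[0], xd[1:] - cfg.preemphasis * xd[:-1])
    order = 2 + int(round(fsd / 1000.0))
    half = int(round(cfg.frame_len_s * fsd / 2))
    window = np.hamming(2 * half)
    for i in np.nonzero(voiced)[0]:
        c = int(round(frame_times[i] * fsd))
        lo, hi = c - half, c + half
        if lo < 0 or hi > xd.size:
            continue
        seg = xd[lo:hi] * window
        try:
            a = _lpc(seg, order)
        except np.linalg.LinAlgError:
            continue
        f1[i], f2[i] = _formants_from_lpc(a, fsd, cfg.max_formant_bw_hz)
    return f1, f2


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_activity(track: FrameTrack, config: AcousticsConfig | None = None
                     ) -> SegmentSet:
    """Energy-threshold voice-activity segmentation with edge refinement.

    Detection runs on the fine RMS envelope at ``vad_offset_db`` above the
    noise floor; each boundary is then refined to the crossing of the
    segment's own level minus ``boundary_refine_db``, with the envelope
    window's known half-overlap bias compensated.  Gaps of at least
    ``min_pause_s`` between kept segments become pauses; shorter gaps are
    treated as articulatory and ignored.
    """
    cfg = config or AcousticsConfig()
    env_t, env_db = track.env_times, track.env_db
    if env_t.size == 0:
        return SegmentSet([], [])
    floor = float(np.percentile(env_db, 5))
    speech = float(np.percentile(env_db, 90))
    if speech - floor < cfg.vad_offset_db + 3.0:
        # no dynamic range: either continuous speech or continuous silence
        if track.n_voiced > 0:
            return SegmentSet([(0.0, track.duration_s)], [])
        return SegmentSet([], [])
    thr = floor + cfg.vad_offset_db
    active = env_db > thr

    # maximal active runs
    runs = []
    in_run = False
    for i, a in enumerate(active):
        if a and not in_run:
            start, in_run = i, True
        elif not a and in_run:
            runs.append((start, i - 1))
            in_run = False
    if in_run:
        runs.append((start, active.size - 1))

    # merge runs separated by sub-articulatory gaps
    merged = []
    for r in runs:
        if merged and (env_t[r[0]] - env_t[merged[-1][1]]) < cfg.merge_gap_s:
            merged[-1] = (merged[-1][0], r[1])
        else:
            merged.append(r)

    # refine boundaries; the crossing of (level - D) happens ~w*10^(-D/10)
    # before the true edge because of window overlap
    w = cfg.env_window_s
    bias = w * (0.5 - 10.0 ** (-cfg.boundary_refine_db / 10.0))
    segments = []
    for i0, i1 in merged:
        if env_t[i1] - env_t[i0] < cfg.min_phonation_s:
            continue
        level = float(np.median(env_db[i0:i1 + 1]))
        refine_thr = level - cfg.boundary_refine_db
        j = i0
        while j <= i1 and env_db[j] < refine_thr:
            j += 1
        k = i1
        while k >= i0 and env_db[k] < refine_thr:
            k -= 1
        if j > k:
            continue
        onset = env_t[j] + bias
        offset = env_t[k] - bias
        if offset - onset >= cfg.min_phonation_s:
            segments.append((onset, offset))

    pauses = [
        (a_end, b_start)
        for (_, a_end), (b_start, _) in zip(segments, segments[1:])
        if b_start - a_end >= cfg.min_pause_s
    ]
    return SegmentSet(segments, pauses)


# ---------------------------------------------------------------------------
# cycle-level analysis
# ---------------------------------------------------------------------------

def _resonator_inverse(params: np.ndarray, fs: float) -> np.ndarray:
    """FIR inverse of a cascade of (center, bandwidth) two-pole resonators."""
    a = np.array([1.0])
    for fc, bw in params.reshape(-1, 2):
        r = math.exp(-math.pi * bw / fs)
        theta = 2.0 * math.pi * fc / fs
        a = np.convolve(a, [1.0, -2.0 * r * math.cos(theta), r * r])
    return a


def _glottal_residual(seg: np.ndarray, fs: float, cfg: "AcousticsConfig"
                      ) -> np.ndarray:
    """Whiten one phonation stretch down to its excitation pulses.

    A low-order LPC fit seeds the dominant vocal-tract resonances; the
    resonator parameters are then refined by sparse deconvolution —
    minimizing the L1 norm of the inverse-filtered signal, which is
    smallest when the residual collapses onto the glottal pulses.
    """
    from scipy.optimize import minimize

    n_res = cfg.whitening_resonators
    try:
        a0 = _lpc(seg, 2 * n_res)
    except np.linalg.LinAlgError:
        return seg
    roots = np.roots(a0)
    roots = roots[np.imag(roots) > 1e-9]
    fcs = np.angle(roots) * fs / (2.0 * math.pi)
    bws = -np.log(np.clip(np.abs(roots), 1e-9, 1 - 1e-9)) * fs / math.pi
    order = np.argsort(fcs)
    fcs, bws = fcs[order], np.clip(bws[order], 30.0, 400.0)
    # pad with generic formant guesses if LPC found too few resonances
    defaults = [(500.0, 100.0), (1500.0, 150.0), (2500.0, 200.0)]
    pairs = list(zip(fcs, bws)) + defaults
    p0 = np.asarray(pairs[:n_res], dtype=float).ravel()

    def cost(p: np.ndarray) -> float:
        if np.any(p < 20.0) or np.any(p.reshape(-1, 2)[:, 0] > fs / 2 - 50):
            return np.inf
        return float(np.mean(np.abs(lfilter(_resonator_inverse(p, fs), [1.0], seg))))

    r = minimize(cost, p0, method="Nelder-Mead",
                 options=dict(maxiter=cfg.whitening_maxiter, xatol=0.5,
                              fatol=0.0))
    best = r.x if np.isfinite(r.fun) and r.fun <= cost(p0) else p0
    return lfilter(_resonator_inverse(best, fs), [1.0], seg)


def extract_periods(
    audio: AudioBuffer,
    track: FrameTrack,
    config: AcousticsConfig | None = None,
    segments: SegmentSet | None = None,
) -> PeriodSequence:
    """Locate glottal cycles and return their periods and amplitudes.

    Each phonation segment is LPC inverse-filtered (whitened) so the
    excitation pulses stand clear of vocal-tract ringing; pulse instants
    are then peak-picked at the F0-track spacing with parabolic sub-sample
    interpolation.  Cycles never straddle a segment boundary.
    """
    cfg = config or AcousticsConfig()
    if track.n_voiced == 0:
        raise NoVoiceError("no voiced frames; cannot extract pitch periods")
    segs = segments or segment_activity(track, cfg)
    fs = audio.sample_rate_hz
    x = audio.samples

    all_periods: list[np.ndarray] = []
    all_amps: list[np.ndarray] = []
    run_lengths: list[int] = []
    for start, end in segs.phonation_segments:
        lo, hi = int(start * fs), min(int(end * fs), x.size)
        if hi - lo < 64:
            continue
        in_seg = (track.frame_times >= start) & (track.frame_times <= end)
        f0s = track.f0_hz[in_seg & track.voiced]
        if f0s.size == 0:
            continue
        f0_seg = float(np.median(f0s))
        seg = x[lo:hi]
        res = _glottal_residual(seg, fs, cfg)
        mag = np.abs(res)
        # blank the inverse-filter warm-up (the segment starts mid-ring) and
        # gate on a robust quantile, not the max, which the warm-up spike
        # or a single loud cycle would dominate
        mag[: int(0.003 * fs)] = 0.0
        min_dist = max(2, int(0.75 * fs / f0_seg))
        peaks, _ = find_peaks(mag, distance=min_dist,
                              height=0.25 * float(np.percentile(mag, 98)))
        if peaks.size < 2:
            continue
        # sub-sample pulse instants via the local |residual| centroid; the
        # excitation pulse is split across neighbouring samples, so single-
        # sample peak positions fluctuate
        t_marks = []
        heights = []
        for p in peaks:
            a0, b0 = max(0, p - 2), min(mag.size, p + 3)
            w_loc = mag[a0:b0]
            centroid = float(np.sum(w_loc * np.arange(a0, b0)) / np.sum(w_loc))
            t_marks.append((lo + centroid) / fs)
            # signed window sum stays linear in the pulse amplitude no
            # matter how the pulse splits across samples
            s0, s1 = max(0, p - 3), min(res.size, p + 4)
            heights.append(abs(float(np.sign(res[p]) * np.sum(res[s0:s1]))))
        t_marks = np.asarray(t_marks)
        heights = np.asarray(heights)
        periods = np.diff(t_marks)
        med = np.median(periods)
        ok = (periods > 0.6 * med) & (periods < 1.5 * med)
        # onset/offset cycles are unreliable (truncated analysis windows);
        # drop one cycle at each end of runs long enough to afford it
        if ok.sum() >= 5:
            ok &= np.concatenate(([False], np.ones(ok.size - 2, bool), [False]))
        if not ok.any():
            continue
        all_periods.append(periods[ok])
        all_amps.append(heights[:-1][ok])
        run_lengths.append(int(ok.sum()))

    if not all_periods:
        raise NoVoiceError("no analyzable voiced segments found")
    return PeriodSequence(np.concatenate(all_periods),
                          np.concatenate(all_amps), run_lengths)


# ---------------------------------------------------------------------------
# the eight features
# ---------------------------------------------------------------------------

def _local_variation_pct(values: np.ndarray, seq: PeriodSequence) -> float:
    diffs = [np.abs(np.diff(run)) for run in seq._runs(values) if run.size >= 2]
    if not diffs:
        raise ValueError("need at least 2 cycles in some run")
    diffs = np.concatenate(diffs)
    if diffs.size == 0:
        raise ValueError("need at least 2 consecutive cycles")
    return 100.0 * float(np.mean(diffs)) / float(np.mean(values))


def jitter_percent(p: PeriodSequence) -> float:
    """Local jitter: 100 * mean|T_{i+1} - T_i| / mean(T)."""
    if p.periods_s.size < 2:
        raise ValueError("jitter requires at least 2 periods")
    return _local_variation_pct(p.periods_s, p)


def shimmer_percent(p: PeriodSequence) -> float:
    """Local shimmer: 100 * mean|A_{i+1} - A_i| / mean(A)."""
    if p.amplitudes.size < 2:
        raise ValueError("shimmer requires at least 2 cycles")
    return _local_variation_pct(p.amplitudes, p)


def pitch_variability_octaves(track: FrameTrack) -> float:
    """Population SD of log2(F0) over voiced frames."""
    f0 = track.f0_hz[track.voiced]
    if f0.size < 2:
        raise ValueError("pitch variability requires at least 2 voiced frames")
    return float(np.std(np.log2(f0)))


def energy_variability_db(track: FrameTrack, config: AcousticsConfig | None = None
                          ) -> float:
    """Population SD of frame energy (dB) over speech frames.

    Speech frames are those that are voiced or whose energy clears the
    voice-activity offset above the noise floor.
    """
    cfg = config or AcousticsConfig()
    floor = float(np.percentile(track.energy_db, 5))
    speechy = track.voiced | (track.energy_db > floor + cfg.voicing_energy_offset_db)
    e = track.energy_db[speechy]
    if e.size < 2:
        raise ValueError("energy variability requires at least 2 speech frames")
    return float(np.std(e))


def vowel_space(track: FrameTrack) -> float:
    """Mean squared F1-F2 separation over voiced frames, in 'MHz^2'.

    Computed in Hz^2 and scaled by 1e-6 — the convention under which the
    reference band (0.33-0.43) matches typical formant separations.
    """
    ok = track.voiced & np.isfinite(track.f1_hz) & np.isfinite(track.f2_hz)
    if not ok.any():
        raise ValueError("no frames with both formants available")
    sep = track.f2_hz[ok] - track.f1_hz[ok]
    return float(np.mean(sep**2)) / 1e6


def phonation_duration_ms(segs: SegmentSet) -> float:
    """Mean phonation-segment duration, in msec."""
    if not segs.phonation_segments:
        raise ValueError("no phonation segments")
    durs = [e - s for s, e in segs.phonation_segments]
    return 1000.0 * float(np.mean(durs))


def pause_duration_s(segs: SegmentSet) -> float:
    """Median pause duration, in sec (mean of central pair for even counts)."""
    if not segs.pauses:
        raise ValueError("no pauses")
    return float(np.median([e - s for s, e in segs.pauses]))


def speech_rate_wpm(
    segs: SegmentSet,
    track: FrameTrack,
    duration_s: float,
    config: AcousticsConfig | None = None,
) -> float:
    """Words per minute via a syllable-nuclei proxy.

    Syllable nuclei are local maxima of the smoothed energy envelope
    within phonation segments (at least one per segment); the word count
    is nuclei / words_per_syllable.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    cfg = config or AcousticsConfig()
    if not segs.phonation_segments:
        return 0.0
    env_lin = 10.0 ** (track.env_db / 20.0)
    hop = float(np.median(np.diff(track.env_times))) if track.env_times.size > 1 else 1.0
    smooth_n = max(1, int(round(cfg.nuclei_smooth_s / hop)))
    kernel = np.ones(smooth_n) / smooth_n
    env_s = np.convolve(env_lin, kernel, mode="same")
    min_dist = max(1, int(round(cfg.nuclei_min_sep_s / hop)))
    nuclei = 0
    for start, end in segs.phonation_segments:
        sel = (track.env_times >= start) & (track.env_times <= end)
        seg = env_s[sel]
        if seg.size == 0:
            continue
        peaks, _ = find_peaks(seg, distance=min_dist, height=0.3 * float(seg.max()))
        nuclei += max(1, int(peaks.size))
    words = nuclei / cfg.words_per_syllable
    return words * 60.0 / duration_s


def extract_feature_vector(
    audio: AudioBuffer, config: AcousticsConfig | None = None
) -> FeatureVector:
    """Run every extractor and assemble the eight-feature vector.

    Raises :class:`NoVoiceError` when no voiced speech is detectable and
    :class:`FeatureError` naming each feature that could not be computed
    otherwise — nothing is imputed silently.  An utterance with no pause
    at all substitutes the configured ``default_pause_s`` floor.
    """
    cfg = config or AcousticsConfig()
    if audio.duration_s < 1.0:
        raise ValueError("audio too short for feature extraction (< 1 s)")
    track = track_frames(audio, config=cfg)
    if track.n_voiced == 0:
        raise NoVoiceError("no voice detected in the recording")
    segs = segment_activity(track, cfg)
    failures: dict[str, str] = {}
    values: dict[str, float] = {}

    try:
        periods = extract_periods(audio, track, cfg, segments=segs)
        values["jitter_pct"] = jitter_percent(periods)
        values["shimmer_pct"] = shimmer_percent(periods)
    except (ValueError, NoVoiceError) as e:
        failures["jitter_pct"] = failures["shimmer_pct"] = str(e)

    for name, fn in (
        ("pitch_variability_oct", lambda: pitch_variability_octaves(track)),
        ("energy_variability_db", lambda: energy_variability_db(track, cfg)),
        ("vowel_space_mhz2", lambda: vowel_space(track)),
        ("phonation_duration_ms", lambda: phonation_duration_ms(segs)),
        ("speech_rate_wpm",
         lambda: speech_rate_wpm(segs, track, audio.duration_s, cfg)),
    ):
        try:
            values[name] = fn()
        except ValueError as e:
            failures[name] = str(e)

    try:
        values["pause_duration_s"] = pause_duration_s(segs)
    except ValueError:
        values["pause_duration_s"] = cfg.default_pause_s

    if failures:
        raise FeatureError(failures)
    return FeatureVector(**values)
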