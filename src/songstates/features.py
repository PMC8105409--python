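"""Sliding-window acoustic features for song analysis.

Each song bout is analyzed in short FFT windows (default 10 ms, stepped
every 1 ms). Per window the extractor computes:

* amplitude (dB against a configurable uncalibrated baseline),
* pitch (Hz; a weighted harmonic-sum estimator with a spectral-centroid
  fallback for windows of low harmonicity),
* frequency modulation (degrees in [0, 90], with a separate up/down sign),
* Wiener entropy (log ratio of geometric to arithmetic mean of the power
  spectrum; 0 for a flat spectrum, strongly negative for tones),
* spectral continuity (cosine similarity of nearby spectra, in [0, 1]).

Windows whose amplitude exceeds a threshold (default 50 dB against a 70 dB
baseline) are flagged *voiced*; everything downstream of feature
extraction operates on voiced windows only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import uniform_filter1d

from .audio import AudioClip

__all__ = ["FeatureConfig", "FeatureTrack", "compute_features", "voiced_segments"]


@dataclass(frozen=True)
class FeatureConfig:
    """Settings for sliding-window feature extraction.

    The defaults mirror common practice for zebra finch song: 10 ms
    analysis windows in 1 ms steps, a 50 dB voicing threshold against an
    uncalibrated 70 dB full-scale baseline, and a 300-8600 Hz analysis
    band covering the species' song energy.
    """

    window_ms: float = 10.0
    step_ms: float = 1.0
    threshold_db: float = 50.0
    baseline_db: float = 70.0
    band_low_hz: float = 300.0
    band_high_hz: float = 8600.0
    pitch_min_hz: float = 300.0
    pitch_max_hz: float = 3000.0
    n_harmonics: int = 6
    harmonicity_min: float = 0.08
    pitch_smooth_ms: float = 11.0
    spectral_smooth_bins: int = 7
    wiener_floor: float = 1e-3
    fm_scale_hz_per_ms: float = 5.0
    fm_dt_ms: float = 4.0
    fm_avg_ms: float = 15.0
    fm_sign_min_corr: float = 0.2
    continuity_dt_ms: float = 3.0

    def __post_init__(self) -> None:
        if self.window_ms <= 0 or self.step_ms <= 0:
            raise ValueError("window_ms and step_ms must be positive")
        if self.threshold_db <= 0 or self.baseline_db <= 0:
            raise ValueError("threshold_db and baseline_db must be positive")
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ValueError("invalid analysis band")


@dataclass
class FeatureTrack:
    """Per-window acoustic features of one song bout.

    All arrays share one length (one row per analysis window). ``pitch_hz``
    is physically meaningful on voiced windows only; ``fm_deg`` is the
    magnitude of frequency modulation and ``fm_sign`` its direction
    (+1 up-modulated, -1 down-modulated, 0 flat).
    """

    time_s: np.ndarray
    amplitude_db: np.ndarray
    pitch_hz: np.ndarray
    fm_deg: np.ndarray
    fm_sign: np.ndarray
    wiener_entropy: np.ndarray
    spectral_continuity: np.ndarray
    voiced: np.ndarray
    config: FeatureConfig = field(default_factory=FeatureConfig)
    bird_id: str | None = None

    def __len__(self) -> int:
        return self.time_s.size

    @property
    def step_s(self) -> float:
        return self.config.step_ms / 1000.0

    @property
    def n_voiced(self) -> int:
        return int(self.voiced.sum())

    @property
    def fm_signed(self) -> np.ndarray:
        return self.fm_deg * self.fm_sign

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "amplitude_db": self.amplitude_db,
                "pitch_hz": self.pitch_hz,
                "fm_deg": self.fm_deg,
                "fm_sign": self.fm_sign,
                "wiener_entropy": self.wiener_entropy,
                "spectral_continuity": self.spectral_continuity,
                "voiced": self.voiced.astype(int),
            }
        )

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write the feature table as CSV plus a JSON config sidecar."""
        self.to_frame().to_csv(path, index=False, float_format="%.6g")
        if sidecar:
            meta = {"config": asdict(self.config), "bird_id": self.bird_id,
                    "n_windows": len(self)}
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=2)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   config: FeatureConfig | None = None,
                   bird_id: str | None = None) -> "FeatureTrack":
        return cls(
            time_s=frame["time_s"].to_numpy(float),
            amplitude_db=frame["amplitude_db"].to_numpy(float),
            pitch_hz=frame["pitch_hz"].to_numpy(float),
            fm_deg=frame["fm_deg"].to_numpy(float),
            fm_sign=frame["fm_sign"].to_numpy(float),
            wiener_entropy=frame["wiener_entropy"].to_numpy(float),
            spectral_continuity=frame["spectral_continuity"].to_numpy(float),
            voiced=frame["voiced"].to_numpy(bool),
            config=config or FeatureConfig(),
            bird_id=bird_id,
        )


def _power_spectrogram(x: np.ndarray, fs: int, cfg: FeatureConfig):
    win = int(round(cfg.window_ms * fs / 1000.0))
    hop = int(round(cfg.step_ms * fs / 1000.0))
    if x.size < win:
        raise ValueError("clip too short for one analysis window")
    frames = sliding_window_view(x, win)[::hop]
    nfft = 1 << max(9, int(np.ceil(np.log2(4 * win))))
    taper = np.hanning(win)
    tapered = frames * taper
    spec = np.abs(np.fft.rfft(tapered, n=nfft, axis=1)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    # native (unpadded) resolution spectrum: bins are near-independent,
    # which matters for an unbiased Wiener entropy of broadband sounds
    spec_nat = np.abs(np.fft.rfft(tapered, axis=1)) ** 2
    freqs_nat = np.fft.rfftfreq(win, d=1.0 / fs)
    times = (np.arange(frames.shape[0]) * hop + win / 2.0) / fs
    rms2 = np.mean(frames**2, axis=1)
    return spec, freqs, spec_nat, freqs_nat, times, rms2


def _pitch_harmonic_sum(band_power: np.ndarray, band_freqs: np.ndarray,
                        cfg: FeatureConfig):
    """Weighted harmonic-sum pitch over candidate fundamentals.

    Candidates are the band FFT bins within [pitch_min, pitch_max]; the
    objective sums power at harmonics k*f0 with 1/k weights, which breaks
    octave ties in favor of the true fundamental. A parabolic refinement
    on the objective gives sub-bin resolution. Returns the pitch and a
    harmonicity score (objective peak over total band power).
    """
    cand_mask = (band_freqs >= cfg.pitch_min_hz) & (band_freqs <= cfg.pitch_max_hz)
    cand_idx = np.nonzero(cand_mask)[0]
    cand_freqs = band_freqs[cand_idx]
    n_win = band_power.shape[0]
    objective = np.zeros((n_win, cand_idx.size))
    df = band_freqs[1] - band_freqs[0]
    for k in range(1, cfg.n_harmonics + 1):
        h_idx = np.round((cand_freqs * k - band_freqs[0]) / df).astype(int)
        ok = h_idx < band_freqs.size
        if not ok.any():
            break
        objective[:, ok] += band_power[:, h_idx[ok]] / k
    best = np.argmax(objective, axis=1)
    rows = np.arange(n_win)
    # parabolic interpolation around the objective peak
    left = np.clip(best - 1, 0, cand_idx.size - 1)
    right = np.clip(best + 1, 0, cand_idx.size - 1)
    y0, y1, y2 = objective[rows, left], objective[rows, best], objective[rows, right]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-30, 0.5 * (y0 - y2) / denom, 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    pitch = cand_freqs[best] + shift * df
    total = band_power.sum(axis=1)
    harmonicity = np.where(total > 0, y1 / np.maximum(total, 1e-300), 0.0)
    return np.clip(pitch, cfg.pitch_min_hz, cfg.pitch_max_hz), harmonicity


def compute_features(clip: AudioClip, config: FeatureConfig | None = None,
                     bird_id: str | None = None) -> FeatureTrack:
    """Extract the per-window feature track of a song bout.

    Raises ``ValueError`` for clips shorter than one analysis window. The
    number of windows is ``floor((duration_ms - window_ms)/step_ms) + 1``
    (up to sample rounding of the hop).
    """
    cfg = config or FeatureConfig()
    fs = clip.sample_rate
    spec, freqs, spec_nat, freqs_nat, times, rms2 = _power_spectrogram(
        clip.samples, fs, cfg)

    band = (freqs >= cfg.band_low_hz) & (freqs <= cfg.band_high_hz)
    band_freqs = freqs[band]
    band_power = spec[:, band]
    smooth = uniform_filter1d(band_power, size=cfg.spectral_smooth_bins,
                              axis=1, mode="nearest")

    amplitude_db = cfg.baseline_db + 10.0 * np.log10(np.maximum(rms2, 1e-12))
    voiced = amplitude_db >= cfg.threshold_db

    # Wiener entropy from the native-resolution spectrum, lightly smoothed
    # across frequency so single-periodogram chi-squared noise does not
    # bias broadband sounds away from zero
    band_nat = (freqs_nat >= cfg.band_low_hz) & (freqs_nat <= cfg.band_high_hz)
    nat = uniform_filter1d(spec_nat[:, band_nat],
                           size=cfg.spectral_smooth_bins, axis=1,
                           mode="nearest")
    arith = nat.mean(axis=1)
    # bins are floored at a fraction of the arithmetic mean: unbounded
    # log terms from near-empty bins would otherwise make the entropy of
    # tonal sounds hypersensitive to the noise floor
    floor = np.maximum(arith[:, None] * cfg.wiener_floor, 1e-300)
    wiener = np.log(np.maximum(nat, floor)).mean(axis=1) - np.log(
        np.maximum(arith, 1e-300))
    wiener = np.minimum(wiener, 0.0)

    # pitch on voiced windows; unvoiced left as NaN
    pitch = np.full(len(times), np.nan)
    if voiced.any():
        p, harm = _pitch_harmonic_sum(band_power[voiced], band_freqs, cfg)
        # low-harmonicity fallback: centroid of the pitch band, so noisy
        # windows land mid-range instead of clipping at the band edge
        pb = (band_freqs >= cfg.pitch_min_hz) & (band_freqs <= cfg.pitch_max_hz)
        centroid = (band_power[voiced][:, pb] * band_freqs[pb]).sum(axis=1) / \
            np.maximum(band_power[voiced][:, pb].sum(axis=1), 1e-300)
        use_centroid = harm < cfg.harmonicity_min
        p = np.where(use_centroid,
                     np.clip(centroid, cfg.pitch_min_hz, cfg.pitch_max_hz), p)
        pitch[voiced] = p
        # smooth pitch across time within each voiced run: pitch moves on
        # syllable timescales, so this suppresses per-window estimator
        # noise without distorting frequency sweeps
        smooth_n = max(1, int(round(cfg.pitch_smooth_ms / cfg.step_ms)))
        if smooth_n > 1:
            vidx = np.nonzero(voiced)[0]
            run_breaks = np.nonzero(np.diff(vidx) > 1)[0]
            for lo, hi in zip(np.concatenate(([0], run_breaks + 1)),
                              np.concatenate((run_breaks + 1, [vidx.size]))):
                run = vidx[lo:hi]
                pitch[run] = uniform_filter1d(pitch[run], size=smooth_n,
                                              mode="nearest")

    # frequency modulation: ratio of time- to frequency-direction
    # derivatives of the (amplitude-normalized) spectrum; for an ideal
    # moving spectral ridge the ratio equals the ridge slope in Hz/ms.
    # Normalizing each frame's total power first makes pure amplitude
    # modulation contribute nothing to the time derivative.
    norm = smooth / np.maximum(smooth.sum(axis=1, keepdims=True), 1e-300)
    dt = max(1, int(round(cfg.fm_dt_ms / cfg.step_ms)))
    n_frames = norm.shape[0]
    dsdt = np.zeros_like(norm)
    if n_frames > 2 * dt:
        dsdt[dt:-dt] = (norm[2 * dt:] - norm[:-2 * dt]) / (2 * dt * cfg.step_ms)
        dsdt[:dt] = dsdt[dt:dt + 1]
        dsdt[-dt:] = dsdt[-dt - 1:-dt]
    df_hz = band_freqs[1] - band_freqs[0]
    dsdf = np.gradient(norm, axis=1) / df_hz
    # derivative energies are averaged over a short neighborhood before
    # taking the ratio, which stabilizes FM against broadband noise
    avg = max(1, int(round(cfg.fm_avg_ms / cfg.step_ms)))
    num = uniform_filter1d((dsdt**2).sum(axis=1), size=avg, mode="nearest")
    den = uniform_filter1d((dsdf**2).sum(axis=1), size=avg, mode="nearest")
    slope = np.sqrt(np.maximum(num, 0.0) / np.maximum(den, 1e-30))  # Hz/ms
    fm_deg = np.degrees(np.arctan(slope / cfg.fm_scale_hz_per_ms))
    cross = uniform_filter1d((dsdt * dsdf).sum(axis=1), size=avg,
                             mode="nearest")
    # modulation direction only when the time and frequency derivatives
    # are actually correlated (a moving ridge); unmodulated sounds get
    # sign 0 instead of a noise-driven coin flip
    rho = cross / np.maximum(np.sqrt(np.maximum(num, 0.0) *
                                     np.maximum(den, 0.0)), 1e-30)
    fm_sign = -np.sign(rho) * (np.abs(rho) > cfg.fm_sign_min_corr)

    # spectral continuity: cosine similarity of spectra a few ms apart
    dc = max(1, int(round(cfg.continuity_dt_ms / cfg.step_ms)))
    a = smooth[:-dc]
    b = smooth[dc:]
    num = (a * b).sum(axis=1)
    den = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    cont_core = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    continuity = np.empty(len(times))
    continuity[:-dc] = cont_core
    continuity[-dc:] = cont_core[-1] if cont_core.size else 0.0
    continuity = np.clip(continuity, 0.0, 1.0)

    return FeatureTrack(
        time_s=times, amplitude_db=amplitude_db, pitch_hz=pitch,
        fm_deg=fm_deg, fm_sign=fm_sign, wiener_entropy=wiener,
        spectral_continuity=continuity, voiced=voiced, config=cfg,
        bird_id=bird_id,
    )


def voiced_segments(track: FeatureTrack, min_gap_ms: float = 5.0,
                    min_dur_ms: float = 15.0) -> list[tuple[float, float]]:
    """Maximal voiced intervals of a track, in seconds.

    Runs of voiced windows are located, gaps shorter than ``min_gap_ms``
    are merged, and runs shorter than ``min_dur_ms`` are dropped. Intervals
    are half-open ``(onset_s, offset_s)``, sorted and non-overlapping.
    """
    v = track.voiced.astype(int)
    if not v.any():
        return []
    edges = np.diff(np.concatenate(([0], v, [0])))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    step = track.step_s
    merged: list[list[int]] = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if (s - merged[-1][1]) * step * 1000.0 < min_gap_ms:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    t0 = track.time_s[0]
    for s, e in merged:
        if (e - s) * step * 1000.0 >= min_dur_ms:
            out.append((t0 + s * step, t0 + e * step))
    return out
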