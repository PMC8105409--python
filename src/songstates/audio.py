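"""Audio containers and WAV input/output.

Song bouts are handled as mono PCM clips in the range [-1, 1]. Files are
read and written with :mod:`scipy.io.wavfile`; integer PCM of 16/24/32 bit
and float formats are accepted, stereo files are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile

MIN_SAMPLE_RATE = 22050


@dataclass(frozen=True)
class AudioClip:
    """A mono song recording.

    Parameters
    ----------
    samples : ndarray of float
        Mono PCM samples, nominally in [-1, 1].
    sample_rate : int
        Sampling rate in Hz; at least 22050 so the full zebra finch song
        band (up to ~8.6 kHz) is representable.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioClip requires mono (1-D) samples")
        if samples.size == 0:
            raise ValueError("AudioClip requires a positive duration")
        if not np.all(np.isfinite(samples)):
            raise ValueError("AudioClip samples must be finite")
        if self.sample_rate < MIN_SAMPLE_RATE:
            raise ValueError(
                f"sample_rate must be >= {MIN_SAMPLE_RATE} Hz, got {self.sample_rate}"
            )
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def scaled(self, factor: float) -> "AudioClip":
        """Return a copy with samples multiplied by ``factor``."""
        return AudioClip(self.samples * factor, self.sample_rate)


_PCM_SCALE = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31,
              np.dtype(np.uint8): 2**7}


def read_wav(path) -> AudioClip:
    """Read a mono WAV file into an :class:`AudioClip`.

    Integer PCM is rescaled to [-1, 1]; float data is passed through.
    Stereo (or any multi-channel) input raises ``ValueError``.
    """
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono WAV, got {data.shape[1]} channels")
    if data.dtype in _PCM_SCALE:
        scale = _PCM_SCALE[data.dtype]
        if data.dtype == np.uint8:
            samples = (data.astype(np.float64) - 128.0) / scale
        else:
            samples = data.astype(np.float64) / scale
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV sample format {data.dtype}")
    return AudioClip(samples, int(rate))


def write_wav(path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM WAV."""
    scaled = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(path, clip.sample_rate, (scaled * 32767).astype(np.int16))
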