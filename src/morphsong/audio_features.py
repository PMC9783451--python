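"""Spectral extraction of the nine song characteristics.

Cricket song is characterized here by nine numbers per recording: the
dominant frequency (spectral peak), the overall amplitude (RMS level in dB
relative to full scale), the relative amplitude of six frequency bands A–F
(proportions of total band energy), and frequency evenness — the negated
standard deviation of the six relative amplitudes, a broadbandedness score
that is 0 for a perfectly even spectrum and approaches -sqrt(1/6) for a
spectrum concentrated in a single band.

The band edges follow clusters of auditory receptor fiber best frequencies
in *T. oceanicus* hearing; they are configuration, not constants, and every
feature row records the band table that produced it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import welch

__all__ = [
    "SongRecording",
    "PowerSpectrum",
    "FrequencyBands",
    "SongFeatures",
    "SongAnalysisConfig",
    "read_wav",
    "power_spectrum",
    "dominant_frequency",
    "band_relative_amplitudes",
    "frequency_evenness",
    "extract_song_features",
    "features_to_frame",
    "DEFAULT_BAND_EDGES_HZ",
]

#: Default edges (Hz) of the six contiguous half-open analysis bands A-F.
#: Motivated by receptor-fiber tuning clusters; spans 0-20 kHz.
DEFAULT_BAND_EDGES_HZ = (0.0, 3000.0, 5500.0, 8000.0, 11000.0, 16000.0, 20000.0)

BAND_LABELS = ("A", "B", "C", "D", "E", "F")


@dataclass(frozen=True)
class SongRecording:
    """A mono waveform with its provenance.

    ``samples`` are real-valued in [-1, 1]; ``song_type`` is ``"calling"``
    or ``"courtship"``.
    """

    samples: np.ndarray
    sample_rate: float
    song_type: str = "calling"
    individual_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError(
                f"recording must be mono (1-D); got shape {samples.shape}"
            )
        if not np.all(np.isfinite(samples)):
            raise ValueError("recording contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.song_type not in ("calling", "courtship"):
            raise ValueError(
                f"song_type must be 'calling' or 'courtship', got {self.song_type!r}"
            )
        object.__setattr__(self, "samples", samples)

    @property
    def nyquist(self) -> float:
        return self.sample_rate / 2.0

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided averaged power spectral density estimate."""

    frequencies: np.ndarray
    power: np.ndarray
    window_size: int
    window: str = "hann"

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.shape != p.shape:
            raise ValueError("frequencies and power must have matching shapes")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("power must be non-negative everywhere")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "power", p)

    @property
    def bin_spacing(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def total_power(self) -> float:
        """Integrated power (mean-square amplitude) across all bins."""
        return float(np.sum(self.power) * self.bin_spacing)


@dataclass(frozen=True)
class FrequencyBands:
    """Six labeled, contiguous, half-open frequency intervals [lo, hi)."""

    edges_hz: tuple[float, ...] = DEFAULT_BAND_EDGES_HZ

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges_hz)
        if len(edges) != 7:
            raise ValueError(
                f"six bands require exactly 7 edges, got {len(edges)}"
            )
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("band edges must be strictly increasing")
        object.__setattr__(self, "edges_hz", edges)

    @property
    def intervals(self) -> list[tuple[str, float, float]]:
        return [
            (lab, self.edges_hz[i], self.edges_hz[i + 1])
            for i, lab in enumerate(BAND_LABELS)
        ]

    @property
    def span(self) -> tuple[float, float]:
        return self.edges_hz[0], self.edges_hz[-1]


@dataclass(frozen=True)
class SongFeatures:
    """The nine characteristics of one song plus analysis provenance."""

    individual_id: str
    song_type: str
    dominant_frequency: float
    amplitude_db: float
    rel_amplitude: tuple[float, ...]  # bands A..F, sum to 1
    frequency_evenness: float
    band_edges_hz: tuple[float, ...] = DEFAULT_BAND_EDGES_HZ
    window_size: int = 256

    def __post_init__(self) -> None:
        rel = tuple(float(v) for v in self.rel_amplitude)
        if len(rel) != 6:
            raise ValueError("rel_amplitude must have six entries")
        if abs(sum(rel) - 1.0) > 1e-9:
            raise ValueError("relative amplitudes must sum to 1")
        if any(v < 0 or v > 1 for v in rel):
            raise ValueError("relative amplitudes must lie in [0, 1]")
        object.__setattr__(self, "rel_amplitude", rel)

    def to_dict(self) -> dict:
        d = {
            "individual_id": self.individual_id,
            "song_type": self.song_type,
            "dominant_frequency": self.dominant_frequency,
            "amplitude_db": self.amplitude_db,
            "frequency_evenness": self.frequency_evenness,
        }
        for lab, v in zip(BAND_LABELS, self.rel_amplitude):
            d[f"rel_amplitude_{lab}"] = v
        d["band_edges_hz"] = ";".join(str(e) for e in self.band_edges_hz)
        d["window_size"] = self.window_size
        return d


@dataclass(frozen=True)
class SongAnalysisConfig:
    """Analysis settings: window, overlap, band table, dB reference, SD flavor."""

    window_size: int = 256
    overlap: float = 0.5
    bands: FrequencyBands = field(default_factory=FrequencyBands)
    db_reference: float = 1.0  # full-scale RMS reference
    evenness_ddof: int = 1  # sample SD by default


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a mono RIFF WAV (PCM 16/24/32-bit or float32) to float in [-1, 1].

    Stereo files are rejected: channel mixing is a curation decision that
    should happen before analysis.
    """
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(
            f"{path}: expected mono audio, got {data.shape[1]} channels"
        )
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        samples = data.astype(float) / scale
    else:
        samples = data.astype(float)
    return samples, float(rate)


def write_wav(path: str | Path, recording: SongRecording) -> None:
    """Write a recording as 32-bit float WAV."""
    wavfile.write(
        str(path), int(recording.sample_rate), recording.samples.astype(np.float32)
    )


def power_spectrum(
    recording: SongRecording, window_size: int = 256, overlap: float = 0.5
) -> PowerSpectrum:
    """Welch-averaged, Hann-tapered power spectral density of a recording.

    Bin spacing is ``sample_rate / window_size``. A single full-length
    window reduces this to a plain tapered periodogram.
    """
    if window_size < 16 or window_size & (window_size - 1):
        raise ValueError(f"window_size must be a power of two >= 16, got {window_size}")
    n = len(recording.samples)
    if n < window_size:
        raise ValueError(
            f"recording has {n} samples but at least {window_size} are required "
            f"for one analysis window"
        )
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    freqs, psd = welch(
        recording.samples,
        fs=recording.sample_rate,
        window="hann",
        nperseg=window_size,
        noverlap=int(round(overlap * window_size)),
        detrend=False,
        scaling="density",
    )
    return PowerSpectrum(freqs, psd, window_size=window_size)


def dominant_frequency(spectrum: PowerSpectrum) -> float:
    """Frequency (Hz) of maximum spectral power; ties go to the lowest bin."""
    if not np.any(spectrum.power > 0):
        raise ValueError("no signal: spectrum is all zero")
    idx = int(np.argmax(spectrum.power))  # argmax returns the first maximum
    return float(spectrum.frequencies[idx])


def _band_amplitudes(spectrum: PowerSpectrum, bands: FrequencyBands) -> np.ndarray:
    """RMS amplitude per band: sqrt of spectral power integrated over [lo, hi)."""
    df = spectrum.bin_spacing
    amps = np.empty(6)
    for i, (_, lo, hi) in enumerate(bands.intervals):
        mask = (spectrum.frequencies >= lo) & (spectrum.frequencies < hi)
        amps[i] = math.sqrt(float(np.sum(spectrum.power[mask]) * df))
    return amps


def band_relative_amplitudes(
    recording: SongRecording,
    bands: FrequencyBands | None = None,
    window_size: int = 256,
    overlap: float = 0.5,
) -> np.ndarray:
    """Proportion of band RMS amplitude in each of the six bands A-F.

    Each band's RMS amplitude is divided by the sum of all six band
    amplitudes, so the result is scale-invariant and sums to 1.
    """
    bands = bands or FrequencyBands()
    if recording.sample_rate < 2 * bands.span[1]:
        raise ValueError(
            f"sample rate {recording.sample_rate} Hz cannot resolve the band "
            f"table's upper edge {bands.span[1]} Hz (need > {2 * bands.span[1]})"
        )
    spectrum = power_spectrum(recording, window_size=window_size, overlap=overlap)
    amps = _band_amplitudes(spectrum, bands)
    total = amps.sum()
    if total <= 0:
        raise ValueError("zero total band energy: cannot form relative amplitudes")
    return amps / total


def frequency_evenness(rel_amps, ddof: int = 1) -> float:
    """Negated standard deviation of the six relative amplitudes.

    0 for a perfectly even spectrum; more negative the more concentrated
    the energy. Sample SD (n-1 denominator) by default.
    """
    rel = np.asarray(rel_amps, dtype=float)
    if rel.shape != (6,):
        raise ValueError(f"expected six proportions, got shape {rel.shape}")
    if abs(rel.sum() - 1.0) > 1e-6:
        raise ValueError("relative amplitudes must sum to 1")
    return float(-np.std(rel, ddof=ddof))


def extract_song_features(
    recording: SongRecording, config: SongAnalysisConfig | None = None
) -> SongFeatures:
    """Compute all nine song characteristics of one recording.

    amplitude_db = 20 log10(waveform RMS / reference); with the default
    full-scale reference this is dBFS. Deterministic given inputs.
    """
    config = config or SongAnalysisConfig()
    spectrum = power_spectrum(
        recording, window_size=config.window_size, overlap=config.overlap
    )
    rel = band_relative_amplitudes(
        recording,
        bands=config.bands,
        window_size=config.window_size,
        overlap=config.overlap,
    )
    rms = float(np.sqrt(np.mean(recording.samples**2)))
    if rms <= 0:
        raise ValueError("silent recording: amplitude undefined")
    return SongFeatures(
        individual_id=recording.individual_id,
        song_type=recording.song_type,
        dominant_frequency=dominant_frequency(spectrum),
        amplitude_db=20.0 * math.log10(rms / config.db_reference),
        rel_amplitude=tuple(rel),
        frequency_evenness=frequency_evenness(rel, ddof=config.evenness_ddof),
        band_edges_hz=config.bands.edges_hz,
        window_size=config.window_size,
    )


def features_to_frame(features: list[SongFeatures]) -> pd.DataFrame:
    """Stack SongFeatures into a tidy one-row-per-recording DataFrame."""
    return pd.DataFrame([f.to_dict() for f in features])
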