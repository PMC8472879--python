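"""Signal conditioning: filtering, windowing, SNR gating, POS extraction.

Turns continuous pulse-wave recordings into fixed-length, quality-gated
model inputs.  The two cropping strategies are ``const_time`` (fixed
duration, beats may be cut) and ``const_beats`` (an integer number of
estimated pulse cycles, resampled to ``n_beats * 125`` samples so that every
window has an effective heart rate of 60 bpm).  Quality gating uses the
de Haan spectral signal-to-noise ratio: the energy in narrow bands around
the pulse peak and its first harmonic relative to the remaining in-band
energy, in dB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.fft import next_fast_len, rfft, rfftfreq

__all__ = [
    "WaveformRecord",
    "WindowingConfig",
    "SignalWindow",
    "SnrResult",
    "ConstantChannelError",
    "UndefinedHeartRateError",
    "bandpass_ppg",
    "estimate_heart_rate",
    "crop_windows",
    "resample_to_effective_60bpm",
    "add_derivative_channels",
    "compute_snr",
    "snr_from_energies",
    "gate_by_snr",
    "normalize_window",
    "pos_extract",
    "ADMISSIBLE_LENGTHS",
    "PIPELINE_ORDER",
]

#: window lengths (seconds or beat counts) used throughout the analyses
ADMISSIBLE_LENGTHS = (1, 2, 5, 7, 9, 11, 13, 15, 17, 20)

#: fixed stage order of the standard preprocessing pipeline
PIPELINE_ORDER = ("bandpass", "crop", "snr_gate", "label_filter", "normalize")

#: samples per beat after const_beats resampling (125 Hz at 60 bpm)
TARGET_SAMPLES_PER_BEAT = 125

#: spectral search band for the pulse peak, Hz (30-180 bpm)
HR_BAND = (0.5, 3.0)

#: analysis band for the SNR measure, Hz
SNR_ANALYSIS_BAND = (0.5, 8.0)

#: half-width of the bands around the pulse peak and its harmonic, Hz
SNR_BAND_HALFWIDTH = 0.2

#: maximum FFT frequency-bin width for spectral HR estimation, Hz
HR_FREQ_RESOLUTION = 0.02


class ConstantChannelError(ValueError):
    """A window channel is constant and cannot be normalized."""


class UndefinedHeartRateError(ValueError):
    """No spectral pulse peak exists (e.g. all-zero input)."""


@dataclass
class WaveformRecord:
    """One subject's continuous paired pulse/pressure time series.

    ``abp`` is absent (``None``) for camera-derived pulse signals, which
    carry reference BP separately at bedside-monitor resolution.
    """

    subject_id: str
    ppg: np.ndarray
    abp: np.ndarray | None
    fs: float = 125.0

    def __post_init__(self) -> None:
        self.ppg = np.asarray(self.ppg, dtype=float)
        if self.abp is not None:
            self.abp = np.asarray(self.abp, dtype=float)
            if len(self.abp) != len(self.ppg):
                raise ValueError("ppg and abp must have equal length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.ppg) / self.fs


@dataclass
class WindowingConfig:
    """Cropping strategy and length for model-input windows."""

    strategy: str = "const_beats"
    length_parameter: int = 7
    target_samples_per_beat: int = TARGET_SAMPLES_PER_BEAT
    overlap: float = 0.0

    def __post_init__(self) -> None:
        if self.strategy not in ("const_time", "const_beats"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.length_parameter <= 0:
            raise ValueError("length_parameter must be positive")
        if self.length_parameter not in ADMISSIBLE_LENGTHS:
            warnings.warn(
                f"length_parameter {self.length_parameter} outside the "
                f"standard set {ADMISSIBLE_LENGTHS}", stacklevel=2)
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must lie in [0, 1)")


@dataclass
class SignalWindow:
    """One fixed-length model-input segment with provenance metadata."""

    samples: np.ndarray           # (n,) single channel or (n, 3)
    subject_id: str
    source_offset: int            # sample index into the parent record
    estimated_hr: float = np.nan  # beats/min
    snr_db: float = np.nan
    strategy_tag: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[-1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


@dataclass
class SnrResult:
    """De Haan SNR decomposition of one window."""

    snr_db: float
    pulse_freq: float
    energy_pulse: float
    energy_rest: float
    infinite: bool = False


def bandpass_ppg(record: WaveformRecord, low: float = 0.5, high: float = 8.0,
                 order: int = 4) -> WaveformRecord:
    """Band-pass the pulse channel with a Butterworth filter.

    Applied forward-backward (zero phase) so pulse morphology is not
    phase-distorted; the pressure channel is untouched.
    """
    nyq = record.fs / 2.0
    if not 0.0 < low < high < nyq:
        raise ValueError(f"cutoffs ({low}, {high}) must satisfy 0 < low < high < fs/2")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=record.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, record.ppg)
    return replace(record, ppg=filtered)


def _pulse_spectrum(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Zero-padded power spectrum with bin width <= HR_FREQ_RESOLUTION."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    nfft = next_fast_len(max(n, int(np.ceil(fs / HR_FREQ_RESOLUTION))))
    power = np.abs(rfft(x - x.mean(), nfft)) ** 2
    freqs = rfftfreq(nfft, 1.0 / fs)
    return freqs, power


def estimate_heart_rate(segment: np.ndarray, fs: float) -> float:
    """Heart rate (beats/min) from the dominant spectral component.

    Searches 0.5-3.0 Hz on a zero-padded FFT so the frequency resolution is
    at most 0.02 Hz regardless of segment length.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0 or np.allclose(segment, segment.flat[0]):
        raise UndefinedHeartRateError("segment has no oscillatory content")
    freqs, power = _pulse_spectrum(segment, fs)
    band = (freqs >= HR_BAND[0]) & (freqs <= HR_BAND[1])
    if not band.any():
        raise UndefinedHeartRateError("sampling rate too low for the pulse band")
    if power[band].max() <= 0.0:
        raise UndefinedHeartRateError("segment has no oscillatory content")
    peak_freq = freqs[band][np.argmax(power[band])]
    return 60.0 * peak_freq


def resample_to_effective_60bpm(segment: np.ndarray, n_beats: int,
                                target_samples_per_beat: int = TARGET_SAMPLES_PER_BEAT,
                                ) -> np.ndarray:
    """Fourier-resample a segment of ``n_beats`` pulses to a fixed length.

    The output has exactly ``n_beats * target_samples_per_beat`` samples, so
    at the notional 125 Hz rate each beat spans one second (60 bpm).
    """
    segment = np.asarray(segment, dtype=float)
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if segment.size == 0:
        raise ValueError("segment is empty")
    return sps.resample(segment, n_beats * target_samples_per_beat)


#: seconds of context used for per-window HR estimation in const_beats mode
_HR_CONTEXT_S = 20.0


def crop_windows(record: WaveformRecord, cfg: WindowingConfig,
                 ) -> list[tuple[SignalWindow, np.ndarray | None]]:
    """Crop a record into windows, returning (window, abp_segment) pairs.

    ``const_time``: consecutive fixed-duration segments (beats may be cut).
    ``const_beats``: the local heart rate is estimated on a 20 s
    neighbourhood, the span holding exactly ``length_parameter`` beats is
    cropped and Fourier-resampled to ``length_parameter * 125`` samples.
    The ABP segment always covers the original (un-resampled) time span, so
    labels are unaffected by resampling.  Windows are consecutive and
    disjoint by default; a record shorter than one window yields an empty
    list.
    """
    out: list[tuple[SignalWindow, np.ndarray | None]] = []
    n_total = len(record.ppg)
    start = 0
    while True:
        if cfg.strategy == "const_time":
            span = int(round(cfg.length_parameter * record.fs))
            if start + span > n_total:
                break
            samples = record.ppg[start:start + span]
            hr = np.nan
        else:
            ctx_half = int(_HR_CONTEXT_S * record.fs / 2)
            lo = max(0, start - ctx_half)
            hi = min(n_total, start + ctx_half)
            try:
                hr = estimate_heart_rate(record.ppg[lo:hi], record.fs)
            except UndefinedHeartRateError:
                break
            span = int(round(cfg.length_parameter * (60.0 / hr) * record.fs))
            if span < 2 or start + span > n_total:
                break
            samples = resample_to_effective_60bpm(
                record.ppg[start:start + span], cfg.length_parameter,
                cfg.target_samples_per_beat)
        abp_seg = None if record.abp is None else record.abp[start:start + span]
        out.append((
            SignalWindow(samples=samples, subject_id=record.subject_id,
                         source_offset=start, estimated_hr=hr,
                         strategy_tag=f"{cfg.strategy}_{cfg.length_parameter}"),
            abp_seg,
        ))
        start += max(1, int(round(span * (1.0 - cfg.overlap))))
    return out


def add_derivative_channels(window: SignalWindow) -> SignalWindow:
    """Stack the raw window with its first and second discrete derivatives.

    Central differences with one-sided ends; the second derivative is the
    first-derivative operator applied twice.  Must be called before
    normalization (channels are normalized independently afterwards).
    """
    if window.channels != 1:
        raise ValueError("window already has derivative channels")
    d1 = np.gradient(window.samples)
    d2 = np.gradient(d1)
    return replace(window, samples=np.stack([window.samples, d1, d2], axis=-1))


def snr_from_energies(energy_pulse: float, energy_rest: float) -> float:
    """SNR in dB, ``10 * log10(E_P / E_S)``."""
    if energy_rest <= 0.0:
        return np.inf
    return 10.0 * np.log10(energy_pulse / energy_rest)


def compute_snr(window: np.ndarray, fs: float) -> SnrResult:
    """De Haan spectral SNR of a pulse window.

    The pulse peak is located as in :func:`estimate_heart_rate`; ``E_P``
    sums the power inside +/-0.2 Hz bands around the peak and its first
    harmonic, ``E_S`` the remaining power within the 0.5-8 Hz analysis band.
    The measure becomes unreliable below roughly 4 s of signal.
    """
    window = np.asarray(window, dtype=float)
    if window.size == 0 or np.allclose(window, window.flat[0]):
        return SnrResult(snr_db=-np.inf, pulse_freq=np.nan,
                         energy_pulse=0.0, energy_rest=0.0, infinite=False)
    freqs, power = _pulse_spectrum(window, fs)
    hr_band = (freqs >= HR_BAND[0]) & (freqs <= HR_BAND[1])
    if not hr_band.any() or power[hr_band].max() <= 0.0:
        return SnrResult(snr_db=-np.inf, pulse_freq=np.nan,
                         energy_pulse=0.0, energy_rest=0.0, infinite=False)
    f0 = freqs[hr_band][np.argmax(power[hr_band])]
    band_hi = min(SNR_ANALYSIS_BAND[1], fs / 2.0)
    analysis = (freqs >= SNR_ANALYSIS_BAND[0]) & (freqs <= band_hi)
    pulse_bands = (np.abs(freqs - f0) <= SNR_BAND_HALFWIDTH) | \
                  (np.abs(freqs - 2.0 * f0) <= SNR_BAND_HALFWIDTH)
    e_p = float(power[analysis & pulse_bands].sum())
    e_s = float(power[analysis & ~pulse_bands].sum())
    if e_s <= 0.0:
        return SnrResult(snr_db=np.inf, pulse_freq=f0, energy_pulse=e_p,
                         energy_rest=e_s, infinite=True)
    return SnrResult(snr_db=snr_from_energies(e_p, e_s), pulse_freq=f0,
                     energy_pulse=e_p, energy_rest=e_s)


def gate_by_snr(windows: list[SignalWindow], threshold: float = -7.0,
                ) -> list[SignalWindow]:
    """Keep windows with ``snr_db >= threshold`` (boundary inclusive)."""
    return [w for w in windows if w.snr_db >= threshold]


def normalize_window(window: SignalWindow) -> SignalWindow:
    """Scale each channel to zero mean and unit (population) variance."""
    x = window.samples
    x2 = x[:, None] if x.ndim == 1 else x
    std = x2.std(axis=0)
    if np.any(std == 0.0):
        raise ConstantChannelError(
            f"constant channel in window at offset {window.source_offset} "
            f"of subject {window.subject_id}")
    out = (x2 - x2.mean(axis=0)) / std
    if x.ndim == 1:
        out = out[:, 0]
    return replace(window, samples=out)


#: POS projection matrix (plane orthogonal to the skin-tone axis)
_POS_PROJECTION = np.array([[0.0, 1.0, -1.0],
                            [-2.0, 1.0, 1.0]])

#: POS sliding-window length, seconds
POS_WINDOW_S = 1.6


def pos_extract(rgb_trace: np.ndarray, fs: float) -> np.ndarray:
    """Plane-orthogonal-to-skin pulse extraction from an RGB trace.

    Each 1.6 s sliding window is temporally normalized by its per-channel
    running mean, projected onto the two POS axes, recombined with the
    alpha weighting ``h = s1 + (sigma(s1)/sigma(s2)) * s2`` and overlap-added
    after mean removal.  Scale-invariant by construction; equal constant
    channels yield zero output.
    """
    rgb = np.asarray(rgb_trace, dtype=float)
    if rgb.ndim != 2 or rgb.shape[1] != 3:
        raise ValueError("rgb_trace must have shape (n, 3)")
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = rgb.shape[0]
    win = int(round(POS_WINDOW_S * fs))
    if n < win:
        raise ValueError(f"trace shorter than one POS window ({win} samples)")
    pulse = np.zeros(n)
    for end in range(win, n + 1):
        c = rgb[end - win:end]
        mean = c.mean(axis=0)
        if np.any(mean == 0.0):
            raise ValueError("channel with zero running mean")
        cn = c / mean
        s = cn @ _POS_PROJECTION.T
        s1, s2 = s[:, 0], s[:, 1]
        sd2 = s2.std()
        h = s1 + (s1.std() / sd2) * s2 if sd2 > 0.0 else s1
        pulse[end - win:end] += h - h.mean()
    return pulse
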