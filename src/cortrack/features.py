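"""Acoustic, phonemic, and semantic stimulus representations.

Sounds are represented four ways: a cochlea-like auditory spectrogram
(128 overlapping log-spaced bands, 180-7246 Hz, 10 ms frames integrated
over 16 ms), its across-band average (the amplitude envelope), a
time-integrated per-band power spectrum, and a modulation power spectrum
(MPS) at four spectral scales and four temporal rates.  Spoken words are
additionally encoded as a +/-1 phoneme-by-frame indicator matrix from
time-aligned annotations.

All features are standardized *across stimuli* before decoding: the
spectrogram and the band power spectrum per frequency band, the MPS per
(scale, rate, band) cell, the envelope and each semantic dimension
globally.  Evoked responses are standardized per (sensor, 10 ms sample)
across stimuli.  The z-score uses the population standard deviation
(divide by n), so two stimuli with values {1, 3} map exactly to
{-1, +1}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Waveform",
    "Spectrogram",
    "Envelope",
    "SpectrumFFT",
    "ModulationPowerSpectrum",
    "PhonemeSequence",
    "StandardizationState",
    "log_band_centers",
    "standardize_features",
    "compute_spectrogram",
    "compute_envelope",
    "compute_fft_spectrum",
    "compute_mps",
    "encode_phonemes",
    "standardize_time_varying",
    "standardize_static",
    "standardize_responses",
]

DEFAULT_RATE = 16_000
DEFAULT_N_BANDS = 128
DEFAULT_FMIN = 180.0
DEFAULT_FMAX = 7246.0
DEFAULT_FRAME_STEP = 0.010
DEFAULT_INTEGRATION = 0.016
DEFAULT_SCALES = (0.5, 1.0, 2.0, 4.0)  # cycles/octave
DEFAULT_RATES = (1.0, 3.0, 9.0, 27.0)  # Hz


@dataclass
class Waveform:
    """Mono sound pressure waveform.

    Parameters
    ----------
    samples : ndarray, shape (n_samples,)
        Amplitude sequence (dimensionless).
    rate : int
        Sampling rate in Hz; stimuli are assumed low-pass filtered and
        resampled to 16 kHz upstream.
    """

    samples: np.ndarray
    rate: int = DEFAULT_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("waveform must be mono (1-D)")
        if self.samples.size == 0:
            raise ValueError("waveform is empty")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite values")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass
class Spectrogram:
    """Band x frame energy matrix from the auditory filterbank."""

    values: np.ndarray  # (n_bands, n_frames)
    center_freqs: np.ndarray  # Hz, strictly increasing
    frame_step: float = DEFAULT_FRAME_STEP
    integration_window: float = DEFAULT_INTEGRATION

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class Envelope:
    """Across-band mean of a spectrogram; one value per 10 ms frame."""

    values: np.ndarray  # (n_frames,)
    frame_step: float = DEFAULT_FRAME_STEP


@dataclass
class SpectrumFFT:
    """Time-integrated power per filterbank band (non time-varying)."""

    values: np.ndarray  # (n_bands,)
    center_freqs: np.ndarray


@dataclass
class ModulationPowerSpectrum:
    """Modulation energy per (spectral scale, temporal rate, band).

    Upward- and downward-going modulations are combined into a single
    value per cell.
    """

    values: np.ndarray  # (n_scales, n_rates, n_bands)
    scales: tuple = DEFAULT_SCALES
    rates: tuple = DEFAULT_RATES


@dataclass
class PhonemeSequence:
    """Phoneme x frame indicator matrix with entries in {-1, +1}."""

    values: np.ndarray  # (n_phonemes, n_frames)
    phoneme_labels: list = field(default_factory=list)


def log_band_centers(
    n_bands: int = DEFAULT_N_BANDS,
    fmin: float = DEFAULT_FMIN,
    fmax: float = DEFAULT_FMAX,
) -> np.ndarray:
    """Logarithmically spaced band center frequencies in Hz."""
    return np.geomspace(fmin, fmax, n_bands)


def _band_windows(freqs: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Gaussian band weights in log-frequency, (n_bands, n_freqs).

    Bandwidth is tied to the inter-band spacing so that neighbouring
    bands overlap, mimicking overlapping cochlear filters.
    """
    log_f = np.log(np.maximum(freqs, 1e-12))
    log_c = np.log(centers)
    # spacing in log-Hz between adjacent centers; sigma = one spacing
    spacing = (log_c[-1] - log_c[0]) / max(len(centers) - 1, 1)
    sigma = max(spacing, 1e-6)
    w = np.exp(-0.5 * ((log_f[None, :] - log_c[:, None]) / sigma) ** 2)
    w[:, freqs <= 0] = 0.0
    return w


def compute_spectrogram(
    w: Waveform,
    n_bands: int = DEFAULT_N_BANDS,
    fmin: float = DEFAULT_FMIN,
    fmax: float = DEFAULT_FMAX,
    frame_step: float = DEFAULT_FRAME_STEP,
    integration_window: float = DEFAULT_INTEGRATION,
) -> Spectrogram:
    """Auditory spectrogram via a log-spaced band-pass filterbank.

    Each band-pass signal is obtained by Gaussian weighting of the
    signal spectrum in log-frequency, half-wave rectified, and averaged
    within an ``integration_window`` advancing in ``frame_step`` hops.
    Frame ``t`` covers ``[t*frame_step, t*frame_step + integration_window)``
    with zero padding past the end of the sound; the frame count is
    ``ceil(duration / frame_step)``.
    """
    if w.duration <= integration_window:
        raise ValueError("waveform shorter than the integration window")
    x = w.samples
    n = x.size
    centers = log_band_centers(n_bands, fmin, fmax)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / w.rate)
    win = _band_windows(freqs, centers)
    # band signals: inverse transform of the weighted spectrum
    band_sig = np.fft.irfft(win * spec[None, :], n=n, axis=1)
    rect = np.maximum(band_sig, 0.0)

    step = int(round(frame_step * w.rate))
    ilen = int(round(integration_window * w.rate))
    n_frames = int(np.ceil(n / step))
    pad = (n_frames - 1) * step + ilen - n
    if pad > 0:
        rect = np.pad(rect, ((0, 0), (0, pad)))
    # sliding mean over the integration window at each hop
    csum = np.concatenate(
        [np.zeros((n_bands, 1)), np.cumsum(rect, axis=1)], axis=1
    )
    starts = np.arange(n_frames) * step
    values = (csum[:, starts + ilen] - csum[:, starts]) / ilen
    return Spectrogram(values, centers, frame_step, integration_window)


def compute_envelope(s: Spectrogram) -> Envelope:
    """Amplitude envelope: the across-band mean of the spectrogram."""
    return Envelope(s.values.mean(axis=0), s.frame_step)


def compute_fft_spectrum(
    w: Waveform,
    n_bands: int = DEFAULT_N_BANDS,
    fmin: float = DEFAULT_FMIN,
    fmax: float = DEFAULT_FMAX,
) -> SpectrumFFT:
    """Stimulus power per frequency band, integrated over the sound.

    Uses the same band definitions as the spectrogram filterbank; the
    squared magnitude spectrum is accumulated under each band window.
    """
    x = w.samples
    centers = log_band_centers(n_bands, fmin, fmax)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / w.rate)
    win = _band_windows(freqs, centers)
    power = win @ (np.abs(spec) ** 2) / x.size
    return SpectrumFFT(power, centers)


def compute_mps(
    s: Spectrogram,
    scales: tuple = DEFAULT_SCALES,
    rates: tuple = DEFAULT_RATES,
) -> ModulationPowerSpectrum:
    """Modulation power spectrum of the (log) auditory spectrogram.

    The mean-removed log-spectrogram is filtered in the 2-D modulation
    domain with Gaussian filters centered at each (scale, rate) pair;
    the response magnitude is symmetric in both modulation axes, so
    upward and downward sweeps contribute to the same cell.  Filter
    bandwidth is half the center frequency with a floor (1.5 Hz
    temporal, 0.5 cyc/oct spectral) so that slow/broad energy loads
    the lowest-rate/-scale filters hardest.  Per band, the energy is
    the temporal mean square of the filtered spectrogram.
    """
    vals = s.values
    n_bands, n_frames = vals.shape
    if n_frames < 2:
        raise ValueError("spectrogram must have at least 2 frames")
    # support check against the slowest temporal filter
    slowest = min(rates)
    if n_frames * s.frame_step < 1.0 / slowest:
        warnings.warn(
            "spectrogram shorter than the slowest modulation filter "
            "period; computing on the zero-padded signal",
            RuntimeWarning,
        )
    eps = 1e-12
    L = np.log(vals + eps)
    L = L - L.mean()

    # modulation-domain axes: spectral in cycles/octave, temporal in Hz
    d_oct = np.log2(s.center_freqs[-1] / s.center_freqs[0]) / max(
        n_bands - 1, 1
    )
    omega = np.abs(np.fft.fftfreq(n_bands, d=d_oct))  # cycles/octave
    rate_ax = np.abs(np.fft.fftfreq(n_frames, d=s.frame_step))  # Hz

    F = np.fft.fft2(L)
    out = np.zeros((len(scales), len(rates), n_bands))
    for i, sc in enumerate(scales):
        hs = np.exp(-0.5 * ((omega - sc) / max(sc / 2.0, 0.5)) ** 2)
        for j, rt in enumerate(rates):
            ht = np.exp(-0.5 * ((rate_ax - rt) / max(rt / 2.0, 1.5)) ** 2)
            filt = np.fft.ifft2(F * np.outer(hs, ht)).real
            out[i, j] = (filt**2).mean(axis=1)
    return ModulationPowerSpectrum(out, tuple(scales), tuple(rates))


def encode_phonemes(
    annotation: pd.DataFrame,
    frame_step: float = DEFAULT_FRAME_STEP,
    min_count: int = 10,
    n_frames: dict | None = None,
) -> dict[object, PhonemeSequence]:
    """Encode time-aligned phoneme tables as +/-1 frame matrices.

    Parameters
    ----------
    annotation : DataFrame
        Columns ``word_id``, ``phoneme``, ``start_s``, ``end_s``; times
        in seconds from word onset, intervals non-overlapping within a
        word.
    frame_step : float
        Frame hop in seconds (10 ms frames).
    min_count : int
        Phonemes with fewer instances across the whole stimulus set are
        dropped from the row set (default 10 instances).
    n_frames : dict, optional
        Frame count per word; defaults to covering the last annotated
        interval of each word.

    Returns
    -------
    dict
        ``word_id -> PhonemeSequence``; row order (the retained phoneme
        labels, sorted) is shared by all words.  A frame is +1 for the
        phoneme whose interval contains the frame onset, -1 elsewhere;
        at most one phoneme is active per frame.
    """
    required = {"word_id", "phoneme", "start_s", "end_s"}
    if not required.issubset(annotation.columns):
        raise ValueError(f"annotation needs columns {sorted(required)}")
    for wid, grp in annotation.groupby("word_id"):
        iv = grp.sort_values("start_s")[["start_s", "end_s"]].to_numpy()
        if np.any(iv[:, 1] < iv[:, 0]) or np.any(iv[1:, 0] < iv[:-1, 1] - 1e-12):
            raise ValueError(f"overlapping phoneme intervals in word {wid!r}")

    counts = annotation["phoneme"].value_counts()
    labels = sorted(counts[counts >= min_count].index)
    out: dict[object, PhonemeSequence] = {}
    for wid, grp in annotation.groupby("word_id"):
        if n_frames is not None:
            nf = int(n_frames[wid])
        else:
            nf = int(np.ceil(grp["end_s"].max() / frame_step))
        mat = -np.ones((len(labels), nf))
        onsets = np.arange(nf) * frame_step
        for _, row in grp.iterrows():
            if row["phoneme"] not in labels:
                continue
            r = labels.index(row["phoneme"])
            active = (onsets >= row["start_s"] - 1e-12) & (
                onsets < row["end_s"] - 1e-12
            )
            mat[r, active] = 1.0
        out[wid] = PhonemeSequence(mat, list(labels))
    return out


@dataclass
class StandardizationState:
    """Per-feature mean/sd across stimuli (population sd convention).

    ``sd == 0`` marks zero-variance features, which are centered to 0
    and left there; :meth:`invert` restores the mean.
    """

    mean: np.ndarray
    sd: np.ndarray
    grouping: str = ""

    def apply(self, x: np.ndarray) -> np.ndarray:
        safe = np.where(self.sd > 0, self.sd, 1.0)
        return (x - self.mean) / safe

    def invert(self, z: np.ndarray) -> np.ndarray:
        safe = np.where(self.sd > 0, self.sd, 1.0)
        return z * safe + self.mean


def _warn_zero_variance(sd: np.ndarray, what: str) -> None:
    if np.any(sd == 0):
        warnings.warn(
            f"{int(np.sum(sd == 0))} zero-variance {what} left centered at 0",
            RuntimeWarning,
        )


def standardize_features(features, grouping: str):
    """Standardize a feature set across stimuli under a grouping rule.

    ``grouping="per-band"`` treats ``features`` as a list of band x
    frame arrays (spectrogram, envelope) and pools frames within each
    band; ``grouping="per-feature"`` treats it as an (n_stimuli,
    n_features) matrix (band power spectrum, flattened MPS, semantic
    vectors) with statistics per column.
    """
    if grouping == "per-band":
        return standardize_time_varying(features)
    if grouping == "per-feature":
        return standardize_static(np.asarray(features))
    raise ValueError("grouping must be 'per-band' or 'per-feature'")


def standardize_time_varying(
    arrays: list[np.ndarray],
) -> tuple[list[np.ndarray], StandardizationState]:
    """Standardize band x frame features per band across stimuli.

    Statistics pool every frame of every stimulus within a band.  A
    1-D sequence (the envelope) is treated as a single band.
    """
    if len(arrays) < 2:
        raise ValueError("need at least 2 stimuli")
    arrs = [np.atleast_2d(np.asarray(a, dtype=float)) for a in arrays]
    pooled = np.concatenate(arrs, axis=1)
    mean = pooled.mean(axis=1, keepdims=True)
    sd = pooled.std(axis=1, keepdims=True)  # population sd
    _warn_zero_variance(sd, "bands")
    state = StandardizationState(mean, sd, grouping="per-band")
    out = [state.apply(a) for a in arrs]
    if arrays[0].ndim == 1:
        out = [o[0] for o in out]
    return out, state


def standardize_static(
    values: np.ndarray,
) -> tuple[np.ndarray, StandardizationState]:
    """Standardize an (n_stimuli, n_features) matrix per feature.

    Covers the band power spectrum (per band), the MPS (per scale x
    rate x band cell, flattened), and semantic vectors (per dimension).
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 stimuli")
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    _warn_zero_variance(sd, "features")
    state = StandardizationState(mean, sd, grouping="per-feature")
    return state.apply(values), state


def standardize_responses(
    data: np.ndarray,
) -> tuple[np.ndarray, StandardizationState]:
    """Standardize evoked responses per (sensor, 10 ms sample).

    ``data`` is (n_stimuli, n_sensors, n_times); statistics are taken
    across stimuli independently for every sensor/time cell.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected (n_stimuli, n_sensors, n_times)")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 stimuli")
    mean = data.mean(axis=0)
    sd = data.std(axis=0)
    _warn_zero_variance(sd, "sensor/time cells")
    state = StandardizationState(mean, sd, grouping="per-sensor-time")
    return state.apply(data), state
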