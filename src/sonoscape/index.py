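"""Per-minute spectral indices: background noise (BGNsp), PMNsp and ΣPMN.

The index pipeline works on one-minute mono recordings sampled at 48 kHz.
Each minute is turned into a dB spectrogram of 256 frequency bands
(93.75 Hz wide, spanning 0-24 kHz) by 5625 non-overlapping 512-sample
Hann-windowed FFT frames (~0.01067 s each).  Per band, the modal dB value
over the minute is taken as the background noise BGNsp; the de-noised
spectrogram is the clipped residual above that mode.  ΣPMN is the sum of
the residual over all frames of a band; PMNsp is its maximum.  Stationary
components (sensor self-noise, steady rain or wind, constant insect drones)
shift a band's mode and are therefore removed, while transient events
(calls, song pulses) survive and accumulate into ΣPMN.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile
from scipy.ndimage import uniform_filter1d

logger = logging.getLogger(__name__)

SAMPLE_RATE = 48_000
FFT_SIZE = 512
N_BANDS = FFT_SIZE // 2  # Nyquist bin dropped
FRAMES_PER_MINUTE = 60 * SAMPLE_RATE // FFT_SIZE  # 5625
BAND_WIDTH_HZ = SAMPLE_RATE / FFT_SIZE  # 93.75
DB_FLOOR = -120.0

#: 1-based minute-of-day labels excluded from all analyses (recorder quirk).
DEFAULT_EXCLUDED_MINUTES = (385, 386, 1080)
#: Minutes trimmed from each end of a deployment (fieldwork sounds).
DEFAULT_EDGE_MINUTES = 30


class InputError(ValueError):
    """Raised for invalid audio or table inputs."""


@dataclass
class MinuteSpectrogram:
    """dB magnitude matrix for one site-minute: ``values[band, frame]``."""

    values: np.ndarray
    site_id: str = ""
    day: int = 0
    minute_of_day: int = 0
    band_width_hz: float = BAND_WIDTH_HZ
    frame_duration_s: float = FFT_SIZE / SAMPLE_RATE

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class NoiseProfile:
    """Per-band modal dB amplitude (BGNsp) for one minute."""

    bgn_sp: np.ndarray


def band_centers(n_bands: int = N_BANDS, band_width: float = BAND_WIDTH_HZ) -> np.ndarray:
    """Center frequencies (Hz) of the native analysis bands."""
    return (np.arange(n_bands) + 0.5) * band_width


def bands_in_range(freq_lo: float, freq_hi: float,
                   n_bands: int = N_BANDS,
                   band_width: float = BAND_WIDTH_HZ) -> np.ndarray:
    """Indices of bands whose center frequency lies in the half-open [lo, hi).

    The half-open convention makes adjacent ranges partition the bands, so
    e.g. the eight 1-kHz aggregates between 1 and 9 kHz sum exactly to the
    1-9 kHz aggregate.
    """
    c = band_centers(n_bands, band_width)
    return np.nonzero((c >= freq_lo) & (c < freq_hi))[0]


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a mono WAV file, returning float samples in [-1, 1] and the rate."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        raise InputError(f"{path}: expected mono audio, got {data.ndim} channels")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return data, int(rate)


def write_wav(path, audio: np.ndarray, sample_rate: int = SAMPLE_RATE) -> None:
    wavfile.write(path, sample_rate, np.asarray(audio, dtype=np.float32))


def compute_spectrogram(audio: np.ndarray,
                        sample_rate: int = SAMPLE_RATE,
                        fft_size: int = FFT_SIZE,
                        db_floor: float = DB_FLOOR,
                        site_id: str = "",
                        day: int = 0,
                        minute_of_day: int = 0) -> MinuteSpectrogram:
    """dB spectrogram of one 60-s minute: non-overlapping Hann frames.

    With the defaults (48 kHz, FFT 512, hop = frame length) a full minute is
    exactly 5625 frames of 256 bands, 93.75 Hz each, topping out at 24 kHz.
    Audio longer than 60 s is truncated; shorter audio is an error.
    """
    if sample_rate != SAMPLE_RATE:
        raise InputError(f"expected {SAMPLE_RATE} Hz audio, got {sample_rate}")
    n_needed = 60 * sample_rate
    audio = np.asarray(audio, dtype=np.float64).ravel()
    if audio.size < n_needed:
        raise InputError(f"audio too short: {audio.size} samples < {n_needed}")
    audio = audio[:n_needed]
    n_frames = n_needed // fft_size
    frames = audio.reshape(n_frames, fft_size)
    window = np.hanning(fft_size)
    mag = np.abs(np.fft.rfft(frames * window, axis=1))[:, : fft_size // 2]
    floor_amp = 10.0 ** (db_floor / 20.0)
    db = 20.0 * np.log10(np.maximum(mag, floor_amp))
    return MinuteSpectrogram(values=db.T.copy(), site_id=site_id, day=day,
                             minute_of_day=minute_of_day,
                             band_width_hz=sample_rate / fft_size,
                             frame_duration_s=fft_size / sample_rate)


def modal_background(values: np.ndarray,
                     bin_width: float = 1.0,
                     smooth_bins: int = 5) -> float:
    """Modal dB of one band: histogram mode with quiet-biased tie-breaking.

    The histogram uses ``bin_width``-dB bins anchored at the observed
    minimum.  To stabilize the estimate against sparse histograms, the
    maximal ``smooth_bins``-bin moving window of counts is located first
    (integer sums, ties toward the lowest bin) and the mode is the bin with
    the highest raw count inside that window, again tie-broken toward the
    lowest bin; the lower edge of that bin is returned.  Anchoring at the
    minimum makes the estimate exactly equivariant under constant dB shifts,
    and a constant band returns its own value.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise InputError("cannot estimate background of an empty band")
    mn = float(x.min())
    idx = np.floor((x - mn) / bin_width).astype(np.int64)
    counts = np.bincount(idx)
    j = _windowed_mode_bin(counts[None, :], smooth_bins)[0]
    return mn + j * bin_width


def _windowed_mode_bin(counts: np.ndarray, smooth_bins: int) -> np.ndarray:
    """Row-wise modal bin: raw-count argmax inside the maximal count window.

    ``counts`` is (rows, bins) of non-negative integers.  All arithmetic is
    integer-exact so scalar and batch paths tie-break identically.
    """
    n_rows, k = counts.shape
    if smooth_bins <= 1:
        return np.argmax(counts, axis=1)
    half = smooth_bins // 2
    padded = np.zeros((n_rows, k + 2 * half + 1), dtype=np.int64)
    padded[:, half + 1:half + 1 + k] = counts
    csum = np.cumsum(padded, axis=1)
    # window_sum[:, j] = counts[:, j-half .. j+half], zero outside
    window_sum = csum[:, smooth_bins:] - csum[:, :k]
    jw = np.argmax(window_sum, axis=1)  # first max = lowest bin on ties
    offsets = np.arange(-half, half + 1)
    win_idx = jw[:, None] + offsets
    valid = (win_idx >= 0) & (win_idx < k)
    vals = np.take_along_axis(counts, np.clip(win_idx, 0, k - 1), axis=1)
    vals = np.where(valid, vals, -1)
    return np.clip(win_idx[np.arange(n_rows), np.argmax(vals, axis=1)], 0, k - 1)


def modal_background_batch(values: np.ndarray,
                           bin_width: float = 1.0,
                           smooth_bins: int = 5) -> np.ndarray:
    """Vectorized :func:`modal_background` over the rows of a 2-D array.

    Bit-identical to the scalar routine applied row by row (a tested
    property); used by the batch index path where hundreds of thousands of
    band-minutes are processed.
    """
    X = np.asarray(values)
    if X.ndim != 2 or X.shape[1] == 0:
        raise InputError("expected a non-empty 2-D array of band rows")
    n_rows = X.shape[0]
    mn = X.min(axis=1, keepdims=True)
    # X - mn >= 0, so integer truncation is the floor
    idx = ((X - mn) * (1.0 / bin_width)).astype(np.int64)
    k = int(idx.max()) + 1
    flat = (idx + (np.arange(n_rows, dtype=np.int64) * k)[:, None]).ravel()
    counts = np.bincount(flat, minlength=n_rows * k).reshape(n_rows, k)
    j = _windowed_mode_bin(counts, smooth_bins)
    return mn.ravel() + j * bin_width


def estimate_background(spec: MinuteSpectrogram | np.ndarray,
                        bin_width: float = 1.0,
                        smooth_bins: int = 5) -> NoiseProfile:
    """BGNsp: per-band modal dB amplitude of the minute."""
    values = spec.values if isinstance(spec, MinuteSpectrogram) else np.asarray(spec)
    return NoiseProfile(bgn_sp=modal_background_batch(values, bin_width, smooth_bins))


def denoise(spec: MinuteSpectrogram | np.ndarray,
            noise: NoiseProfile | np.ndarray,
            smooth: bool = True,
            clip_negative: bool = True,
            smooth_frames: int = 3) -> np.ndarray:
    """Residual spectrogram above the background mode.

    ``residual[b, t] = dB[b, t] - bgn_sp[b]``, clipped at zero (unless
    ``clip_negative`` is disabled, in which case signed deviations are kept),
    then smoothed along time by a centered ``smooth_frames`` moving average
    with replicated edges.  Smoothing can be switched off to preserve exact
    toy arithmetic.
    """
    values = spec.values if isinstance(spec, MinuteSpectrogram) else np.asarray(spec)
    bgn = noise.bgn_sp if isinstance(noise, NoiseProfile) else np.asarray(noise)
    if values.shape[0] != bgn.shape[0]:
        raise InputError(
            f"shape mismatch: {values.shape[0]} bands vs {bgn.shape[0]} noise values")
    residual = values - bgn[:, None]
    if clip_negative:
        residual = np.maximum(residual, 0.0)
    if smooth:
        residual = uniform_filter1d(residual, size=smooth_frames, axis=1,
                                    mode="nearest")
    return residual


def compute_indices(denoised: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ΣPMN and PMNsp per band of a de-noised spectrogram.

    ``sigma_pmn[b]`` is the sum of the residual over all frames of band *b*
    (dB·frames); ``pmn_sp[b]`` is the maximum residual frame.
    """
    denoised = np.asarray(denoised)
    return denoised.sum(axis=1), denoised.max(axis=1)


def sigma_pmn_minute(values: np.ndarray,
                     smooth: bool = True,
                     clip_negative: bool = True) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convenience: (sigma_pmn, pmn_sp, bgn_sp) for one dB spectrogram."""
    noise = estimate_background(values)
    residual = denoise(values, noise, smooth=smooth, clip_negative=clip_negative)
    sigma, pmn = compute_indices(residual)
    return sigma, pmn, noise.bgn_sp


def sigma_pmn_batch(values: np.ndarray,
                    smooth: bool = True,
                    clip_negative: bool = True,
                    smooth_frames: int = 3) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batch index computation over an (minutes, bands, frames) dB array.

    Returns (sigma_pmn, pmn_sp, bgn_sp), each of shape (minutes, bands).
    Matches the per-minute path exactly (tested property).
    """
    X = np.asarray(values)
    if X.ndim != 3:
        raise InputError("expected a 3-D (minutes, bands, frames) array")
    m, b, t = X.shape
    bgn = modal_background_batch(X.reshape(m * b, t)).reshape(m, b)
    residual = X - bgn[:, :, None].astype(X.dtype)
    if clip_negative:
        np.maximum(residual, 0.0, out=residual)
    if smooth:
        residual = uniform_filter1d(residual, size=smooth_frames, axis=2,
                                    mode="nearest")
    return residual.sum(axis=2), residual.max(axis=2), bgn


def aggregate_bands(sigma_pmn: np.ndarray,
                    freq_range: tuple[float, float],
                    band_width: float = BAND_WIDTH_HZ) -> float | np.ndarray:
    """Sum ΣPMN over the bands whose centers fall in ``freq_range`` ([lo, hi)).

    Works on a per-band vector or on an (..., bands) array (summing the last
    axis).  An interval containing no band centers returns 0 with a warning.
    """
    sigma_pmn = np.asarray(sigma_pmn)
    lo, hi = freq_range
    idx = bands_in_range(lo, hi, n_bands=sigma_pmn.shape[-1], band_width=band_width)
    if idx.size == 0:
        warnings.warn(f"frequency range {freq_range} contains no band centers")
        return np.zeros(sigma_pmn.shape[:-1]) if sigma_pmn.ndim > 1 else 0.0
    return sigma_pmn[..., idx].sum(axis=-1)


def internal_minutes(labels, one_based: bool = True) -> list[int]:
    """Convert recorder minute-of-day labels to internal 0-based indices."""
    return [int(m) - 1 if one_based else int(m) for m in labels]


def apply_exclusions(records,
                     edge_minutes: int = DEFAULT_EDGE_MINUTES,
                     excluded_minutes=DEFAULT_EXCLUDED_MINUTES,
                     one_based_labels: bool = True,
                     min_band_center_hz: float | None = None,
                     band_width: float = BAND_WIDTH_HZ):
    """Drop deployment-edge minutes, globally excluded minutes and low bands.

    Per site, the first and last ``edge_minutes`` recorded minutes are
    removed (fieldwork noise), minutes-of-day matching ``excluded_minutes``
    are dropped everywhere, and — when ``min_band_center_hz`` is given and a
    ``band`` column is present — bands whose center frequency falls below
    the cutoff are removed (anthropophony-dominated low range).

    ``records`` is a DataFrame with at least site_id, day and minute_of_day
    columns; a filtered copy is returned and the tally is logged.
    """
    import pandas as pd

    df = records
    n0 = len(df)
    t = df["day"].to_numpy() * 1440 + df["minute_of_day"].to_numpy()
    keep = np.ones(len(df), dtype=bool)
    for _, grp_idx in df.groupby("site_id").indices.items():
        tt = t[grp_idx]
        lo, hi = tt.min(), tt.max()
        keep[grp_idx] &= (tt >= lo + edge_minutes) & (tt <= hi - edge_minutes)
    n_edge = int((~keep).sum())
    bad = set(internal_minutes(excluded_minutes, one_based_labels))
    keep &= ~df["minute_of_day"].isin(bad).to_numpy()
    n_after_minutes = int((~keep).sum())
    if min_band_center_hz is not None and "band" in df.columns:
        centers = (df["band"].to_numpy() + 0.5) * band_width
        keep &= centers >= min_band_center_hz
    out = df.loc[keep].reset_index(drop=True)
    logger.info("exclusions: %d -> %d rows (%d edge, %d excluded-minute, %d band)",
                n0, len(out), n_edge, n_after_minutes - n_edge,
                n0 - len(out) - n_after_minutes)
    return out


def aggregate_time(records, scheme: str = "minute_of_day", value_cols=None):
    """Average index values across days per minute, or into 10-min bins.

    ``scheme='minute_of_day'`` averages across days within each
    (site, minute-of-day); ``scheme='ten_min_bin'`` additionally pools
    minutes into the 144 daily 10-min bins [10i, 10i+10).  Empty groups are
    simply absent from the grouped output.
    """
    import pandas as pd

    df = records.copy()
    if value_cols is None:
        skip = {"site_id", "day", "minute_of_day", "band", "time_bin"}
        value_cols = [c for c in df.columns
                      if c not in skip and pd.api.types.is_numeric_dtype(df[c])]
    extra = ["band"] if "band" in df.columns else []
    if scheme == "minute_of_day":
        keys = ["site_id", "minute_of_day"] + extra
    elif scheme == "ten_min_bin":
        df["time_bin"] = df["minute_of_day"] // 10
        keys = ["site_id", "time_bin"] + extra
    else:
        raise ValueError(f"unknown aggregation scheme: {scheme!r}")
    return df.groupby(keys, as_index=False)[list(value_cols)].mean()
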