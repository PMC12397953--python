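"""Morlet wavelet behavioral feature space.

Each (normalized) metric timeseries is convolved with a bank of 25 complex
Morlet wavelets whose centre frequencies are log-spaced between 0.01 and
2.5 Hz (the Nyquist limit of 5 Hz tracking).  The per-frequency wavelet
amplitude captures how much oscillatory structure at that timescale is
present around each frame; stacking the three metrics' spectrograms yields
a 75-dimensional behavioral phenotype space with one point per frame.

The transform is computed per observation day (overnight gaps are treated
as series boundaries) by FFT convolution with reflection padding, using an
analytic Morlet kernel scaled so that a unit-amplitude sinusoid at a
channel's centre frequency produces a peak amplitude of ~1 in that channel
regardless of frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.fft import fft, ifft, next_fast_len

from .metrics import METRICS, MetricSeries

__all__ = [
    "make_frequency_ladder",
    "normalize_series",
    "wavelet_spectrogram",
    "FeatureMatrix",
    "build_feature_matrix",
    "features_for_individual",
]

log = logging.getLogger(__name__)

DEFAULT_N_WAVELETS = 25
DEFAULT_F_MIN = 0.01
DEFAULT_F_MAX = 2.5
DEFAULT_OMEGA0 = 5.0
FS = 5.0  # Hz


def make_frequency_ladder(
    n: int = DEFAULT_N_WAVELETS,
    f_min: float = DEFAULT_F_MIN,
    f_max: float = DEFAULT_F_MAX,
    fs: float = FS,
) -> np.ndarray:
    """``n`` log-spaced centre frequencies from ``f_min`` to ``f_max`` (Hz).

    Consecutive frequencies share a constant ratio ``(f_max/f_min)**(1/(n-1))``
    so the ladder covers the 2.4 decades between the slowest behaviorally
    meaningful rhythms and the Nyquist frequency evenly on a log axis.
    """
    if n < 2:
        raise ValueError("need at least 2 frequencies")
    if not (0 < f_min < f_max):
        raise ValueError("need 0 < f_min < f_max")
    if f_max > fs / 2 + 1e-12:
        raise ValueError(f"f_max={f_max} exceeds the Nyquist frequency {fs / 2}")
    return np.geomspace(f_min, f_max, n)


def normalize_series(x: np.ndarray, mean: float | None = None, sd: float | None = None) -> np.ndarray:
    """Z-score a metric series; NaNs are ignored for the statistics.

    ``mean``/``sd`` may be supplied to normalize with statistics from a
    wider scope (e.g. an individual's whole observation period rather than
    one day).  A zero-variance series maps to all zeros.
    """
    x = np.asarray(x, dtype=float)
    if mean is None:
        mean = np.nanmean(x) if np.isfinite(x).any() else 0.0
    if sd is None:
        sd = np.nanstd(x) if np.isfinite(x).any() else 0.0
    if not np.isfinite(sd) or sd == 0:
        return np.where(np.isfinite(x), 0.0, x)
    return (x - mean) / sd


def wavelet_spectrogram(
    series: np.ndarray,
    freqs: np.ndarray,
    fs: float = FS,
    omega0: float = DEFAULT_OMEGA0,
) -> np.ndarray:
    """Amplitude of the continuous Morlet transform, shape (T, n_freqs).

    Uses the analytic Morlet kernel ``psi_hat(s w) = 2 exp(-(s w - w0)^2/2)``
    on positive frequencies with scale ``s = w0 / (2 pi f)``, so a unit
    cosine at frequency ``f`` yields amplitude ~1 in channel ``f`` (its
    positive-frequency half, weight 1/2, times the kernel peak of 2).  The
    series is reflection-padded before the FFT; NaNs must be removed or
    zero-filled by the caller.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    freqs = np.asarray(freqs, dtype=float)
    T = len(x)
    if T == 0:
        return np.zeros((0, len(freqs)), dtype=np.float32)
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values; fill or drop first")
    min_period = fs / freqs.min()
    if T < min_period:
        log.info(
            "series of %d frames is shorter than one period of the slowest "
            "wavelet (%.0f frames); low-frequency channels are low-confidence",
            T,
            min_period,
        )
    pad = min(T - 1, int(np.ceil(fs / freqs.min() * omega0)))
    if pad > 0:
        x = np.concatenate([x[pad:0:-1], x, x[-2 : -2 - pad : -1]])
    n = next_fast_len(len(x))
    X = fft(x, n)
    w = 2 * np.pi * np.fft.fftfreq(n, d=1.0 / fs)
    out = np.empty((T, len(freqs)), dtype=np.float32)
    for j, f in enumerate(freqs):
        s = omega0 / (2 * np.pi * f)
        H = np.where(w > 0, 2.0 * np.exp(-0.5 * (s * w - omega0) ** 2), 0.0)
        if n % 2 == 0:
            # Nyquist bin is stored with negative sign and, being unpaired,
            # carries full (not half) amplitude: weight 1 instead of 2.
            H[n // 2] = np.exp(-0.5 * (s * np.pi * fs - omega0) ** 2)
        W = ifft(X * H)
        out[:, j] = np.abs(W[pad : pad + T]).astype(np.float32)
    return out


@dataclass
class FeatureMatrix:
    """Wavelet features with row alignment back to (individual, day, time).

    ``values`` is (T, 75) float32, columns ordered metric-major
    (step f1..f25, turn f1..f25, wall f1..f25); ``index`` is a DataFrame
    with columns individual_id, day_index, time_s, one row per feature row.
    """

    values: np.ndarray
    index: pd.DataFrame
    freqs_hz: np.ndarray
    metrics: tuple = METRICS

    def __post_init__(self):
        if self.values.shape[0] != len(self.index):
            raise ValueError("feature rows and index misaligned")
        if self.values.shape[1] != len(self.metrics) * len(self.freqs_hz):
            raise ValueError("column count != n_metrics * n_freqs")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def column_names(self) -> list[str]:
        return [f"{m}_f{j + 1:02d}" for m in self.metrics for j in range(len(self.freqs_hz))]

    @classmethod
    def concat(cls, parts: list["FeatureMatrix"]) -> "FeatureMatrix":
        first = parts[0]
        return cls(
            values=np.vstack([p.values for p in parts]),
            index=pd.concat([p.index for p in parts], ignore_index=True),
            freqs_hz=first.freqs_hz,
            metrics=first.metrics,
        )


def build_feature_matrix(
    spectrograms: dict[str, np.ndarray],
    index: pd.DataFrame,
    freqs: np.ndarray,
    valid: np.ndarray | None = None,
) -> FeatureMatrix:
    """Concatenate per-metric spectrograms metric-major into a FeatureMatrix.

    ``spectrograms`` maps each metric name to a (T, n_freqs) block on the
    same timepoints.  Rows where ``valid`` is False (any underlying metric
    undefined at that frame) are dropped and their count logged.
    """
    blocks = []
    T = len(index)
    for m in METRICS:
        b = spectrograms[m]
        if b.shape != (T, len(freqs)):
            raise ValueError(
                f"spectrogram for {m!r} has shape {b.shape}, expected {(T, len(freqs))}"
            )
        blocks.append(b)
    values = np.hstack(blocks).astype(np.float32)
    if valid is not None:
        dropped = int((~valid).sum())
        if dropped:
            log.info("dropping %d feature rows with invalid underlying metrics", dropped)
        values = values[valid]
        index = index.loc[valid].reset_index(drop=True)
    return FeatureMatrix(values=values, index=index.reset_index(drop=True), freqs_hz=freqs)


def features_for_individual(
    series_list: list[MetricSeries],
    freqs: np.ndarray,
    fs: float = FS,
    omega0: float = DEFAULT_OMEGA0,
    abs_turn: bool = True,
) -> FeatureMatrix:
    """Whole-period features for one individual, one transform segment per day.

    Metric series are z-scored with per-individual whole-period statistics
    (the normalization scope shared by all days), invalid frames are
    zero-filled for the convolution and dropped from the output rows.
    The turning angle enters as ``|turn|`` when ``abs_turn`` so that its
    wavelet channels measure rhythms in turning intensity, matching the
    CoV treatment of the same metric.
    """
    # whole-period normalization statistics per metric
    stats = {}
    for m in METRICS:
        vals = np.concatenate([np.where(ms.values(m)[1], ms.values(m)[0], np.nan) for ms in series_list])
        if m == "turn" and abs_turn:
            vals = np.abs(vals)
        finite = vals[np.isfinite(vals)]
        stats[m] = (finite.mean(), finite.std()) if finite.size else (0.0, 0.0)

    parts = []
    for ms in sorted(series_list, key=lambda s: s.day_index):
        spects = {}
        valid_all = np.ones(len(ms), dtype=bool)
        for m in METRICS:
            vals, vmask = ms.values(m)
            if m == "turn" and abs_turn:
                vals = np.abs(vals)
            z = normalize_series(vals, *stats[m])
            z = np.where(vmask, z, 0.0)
            spects[m] = wavelet_spectrogram(z, freqs, fs=fs, omega0=omega0)
            valid_all &= vmask
        idx = pd.DataFrame(
            {
                "individual_id": ms.individual_id,
                "day_index": ms.day_index,
                "time_s": ms.time_s,
            }
        )
        parts.append(build_feature_matrix(spects, idx, freqs, valid=valid_all))
    return FeatureMatrix.concat(parts)
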