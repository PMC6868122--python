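"""EEG preprocessing: QC, common-average reference, filter bank, band
power, standardization and lag embedding.

The decoding features are windowed band powers of four sensorimotor
bands -- mu (8-12 Hz), low beta (12-18 Hz), high beta (18-28 Hz) and low
gamma (28-40 Hz) -- computed from common-average-referenced EEG in a
250 ms sliding window.  At calibration the window steps by one sample
(8.33 ms at 120 samples/s); predictions are emitted every 25 ms (3
samples) to match the 40 FPS display.  Features are standardized by the
per-feature standard deviation estimated on training folds only, then
lag-embedded (embedding dimension L+1) for the linear decoder.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

#: 16-channel sensorimotor montage (10/20 labels) used by default.
DEFAULT_MONTAGE = (
    "FC3", "FC1", "FCz", "FC2", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP3", "CP1", "CPz", "CP4",
)

#: band edges (Hz) for trajectory decoding
MTP_BANDS = ((8.0, 12.0), (12.0, 18.0), (18.0, 28.0), (28.0, 40.0))
MTP_BAND_NAMES = ("mu", "low_beta", "high_beta", "low_gamma")

#: band edges (Hz) for the FBCSP comparator (filter bank)
FBCSP_BANDS = ((0.5, 4.0), (4.0, 8.0)) + MTP_BANDS
FBCSP_BAND_NAMES = ("delta", "theta") + MTP_BAND_NAMES


class QCError(ValueError):
    pass


class DegenerateFeatureError(ValueError):
    pass


@dataclass
class EEGRecording:
    """Multichannel EEG potentials in microvolts."""

    data: np.ndarray  # (n_channels, n_samples), uV
    sfreq: float
    ch_names: list[str]
    reference: str = "A1"

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sfreq

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            self.data.copy(), self.sfreq, list(self.ch_names), self.reference
        )

    def pick(self, labels) -> "EEGRecording":
        idx = [self.ch_names.index(l) for l in labels]
        return EEGRecording(
            self.data[idx], self.sfreq, [self.ch_names[i] for i in idx],
            self.reference,
        )


def qc_channels(
    rec: EEGRecording,
    abs_amp_threshold: float = 200.0,
    flat_threshold: float = 0.01,
) -> tuple[EEGRecording, list[str]]:
    """Automated channel quality control.

    Drops channels whose peak absolute amplitude exceeds
    ``abs_amp_threshold`` (uV) or whose standard deviation falls below
    ``flat_threshold`` (uV).  Stands in for the manual per-channel
    inspection an experimenter would perform.
    """
    if abs_amp_threshold <= 0 or flat_threshold <= 0:
        raise ValueError("thresholds must be positive")
    peak = np.max(np.abs(rec.data), axis=1)
    std = np.std(rec.data, axis=1)
    bad = (peak > abs_amp_threshold) | (std < flat_threshold)
    rejected = [n for n, b in zip(rec.ch_names, bad) if b]
    if all(bad):
        raise QCError("all channels rejected by QC")
    keep = [n for n, b in zip(rec.ch_names, bad) if not b]
    return rec.pick(keep), rejected


def car_filter(rec: EEGRecording) -> EEGRecording:
    """Common average reference: subtract the instantaneous channel mean.

    Removes common-mode artifacts; the channel mean of the output is
    zero at every sample, so the filter is idempotent.
    """
    if rec.n_channels < 2:
        raise ValueError("CAR requires at least 2 channels")
    out = rec.copy()
    out.data = rec.data - rec.data.mean(axis=0, keepdims=True)
    out.reference = "CAR"
    return out


def design_bandpass(
    low: float,
    high: float,
    sfreq: float,
    attenuation_db: float = 60.0,
    transition: float | None = None,
) -> np.ndarray:
    """Linear-phase FIR band-pass taps (Kaiser design).

    The transition width defaults to ``min(2 Hz, 0.8 * low)`` so the
    stop band reaches the required attenuation even for the 0.5-4 Hz
    filter-bank band.  Applied zero-phase via :func:`apply_fir`.
    """
    if not (0.0 < low < high < sfreq / 2.0):
        raise ValueError(f"invalid band edges ({low}, {high}) at fs={sfreq}")
    if transition is None:
        transition = min(2.0, 0.8 * low)
    numtaps, beta = signal.kaiserord(attenuation_db + 5.0, 2.0 * transition / sfreq)
    numtaps |= 1  # odd length -> integer group delay, exact zero-phase
    return signal.firwin(
        numtaps, [low, high], pass_zero=False, window=("kaiser", beta), fs=sfreq
    )


def apply_fir(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Zero-phase application of symmetric FIR taps along the last axis."""
    return signal.oaconvolve(data, taps[None, :], mode="same", axes=-1)


def bandpass_filterbank(
    rec: EEGRecording, bands=MTP_BANDS, attenuation_db: float = 60.0
) -> list[EEGRecording]:
    """Zero-phase FIR band-pass per band (>= 60 dB stop-band)."""
    out = []
    for low, high in bands:
        taps = design_bandpass(low, high, rec.sfreq, attenuation_db)
        filt = rec.copy()
        filt.data = apply_fir(rec.data, taps)
        out.append(filt)
    return out


@dataclass
class BandPowerSeries:
    """Windowed band power, bands x channels x window offsets (uV^2).

    ``times`` holds the *end* of each half-open analysis window, i.e.
    the first instant at which the feature is causally available.
    """

    values: np.ndarray  # (n_bands, n_channels, n_windows)
    times: np.ndarray  # (n_windows,)
    bands: tuple
    ch_names: list[str]
    window_width: float  # s
    window_step: float  # s

    @property
    def n_windows(self) -> int:
        return self.values.shape[2]

    def pick(self, labels) -> "BandPowerSeries":
        idx = [self.ch_names.index(l) for l in labels]
        return replace(
            self, values=self.values[:, idx, :],
            ch_names=[self.ch_names[i] for i in idx],
        )


def band_power(
    filtered: EEGRecording, window_width: float = 0.25, window_step_samples: int = 1
) -> BandPowerSeries:
    """Mean of squared samples in a sliding half-open window.

    The window count is ``floor((T - width) / step) + 1``.
    """
    m = int(round(window_width * filtered.sfreq))
    if m < 2:
        raise ValueError("window must span at least 2 samples")
    if m > filtered.n_samples:
        raise ValueError("window longer than recording")
    sq = filtered.data.astype(float) ** 2
    csum = np.concatenate(
        [np.zeros((filtered.n_channels, 1)), np.cumsum(sq, axis=1)], axis=1
    )
    starts = np.arange(0, filtered.n_samples - m + 1, window_step_samples)
    vals = (csum[:, starts + m] - csum[:, starts]) / m
    times = (starts + m) / filtered.sfreq
    return BandPowerSeries(
        values=vals[None, :, :],
        times=times,
        bands=((0.0, filtered.sfreq / 2.0),),
        ch_names=list(filtered.ch_names),
        window_width=window_width,
        window_step=window_step_samples / filtered.sfreq,
    )


def bandpower_features(
    rec: EEGRecording,
    bands=MTP_BANDS,
    window_width: float = 0.25,
    window_step_samples: int = 1,
) -> BandPowerSeries:
    """Filter-bank band power: one power series per band and channel."""
    per_band = []
    times = None
    for filt in bandpass_filterbank(rec, bands):
        bp = band_power(filt, window_width, window_step_samples)
        per_band.append(bp.values[0])
        times = bp.times
    return BandPowerSeries(
        values=np.stack(per_band, axis=0),
        times=times,
        bands=tuple(bands),
        ch_names=list(rec.ch_names),
        window_width=window_width,
        window_step=window_step_samples / rec.sfreq,
    )


@dataclass
class FeatureTensor:
    """Standardized band-power features with the training-fold sigma."""

    values: np.ndarray  # (n_bands, n_channels, n_windows)
    times: np.ndarray
    sigma: np.ndarray  # (n_bands, n_channels)
    bands: tuple
    ch_names: list[str]
    window_step: float
    first_difference: bool = False


def standardize(
    bp: BandPowerSeries,
    sigma: np.ndarray | None = None,
    first_difference: bool = False,
) -> FeatureTensor:
    """Divide each band-power feature by its training-fold sigma.

    When ``sigma`` is ``None`` it is estimated from the input (a
    training fold) and stored on the result for reuse on test folds.
    ``first_difference=True`` additionally differences the series in
    time before scaling (off by default; the plain scale is the
    reference behaviour).
    """
    vals = bp.values
    times = bp.times
    if first_difference:
        vals = np.diff(vals, axis=2)
        times = times[1:]
    if sigma is None:
        sigma = vals.std(axis=2)
    else:
        sigma = np.asarray(sigma, float)
        if sigma.shape != vals.shape[:2]:
            raise ValueError("sigma dimensions do not match features")
    if np.any(sigma <= 0):
        bad = np.argwhere(sigma <= 0)
        raise DegenerateFeatureError(
            f"zero sigma for band/channel pairs {bad.tolist()}; "
            "flat channels should have been removed by QC"
        )
    return FeatureTensor(
        values=vals / sigma[:, :, None],
        times=times,
        sigma=sigma,
        bands=bp.bands,
        ch_names=list(bp.ch_names),
        window_step=bp.window_step,
        first_difference=first_difference,
    )


@dataclass
class LaggedFeatures:
    """Lag-embedded design matrix with per-column provenance.

    Column ``c`` holds band ``col_band[c]``, channel ``col_channel[c]``
    at lag index ``col_lag[c]`` (0 = current sample); the embedding
    dimension is ``n_lags + 1``.  Leading samples without a full lag
    history are dropped, so the design is strictly causal.
    """

    X: np.ndarray  # (n_times, n_features)
    times: np.ndarray
    col_band: np.ndarray
    col_channel: np.ndarray
    col_lag: np.ndarray
    bands: tuple
    ch_names: list[str]
    lag_spacing: float
    n_lags: int
    sigma: np.ndarray | None = None


def _embed(values: np.ndarray, lag_step: int, n_lags: int):
    """Core lag embedding of a (B, N, T) tensor -> (T', B*N*(L+1))."""
    b, n, t = values.shape
    start = n_lags * lag_step
    if start >= t:
        raise ValueError("lag history longer than recording")
    t_out = t - start
    flat = values.reshape(b * n, t)
    cols = []
    for k in range(n_lags + 1):
        sl = flat[:, start - k * lag_step : t - k * lag_step]
        cols.append(sl)
    # feature order: (band, channel) major, lag minor
    X = np.stack(cols, axis=1).reshape(b * n * (n_lags + 1), t_out).T
    bn = np.arange(b * n)
    col_band = np.repeat(bn // n, n_lags + 1)
    col_channel = np.repeat(bn % n, n_lags + 1)
    col_lag = np.tile(np.arange(n_lags + 1), b * n)
    return X, col_band, col_channel, col_lag, start


def lag_embed(
    ft: FeatureTensor, lag_spacing: float, n_lags: int
) -> LaggedFeatures:
    """Concatenate features at t, t-delta, ..., t-L*delta."""
    lag_step = int(round(lag_spacing / ft.window_step))
    if n_lags > 0:
        if lag_step < 1 or abs(lag_step * ft.window_step - lag_spacing) > 1e-9:
            raise ValueError(
                f"lag spacing {lag_spacing}s is not a multiple of the "
                f"window step {ft.window_step:.6f}s"
            )
    X, cb, cc, cl, start = _embed(ft.values, max(lag_step, 1), n_lags)
    return LaggedFeatures(
        X=X,
        times=ft.times[start:],
        col_band=cb,
        col_channel=cc,
        col_lag=cl,
        bands=ft.bands,
        ch_names=list(ft.ch_names),
        lag_spacing=lag_spacing,
        n_lags=n_lags,
        sigma=ft.sigma,
    )
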