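"""Per-window signal feature bank and feature-matrix assembly.

Twenty-two features per channel per window: eighteen time-domain
statistics (extrema, population moments, shape ratios such as crest,
impulse and clearance factors, and the kurtosis of a Teager-style
energy-operator series) and four spectral summaries (mean spectral
amplitude, center frequency, RMS frequency, and variance of frequency
about the center).  With 7 IMUs x 6 channels x 22 features the full
matrix has 924 columns.

All moments use the population (1/Ns) normalization.  The spectrum is
the one-sided DFT magnitude of the raw, untapered window with Nfft=Ns
and the DC bin excluded.  Windows with zero spread or zero amplitude
would make the ratio features undefined; those features are mapped to 0
and the window flagged, so downstream model fits always see finite
numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import WindowSet

__all__ = [
    "ChannelWindow",
    "FeatureVector",
    "FeatureMatrix",
    "FEATURE_IDS",
    "FEATURE_REGISTRY",
    "feature_names",
    "compute_time_features",
    "compute_freq_features",
    "compute_features",
    "extract_matrix",
    "standardize",
]

FEATURE_IDS = tuple(f"F{k:02d}" for k in range(1, 23))

#: Short definitions of the per-channel feature bank.
FEATURE_REGISTRY: dict[str, str] = {
    "F01": "maximum value",
    "F02": "minimum value",
    "F03": "mean absolute value",
    "F04": "range (max - min)",
    "F05": "root mean square",
    "F06": "mean",
    "F07": "standard deviation (population)",
    "F08": "skewness (central, standardized)",
    "F09": "kurtosis (central, non-excess)",
    "F10": "variance (population)",
    "F11": "waveform factor: RMS / mean absolute value",
    "F12": "crest factor: peak absolute value / RMS",
    "F13": "reciprocal coefficient of variation: mean / sd",
    "F14": "non-centered skewness coefficient: mean of (x/sd)^3",
    "F15": "non-centered kurtosis coefficient: mean of (x/sd)^4",
    "F16": "clearance factor: peak / squared mean root of |x|",
    "F17": "impulse factor: peak absolute value / mean absolute value",
    "F18": "kurtosis of the energy-operator series dx(i)=x(i)^2-x(i+1)x(i-1)",
    "F19": "mean spectral amplitude (one-sided, DC excluded)",
    "F20": "center frequency: amplitude-weighted mean frequency",
    "F21": "RMS frequency: sqrt of amplitude-weighted mean squared frequency",
    "F22": "variance of frequency about the center frequency",
}


@dataclass(frozen=True)
class ChannelWindow:
    """One channel's samples over one window."""

    x: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if x.ndim != 1 or x.size < 2:
            raise ValueError("window must be 1-D with at least 2 samples")
        if not np.all(np.isfinite(x)):
            raise ValueError("window contains non-finite samples")
        object.__setattr__(self, "x", x)


@dataclass
class FeatureVector:
    values: dict[str, float]
    nfft: int
    degenerate: bool = False


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise num/den with 0 where the denominator vanishes."""
    den = np.asarray(den, dtype=float)
    out = np.zeros(np.broadcast_shapes(np.shape(num), den.shape))
    np.divide(num, den, out=out, where=den != 0)
    return out


def _time_bank(X: np.ndarray, strict_clearance: bool) -> tuple[np.ndarray, np.ndarray]:
    """F01-F18 for every row of X (n_windows x Ns); returns (bank, degenerate)."""
    absX = np.abs(X)
    mx = X.max(axis=1)
    mn = X.min(axis=1)
    meanabs = absX.mean(axis=1)
    maxabs = absX.max(axis=1)
    mean = X.mean(axis=1)
    rms = np.sqrt((X * X).mean(axis=1))
    centered = X - mean[:, None]
    var = (centered * centered).mean(axis=1)
    sd = np.sqrt(var)
    m3 = (centered**3).mean(axis=1)
    m4 = (centered**4).mean(axis=1)

    skew = _safe_div(m3, sd**3)
    kurt = _safe_div(m4, var * var)
    f11 = _safe_div(rms, meanabs)
    f12 = _safe_div(maxabs, rms)
    f13 = _safe_div(mean, sd)
    f14 = _safe_div((X**3).mean(axis=1), sd**3)
    f15 = _safe_div((X**4).mean(axis=1), sd**4)
    if strict_clearance:
        f16 = f12
    else:
        smr = np.sqrt(absX).mean(axis=1) ** 2  # squared mean root
        f16 = _safe_div(maxabs, smr)
    f17 = _safe_div(maxabs, meanabs)

    # Energy-operator series with wrapped endpoints.
    dx = X * X - np.roll(X, -1, axis=1) * np.roll(X, 1, axis=1)
    dmean = dx.mean(axis=1)
    dcent = dx - dmean[:, None]
    dvar = (dcent * dcent).mean(axis=1)
    f18 = _safe_div((dcent**4).mean(axis=1), dvar * dvar)

    bank = np.column_stack(
        [mx, mn, meanabs, mx - mn, rms, mean, sd, skew, kurt, var,
         f11, f12, f13, f14, f15, f16, f17, f18]
    )
    degenerate = (sd == 0) | (meanabs == 0) | (rms == 0)
    return bank, degenerate


def _freq_bank(X: np.ndarray, fs: float) -> np.ndarray:
    """F19-F22 for every row of X; Nfft = Ns, DC excluded, one-sided."""
    ns = X.shape[1]
    spec = np.abs(np.fft.rfft(X, axis=1))[:, 1 : ns // 2 + 1]
    freqs = np.arange(1, ns // 2 + 1) * fs / ns
    total = spec.sum(axis=1)
    f19 = spec.mean(axis=1)
    f20 = _safe_div(spec @ freqs, total)
    f21 = np.sqrt(_safe_div(spec @ (freqs * freqs), total))
    dev = (freqs[None, :] - f20[:, None]) ** 2
    f22 = _safe_div((spec * dev).sum(axis=1), total)
    return np.column_stack([f19, f20, f21, f22])


def compute_features_bulk(
    X: np.ndarray, fs: float, strict_clearance: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Full 22-feature bank for a stack of windows.

    Parameters
    ----------
    X : array, shape (n_windows, Ns)
    fs : sampling rate in Hz.
    strict_clearance : reproduce the clearance factor exactly as a
        duplicate of the crest factor instead of the conventional
        squared-mean-root form.

    Returns
    -------
    bank : array (n_windows, 22), degenerate : bool array (n_windows,)
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 4:
        raise ValueError("windows must have at least 4 samples")
    tbank, degenerate = _time_bank(X, strict_clearance)
    fbank = _freq_bank(X, fs)
    return np.hstack([tbank, fbank]), degenerate


def compute_time_features(
    w: ChannelWindow, strict_clearance: bool = False
) -> FeatureVector:
    """F01-F18 for a single channel window."""
    if w.x.size < 2:
        raise ValueError("time features need at least 2 samples")
    bank, degen = _time_bank(w.x[None, :], strict_clearance)
    values = {fid: float(v) for fid, v in zip(FEATURE_IDS[:18], bank[0])}
    return FeatureVector(values, nfft=w.x.size, degenerate=bool(degen[0]))


def compute_freq_features(w: ChannelWindow) -> FeatureVector:
    """F19-F22 for a single channel window."""
    if w.x.size < 4:
        raise ValueError("frequency features need at least 4 samples")
    bank = _freq_bank(w.x[None, :], w.sampling_rate_hz)
    values = {fid: float(v) for fid, v in zip(FEATURE_IDS[18:], bank[0])}
    return FeatureVector(values, nfft=w.x.size)


def compute_features(w: ChannelWindow, strict_clearance: bool = False) -> FeatureVector:
    """All 22 features for a single channel window."""
    t = compute_time_features(w, strict_clearance)
    f = compute_freq_features(w)
    return FeatureVector({**t.values, **f.values}, nfft=t.nfft, degenerate=t.degenerate)


def feature_names(columns: list[str]) -> list[str]:
    """Feature-matrix column names: sensor-major, channel-minor, feature-minor."""
    return [f"{c}_{fid}" for c in columns for fid in FEATURE_IDS]


@dataclass
class FeatureMatrix:
    """Window-by-feature table with labels, patient ids and scaler state."""

    features: pd.DataFrame  # rows = windows, columns = named features
    labels: pd.Series
    patient_ids: pd.Series
    degenerate: np.ndarray | None = None
    scaler_mean: pd.Series | None = None
    scaler_sd: pd.Series | None = None
    zero_sd_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.features)
        if len(self.labels) != n or len(self.patient_ids) != n:
            raise ValueError("labels/patient_ids must align with feature rows")

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def to_frame(self) -> pd.DataFrame:
        out = self.features.copy()
        out["label"] = self.labels.values
        out["patient_id"] = self.patient_ids.values
        return out

    def subset_columns(self, names: list[str]) -> "FeatureMatrix":
        return FeatureMatrix(
            features=self.features[names].copy(),
            labels=self.labels.copy(),
            patient_ids=self.patient_ids.copy(),
            degenerate=self.degenerate,
        )


def extract_matrix(ws: WindowSet, strict_clearance: bool = False) -> FeatureMatrix:
    """Feature matrix of one recording's window set.

    Column count is ``n_channels x 22`` (924 for the 7-sensor, 6-channel
    layout); the label and patient id of each window are carried along.
    """
    rec = ws.recording
    if rec is None:
        raise ValueError("WindowSet carries no recording to extract from")
    p = ws.params
    n_win = len(ws.windows)
    names = feature_names(rec.columns)
    if n_win == 0:
        empty = pd.DataFrame(np.empty((0, len(names))), columns=names)
        return FeatureMatrix(empty, pd.Series([], dtype=object), pd.Series([], dtype=object),
                             degenerate=np.zeros(0, dtype=bool))
    starts = np.array([w.start for w in ws.windows])
    if any(w.end - w.start != p.window_size for w in ws.windows):
        raise ValueError("window length inconsistent with declared window_size")
    if starts.max() + p.window_size > rec.n_samples:
        raise ValueError("window extends past the recording")

    out = np.empty((n_win, len(names)))
    degenerate = np.zeros(n_win, dtype=bool)
    for c in range(rec.signals.shape[1]):
        view = np.lib.stride_tricks.sliding_window_view(
            rec.signals[:, c], p.window_size
        )[starts]
        bank, degen = compute_features_bulk(
            view, rec.sampling_rate_hz, strict_clearance
        )
        out[:, c * 22 : (c + 1) * 22] = bank
        degenerate |= degen

    return FeatureMatrix(
        features=pd.DataFrame(out, columns=names),
        labels=pd.Series([w.label for w in ws.windows]),
        patient_ids=pd.Series([w.patient_id for w in ws.windows]),
        degenerate=degenerate,
    )


def concat_matrices(mats: list[FeatureMatrix]) -> FeatureMatrix:
    """Stack per-patient feature matrices (identical column sets required)."""
    if not mats:
        raise ValueError("nothing to concatenate")
    cols = list(mats[0].features.columns)
    for m in mats[1:]:
        if list(m.features.columns) != cols:
            raise ValueError("feature matrices have differing columns")
    return FeatureMatrix(
        features=pd.concat([m.features for m in mats], ignore_index=True),
        labels=pd.concat([m.labels for m in mats], ignore_index=True),
        patient_ids=pd.concat([m.patient_ids for m in mats], ignore_index=True),
        degenerate=np.concatenate(
            [m.degenerate if m.degenerate is not None else np.zeros(len(m.features), bool)
             for m in mats]
        ),
    )


def standardize(fm: FeatureMatrix, training_mask: np.ndarray) -> FeatureMatrix:
    """Z-score all rows using mean/sd fitted on the training rows only.

    Population standard deviation; zero-spread columns pass through
    unchanged and are flagged in ``zero_sd_columns``.
    """
    training_mask = np.asarray(training_mask, dtype=bool)
    if training_mask.sum() < 2:
        raise ValueError("need at least 2 training rows")
    train = fm.features.loc[training_mask]
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    zero = sd == 0
    safe_sd = sd.where(~zero, 1.0)
    z = (fm.features - mean) / safe_sd
    z.loc[:, zero] = fm.features.loc[:, zero]
    return FeatureMatrix(
        features=z,
        labels=fm.labels.copy(),
        patient_ids=fm.patient_ids.copy(),
        degenerate=fm.degenerate,
        scaler_mean=mean,
        scaler_sd=sd,
        zero_sd_columns=list(sd.index[zero]),
    )
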