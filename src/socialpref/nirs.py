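"""fNIRS signal handling: modified Beer–Lambert conversion and preprocessing.

Two-wavelength (760/850 nm) optical-density changes from a 16-channel
prefrontal montage are converted to oxygenated/deoxygenated hemoglobin
concentration changes by inverting the modified Beer–Lambert law

    dOD(lambda) = [mu_a_O2Hb(lambda)*dO2Hb + mu_a_HHb(lambda)*dHHb] * d * DPF(lambda)

per sample and channel.  Total hemoglobin dtHb = dO2Hb + dHHb is the primary
signal of interest (a blood-volume proxy less sensitive to vein
contamination).  Concentrations are expressed in the arbitrary unit system
implied by the absorption coefficients below; all downstream model fits
standardize the data, so the absolute scale is immaterial.

Channels 1-8 cover dorsolateral prefrontal cortex (dlPFC), channels 9-16
dorsomedial prefrontal cortex (dmPFC); odd positions of each block sit on
the left hemisphere, even on the right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "BeerLambertConstants",
    "OpticalRecording",
    "ChromophoreSeries",
    "WindowGrid",
    "DLPFC_CHANNELS",
    "DMPFC_CHANNELS",
    "REGION_CHANNELS",
    "od_to_concentration",
    "concentration_to_od",
    "baseline_correct",
    "detrend",
    "despike",
    "extract_windows",
    "windows_to_frame",
    "canonical_hrf",
]

WAVELENGTHS: Tuple[int, int] = (760, 850)

#: 0-based channel indices per cortical region (1-8 / 9-16 in probe numbering).
DLPFC_CHANNELS: Tuple[int, ...] = tuple(range(0, 8))
DMPFC_CHANNELS: Tuple[int, ...] = tuple(range(8, 16))
REGION_CHANNELS: Mapping[str, Tuple[int, ...]] = {
    "dlPFC": DLPFC_CHANNELS, "dmPFC": DMPFC_CHANNELS}


@dataclass(frozen=True)
class BeerLambertConstants:
    """Absorption coefficients, pathlength factors and probe geometry."""

    mu_a_o2hb: Mapping[int, float] = field(
        default_factory=lambda: {760: 1486.0, 850: 2526.0})
    mu_a_hhb: Mapping[int, float] = field(
        default_factory=lambda: {760: 3843.0, 850: 1798.0})
    dpf: Mapping[int, float] = field(
        default_factory=lambda: {760: 7.25, 850: 6.38})
    distance_mm: float = 30.0

    def matrix(self) -> np.ndarray:
        """2x2 forward matrix mapping (dO2Hb, dHHb) to (dOD760, dOD850)."""
        rows = []
        for wl in WAVELENGTHS:
            scale = self.distance_mm * self.dpf[wl]
            rows.append([self.mu_a_o2hb[wl] * scale, self.mu_a_hhb[wl] * scale])
        a = np.array(rows, dtype=float)
        if abs(np.linalg.det(a)) < 1e-12:
            raise ValueError("Beer-Lambert coefficient matrix is singular")
        return a


@dataclass
class OpticalRecording:
    """Raw optical-density changes, shape ``(n_samples, n_channels, 2)``."""

    od: np.ndarray
    fs: float = 10.0

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        if self.od.ndim != 3 or self.od.shape[2] != 2:
            raise ValueError("od must have shape (n_samples, n_channels, 2)")

    @property
    def n_samples(self) -> int:
        return self.od.shape[0]

    @property
    def n_channels(self) -> int:
        return self.od.shape[1]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.time}
        for ch in range(self.n_channels):
            for j, wl in enumerate(WAVELENGTHS):
                data[f"ch{ch + 1}_wl{wl}"] = self.od[:, ch, j]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, fs: float = 10.0) -> "OpticalRecording":
        chans = sorted({int(c.split("_")[0][2:]) for c in df.columns
                        if c.startswith("ch")})
        od = np.stack([
            np.stack([df[f"ch{ch}_wl{wl}"].to_numpy() for wl in WAVELENGTHS],
                     axis=-1)
            for ch in chans], axis=1)
        return cls(od=od, fs=fs)


@dataclass
class ChromophoreSeries:
    """Per-channel dO2Hb / dHHb time series; dtHb is derived on demand."""

    o2hb: np.ndarray  # (n_samples, n_channels)
    hhb: np.ndarray
    fs: float = 10.0

    def __post_init__(self) -> None:
        self.o2hb = np.asarray(self.o2hb, dtype=float)
        self.hhb = np.asarray(self.hhb, dtype=float)
        if self.o2hb.shape != self.hhb.shape:
            raise ValueError("o2hb and hhb must have equal shapes")

    @property
    def thb(self) -> np.ndarray:
        return self.o2hb + self.hhb

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.o2hb.shape[0]) / self.fs

    def apply(self, fn) -> "ChromophoreSeries":
        """Apply an (array, fs) -> array transform to both chromophores."""
        return ChromophoreSeries(fn(self.o2hb, self.fs), fn(self.hhb, self.fs),
                                 fs=self.fs)

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.time}
        for ch in range(self.o2hb.shape[1]):
            data[f"ch{ch + 1}_o2hb"] = self.o2hb[:, ch]
            data[f"ch{ch + 1}_hhb"] = self.hhb[:, ch]
            data[f"ch{ch + 1}_thb"] = self.thb[:, ch]
        return pd.DataFrame(data)


@dataclass(frozen=True)
class WindowGrid:
    """Sliding-window grid aligned to transfer onset (time 0 per trial)."""

    width: float = 2.5
    step: float = 0.18
    n_windows: int = 40

    def starts(self) -> np.ndarray:
        return np.arange(self.n_windows) * self.step

    @property
    def span(self) -> float:
        """Seconds from onset covered by the last window's end."""
        return (self.n_windows - 1) * self.step + self.width


def od_to_concentration(recording: OpticalRecording,
                        constants: BeerLambertConstants | None = None,
                        ) -> ChromophoreSeries:
    """Invert the modified Beer–Lambert law sample-by-sample."""
    constants = constants or BeerLambertConstants()
    inv = np.linalg.inv(constants.matrix())
    conc = recording.od @ inv.T  # (n, ch, 2): columns dO2Hb, dHHb
    return ChromophoreSeries(o2hb=conc[:, :, 0], hhb=conc[:, :, 1],
                             fs=recording.fs)


def concentration_to_od(series: ChromophoreSeries,
                        constants: BeerLambertConstants | None = None,
                        ) -> OpticalRecording:
    """Forward modified Beer–Lambert law (the inverse of the conversion)."""
    constants = constants or BeerLambertConstants()
    a = constants.matrix()
    conc = np.stack([series.o2hb, series.hhb], axis=-1)
    return OpticalRecording(od=conc @ a.T, fs=series.fs)


def baseline_correct(x: np.ndarray, fs: float,
                     baseline_duration: float = 60.0) -> np.ndarray:
    """Subtract each channel's mean over the first ``baseline_duration`` s."""
    x = np.asarray(x, dtype=float)
    n_base = int(round(baseline_duration * fs))
    if x.shape[0] < n_base:
        raise ValueError(
            f"recording ({x.shape[0]} samples) shorter than baseline "
            f"({n_base} samples)")
    return x - x[:n_base].mean(axis=0, keepdims=True)


def detrend(x: np.ndarray, fs: float | None = None) -> np.ndarray:
    """Remove the per-channel least-squares linear trend."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    t = np.arange(n, dtype=float)
    design = np.column_stack([np.ones(n), t])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ coef


def despike(x: np.ndarray, fs: float, threshold: float = 5.0,
            window_s: float = 1.0) -> np.ndarray:
    """Replace samples deviating > ``threshold`` robust SDs from a rolling median.

    A lightweight automatic alternative to manual motion-artifact removal;
    off by default in the pipeline.
    """
    x = np.asarray(x, dtype=float)
    win = max(3, int(round(window_s * fs)) | 1)  # odd
    out = x.copy()
    cols = x[:, :, None].reshape(x.shape[0], -1) if x.ndim == 3 else x
    med = (pd.DataFrame(cols).rolling(win, center=True, min_periods=1)
           .median().to_numpy())
    resid = cols - med
    mad = np.median(np.abs(resid), axis=0, keepdims=True) / 0.6745
    mad = np.where(mad == 0, np.inf, mad)
    mask = np.abs(resid) > threshold * mad
    cleaned = np.where(mask, med, cols)
    return cleaned.reshape(x.shape) if x.ndim == 3 else cleaned


def extract_windows(series: ChromophoreSeries, onsets: Sequence[float],
                    grid: WindowGrid | None = None) -> np.ndarray:
    """Per-trial sliding-window means of dtHb.

    Returns an array of shape ``(n_trials, n_channels, n_windows)`` where
    window k of a trial averages dtHb over ``[onset + k*step,
    onset + k*step + width)``.
    """
    grid = grid or WindowGrid()
    thb = series.thb
    time = series.time
    duration = time[-1] + 1.0 / series.fs
    out = np.empty((len(onsets), thb.shape[1], grid.n_windows))
    for i, onset in enumerate(onsets):
        if onset + grid.span > duration + 1e-9:
            raise ValueError(
                f"trial {i} (onset {onset:.2f}s) extends past recording end "
                f"({duration:.2f}s)")
        for k, s in enumerate(grid.starts()):
            lo, hi = onset + s, onset + s + grid.width
            sel = (time >= lo - 1e-9) & (time < hi - 1e-9)
            out[i, :, k] = thb[sel].mean(axis=0)
    return out


def windows_to_frame(windows: np.ndarray, participant_id: str | int,
                     ) -> pd.DataFrame:
    """Tidy (participant, trial, channel, window_index, value) table."""
    n_trials, n_channels, n_windows = windows.shape
    idx = np.indices((n_trials, n_channels, n_windows)).reshape(3, -1)
    return pd.DataFrame({
        "participant_id": participant_id,
        "trial_index": idx[0],
        "channel": idx[1] + 1,
        "window_index": idx[2],
        "value": windows.ravel(),
    })


def canonical_hrf(fs: float = 10.0, duration: float = 30.0,
                  peak: float = 6.0, undershoot: float = 16.0,
                  ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak normalized to 1.

    Peak time defaults to 6 s, the middle of the 5-7 s range typically
    reported for the prefrontal optical response.
    """
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0, duration, 1.0 / fs)
    # a gamma density with shape k and unit scale peaks at k - 1
    h = (gamma_dist.pdf(t, peak + 1.0, scale=1.0)
         - ratio * gamma_dist.pdf(t, undershoot + 1.0, scale=1.0))
    return h / h.max()
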