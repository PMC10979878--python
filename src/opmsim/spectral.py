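"""Hilbert envelopes, evoked responses and baseline-corrected spectrograms.

The time-frequency spectrogram (TFS) filters a broadband virtual-electrode
timecourse into a set of overlapping frequency bands, computes the Hilbert
envelope per band and trial, averages across trials, and expresses each
band as relative change from its mean in a control window:

    TFS_b(t) = (E_b(t) − mean E_b over control) / mean E_b over control.

Bands default to 5-Hz-wide bins stepped by 2.5 Hz spanning 1-150 Hz.
Before the Hilbert transform each trial is reflection-padded by 0.25 s to
limit edge artefacts; conclusions should not rely on the padded edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .beamformer import VirtualElectrode


class SpectralError(ValueError):
    pass


EDGE_PAD = 0.25  # s of reflection padding around the Hilbert transform


def default_bands(low: float = 1.0, high: float = 150.0, width: float = 5.0,
                  step: float = 2.5) -> list[tuple[float, float]]:
    """Overlapping bands tiling [low, high] with no gaps."""
    lows = list(np.arange(low, high - width + 1e-9, step))
    bands = [(float(lo), float(lo + width)) for lo in lows]
    if bands[-1][1] < high:
        bands.append((high - width, high))
    return bands


@dataclass
class TFS:
    """Baseline-corrected relative amplitude change, band x time."""

    bands: list[tuple[float, float]]
    times: np.ndarray
    values: np.ndarray  # (n_bands, n_times)
    control_window: tuple[float, float]
    invalid_bands: np.ndarray | None = None

    def band_mask(self, lo: float, hi: float) -> np.ndarray:
        """Bands fully inside [lo, hi]."""
        return np.array([b[0] >= lo and b[1] <= hi for b in self.bands])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (lo, hi) in enumerate(self.bands):
            rows.append(pd.DataFrame({
                "band_low": lo, "band_high": hi,
                "time": self.times, "value": self.values[i],
            }))
        return pd.concat(rows, ignore_index=True)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _pad_filter_envelope(x: np.ndarray, band: tuple[float, float], fs: float
                         ) -> np.ndarray:
    """Band-pass then Hilbert magnitude, with reflection padding.

    x: (..., n_samples).
    """
    nyq = fs / 2.0
    if band[1] >= nyq:
        raise SpectralError(f"band {band} exceeds Nyquist ({nyq} Hz)")
    pad = int(round(EDGE_PAD * fs))
    pad = min(pad, x.shape[-1] - 1)
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    sos = sps.butter(2, band, btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, xp, axis=-1)
    env = np.abs(sps.hilbert(y, axis=-1))
    return env[..., pad : env.shape[-1] - pad] if pad else env


def hilbert_envelope(ve: VirtualElectrode, band: tuple[float, float],
                     average: bool = True) -> np.ndarray:
    """Oscillatory amplitude envelope of a virtual electrode.

    Band-pass, analytic signal, magnitude; with ``average=True`` the
    per-trial magnitudes are averaged (amplitudes, not complex signals).
    Returns (n_samples,) or (n_trials, n_samples).
    """
    env = _pad_filter_envelope(ve.trials, band, ve.sample_rate)
    return env.mean(axis=0) if average else env


def evoked_response(ve: VirtualElectrode) -> np.ndarray:
    """Trial-averaged (band-limited) virtual-electrode timecourse."""
    if ve.trials.shape[0] < 1:
        raise SpectralError("need at least one trial")
    return ve.average


def time_frequency_spectrogram(ve: VirtualElectrode,
                               control_window: tuple[float, float],
                               bands: list[tuple[float, float]] | None = None,
                               mode: str = "amplitude") -> TFS:
    """Baseline-corrected TFS of a broadband virtual electrode.

    ``mode='amplitude'`` (default) normalises the Hilbert envelope;
    ``mode='power'`` its square.  Bands whose control-window mean is zero
    are flagged invalid (NaN values) rather than dividing by zero.
    """
    fs = ve.sample_rate
    if bands is None:
        bands = [b for b in default_bands() if b[1] < fs / 2.0]
    t0 = ve.window[0]
    times = t0 + np.arange(ve.trials.shape[1]) / fs
    c0, c1 = control_window
    if c0 < t0 - 1e-9 or c1 > ve.window[1] + 1e-9:
        raise SpectralError(f"control window {control_window} outside epoch window")
    ctrl = (times >= c0) & (times < c1)
    values = np.empty((len(bands), times.size))
    invalid = np.zeros(len(bands), dtype=bool)
    for i, band in enumerate(bands):
        env = hilbert_envelope(ve, band, average=True)
        if mode == "power":
            env = env**2
        base = env[ctrl].mean()
        if base <= 0:
            invalid[i] = True
            values[i] = np.nan
        else:
            values[i] = (env - base) / base
    return TFS(list(bands), times, values, control_window, invalid_bands=invalid)
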