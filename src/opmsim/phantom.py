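"""Phantom validation analysis: burst amplitudes, linearity, error stats.

The phantom protocols drive a triangular coil with 17-Hz bursts (2 s on,
1 s off).  Because 2 s holds exactly 34 cycles, the 17-Hz component falls
on an exact DFT bin, so the burst amplitude is read off the magnitude
spectrum without leakage: a pure sinusoid of amplitude A reports A.

Three analyses mirror the validation experiments:

* per-burst 17-Hz amplitude extraction for every channel,
* open- vs closed-loop paired linearity (slope/intercept/R²), and
* background-field error statistics — the percent deviation of each
  burst amplitude from its channel's zero-background value, pooled over
  the best-coupled channels and all non-zero background levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DataFormatError, Recording
from .sessions import PHANTOM_BURST_ON, PHANTOM_FREQ, TRIGGER_CODES


class PhantomAnalysisError(ValueError):
    pass


@dataclass
class LinearityResult:
    """Least-squares fit of paired closed-loop (y) vs open-loop (x) amplitudes."""

    slope: float
    intercept: float
    r_squared: float
    pairs: pd.DataFrame


@dataclass
class ErrorStats:
    """Background-induced amplitude error over the best-coupled channels."""

    per_channel: pd.DataFrame  # channel, level, burst_index, percent_error
    top_channels: np.ndarray
    mean_percent: float
    sd_percent: float
    condition: str


def extract_burst_amplitudes(rec: Recording,
                             trigger_code: int = TRIGGER_CODES["phantom_on"],
                             burst_length: float = PHANTOM_BURST_ON,
                             freq: float = PHANTOM_FREQ) -> pd.DataFrame:
    """Per-burst Fourier magnitude at the phantom frequency, per channel.

    Returns a table with columns channel, burst_index, condition, level,
    amplitude (tesla).  The amplitude is (2/N)|X_k| at the exact bin
    k = freq * burst_length, so an A-amplitude sinusoid reports A; the
    burst length must hold an integer number of cycles.  Burst levels are
    read from ``rec.metadata['burst_levels']`` (mA for the linearity
    protocol, background nT for the sweep).
    """
    fs = rec.sample_rate
    n = int(round(burst_length * fs))
    k = burst_length * freq
    if abs(k - round(k)) > 1e-9:
        raise PhantomAnalysisError(
            f"burst_length {burst_length} s is not an integer number of "
            f"{freq}-Hz cycles"
        )
    k = int(round(k))
    onsets = rec.triggers.get(trigger_code)
    if onsets is None or onsets.size == 0:
        raise PhantomAnalysisError(f"no bursts on trigger code {trigger_code}")
    if onsets.max() + n > rec.n_samples:
        raise DataFormatError("final burst extends past the end of the record")
    levels = rec.metadata.get("burst_levels", [np.nan] * onsets.size)
    condition = rec.metadata.get("loop_mode", "unknown")
    rows = []
    for b, i0 in enumerate(onsets):
        seg = rec.data[:, i0 : i0 + n]
        amp = 2.0 / n * np.abs(np.fft.rfft(seg, axis=1)[:, k])
        rows.append(pd.DataFrame({
            "channel": np.arange(rec.n_channels),
            "burst_index": b,
            "condition": condition,
            "level": levels[b],
            "amplitude": amp,
        }))
    return pd.concat(rows, ignore_index=True)


def linearity_comparison(table_open: pd.DataFrame,
                         table_closed: pd.DataFrame) -> LinearityResult:
    """Pair open- and closed-loop bursts and fit closed = slope*open + b.

    Pairs on (channel, burst_index); mismatched keys raise.  Pooled over
    all channels and bursts, as in the phantom linearity figure.
    """
    merged = table_open.merge(
        table_closed, on=["channel", "burst_index"], suffixes=("_open", "_closed"),
        validate="one_to_one",
    )
    if len(merged) != len(table_open) or len(merged) != len(table_closed):
        raise PhantomAnalysisError("open/closed tables do not share (channel, burst) keys")
    fit = stats.linregress(merged["amplitude_open"], merged["amplitude_closed"])
    return LinearityResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        pairs=merged,
    )


def background_error_stats(table: pd.DataFrame, top_k: int = 10,
                           channels: np.ndarray | None = None,
                           signed: bool = False,
                           max_level: float | None = None) -> ErrorStats:
    """Percent deviation from the zero-background amplitude.

    For each of the ``top_k`` best-coupled channels (largest mean
    zero-background amplitude; pass ``channels`` to reuse a selection made
    on another condition), every non-zero-level burst contributes
    100 * |A − Ā₀| / Ā₀ where Ā₀ is that channel's mean zero-level
    amplitude.  Errors are pooled over channels, bursts and levels;
    ``signed=True`` keeps the sign, ``max_level`` restricts to a
    background sub-range.
    """
    zero = table[table["level"] == 0.0]
    if zero.empty:
        raise PhantomAnalysisError("table has no zero-background bursts")
    baselines = zero.groupby("channel")["amplitude"].mean()
    if channels is None:
        if top_k > baselines.size:
            raise PhantomAnalysisError(f"top_k={top_k} exceeds channel count")
        channels = baselines.nlargest(top_k).index.to_numpy()
    channels = np.asarray(channels)
    sub = table[(table["level"] > 0) & table["channel"].isin(channels)].copy()
    if max_level is not None:
        sub = sub[sub["level"] <= max_level]
    base = baselines.loc[sub["channel"]].to_numpy()
    err = 100.0 * (sub["amplitude"].to_numpy() - base) / base
    if not signed:
        err = np.abs(err)
    sub["percent_error"] = err
    return ErrorStats(
        per_channel=sub[["channel", "level", "burst_index", "percent_error"]],
        top_channels=channels,
        mean_percent=float(err.mean()),
        sd_percent=float(err.std(ddof=1)),
        condition=str(table["condition"].iloc[0]),
    )
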