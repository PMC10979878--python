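"""Preprocessing: channel/trial rejection, filtering, HFC, segmentation.

The chain mirrors standard wearable-MEG practice: automated bad-channel
detection from band-averaged noise density, powerline notches (50 Hz and
two harmonics) plus a 1-150 Hz band-pass (all zero-phase), homogeneous
field correction (HFC) projecting the three spatially uniform field
components out of the 192-channel data, trigger-locked segmentation, and
amplitude-threshold trial rejection.  Visual inspection in the original
workflow is replaced by thresholded median/MAD statistics so runs are
reproducible.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .containers import DataFormatError, Epochs, Recording


class InsufficientDataError(ValueError):
    pass


class RankDeficiencyError(ValueError):
    pass


def channel_noise_density(rec: Recording, band: tuple[float, float] = (3.0, 100.0),
                          ) -> np.ndarray:
    """Band-averaged amplitude spectral density per channel (T/sqrt(Hz))."""
    nperseg = min(rec.n_samples, int(4 * rec.sample_rate))
    f, pxx = sps.welch(rec.data, fs=rec.sample_rate, nperseg=nperseg, axis=1)
    sel = (f >= band[0]) & (f <= band[1])
    return np.sqrt(pxx[:, sel].mean(axis=1))


def detect_bad_channels(rec: Recording, z_threshold: float = 5.0,
                        dead_floor: float = 1e-15) -> np.ndarray:
    """Channels that are excessively noisy or effectively dead.

    A channel is flagged noisy when its 3-100 Hz band-averaged noise
    density exceeds the across-channel median + z_threshold * MAD, and
    dead when it falls below ``dead_floor``.  Requires at least 10 s of
    data for a stable density estimate.  Returns channel indices; the
    recording is not mutated.
    """
    if rec.duration < 10.0:
        raise InsufficientDataError("need at least 10 s to estimate noise density")
    dens = channel_noise_density(rec)
    med = np.median(dens)
    mad = np.median(np.abs(dens - med))
    noisy = dens > med + z_threshold * max(mad, np.finfo(float).tiny)
    dead = dens < dead_floor
    return np.flatnonzero(noisy | dead)


def drop_channels(rec: Recording, bad: np.ndarray) -> Recording:
    """Recording without the given channel indices (array metadata kept
    aligned by recording the retained index list)."""
    keep = np.setdiff1d(np.arange(rec.n_channels), np.asarray(bad, int))
    out = Recording(
        data=rec.data[keep],
        sample_rate=rec.sample_rate,
        array=None,
        triggers={c: v.copy() for c, v in rec.triggers.items()},
        flags=None if rec.flags is None else rec.flags[keep],
        aux=dict(rec.aux),
        metadata={**rec.metadata, "retained_channels": keep.tolist()},
        ground_truth=rec.ground_truth,
    )
    return out


def apply_filters(rec: Recording, notch_freqs: tuple = (50.0, 100.0, 150.0),
                  band: tuple[float, float] = (1.0, 150.0),
                  notch_q: float = 30.0) -> Recording:
    """Zero-phase notch and band-pass filtering of all channels.

    Notches (2nd-order IIR per direction) sit at the powerline frequency
    and two harmonics; the band-pass is a 4th-order Butterworth.  Both run
    forward-backward (filtfilt) so triggers stay aligned.  The sample rate
    must support the requested passband.
    """
    nyq = rec.sample_rate / 2.0
    if band[1] >= nyq:
        raise DataFormatError(
            f"band edge {band[1]} Hz not representable at {rec.sample_rate} Hz"
        )
    data = rec.data
    for f0 in notch_freqs:
        if f0 >= nyq:
            raise DataFormatError(f"notch {f0} Hz above Nyquist")
        b, a = sps.iirnotch(f0, notch_q, fs=rec.sample_rate)
        data = sps.filtfilt(b, a, data, axis=1)
    sos = sps.butter(2, band, btype="bandpass", fs=rec.sample_rate, output="sos")
    data = sps.sosfiltfilt(sos, data, axis=1)
    return rec.copy_with(data, note=f"filters notch={notch_freqs} band={band}")


def hfc_projector(orientations: np.ndarray) -> np.ndarray:
    """Projector removing spatially homogeneous fields: I − N (NᵀN)⁻¹ Nᵀ.

    N is the (n_channels, 3) matrix of sensitive-axis orientations; a
    uniform field b produces channel data N·b, which lies in the null
    space of the returned projector.
    """
    N = np.asarray(orientations, float)
    if np.linalg.matrix_rank(N) < 3:
        raise RankDeficiencyError("orientation matrix has rank < 3; cannot apply HFC")
    return np.eye(N.shape[0]) - N @ np.linalg.solve(N.T @ N, N.T)


def homogeneous_field_correction(rec: Recording) -> Recording:
    """Project the three homogeneous field components out of the data.

    Removes interference from distant sources, which appear nearly uniform
    over the array.  Idempotent; the projector is kept in the metadata for
    provenance.
    """
    if rec.array is None:
        raise DataFormatError("HFC needs channel orientations (rec.array)")
    P = hfc_projector(rec.array.orientations)
    out = rec.copy_with(P @ rec.data, note="hfc")
    out.metadata["hfc_projector"] = P
    return out


def segment_trials(rec: Recording, trigger_code: int,
                   window: tuple[float, float]) -> Epochs:
    """Cut trials around a trigger: half-open [t0, t1), floor rounding.

    Every requested window must lie inside the record; offending trials
    are listed in the truncation error.
    """
    fs = rec.sample_rate
    i0 = int(np.floor(window[0] * fs))
    n_win = int(np.floor((window[1] - window[0]) * fs))
    onsets = rec.triggers.get(trigger_code, np.array([], dtype=int))
    if onsets.size == 0:
        return Epochs(np.empty((0, rec.n_channels, n_win)), fs, window, trigger_code,
                      array=rec.array)
    starts = onsets + i0
    bad = np.flatnonzero((starts < 0) | (starts + n_win > rec.n_samples))
    if bad.size:
        raise DataFormatError(
            f"window {window} exceeds record bounds for trials {bad.tolist()}"
        )
    data = np.stack([rec.data[:, s : s + n_win] for s in starts])
    return Epochs(data, fs, window, trigger_code, array=rec.array)


def reject_bad_trials(ep: Epochs, z_threshold: float = 6.0) -> Epochs:
    """Drop trials whose peak amplitude is an outlier.

    A trial is rejected when its maximum absolute amplitude over channels
    and samples exceeds the across-trial median + z_threshold * MAD.
    """
    if ep.n_trials < 3:
        raise InsufficientDataError("need at least 3 trials for rejection statistics")
    peaks = np.abs(ep.data).max(axis=(1, 2))
    med = np.median(peaks)
    mad = np.median(np.abs(peaks - med))
    keep = peaks <= med + z_threshold * max(mad, np.finfo(float).tiny)
    if not keep.any():
        raise InsufficientDataError("all trials rejected")
    return Epochs(ep.data[keep], ep.sample_rate, ep.window, ep.trigger_code,
                  retained_trial_ids=ep.retained_trial_ids[keep],
                  retained_channel_ids=ep.retained_channel_ids,
                  array=ep.array)
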