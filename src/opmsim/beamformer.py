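"""Scalar LCMV beamforming: covariance, weights, images, virtual electrodes.

The linearly constrained minimum-variance (LCMV) beamformer reconstructs
source activity at a voxel with weights

    w = C⁻¹ l / (lᵀ C⁻¹ l),

where C is the (regularised) band-limited data covariance and l the lead
field of the voxel.  The source orientation is chosen in the tangential
plane to maximise output power, i.e. the generalised-eigenvalue solution
of the 2-orientation lead-field pair (equivalently, the eigenvector of
lᵀC⁻¹l with the smallest eigenvalue).  Covariance matrices are regularised
by adding 1% of their maximum eigenvalue to the diagonal.

Volumetric images contrast beamformer-projected power between an active
and a control window (pseudo-T) or normalise trial-averaged evoked
amplitude by projected sensor noise (pseudo-Z).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, signal as sps, stats

from .containers import DataFormatError, Epochs
from .geometry import SourceGrid


class BeamformerError(ValueError):
    pass


@dataclass
class BeamformerModel:
    """Fitted beamformer state for one band/window definition."""

    covariance: np.ndarray
    regularization_fraction: float
    band: tuple[float, float]
    sample_rate: float
    reg_covariance: np.ndarray | None = None
    weights: np.ndarray | None = None  # (n_voxels, n_channels)
    orientations: np.ndarray | None = None  # (n_voxels, 2), tangential coords
    grid: SourceGrid | None = None
    leadfield_scalar: np.ndarray | None = None  # (n_channels, n_voxels)
    invalid_voxels: np.ndarray | None = None  # externally silent voxels

    @property
    def noise_power(self) -> float:
        """Scaled-identity noise model used by pseudo-Z: reg_fraction * λmax."""
        lam = np.linalg.eigvalsh(self.covariance)[-1]
        return self.regularization_fraction * lam


@dataclass
class StatImage:
    """One statistic value per voxel of a source grid."""

    values: np.ndarray
    statistic: str  # pseudo_t | pseudo_z
    grid: SourceGrid
    band: tuple[float, float]
    active_window: tuple[float, float] | None = None
    control_window: tuple[float, float] | None = None
    invalid: np.ndarray | None = None

    def peak_voxel(self, extremum: str = "max") -> int:
        vals = np.where(np.isfinite(self.values), self.values,
                        -np.inf if extremum == "max" else np.inf)
        return int(np.argmax(vals) if extremum == "max" else np.argmin(vals))

    def peak_position(self, extremum: str = "max") -> np.ndarray:
        return self.grid.voxel_positions[self.peak_voxel(extremum)]

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        df["value"] = self.values
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_nifti(self, path) -> None:
        """Optional NIfTI volume export (mm affine; NaN off the grid)."""
        import nibabel as nib

        idx, shape, origin = self.grid.volume_indices()
        vol = np.full(shape, np.nan)
        vol[idx[:, 0], idx[:, 1], idx[:, 2]] = self.values
        affine = np.diag([self.grid.spacing * 1e3] * 3 + [1.0])
        affine[:3, 3] = origin * 1e3
        nib.save(nib.Nifti1Image(vol, affine), str(path))


@dataclass
class VirtualElectrode:
    """Beamformer-reconstructed source timecourse at one voxel."""

    trials: np.ndarray  # (n_trials, n_samples), source units (A·m-scaled)
    sample_rate: float
    window: tuple[float, float]
    voxel_position: np.ndarray
    band: tuple[float, float]

    @property
    def average(self) -> np.ndarray:
        return self.trials.mean(axis=0)

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.trials.shape[1]) / self.sample_rate


def bandpass_epochs(ep: Epochs, band: tuple[float, float]) -> Epochs:
    """Zero-phase 4th-order Butterworth band-pass of every trial."""
    sos = sps.butter(2, band, btype="bandpass", fs=ep.sample_rate, output="sos")
    data = sps.sosfiltfilt(sos, ep.data, axis=2)
    return Epochs(data, ep.sample_rate, ep.window, ep.trigger_code,
                  retained_trial_ids=ep.retained_trial_ids, array=ep.array)


def compute_covariance(ep: Epochs, band: tuple[float, float],
                       reg_fraction: float = 0.01) -> BeamformerModel:
    """Band-limited sample covariance over all trials, with regularisation.

    Trials are band-passed and concatenated; C_reg = C + reg_fraction *
    λmax(C) * I.  The total sample count must exceed the channel count for
    the unregularised covariance to be full rank.
    """
    if ep.n_trials * ep.n_samples <= ep.n_channels:
        raise BeamformerError("covariance needs more samples than channels")
    filt = bandpass_epochs(ep, band)
    X = filt.data.transpose(1, 0, 2).reshape(ep.n_channels, -1)
    X = X - X.mean(axis=1, keepdims=True)
    C = (X @ X.T) / X.shape[1]
    lam = np.linalg.eigvalsh(C)[-1]
    C_reg = C + reg_fraction * lam * np.eye(C.shape[0])
    return BeamformerModel(C, reg_fraction, band, ep.sample_rate,
                           reg_covariance=C_reg)


def lcmv_weights(model: BeamformerModel, leadfields: np.ndarray,
                 grid: SourceGrid) -> BeamformerModel:
    """Fill in per-voxel scalar weights and optimal tangential orientations.

    leadfields: (n_channels, n_voxels, 2) for the two tangential unit
    moments per voxel.  The orientation minimises lᵀC⁻¹l (maximising
    output power 1/(lᵀC⁻¹l)); its sign is fixed by making the first
    non-zero component of the tangential coefficient vector positive.
    """
    C = model.reg_covariance
    if C is None:
        raise BeamformerError("model has no regularised covariance")
    try:
        cho = linalg.cho_factor(C)
    except linalg.LinAlgError as e:  # pragma: no cover - guarded by regularisation
        raise BeamformerError(f"covariance not invertible: {e}") from e
    n_ch, n_vox, _ = leadfields.shape
    L2 = leadfields.reshape(n_ch, n_vox * 2)
    CiL = linalg.cho_solve(cho, L2).reshape(n_ch, n_vox, 2)
    # 2x2 matrices M_v = L_vᵀ C⁻¹ L_v
    M = np.einsum("cvi,cvj->vij", leadfields, CiL)
    # smallest-eigenvalue eigenvector of each symmetric 2x2
    a, b, d = M[:, 0, 0], M[:, 0, 1], M[:, 1, 1]
    tr, det = a + d, a * d - b * b
    lam_min = 0.5 * (tr - np.sqrt(np.maximum(tr**2 - 4 * det, 0.0)))
    eta = np.stack([-b, a - lam_min], axis=1)
    degenerate = np.linalg.norm(eta, axis=1) < 1e-30
    eta[degenerate] = [1.0, 0.0]
    eta /= np.linalg.norm(eta, axis=1, keepdims=True)
    flip = np.where(np.abs(eta[:, 0]) > 1e-12, np.sign(eta[:, 0]), np.sign(eta[:, 1]))
    eta *= flip[:, None]

    lead = np.einsum("cvi,vi->cv", leadfields, eta)  # (n_ch, n_vox)
    Ci_lead = linalg.cho_solve(cho, lead)
    denom = np.einsum("cv,cv->v", lead, Ci_lead)
    # a dipole at the sphere centre is externally silent: zero lead field,
    # zero denominator.  Such voxels get zero weights and an invalid mark.
    silent = denom <= 1e-12 * denom.max()
    if np.any(denom < 0):
        raise BeamformerError("negative lᵀC⁻¹l; check lead fields")
    safe = np.where(silent, 1.0, denom)
    W = (Ci_lead / safe).T  # (n_vox, n_ch)
    W[silent] = 0.0

    model.weights = W
    model.orientations = eta
    model.grid = grid
    model.leadfield_scalar = lead
    model.invalid_voxels = silent
    return model


def _beamform_power(W: np.ndarray, ep: Epochs, window: tuple[float, float]
                    ) -> np.ndarray:
    """Trial-summed projected power per voxel within a window."""
    sl = ep.sample_slice(window)
    P = np.zeros(W.shape[0])
    for t in range(ep.n_trials):
        Y = W @ ep.data[t, :, sl.start : sl.stop]
        P += np.einsum("vs,vs->v", Y, Y)
    return P


def pseudo_t_image(ep: Epochs, model: BeamformerModel,
                   active: tuple[float, float], control: tuple[float, float],
                   grid: SourceGrid | None = None) -> StatImage:
    """Pseudo-T contrast image: (P_active − P_control)/(P_active + P_control).

    Epochs are band-passed to the model band; P is beamformed power summed
    over trials in each window.  The normalisation is bounded in [−1, 1]
    and needs no separate noise estimate; voxels with zero total power are
    marked invalid.  Antisymmetric under swapping the windows.
    """
    if model.weights is None:
        raise BeamformerError("compute lcmv_weights before imaging")
    grid = grid or model.grid
    filt = bandpass_epochs(ep, model.band)
    Pa = _beamform_power(model.weights, filt, active)
    Pc = _beamform_power(model.weights, filt, control)
    denom = Pa + Pc
    invalid = denom <= 0
    values = np.zeros_like(Pa)
    np.divide(Pa - Pc, denom, out=values, where=~invalid)
    return StatImage(values, "pseudo_t", grid, model.band, active, control,
                     invalid=invalid)


def pseudo_z_image(ep: Epochs, model: BeamformerModel, latency: float,
                   grid: SourceGrid | None = None) -> StatImage:
    """Noise-normalised evoked amplitude image at one latency.

    pseudo-Z = |trial-averaged beamformed amplitude at the latency| /
    sqrt(wᵀ Σ_noise w) with Σ_noise the scaled-identity noise model
    (reg_fraction * λmax * I).
    """
    if model.weights is None:
        raise BeamformerError("compute lcmv_weights before imaging")
    if not (ep.window[0] <= latency < ep.window[1]):
        raise BeamformerError(f"latency {latency} outside epoch window {ep.window}")
    grid = grid or model.grid
    filt = bandpass_epochs(ep, model.band)
    idx = int(np.floor((latency - ep.window[0]) * ep.sample_rate))
    evoked = filt.data.mean(axis=0)[:, idx]
    amp = model.weights @ evoked
    noise = model.noise_power * np.einsum("vc,vc->v", model.weights, model.weights)
    invalid = noise <= 0
    values = np.zeros_like(amp)
    np.divide(np.abs(amp), np.sqrt(noise, where=~invalid, out=np.ones_like(noise)),
              out=values, where=~invalid)
    return StatImage(values, "pseudo_z", grid, model.band,
                     active_window=(latency, latency), invalid=invalid)


def virtual_electrode(ep: Epochs, model: BeamformerModel, voxel: int,
                      bandpass: bool = True) -> VirtualElectrode:
    """Beamformed per-trial timecourse at one grid voxel.

    The weight's sign convention (positive lead-field projection) is fixed
    at weight construction, so repeated runs agree in polarity.
    """
    if model.weights is None:
        raise BeamformerError("compute lcmv_weights before extracting electrodes")
    if not 0 <= voxel < model.weights.shape[0]:
        raise BeamformerError(f"voxel {voxel} not on the grid")
    data = bandpass_epochs(ep, model.band) if bandpass else ep
    w = model.weights[voxel]
    trials = np.einsum("c,tcs->ts", w, data.data)
    return VirtualElectrode(trials, ep.sample_rate, ep.window,
                            model.grid.voxel_positions[voxel], model.band)


def compare_localisations(image_a: StatImage, image_b: StatImage,
                          ve_a: VirtualElectrode, ve_b: VirtualElectrode,
                          extremum: str = "max") -> tuple[float, float]:
    """Run-comparison metrics: peak distance (mm) and timecourse Pearson r.

    ``extremum`` selects the peak convention: 'max' for power increases
    (ERS, evoked), 'min' for decreases (ERD).  Timecourses are trial
    averages; Pearson r is invariant to affine scaling of either input.
    """
    if image_a.grid.n_voxels != image_b.grid.n_voxels or not np.allclose(
        image_a.grid.voxel_positions, image_b.grid.voxel_positions
    ):
        raise BeamformerError("images must share a source grid")
    pa = image_a.peak_position(extremum)
    pb = image_b.peak_position(extremum)
    distance_mm = float(np.linalg.norm(pa - pb) * 1e3)
    ta, tb = ve_a.average, ve_b.average
    if ta.shape != tb.shape:
        raise BeamformerError("timecourses must share length")
    r = float(stats.pearsonr(ta, tb).statistic)
    return distance_mm, r
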