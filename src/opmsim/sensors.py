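"""Zero-field magnetometer response model: open- and closed-loop operation.

An optically pumped magnetometer is linear only within a narrow window
around zero field (±1.5 nT here).  In open loop, a static background field
suppresses the on-axis gain following the Lorentzian zero-field resonance

    G(|B_dc|) = gamma^2 / (gamma^2 + |B_dc|^2),

with gamma the resonance half-width, and background components on the two
orthogonal axes leak into the measured axis (cross-axis projection error,
CAPE), modelled as a bilinear term cape * B_b_ortho1 * B_b_ortho2 / gamma.
In closed loop, on-board coils null the cell field by negative feedback,
so the measured field equals the true field for any background within the
coil range (±50 nT), independent of the gain law.

The transfer operates per sensor in the sensor-local frame (axes X, Y, Z);
``simulate_sensor_outputs`` composes it over a whole triaxial array and
adds white sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .containers import Recording
from .geometry import SensorArray


@dataclass
class FieldState:
    """True vector field at one sensor over time, in the sensor-local frame.

    ``total`` and ``background`` are (n_samples, 3); the signal of interest
    is total − background, componentwise.  Background holds the slow
    (sub-MEG-band) components that drive gain suppression and CAPE.
    """

    total: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        self.total = np.atleast_2d(np.asarray(self.total, float))
        self.background = np.atleast_2d(np.asarray(self.background, float))
        if self.total.shape != self.background.shape or self.total.shape[1] != 3:
            raise ValueError("total and background must both be (n_samples, 3)")

    @property
    def signal(self) -> np.ndarray:
        return self.total - self.background


@dataclass
class SensorModelParams:
    """Physical parameters of the magnetometer response.

    linewidth_gamma : T
        Half-width of the zero-field resonance; sets the gain roll-off.
        The true linewidth of commercial triaxial sensors is not public;
        10 nT is a placeholder of the right order.
    cape_coefficient : dimensionless
        Strength of the bilinear cross-axis projection term.
    dynamic_range : T
        Open-loop linear window (±1.5 nT); beyond it samples are clamped
        and flagged as railed.
    coil_range : T
        Reach of the on-board nulling coils (±50 nT); closed-loop samples
        beyond it are flagged out-of-range.
    loop_bandwidth : Hz or None
        None models an ideal (instantaneous) feedback loop; a finite value
        applies a single-pole tracking model to the compensation field.
    noise_density : T/sqrt(Hz)
        White sensor noise amplitude spectral density (~15 fT/sqrt(Hz)).
    dc_cutoff : Hz
        First-order low-pass corner separating the quasi-static field that
        drives gain suppression from the MEG-band signal.
    """

    linewidth_gamma: float = 10e-9
    cape_coefficient: float = 0.1
    dynamic_range: float = 1.5e-9
    coil_range: float = 50e-9
    loop_mode: str = "open"
    loop_bandwidth: float | None = None
    noise_density: float = 15e-15
    sample_rate: float = 375.0
    dc_cutoff: float = 1.0

    def __post_init__(self) -> None:
        if self.loop_mode not in ("open", "closed"):
            raise ValueError("loop_mode must be 'open' or 'closed'")
        for name in ("linewidth_gamma", "dynamic_range", "coil_range", "sample_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dynamic_range >= self.coil_range:
            raise ValueError("dynamic_range must be below coil_range")

    def with_mode(self, loop_mode: str) -> "SensorModelParams":
        return replace(self, loop_mode=loop_mode)


def _slow_field(x: np.ndarray, params: SensorModelParams) -> np.ndarray:
    """First-order low-pass of each column at ``dc_cutoff`` Hz.

    Initialised at the first sample so a static field passes through
    without a startup transient.
    """
    dt = 1.0 / params.sample_rate
    alpha = dt / (dt + 1.0 / (2.0 * np.pi * params.dc_cutoff))
    b, a = [alpha], [1.0, alpha - 1.0]
    zi = signal.lfilter_zi(b, a)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[:, j], _ = signal.lfilter(b, a, x[:, j], zi=zi * x[0, j])
    return out


def open_loop_transfer(state: FieldState, params: SensorModelParams
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Open-loop measured field and railing flags for one sensor.

    Returns (measured (n_samples, 3), railed (n_samples,) bool).  Each axis
    reads G(|B_dc|) * B_axis plus the CAPE leakage of the two orthogonal
    slow components; |B_dc| is the magnitude of the low-pass-filtered total
    field.  Samples where any true axis field exceeds the dynamic range
    are clamped to ±dynamic_range and flagged railed.
    """
    if params.loop_mode != "open":
        raise ValueError("open_loop_transfer requires loop_mode='open'")
    B = state.total
    gamma = params.linewidth_gamma
    slow = _slow_field(B, params)
    mag2 = np.einsum("ij,ij->i", slow, slow)
    gain = gamma**2 / (gamma**2 + mag2)
    bg = state.background
    measured = gain[:, None] * B
    if params.cape_coefficient:
        cape = params.cape_coefficient / gamma
        measured[:, 0] += cape * bg[:, 1] * bg[:, 2]
        measured[:, 1] += cape * bg[:, 0] * bg[:, 2]
        measured[:, 2] += cape * bg[:, 0] * bg[:, 1]
    railed = np.any(np.abs(B) > params.dynamic_range, axis=1)
    np.clip(measured, -params.dynamic_range, params.dynamic_range, out=measured)
    return measured, railed


def closed_loop_transfer(state: FieldState, params: SensorModelParams
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Closed-loop measured field and out-of-range flags for one sensor.

    Under the ideal loop the feedback coils track the field exactly, so the
    output equals the true field whenever every axis stays within the coil
    range.  A finite ``loop_bandwidth`` low-passes the compensation field;
    the small residual at the cell is then read through the open-loop
    small-signal response (gain ~1), so the output is compensation +
    residual and converges to the ideal loop as bandwidth grows.
    """
    if params.loop_mode != "closed":
        raise ValueError("closed_loop_transfer requires loop_mode='closed'")
    B = state.total
    out_of_range = np.any(np.abs(B) > params.coil_range, axis=1)
    if params.loop_bandwidth is None:
        measured = B.copy()
    else:
        comp = _slow_field(B, replace(params, dc_cutoff=params.loop_bandwidth))
        residual = B - comp
        measured = comp + residual
        out_of_range |= np.any(np.abs(residual) > params.dynamic_range, axis=1)
    np.clip(measured, -params.coil_range, params.coil_range, out=measured)
    return measured, out_of_range


def sensor_transfer(state: FieldState, params: SensorModelParams
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Dispatch to the configured loop mode."""
    if params.loop_mode == "open":
        return open_loop_transfer(state, params)
    return closed_loop_transfer(state, params)


def simulate_sensor_outputs(total_fields: np.ndarray, array: SensorArray,
                            params: SensorModelParams, seed: int,
                            background_fields: np.ndarray | None = None,
                            ) -> Recording:
    """Run the sensor model over a whole array and add sensor noise.

    Parameters
    ----------
    total_fields : (n_sensors, n_samples, 3)
        True field at each sensor in its local frame (X, Y, Z axes).
    background_fields : same shape, optional
        Slow background component; defaults to zero (all field is signal).
    seed : int
        Noise generator seed; identical seeds give identical recordings.

    Returns a Recording whose channel order matches ``array`` (sensor-major,
    axes X, Y, Z) with railing/out-of-range flags, white noise of the
    configured density (std = noise_density * sqrt(sample_rate / 2)), and
    loop mode recorded in the metadata.
    """
    total_fields = np.asarray(total_fields, float)
    n_sensors, n_samples, three = total_fields.shape
    if three != 3 or n_sensors != array.n_sensors:
        raise ValueError(
            f"total_fields shape {total_fields.shape} does not match "
            f"{array.n_sensors} sensors"
        )
    if background_fields is None:
        background_fields = np.zeros((1, 1, 3))
    background_fields = np.broadcast_to(
        np.asarray(background_fields, float), total_fields.shape
    )
    rng = np.random.default_rng(seed)
    noise_std = params.noise_density * np.sqrt(params.sample_rate / 2.0)
    data = np.empty((array.n_channels, n_samples))
    flags = np.zeros((array.n_channels, n_samples), dtype=bool)
    for s in range(n_sensors):
        state = FieldState(total_fields[s], background_fields[s])
        measured, flagged = sensor_transfer(state, params)
        data[3 * s : 3 * s + 3] = measured.T
        flags[3 * s : 3 * s + 3] = flagged[None, :]
    if noise_std > 0:
        for c in range(array.n_channels):
            data[c] += noise_std * rng.standard_normal(n_samples)
    return Recording(
        data=data,
        sample_rate=params.sample_rate,
        array=array,
        flags=flags,
        metadata={"loop_mode": params.loop_mode, "seed": int(seed)},
    )
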