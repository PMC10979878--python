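"""Synthetic session generator: trial schedules and end-to-end recordings.

Builds the study conditions the analysis chain assumes: the pseudo-random
visuo-motor paradigm (60 circle, 120 face, 25 catch trials totalling
~396 s), the 17-Hz triangular-coil phantom protocols (8 amplitude levels x
8 repeats; 81 background levels 0-8 nT x 5 bursts), and an 8-s-trial
sitting-to-standing session with movement-driven background-field
excursions of a few nanotesla.

Neural sources are current dipoles in the conducting sphere.  Oscillatory
(ERD/ERS) sources are band-passed Gaussian noise with a multiplicative,
trigger-locked envelope; evoked sources are deterministic Gaussian-windowed
sinusoids peaking at a fixed latency.  Every simulated Recording carries a
``ground_truth`` dict (dipole positions, source envelopes, burst levels,
coupling patterns) so downstream stages always have an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .containers import Recording
from .geometry import (
    ConductorSphere,
    CurrentDipole,
    SensorArray,
    TriangularCoil,
    attach_phantom_coil,
    dipole_field_sphere,
    triangle_coil_field,
)
from .sensors import SensorModelParams, simulate_sensor_outputs

TRIGGER_CODES = {
    "circles": 1,
    "faces": 2,
    "catch": 3,
    "phantom_on": 4,
    "stand": 5,
    "sit": 6,
}

# printed paradigm parameters
VISUOMOTOR_TRIALS = {
    # trial_type: (count, stimulus duration s)
    "circles": (60, 1.0),
    "faces": (120, 0.5),
    "catch": (25, 0.8),
}
REST_DURATION = 1.25
REST_JITTER = 0.2

PHANTOM_FREQ = 17.0  # Hz
PHANTOM_BURST_ON = 2.0  # s
PHANTOM_BURST_OFF = 1.0  # s
LINEARITY_AMPLITUDES_MA = (0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 0.8, 1.0)
LINEARITY_REPEATS = 8
SWEEP_LEVELS_NT = tuple(np.round(np.linspace(0.0, 8.0, 81), 10))
SWEEP_BURSTS_PER_LEVEL = 5
SWEEP_CURRENT_MA = 1.0


class SessionError(ValueError):
    """Invalid session configuration."""


@dataclass(frozen=True)
class TrialEvent:
    onset: float
    trial_type: str
    stim_duration: float
    rest_duration: float
    trigger_code: int


@dataclass
class TrialSchedule:
    """Ordered trial events with strictly increasing onsets."""

    events: list[TrialEvent]

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise SessionError("event onsets must be strictly increasing")

    @property
    def total_duration(self) -> float:
        e = self.events[-1]
        return e.onset + e.stim_duration + e.rest_duration

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.events:
            out[e.trial_type] = out.get(e.trial_type, 0) + 1
        return out

    def onsets_of(self, trial_type: str) -> np.ndarray:
        return np.array([e.onset for e in self.events if e.trial_type == trial_type])


@dataclass
class SourceSpec:
    """A simulated neural source tied to a trial type.

    effect 'erd'/'ers': band-limited stochastic process whose envelope
    drops/rises by ``modulation_depth`` inside ``effect_window`` (seconds
    relative to each matching trigger).  effect 'evoked': deterministic
    damped oscillation peaking ``evoked_latency`` seconds after each
    trigger, amplitude ``baseline_amplitude``.
    """

    dipole: CurrentDipole
    effect: str  # erd | ers | evoked
    band: tuple[float, float]
    trial_type: str
    baseline_amplitude: float  # A·m
    modulation_depth: float = 0.0
    effect_window: tuple[float, float] = (0.0, 0.6)
    evoked_latency: float = 0.17
    edge_smoothing: float = 0.1  # s, raised-edge width of the envelope box

    def __post_init__(self) -> None:
        if self.effect not in ("erd", "ers", "evoked"):
            raise SessionError(f"unknown effect {self.effect!r}")
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise SessionError("modulation_depth must lie in [0, 1]")
        lo, hi = self.band
        if not (1.0 <= lo < hi <= 150.0):
            raise SessionError("band must lie within [1, 150] Hz")


def default_visuomotor_sources(sphere: ConductorSphere | None = None) -> list[SourceSpec]:
    """The minimum source set of the visuo-motor paradigm.

    A left-sensorimotor beta ERD source tied to catch (button-press)
    trials, a primary-visual gamma ERS source tied to circles, and a
    fusiform evoked source tied to faces.  Amplitudes are in the tens of
    nA·m, the usual scale of cortical current dipoles.
    """
    return [
        SourceSpec(
            dipole=CurrentDipole(np.array([-0.040, 0.015, 0.050]),
                                 np.array([0.0, 1.0, 0.0])),
            effect="erd", band=(13.0, 30.0), trial_type="catch",
            baseline_amplitude=30e-9, modulation_depth=0.5,
            effect_window=(-0.3, 0.3),
        ),
        SourceSpec(
            dipole=CurrentDipole(np.array([0.0, -0.058, 0.012]),
                                 np.array([1.0, 0.0, 0.0])),
            effect="ers", band=(52.0, 65.0), trial_type="circles",
            baseline_amplitude=10e-9, modulation_depth=1.0,
            effect_window=(0.05, 0.95),
        ),
        SourceSpec(
            dipole=CurrentDipole(np.array([0.035, -0.045, -0.020]),
                                 np.array([0.0, 1.0, 0.0])),
            effect="evoked", band=(2.0, 40.0), trial_type="faces",
            baseline_amplitude=25e-9, evoked_latency=0.17,
        ),
    ]


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------


def make_visuomotor_schedule(seed: int, trial_counts: dict | None = None,
                             rest_duration: float = REST_DURATION,
                             jitter: float = REST_JITTER,
                             start: float = 0.0) -> TrialSchedule:
    """Pseudo-randomised visuo-motor schedule.

    Defaults reproduce the printed paradigm: 60 circle trials (1 s
    stimulus), 120 face trials (0.5 s) and 25 catch trials (0.8 s), each
    followed by a rest of 1.25 s jittered uniformly by ±0.2 s, giving an
    expected total duration just over 396 s.  ``jitter=0`` makes every
    trial length exact.  Deterministic for a given seed.
    """
    counts = dict(VISUOMOTOR_TRIALS) if trial_counts is None else dict(trial_counts)
    rng = np.random.default_rng(seed)
    types: list[str] = []
    for name, (n, _dur) in counts.items():
        types += [name] * n
    order = rng.permutation(len(types))
    events = []
    t = start
    for k in order:
        name = types[k]
        stim = counts[name][1]
        rest = rest_duration + (rng.uniform(-jitter, jitter) if jitter else 0.0)
        events.append(TrialEvent(t, name, stim, rest, TRIGGER_CODES[name]))
        t += stim + rest
    return TrialSchedule(events)


# ---------------------------------------------------------------------------
# source waveform synthesis
# ---------------------------------------------------------------------------


def _band_noise(n: int, band: tuple[float, float], fs: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise."""
    x = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    return y / np.std(y)

def _event_box(n: int, fs: float, onsets: np.ndarray, window: tuple[float, float],
               smoothing: float) -> np.ndarray:
    """0/1 indicator of the effect windows, with smoothed edges."""
    box = np.zeros(n)
    for on in onsets:
        i0 = max(0, int(np.floor((on + window[0]) * fs)))
        i1 = min(n, int(np.floor((on + window[1]) * fs)))
        box[i0:i1] = 1.0
    if smoothing > 0:
        w = sps.windows.hann(max(3, 2 * int(smoothing * fs) + 1))
        box = np.convolve(box, w / w.sum(), mode="same")
    return np.clip(box, 0.0, 1.0)


def source_timecourse(spec: SourceSpec, schedule: TrialSchedule, n_samples: int,
                      fs: float, rng: np.random.Generator) -> np.ndarray:
    """Moment amplitude (A·m) over time for one source."""
    onsets = schedule.onsets_of(spec.trial_type)
    if spec.effect == "evoked":
        t = np.arange(n_samples) / fs
        s = np.zeros(n_samples)
        f0 = 0.5 * (spec.band[0] + spec.band[1]) / 2.0  # carrier inside the band
        sigma = 0.04
        for on in onsets:
            tau = t - (on + spec.evoked_latency)
            s += np.exp(-0.5 * (tau / sigma) ** 2) * np.cos(2 * np.pi * f0 * tau)
        return spec.baseline_amplitude * s
    carrier = _band_noise(n_samples, spec.band, fs, rng)
    box = _event_box(n_samples, fs, onsets, spec.effect_window, spec.edge_smoothing)
    sign = -1.0 if spec.effect == "erd" else 1.0
    envelope = spec.baseline_amplitude * (1.0 + sign * spec.modulation_depth * box)
    return envelope * carrier


def _local_patterns(array: SensorArray, field_at_sensors: np.ndarray) -> np.ndarray:
    """Rotate per-sensor head-frame field vectors into sensor-local frames.

    field_at_sensors: (n_sensors, 3) -> (n_sensors, 3) local components.
    """
    out = np.empty_like(field_at_sensors)
    for s in range(array.n_sensors):
        out[s] = array.triad_rotation(s) @ field_at_sensors[s]
    return out


def dipole_pattern(array: SensorArray, sphere: ConductorSphere,
                   dipole: CurrentDipole) -> np.ndarray:
    """(n_sensors, 3) sensor-local field per unit source amplitude.

    The dipole moment direction is normalised; scale by the moment
    magnitude (A·m) to get tesla.
    """
    m = dipole.moment / np.linalg.norm(dipole.moment)
    B = dipole_field_sphere(CurrentDipole(dipole.position, m), sphere,
                            array.sensor_positions)
    return _local_patterns(array, B)


def channel_coupling(array: SensorArray, pattern_local: np.ndarray) -> np.ndarray:
    """Flatten a sensor-local pattern (n_sensors, 3) to per-channel values."""
    return pattern_local.reshape(-1)


def amplitude_for_snr(array: SensorArray, sphere: ConductorSphere,
                      dipole: CurrentDipole, band: tuple[float, float],
                      params: SensorModelParams, snr: float) -> float:
    """Source amplitude (A·m RMS) giving the requested best-channel SNR.

    SNR is defined as best-channel band-limited signal RMS over the sensor
    noise RMS in the same band (noise_density * sqrt(bandwidth)).
    """
    coupling = np.abs(channel_coupling(array, dipole_pattern(array, sphere, dipole)))
    noise_rms = params.noise_density * np.sqrt(band[1] - band[0])
    return snr * noise_rms / coupling.max()


# ---------------------------------------------------------------------------
# end-to-end sessions
# ---------------------------------------------------------------------------


def _trigger_indices(onsets: np.ndarray, fs: float) -> np.ndarray:
    return np.floor(np.asarray(onsets) * fs).astype(int)


def simulate_visuomotor_session(array: SensorArray, schedule: TrialSchedule,
                                sources: list[SourceSpec] | None,
                                params: SensorModelParams, seed: int,
                                sphere: ConductorSphere | None = None,
                                padding: float = 2.0) -> Recording:
    """Full visuo-motor recording through the sensor model.

    ``sources=None`` uses :func:`default_visuomotor_sources`.  The returned
    Recording has one trigger code per trial type and a ground-truth dict
    with the source envelopes and dipole positions.
    """
    sphere = sphere or ConductorSphere()
    if sources is None:
        sources = default_visuomotor_sources(sphere)
    fs = params.sample_rate
    n = int(np.ceil((schedule.total_duration + padding) * fs))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    total = np.zeros((array.n_sensors, n, 3))
    truth: dict = {"sources": [], "seed": int(seed)}
    for spec in sources:
        if not sphere.contains(spec.dipole.position[None, :])[0]:
            raise SessionError("source dipole lies outside the conductor sphere")
        s_t = source_timecourse(spec, schedule, n, fs, rng)
        pat = dipole_pattern(array, sphere, spec.dipole)
        total += pat[:, None, :] * s_t[None, :, None]
        truth["sources"].append(
            {
                "trial_type": spec.trial_type,
                "effect": spec.effect,
                "band": spec.band,
                "position": spec.dipole.position.copy(),
                "timecourse": s_t,
                "pattern_local": pat,
            }
        )
    rec = simulate_sensor_outputs(total, array, params, seed)
    for name in ("circles", "faces", "catch"):
        on = schedule.onsets_of(name)
        if on.size:
            rec.triggers[TRIGGER_CODES[name]] = _trigger_indices(on, fs)
    rec.metadata["session"] = "visuomotor"
    rec.ground_truth = truth
    return rec


def _phantom_bursts(levels: list[float], fs: float, lead_in: float = 1.0):
    """Burst onset times and the total length for a phantom protocol."""
    onsets = lead_in + np.arange(len(levels)) * (PHANTOM_BURST_ON + PHANTOM_BURST_OFF)
    total = onsets[-1] + PHANTOM_BURST_ON + PHANTOM_BURST_OFF
    return onsets, int(np.ceil(total * fs))


def simulate_phantom_protocol(array: SensorArray, coil: TriangularCoil | None,
                              protocol: str, params: SensorModelParams,
                              seed: int,
                              amplitudes_mA: tuple = LINEARITY_AMPLITUDES_MA,
                              n_repeats: int = LINEARITY_REPEATS,
                              sweep_levels_nT: tuple = SWEEP_LEVELS_NT,
                              bursts_per_level: int = SWEEP_BURSTS_PER_LEVEL,
                              background_direction=(0.0, 0.0, 1.0)) -> Recording:
    """Phantom validation recording: 17-Hz bursts, 2 s on / 1 s off.

    protocol 'linearity': every amplitude level (default the 8 printed
    values, 0.01-1 mA) repeated ``n_repeats`` times in zero background
    (64 bursts).  protocol 'background_sweep': a fixed 1 mA burst repeated
    ``bursts_per_level`` times at each of 81 uniform vertical background
    levels from 0 to 8 nT (405 bursts); an aux channel records the
    commanded background in nT.  A trigger (code 4) marks each burst onset
    and ``metadata['burst_levels']`` lists the level of every burst.
    """
    if coil is None:
        coil = attach_phantom_coil(array)
    fs = params.sample_rate
    if abs(PHANTOM_BURST_ON * PHANTOM_FREQ - round(PHANTOM_BURST_ON * PHANTOM_FREQ)) > 1e-9:
        raise SessionError("burst length must hold an integer number of cycles")

    if protocol == "linearity":
        currents = [a * 1e-3 for a in amplitudes_mA for _ in range(n_repeats)]
        levels = [a for a in amplitudes_mA for _ in range(n_repeats)]
        backgrounds = [0.0] * len(currents)
    elif protocol == "background_sweep":
        currents = [SWEEP_CURRENT_MA * 1e-3] * (len(sweep_levels_nT) * bursts_per_level)
        levels = [b for b in sweep_levels_nT for _ in range(bursts_per_level)]
        backgrounds = [b * 1e-9 for b in levels]
    else:
        raise SessionError(f"unknown phantom protocol {protocol!r}")

    onsets, n = _phantom_bursts(levels, fs)
    burst_samples = int(round(PHANTOM_BURST_ON * fs))
    t_burst = np.arange(burst_samples) / fs
    wave = np.sin(2 * np.pi * PHANTOM_FREQ * t_burst)

    unit_coil = TriangularCoil(coil.vertices, current=1.0)
    pattern = _local_patterns(array, triangle_coil_field(unit_coil, array.sensor_positions))
    bdir = np.asarray(background_direction, float)
    bdir = bdir / np.linalg.norm(bdir)
    bg_pattern = _local_patterns(array, np.tile(bdir, (array.n_sensors, 1)))

    current_tc = np.zeros(n)
    bg_tc = np.zeros(n)
    starts = _trigger_indices(onsets, fs)
    block = burst_samples + int(round(PHANTOM_BURST_OFF * fs))
    for k, i0 in enumerate(starts):
        current_tc[i0 : i0 + burst_samples] = currents[k] * wave
        # background held from this burst through the following gap
        bg_tc[i0 : i0 + block] = backgrounds[k]
    bg_tc[: starts[0]] = backgrounds[0]

    total = (pattern[:, None, :] * current_tc[None, :, None]
             + bg_pattern[:, None, :] * bg_tc[None, :, None])
    background = bg_pattern[:, None, :] * bg_tc[None, :, None]
    rec = simulate_sensor_outputs(total, array, params, seed,
                                  background_fields=background)
    rec.triggers[TRIGGER_CODES["phantom_on"]] = starts
    rec.aux["background_nT"] = bg_tc * 1e9
    rec.metadata.update(
        protocol=protocol,
        burst_levels=list(map(float, levels)),
        burst_length=PHANTOM_BURST_ON,
        phantom_freq=PHANTOM_FREQ,
    )
    rec.ground_truth = {
        "coil_vertices": coil.vertices.copy(),
        "channel_coupling": channel_coupling(array, pattern),
        "burst_currents_A": list(map(float, currents)),
        "burst_background_T": list(map(float, backgrounds)),
    }
    return rec


def simulate_sit_to_stand_session(array: SensorArray, n_trials: int,
                                  field_excursion: float,
                                  params: SensorModelParams, seed: int,
                                  sphere: ConductorSphere | None = None,
                                  trial_length: float = 8.0,
                                  erd_depth: float = 0.4,
                                  beta_amplitude: float = 40e-9,
                                  lead_in: float = 1.0) -> Recording:
    """Sitting-to-standing session with movement field transients.

    Trials last 8 s and alternate stand (code 5) / sit (code 6) cues.
    During the first 4 s of every trial, each sensor experiences a smooth
    background excursion of peak magnitude ``field_excursion`` (default
    2 nT, the order observed when moving in the residual room field) along
    a per-sensor random direction drawn once per session, and bilateral
    sensorimotor sources show beta-band desynchronisation of depth
    ``erd_depth``.
    """
    if n_trials < 1:
        raise SessionError("n_trials must be at least 1")
    sphere = sphere or ConductorSphere()
    fs = params.sample_rate
    onsets = lead_in + np.arange(n_trials) * trial_length
    n = int(np.ceil((onsets[-1] + trial_length + 1.0) * fs))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))

    events = [
        TrialEvent(on, "stand" if k % 2 == 0 else "sit", 1.0, trial_length - 1.0,
                   TRIGGER_CODES["stand" if k % 2 == 0 else "sit"])
        for k, on in enumerate(onsets)
    ]
    schedule = TrialSchedule(events)

    sources = [
        SourceSpec(
            dipole=CurrentDipole(np.array([sx, 0.015, 0.050]), np.array([0.0, 1.0, 0.0])),
            effect="erd", band=(13.0, 30.0), trial_type=side,
            baseline_amplitude=beta_amplitude, modulation_depth=erd_depth,
            effect_window=(0.0, 4.0), edge_smoothing=0.25,
        )
        for sx, side in ((-0.040, "stand"), (0.040, "sit"))
    ]
    # both sources respond to every cue type
    total = np.zeros((array.n_sensors, n, 3))
    truth: dict = {"sources": [], "seed": int(seed)}
    both = TrialSchedule(
        [TrialEvent(e.onset, "move", e.stim_duration, e.rest_duration, 0)
         for e in events]
    )
    for spec in sources:
        moved = SourceSpec(spec.dipole, spec.effect, spec.band, "move",
                           spec.baseline_amplitude, spec.modulation_depth,
                           spec.effect_window, edge_smoothing=spec.edge_smoothing)
        s_t = source_timecourse(moved, both, n, fs, rng)
        pat = dipole_pattern(array, sphere, spec.dipole)
        total += pat[:, None, :] * s_t[None, :, None]
        truth["sources"].append(
            {"position": spec.dipole.position.copy(), "band": spec.band,
             "effect": "erd", "timecourse": s_t, "pattern_local": pat}
        )

    # movement transient: per-sensor direction, Hann profile over 0-4 s
    directions = rng.standard_normal((array.n_sensors, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    profile = np.zeros(n)
    half = int(round(4.0 * fs))
    bump = sps.windows.hann(half)
    for on in onsets:
        i0 = int(np.floor(on * fs))
        seg = min(half, n - i0)
        profile[i0 : i0 + seg] = np.maximum(profile[i0 : i0 + seg], bump[:seg])
    background = directions[:, None, :] * (field_excursion * profile)[None, :, None]
    total += background

    rec = simulate_sensor_outputs(total, array, params, seed,
                                  background_fields=background)
    for code, name in ((5, "stand"), (6, "sit")):
        on = schedule.onsets_of(name)
        if on.size:
            rec.triggers[code] = _trigger_indices(on, fs)
    rec.metadata["session"] = "sit_to_stand"
    truth["background_profile"] = field_excursion * profile
    truth["background_directions"] = directions
    rec.ground_truth = truth
    return rec
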