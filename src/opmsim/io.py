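"""Serialization and reproducible pipeline runs.

A Recording is stored as a directory: a flat channel-major float64 binary
(``data.bin``), the channel table as TSV, and a human-readable YAML
sidecar holding the sample rate, triggers, loop mode, seed and processing
provenance.  The format is language-agnostic and diff-able; conversion to
a vendor MEG container is an extension point, not core.

``run_pipeline`` executes simulate → preprocess → beamform →
spectral/phantom stages from a single config mapping, stamping every
output with the config hash and seed so identical configs reproduce
byte-identical TSVs.
"""

from __future__ import annotations

import hashlib
import importlib.resources
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .containers import DataFormatError, Recording
from .geometry import (
    ConductorSphere,
    SensorArray,
    SourceGrid,
    build_lead_fields,
    build_synthetic_helmet,
)
from .sensors import SensorModelParams
from . import beamformer as bf
from . import phantom as ph
from . import preprocess as pp
from . import sessions
from . import spectral as sp

SIDECAR = "meta.yaml"
DATA_FILE = "data.bin"
FLAGS_FILE = "flags.bin"
CHANNELS_FILE = "channels.tsv"


class PipelineError(RuntimeError):
    pass


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _yaml_safe(v) for k, v in obj.items()
                if not isinstance(v, np.ndarray)}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_recording(rec: Recording, path) -> Path:
    """Losslessly serialise a Recording to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rec.data.astype("<f8").tofile(path / DATA_FILE)
    if rec.flags is not None:
        rec.flags.astype(np.uint8).tofile(path / FLAGS_FILE)
    if rec.array is not None:
        rec.array.to_tsv(path / CHANNELS_FILE)
    aux_files = {}
    for name, arr in rec.aux.items():
        fn = f"aux_{name}.bin"
        np.asarray(arr, float).astype("<f8").tofile(path / fn)
        aux_files[name] = fn
    meta = {
        "format_version": 1,
        "package_version": __version__,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "dtype": "<f8",
        "units": "tesla",
        "sample_rate": float(rec.sample_rate),
        "triggers": {int(c): np.asarray(v).tolist() for c, v in rec.triggers.items()},
        "has_flags": rec.flags is not None,
        "aux": aux_files,
        "metadata": _yaml_safe(rec.metadata),
    }
    (path / SIDECAR).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_recording(path) -> Recording:
    """Read a Recording directory written by :func:`write_recording`."""
    path = Path(path)
    sidecar = path / SIDECAR
    if not sidecar.exists():
        raise DataFormatError(f"missing metadata sidecar {sidecar}")
    meta = yaml.safe_load(sidecar.read_text())
    n_ch, n_s = meta["n_channels"], meta["n_samples"]
    data = np.fromfile(path / DATA_FILE, dtype=meta["dtype"])
    if data.size != n_ch * n_s:
        raise DataFormatError(
            f"data has {data.size} values, sidecar promises {n_ch}x{n_s}"
        )
    data = data.reshape(n_ch, n_s)
    array = None
    if (path / CHANNELS_FILE).exists():
        array = SensorArray.from_tsv(path / CHANNELS_FILE)
        if array.n_channels != n_ch:
            raise DataFormatError(
                f"channel table has {array.n_channels} rows for {n_ch}-channel data"
            )
    flags = None
    if meta.get("has_flags"):
        flags = np.fromfile(path / FLAGS_FILE, dtype=np.uint8).reshape(n_ch, n_s).astype(bool)
    aux = {name: np.fromfile(path / fn, dtype="<f8")
           for name, fn in meta.get("aux", {}).items()}
    return Recording(
        data=data,
        sample_rate=meta["sample_rate"],
        array=array,
        triggers={int(c): np.asarray(v, int) for c, v in meta["triggers"].items()},
        flags=flags,
        aux=aux,
        metadata=meta.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def load_config(source) -> dict:
    """Load a run config from a path, name of a bundled config, or dict."""
    if isinstance(source, dict):
        return dict(source)
    p = Path(source)
    if p.exists():
        return yaml.safe_load(p.read_text())
    res = importlib.resources.files("opmsim") / "configs" / f"{source}.yaml"
    if res.is_file():
        return yaml.safe_load(res.read_text())
    raise PipelineError(f"config {source!r} not found")


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(_yaml_safe(config), sort_keys=True).encode()
    ).hexdigest()[:12]


def _build_params(config: dict, seed: int) -> SensorModelParams:
    return SensorModelParams(**config.get("sensor_model", {}))


def _build_array(config: dict) -> SensorArray:
    g = config.get("helmet", {})
    return build_synthetic_helmet(
        n_sensors=g.get("n_sensors", 64),
        head_radius=g.get("head_radius", 0.09),
        standoff=g.get("standoff", 0.015),
        seed=g.get("seed", 0),
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config, seed: int | None = None, out_dir=None) -> Path:
    """Execute a configured run end to end and write its artefacts.

    config['kind'] selects the workflow: 'phantom_linearity',
    'phantom_sweep' (both simulate open- and closed-loop recordings and
    produce burst tables plus linearity / error-statistics reports),
    'visuomotor' (simulate, preprocess, beamform a pseudo-T image and
    virtual-electrode envelope) or 'sit_to_stand' (beta pseudo-T image and
    TFS).  Every artefact is stamped with the config hash and seed.
    """
    config = load_config(config)
    seed = int(config.get("seed", 1) if seed is None else seed)
    out = Path(out_dir or config.get("out", "opmsim_run"))
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    kind = config.get("kind")
    log: list[str] = [f"opmsim {__version__} run kind={kind} seed={seed} config={chash}"]
    try:
        if kind in ("phantom_linearity", "phantom_sweep"):
            _run_phantom(config, seed, out, log)
        elif kind == "visuomotor":
            _run_visuomotor(config, seed, out, log)
        elif kind == "sit_to_stand":
            _run_sit_to_stand(config, seed, out, log)
        else:
            raise PipelineError(f"unknown run kind {kind!r}")
    except Exception as e:
        (out / "run.log").write_text("\n".join(log + [f"FAILED: {e}"]) + "\n")
        raise PipelineError(f"stage failure in {kind!r} run: {e}") from e
    (out / "run.log").write_text("\n".join(log) + "\n")
    return out


def _run_phantom(config: dict, seed: int, out: Path, log: list[str]) -> None:
    array = _build_array(config)
    protocol = "linearity" if config["kind"] == "phantom_linearity" else "background_sweep"
    tables = {}
    for i, mode in enumerate(("open", "closed")):
        params = _build_params(config, seed).with_mode(mode)
        rec = sessions.simulate_phantom_protocol(
            array, None, protocol, params, seed=seed + i
        )
        write_recording(rec, out / f"recording_{mode}")
        tables[mode] = ph.extract_burst_amplitudes(rec)
        tables[mode].to_csv(out / f"burst_amplitudes_{mode}.tsv", sep="\t", index=False)
        log.append(f"{mode}-loop: {rec.n_channels} ch, "
                   f"{len(rec.triggers[sessions.TRIGGER_CODES['phantom_on']])} bursts")
    lines = []
    if protocol == "linearity":
        fit = ph.linearity_comparison(tables["open"], tables["closed"])
        lines += [f"slope {fit.slope:.4f}", f"intercept_fT {fit.intercept*1e15:.3f}",
                  f"r_squared {fit.r_squared:.6f}"]
    else:
        closed = ph.background_error_stats(tables["closed"], top_k=config.get("top_k", 10))
        open_ = ph.background_error_stats(tables["open"], channels=closed.top_channels)
        for st in (closed, open_):
            lines.append(f"{st.condition}_mean_percent {st.mean_percent:.4f}")
            lines.append(f"{st.condition}_sd_percent {st.sd_percent:.4f}")
            st.per_channel.to_csv(out / f"errors_{st.condition}.tsv", sep="\t", index=False)
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    log += lines


def _preprocessed_epochs(rec, trigger_code, window, log):
    bad = pp.detect_bad_channels(rec)
    log.append(f"bad channels: {bad.tolist()}")
    rec = pp.apply_filters(rec)
    if rec.array is not None:
        rec = pp.homogeneous_field_correction(rec)
    ep = pp.segment_trials(rec, trigger_code, window)
    kept = pp.reject_bad_trials(ep)
    log.append(f"trials kept: {kept.n_trials}/{ep.n_trials}")
    return kept


def _imaging_grid(config: dict, sphere: ConductorSphere) -> SourceGrid:
    spacing = config.get("grid", {}).get("spacing", 0.004)
    return SourceGrid.regular(sphere, spacing=spacing)


def _run_visuomotor(config: dict, seed: int, out: Path, log: list[str]) -> None:
    array = _build_array(config)
    params = _build_params(config, seed)
    sphere = ConductorSphere()
    schedule = sessions.make_visuomotor_schedule(seed)
    rec = sessions.simulate_visuomotor_session(array, schedule, None, params, seed, sphere)
    write_recording(rec, out / "recording")
    band = tuple(config.get("band", (52.0, 65.0)))
    ep = _preprocessed_epochs(rec, sessions.TRIGGER_CODES["circles"], (0.0, 2.0), log)
    grid = _imaging_grid(config, sphere)
    lf = build_lead_fields(ep.array if ep.array is not None else array, grid, sphere)
    model = bf.lcmv_weights(bf.compute_covariance(ep, band), lf, grid)
    image = bf.pseudo_t_image(ep, model, (0.0, 0.6), (1.1, 1.7))
    image.to_tsv(out / "pseudo_t_circles.tsv")
    ve = bf.virtual_electrode(ep, model, image.peak_voxel("max"))
    env = sp.hilbert_envelope(ve, band)
    np.savetxt(out / "gamma_envelope.tsv", np.column_stack([ve.times, env]),
               delimiter="\t", header="time\tenvelope", comments="")
    log.append(f"pseudo-T peak at {image.peak_position('max')}")


def _run_sit_to_stand(config: dict, seed: int, out: Path, log: list[str]) -> None:
    array = _build_array(config)
    params = _build_params(config, seed).with_mode("closed")
    sphere = ConductorSphere()
    s2s = config.get("sit_to_stand", {})
    rec = sessions.simulate_sit_to_stand_session(
        array, n_trials=s2s.get("n_trials", 20),
        field_excursion=s2s.get("field_excursion", 2e-9), params=params, seed=seed,
        sphere=sphere,
    )
    write_recording(rec, out / "recording")
    rec.triggers = {
        0: np.sort(np.concatenate([rec.triggers.get(5, []), rec.triggers.get(6, [])])).astype(int),
        **rec.triggers,
    }
    ep = _preprocessed_epochs(rec, 0, (0.0, 8.0), log)
    grid = _imaging_grid(config, sphere)
    lf = build_lead_fields(ep.array if ep.array is not None else array, grid, sphere)
    model = bf.lcmv_weights(bf.compute_covariance(ep, (13.0, 30.0)), lf, grid)
    image = bf.pseudo_t_image(ep, model, (2.0, 3.0), (6.5, 7.5))
    image.to_tsv(out / "pseudo_t_beta.tsv")
    broadband = bf.lcmv_weights(
        bf.compute_covariance(ep, (1.0, min(150.0, rec.sample_rate / 2 - 10))), lf, grid
    )
    ve = bf.virtual_electrode(ep, broadband, image.peak_voxel("min"))
    tfs = sp.time_frequency_spectrogram(
        ve, control_window=(6.5, 7.5),
        bands=[b for b in sp.default_bands() if b[1] < rec.sample_rate / 2],
    )
    tfs.to_tsv(out / "tfs.tsv")
    log.append(f"beta pseudo-T minimum at {image.peak_position('min')}")
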