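"""Sensor-array and source geometry, and quasi-static forward fields.

This module defines the triaxial helmet array, the triangular phantom coil,
current dipoles in a homogeneous conducting sphere, and the regular source
grid used for volumetric imaging.  Forward fields are computed with

* the exact finite-segment Biot–Savart formula for the phantom coil
  (a closed single-turn polyline carrying a known current), and
* the closed-form field of a current dipole inside a homogeneous
  spherical conductor (primary dipole plus volume currents), which is the
  standard analytic MEG forward model.

All positions are in metres, fields in tesla, dipole moments in
ampere-metres, in a right-handed head frame whose origin is the sphere
centre.  The helmet frame coincides with the head frame (co-registration
is out of scope for synthetic data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MU0_OVER_4PI = 1e-7  # T·m/A

AXIS_LABELS = ("X", "Y", "Z")


class GeometryError(ValueError):
    """Invalid or singular geometric configuration."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensorChannel:
    """One sensitive axis of a triaxial sensor."""

    sensor_id: int
    axis_label: str
    position: np.ndarray
    orientation: np.ndarray


@dataclass
class SensorArray:
    """Triaxial sensor array: ``n_sensors`` units, three channels each.

    Channels are stored sensor-major (sensor 0 axes X, Y, Z, then sensor 1,
    ...), so the triad rotation matrix of sensor ``s`` is
    ``orientations[3*s:3*s+3]`` with rows = sensitive axes.  By construction
    axis Z is radial (away from the helmet origin) and X, Y are tangential.
    """

    positions: np.ndarray  # (n_channels, 3)
    orientations: np.ndarray  # (n_channels, 3), unit rows
    sensor_ids: np.ndarray  # (n_channels,)
    axis_labels: np.ndarray  # (n_channels,) of {X, Y, Z}
    frame_name: str = "head"
    helmet_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.orientations = np.asarray(self.orientations, float)
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-10):
            raise GeometryError("channel orientations must have unit norm")
        ids, counts = np.unique(self.sensor_ids, return_counts=True)
        if not np.all(counts == 3):
            raise GeometryError("every sensor_id must own exactly 3 channels")
        for s in ids:
            R = self.orientations[self.sensor_ids == s]
            if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
                raise GeometryError(f"sensor {s} triad is not orthonormal")

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.n_channels // 3

    @property
    def sensor_positions(self) -> np.ndarray:
        """(n_sensors, 3) position of each sensor unit."""
        return self.positions[::3]

    def triad_rotation(self, sensor: int) -> np.ndarray:
        """Rows = sensitive-axis directions of sensor ``sensor`` (3, 3)."""
        return self.orientations[3 * sensor : 3 * sensor + 3]

    @property
    def channels(self) -> list[SensorChannel]:
        return [
            SensorChannel(int(self.sensor_ids[i]), str(self.axis_labels[i]),
                          self.positions[i], self.orientations[i])
            for i in range(self.n_channels)
        ]

    def channel_names(self) -> list[str]:
        return [f"S{int(s):02d}-{a}" for s, a in zip(self.sensor_ids, self.axis_labels)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sensor_id": self.sensor_ids.astype(int),
                "axis_label": self.axis_labels,
                "pos_x": self.positions[:, 0],
                "pos_y": self.positions[:, 1],
                "pos_z": self.positions[:, 2],
                "ori_x": self.orientations[:, 0],
                "ori_y": self.orientations[:, 1],
                "ori_z": self.orientations[:, 2],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, frame_name: str = "head") -> "SensorArray":
        return cls(
            positions=df[["pos_x", "pos_y", "pos_z"]].to_numpy(float),
            orientations=df[["ori_x", "ori_y", "ori_z"]].to_numpy(float),
            sensor_ids=df["sensor_id"].to_numpy(int),
            axis_labels=df["axis_label"].to_numpy(str),
            frame_name=frame_name,
        )

    @classmethod
    def from_tsv(cls, path, frame_name: str = "head") -> "SensorArray":
        return cls.from_frame(pd.read_csv(path, sep="\t"), frame_name=frame_name)


@dataclass
class TriangularCoil:
    """Closed single-turn triangular coil (the dry phantom).

    Default geometry is isosceles with a 5 mm base and 45 mm height
    (area 1.125e-4 m²), matching the dry current-dipole phantom it models.
    """

    vertices: np.ndarray  # (3, 3) m
    current: float = 0.0  # A

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        if self.vertices.shape != (3, 3):
            raise GeometryError("coil needs exactly 3 vertices")
        if self.area < 1e-12:
            raise GeometryError("coil vertices are (nearly) collinear")

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    @property
    def area(self) -> float:
        a, b, c = self.vertices
        return 0.5 * float(np.linalg.norm(np.cross(b - a, c - a)))

    @property
    def normal(self) -> np.ndarray:
        a, b, c = self.vertices
        n = np.cross(b - a, c - a)
        return n / np.linalg.norm(n)

    @property
    def dipole_moment(self) -> np.ndarray:
        """Equivalent magnetic dipole moment I·A·n̂ (A·m²)."""
        return self.current * self.area * self.normal

    @classmethod
    def default(cls, base: float = 0.005, height: float = 0.045,
                current: float = 0.0) -> "TriangularCoil":
        # centroid at the origin, apex along +y, plane normal +z
        verts = np.array(
            [
                [0.0, 2.0 * height / 3.0, 0.0],
                [-base / 2.0, -height / 3.0, 0.0],
                [base / 2.0, -height / 3.0, 0.0],
            ]
        )
        return cls(vertices=verts, current=current)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriangularCoil":
        return TriangularCoil(self.vertices @ np.asarray(rotation, float).T
                              + np.asarray(translation, float), self.current)


@dataclass(frozen=True)
class ConductorSphere:
    """Homogeneous spherical volume conductor."""

    centre: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = 0.08

    def __post_init__(self) -> None:
        object.__setattr__(self, "centre", np.asarray(self.centre, float))
        if self.radius <= 0:
            raise GeometryError("sphere radius must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return np.linalg.norm(pts - self.centre, axis=1) < self.radius


@dataclass
class CurrentDipole:
    """Point current dipole inside the conductor sphere."""

    position: np.ndarray
    moment: np.ndarray  # A·m
    waveform_id: str | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float)
        self.moment = np.asarray(self.moment, float)


@dataclass
class SourceGrid:
    """Regular lattice of candidate source locations inside the sphere."""

    voxel_positions: np.ndarray  # (n_voxels, 3)
    spacing: float = 0.004

    def __post_init__(self) -> None:
        self.voxel_positions = np.atleast_2d(np.asarray(self.voxel_positions, float))
        if self.spacing <= 0:
            raise GeometryError("grid spacing must be positive")

    @property
    def n_voxels(self) -> int:
        return self.voxel_positions.shape[0]

    def nearest_voxel(self, point: np.ndarray) -> int:
        d = np.linalg.norm(self.voxel_positions - np.asarray(point, float), axis=1)
        return int(np.argmin(d))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.voxel_positions, columns=["x", "y", "z"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def volume_indices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Integer lattice indices, volume shape and origin of the grid."""
        origin = self.voxel_positions.min(axis=0)
        idx = np.rint((self.voxel_positions - origin) / self.spacing).astype(int)
        shape = idx.max(axis=0) + 1
        return idx, shape, origin

    def to_nifti_mask(self, path) -> None:
        """Optional NIfTI export of the grid occupancy mask (mm affine)."""
        import nibabel as nib

        idx, shape, origin = self.volume_indices()
        vol = np.zeros(shape, dtype=np.uint8)
        vol[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
        affine = np.diag([self.spacing * 1e3] * 3 + [1.0])
        affine[:3, 3] = origin * 1e3
        nib.save(nib.Nifti1Image(vol, affine), str(path))

    @classmethod
    def regular(cls, sphere: ConductorSphere, spacing: float = 0.004,
                margin: float = 0.004,
                centre: np.ndarray | None = None,
                half_extent: float | None = None) -> "SourceGrid":
        """Regular grid covering the sphere (or a cubic region of interest).

        ``margin`` keeps voxels strictly inside the conductor, where the
        forward model is defined.  Passing ``centre``/``half_extent``
        restricts the lattice to a cube, useful for fast targeted scans.
        """
        if centre is None:
            centre = sphere.centre
            half_extent = sphere.radius
        centre = np.asarray(centre, float)
        n = int(np.floor(half_extent / spacing))
        offs = np.arange(-n, n + 1) * spacing
        xs, ys, zs = np.meshgrid(offs, offs, offs, indexing="ij")
        pts = centre + np.stack([xs, ys, zs], axis=-1).reshape(-1, 3)
        keep = np.linalg.norm(pts - sphere.centre, axis=1) <= sphere.radius - margin
        return cls(voxel_positions=pts[keep], spacing=spacing)


# ---------------------------------------------------------------------------
# helmet construction
# ---------------------------------------------------------------------------


def build_synthetic_helmet(n_sensors: int = 64, head_radius: float = 0.09,
                           standoff: float = 0.015, seed: int = 0,
                           cap_fraction: float = 0.75) -> SensorArray:
    """Quasi-uniform triaxial array on a spherical cap above the head.

    Sensors sit on a sphere of radius ``head_radius + standoff`` on a
    golden-angle (Fibonacci) lattice covering the upper ``cap_fraction`` of
    the sphere; the seed only rotates the lattice in azimuth, so arrays with
    the same seed are identical.  Per sensor, axis Z points radially outward
    and X, Y span the tangent plane (Gram–Schmidt against the global x-axis,
    with the y-axis as fallback at the pole).

    Parameters
    ----------
    n_sensors : number of triaxial units (>= 4); channels = 3 * n_sensors.
    head_radius, standoff : metres; both must be positive.
    seed : azimuthal registration of the lattice; deterministic.
    """
    if n_sensors < 4:
        raise GeometryError("need at least 4 sensors")
    if head_radius <= 0 or standoff <= 0:
        raise GeometryError("head_radius and standoff must be positive")

    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi)
    radius = head_radius + standoff
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n_sensors)
    # cos(theta) from 1 (pole) down to 1 - 2*cap_fraction
    z = 1.0 - (i + 0.5) / n_sensors * 2.0 * cap_fraction
    theta = np.arccos(np.clip(z, -1, 1))
    phi = phase + golden * i
    dirs = np.stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)],
        axis=1,
    )

    positions = np.repeat(radius * dirs, 3, axis=0)
    orientations = np.empty((3 * n_sensors, 3))
    for s in range(n_sensors):
        radial = dirs[s]
        e1, e2 = tangential_basis(radial)
        orientations[3 * s] = e1
        orientations[3 * s + 1] = e2
        orientations[3 * s + 2] = radial
    sensor_ids = np.repeat(np.arange(n_sensors), 3)
    axis_labels = np.array(list(AXIS_LABELS) * n_sensors)
    return SensorArray(positions, orientations, sensor_ids, axis_labels)


def tangential_basis(radial: np.ndarray, reference: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal vectors spanning the plane perpendicular to ``radial``.

    Built by Gram–Schmidt from a fixed reference axis (default global x);
    when ``radial`` is within ~1e-6 of the reference, the global y-axis is
    the documented fallback, so the basis is always well defined.
    """
    radial = np.asarray(radial, float)
    radial = radial / np.linalg.norm(radial)
    ref = np.array([1.0, 0.0, 0.0]) if reference is None else np.asarray(reference, float)
    e1 = ref - np.dot(ref, radial) * radial
    if np.linalg.norm(e1) < 1e-6:
        ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - np.dot(ref, radial) * radial
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(radial, e1)
    return e1, e2


def attach_phantom_coil(array: SensorArray, slot_sensor: int | None = None,
                        offset: float = 0.045, base: float = 0.005,
                        height: float = 0.045) -> TriangularCoil:
    """Place the triangular phantom coil inside the helmet.

    The coil models a phantom glued into an empty sensor casing: its
    centroid sits ``offset`` metres radially inward of the chosen helmet
    slot (default: the sensor closest to the array's mean direction), with
    the coil normal along the local radial direction.  With the default
    45 mm offset and a 1 mA current the best-coupled channel sees a field
    of a few hundred picotesla, the scale of the phantom experiments.
    """
    sensor_pos = array.sensor_positions
    if slot_sensor is None:
        mean_dir = sensor_pos.mean(axis=0)
        mean_dir = mean_dir / np.linalg.norm(mean_dir)
        slot_sensor = int(np.argmax(sensor_pos @ mean_dir / np.linalg.norm(sensor_pos, axis=1)))
    slot = sensor_pos[slot_sensor]
    radial = slot / np.linalg.norm(slot)
    e1, e2 = tangential_basis(radial)
    R = np.stack([e1, e2, radial], axis=1)  # maps local (x,y,z) -> head frame
    centroid = slot - offset * radial
    return TriangularCoil.default(base=base, height=height).transformed(R, centroid)


# ---------------------------------------------------------------------------
# forward fields
# ---------------------------------------------------------------------------


def segment_field(a: np.ndarray, b: np.ndarray, current: float,
                  points: np.ndarray) -> np.ndarray:
    """Biot–Savart field of a finite straight segment a→b at ``points``.

    Uses the exact closed form B = (mu0 I / 4π) (r1 × r2) (|r1| + |r2|) /
    (|r1||r2| (|r1||r2| + r1·r2)) with r1, r2 the vectors from the field
    point to the segment endpoints.  Singular within 1e-6 m of the segment.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    r1 = np.asarray(a, float) - pts
    r2 = np.asarray(b, float) - pts
    n1 = np.linalg.norm(r1, axis=1)
    n2 = np.linalg.norm(r2, axis=1)
    denom = n1 * n2 * (n1 * n2 + np.einsum("ij,ij->i", r1, r2))
    if np.any(denom < 1e-18) or np.any(n1 < 1e-6) or np.any(n2 < 1e-6):
        raise GeometryError("field point lies on (or within 1e-6 m of) a coil segment")
    cross = np.cross(r1, r2)
    B = MU0_OVER_4PI * current * cross * ((n1 + n2) / denom)[:, None]
    return B if np.asarray(points).ndim == 2 else B[0]


def triangle_coil_field(coil: TriangularCoil, points: np.ndarray) -> np.ndarray:
    """Exact Biot–Savart field of the closed triangular coil (tesla).

    Linear in ``coil.current``; accepts a single point or an (N, 3) array.
    """
    single = np.asarray(points).ndim == 1
    pts = np.atleast_2d(np.asarray(points, float))
    B = np.zeros_like(pts)
    v = coil.vertices
    for k in range(3):
        B += segment_field(v[k], v[(k + 1) % 3], coil.current, pts)
    return B[0] if single else B


def free_space_dipole_field(moment: np.ndarray, position: np.ndarray,
                            points: np.ndarray) -> np.ndarray:
    """Magnetic field of a current dipole Q at ``position`` in free space.

    B = (mu0/4π) (Q × r) / |r|³ with r from the dipole to the field point.
    """
    single = np.asarray(points).ndim == 1
    pts = np.atleast_2d(np.asarray(points, float))
    r = pts - np.asarray(position, float)
    n = np.linalg.norm(r, axis=1)
    B = MU0_OVER_4PI * np.cross(np.asarray(moment, float), r) / n[:, None] ** 3
    return B[0] if single else B


def dipole_field_sphere(dipole: CurrentDipole, sphere: ConductorSphere,
                        points: np.ndarray) -> np.ndarray:
    """Field outside a homogeneous conducting sphere from an internal dipole.

    Closed-form solution including volume currents (Sarvas).  Radial
    dipoles are externally silent, and the radial field component equals
    that of the free-space current dipole.  Linear in ``dipole.moment``.
    """
    single = np.asarray(points).ndim == 1
    pts = np.atleast_2d(np.asarray(points, float))
    c = sphere.centre
    r0 = dipole.position - c
    if np.linalg.norm(r0) >= sphere.radius:
        raise GeometryError("dipole must lie inside the conductor sphere")
    r = pts - c
    rn = np.linalg.norm(r, axis=1)
    if np.any(rn <= sphere.radius - 1e-12):
        raise GeometryError("field points must lie outside the conductor sphere")
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    ar = np.einsum("ij,j->i", r, r0)  # r·r0
    adotr = np.einsum("ij,ij->i", a_vec, r)
    F = a * (rn * a + rn**2 - ar)
    gradF = (
        (a**2 / rn + adotr / a + 2.0 * a + 2.0 * rn)[:, None] * r
        - (a + 2.0 * rn + adotr / a)[:, None] * r0
    )
    Qxr0 = np.cross(dipole.moment, r0)
    B = MU0_OVER_4PI / F[:, None] ** 2 * (
        F[:, None] * Qxr0 - (np.einsum("ij,j->i", r, Qxr0))[:, None] * gradF
    )
    return B[0] if single else B


def build_lead_fields(array: SensorArray, grid: SourceGrid,
                      sphere: ConductorSphere) -> np.ndarray:
    """Lead fields (n_channels, n_voxels, 2) in T per A·m.

    Per voxel, columns hold the fields of unit dipoles along the two
    tangential basis directions (radial sources are silent in a sphere),
    projected onto each channel's sensitive axis.
    """
    if not np.all(sphere.contains(grid.voxel_positions)):
        raise GeometryError("all grid voxels must lie inside the conductor sphere")
    L = np.zeros((array.n_channels, grid.n_voxels, 2))
    for v in range(grid.n_voxels):
        pos = grid.voxel_positions[v]
        radial = pos - sphere.centre
        nr = np.linalg.norm(radial)
        if nr < 1e-9:
            radial = np.array([0.0, 0.0, 1.0])
        e1, e2 = tangential_basis(radial)
        for j, e in enumerate((e1, e2)):
            B = dipole_field_sphere(CurrentDipole(pos, e), sphere, array.positions)
            L[:, v, j] = np.einsum("ij,ij->i", B, array.orientations)
    return L
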