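"""Analytic spherical-conductor MEG forward model.

The magnetic field of a current dipole inside a homogeneous conducting
sphere has a closed form (the Sarvas formula); it is exact for spherical
geometry and the standard choice for MEG simulation.  Radial dipoles are
magnetically silent in this model, so source orientations that come too
close to radial are given a small tangential tilt before the lead field is
assembled (otherwise the sLORETA standardisation would divide by ~0).

Positions are millimetres (surface RAS), dipole moments nA*m.  Magnetometer
gains are tesla per nA*m; planar gradiometers are modelled as the difference
of two point magnetometers a fixed baseline apart, divided by the baseline,
giving T/m per nA*m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import SourceSpace

__all__ = [
    "MU0",
    "SensorArray",
    "LeadField",
    "sarvas_field",
    "build_sensor_array",
    "regularize_orientations",
    "build_leadfield",
    "build_free_gain",
    "project",
]

MU0 = 4e-7 * np.pi  # vacuum permeability, T*m/A

_MM = 1e-3  # mm -> m
_NAM = 1e-9  # nA*m -> A*m


@dataclass
class SensorArray:
    """A whole-head MEG array on an upper-hemisphere helmet.

    ``orientations`` holds the sensing direction for magnetometers (outward
    radial) and the baseline direction for planar gradiometers (tangential);
    a gradiometer senses the radial field component at two points separated
    by ``pair_offset`` mm along its baseline.
    """

    positions: np.ndarray  # (n, 3) mm
    orientations: np.ndarray  # (n, 3) unit
    kinds: np.ndarray  # (n,) "mag" | "grad"
    pair_offsets: np.ndarray  # (n,) mm; 0 for magnetometers
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def n_channels(self) -> int:
        return len(self.positions)

    def kind_mask(self, kind: str) -> np.ndarray:
        return self.kinds == kind

    def radial_directions(self) -> np.ndarray:
        rel = self.positions - self.center
        return rel / np.linalg.norm(rel, axis=1, keepdims=True)


@dataclass
class LeadField:
    """Gain matrix: channel x source, field per unit dipole moment (1 nA*m)."""

    gain: np.ndarray  # (n_channels, n_sources)
    sensors: SensorArray
    source_space: SourceSpace
    head_radius: float
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


def _dipole_field(r0_m: np.ndarray, q_am: np.ndarray, r_m: np.ndarray) -> np.ndarray:
    """Sarvas field vectors.

    Parameters are metres / A*m, sphere centred at the origin:
    ``r0_m`` (S, 3) dipole positions, ``q_am`` (S, 3) moments, ``r_m`` (P, 3)
    field points.  Returns (P, S, 3) in tesla.
    """
    r0 = np.atleast_2d(r0_m)[None, :, :]  # (1, S, 3)
    q = np.atleast_2d(q_am)[None, :, :]
    r = np.atleast_2d(r_m)[:, None, :]  # (P, 1, 3)
    a_vec = r - r0  # (P, S, 3)
    a = np.linalg.norm(a_vec, axis=-1)  # (P, S)
    rn = np.linalg.norm(r, axis=-1)  # (P, 1)
    r0_dot_r = np.einsum("psk,psk->ps", np.broadcast_to(r0, a_vec.shape), np.broadcast_to(r, a_vec.shape))
    a_dot_r = np.einsum("psk,psk->ps", a_vec, np.broadcast_to(r, a_vec.shape))
    F = a * (rn * a + rn**2 - r0_dot_r)
    c1 = a**2 / rn + a_dot_r / a + 2 * a + 2 * rn
    c2 = a + 2 * rn + a_dot_r / a
    gradF = c1[..., None] * r - c2[..., None] * r0  # (P, S, 3)
    qxr0 = np.cross(np.broadcast_to(q, a_vec.shape), np.broadcast_to(r0, a_vec.shape))
    qxr0_dot_r = np.einsum("psk,psk->ps", qxr0, np.broadcast_to(r, a_vec.shape))
    B = (MU0 / (4 * np.pi)) * (F[..., None] * qxr0 - qxr0_dot_r[..., None] * gradF) / (F**2)[..., None]
    return B


def sarvas_field(
    dipole_position: np.ndarray,
    dipole_moment: np.ndarray,
    sensor_position: np.ndarray,
    sensor_orientation: np.ndarray,
    head_radius: float = 85.0,
    center: np.ndarray | None = None,
) -> float:
    """Field of one current dipole projected onto one sensor direction (T).

    ``dipole_position``/``sensor_position`` in mm, ``dipole_moment`` in nA*m.
    The dipole must lie strictly inside and the sensor strictly outside the
    conductor sphere of ``head_radius`` mm around ``center``.
    """
    c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    r0 = (np.asarray(dipole_position, dtype=float) - c) * _MM
    r = (np.asarray(sensor_position, dtype=float) - c) * _MM
    R = head_radius * _MM
    if np.linalg.norm(r0) >= R:
        raise ValueError("dipole must be strictly inside the head sphere")
    if np.linalg.norm(r) <= R:
        raise ValueError("sensor must be strictly outside the head sphere")
    q = np.asarray(dipole_moment, dtype=float) * _NAM
    B = _dipole_field(r0[None], q[None], r[None])[0, 0]
    return float(B @ np.asarray(sensor_orientation, dtype=float))


def build_sensor_array(
    n_mag: int = 102,
    n_grad_pairs: int = 102,
    helmet_radius: float = 110.0,
    seed: int = 0,
    pair_offset: float = 17.0,
    center: np.ndarray | None = None,
) -> SensorArray:
    """Near-uniform upper-hemisphere helmet of triplet sensor sites.

    Sites are a Fibonacci lattice on the upper half-sphere (random azimuthal
    phase from ``seed``); each of the ``n_mag`` sites carries one radial
    magnetometer and, for the first ``n_grad_pairs`` sites, two orthogonal
    planar gradiometers with tangential baselines.  Defaults give the
    306-channel layout (102 magnetometers + 204 planar gradiometers).
    """
    c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi)
    n_sites = max(n_mag, n_grad_pairs)
    i = np.arange(n_sites)
    z = (i + 0.5) / n_sites  # upper hemisphere: z in (0, 1)
    golden = np.pi * (3 - np.sqrt(5))
    phi = golden * i + phase
    rho = np.sqrt(1 - z**2)
    units = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    sites = c + helmet_radius * units

    positions, orientations, kinds, offsets = [], [], [], []
    for s in range(n_sites):
        u = units[s]
        # tangent frame at the site
        ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e1 = np.cross(u, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        if s < n_mag:
            positions.append(sites[s])
            orientations.append(u)
            kinds.append("mag")
            offsets.append(0.0)
        if s < n_grad_pairs:
            for e in (e1, e2):
                positions.append(sites[s])
                orientations.append(e)
                kinds.append("grad")
                offsets.append(pair_offset)
    return SensorArray(
        positions=np.array(positions),
        orientations=np.array(orientations),
        kinds=np.array(kinds, dtype=object),
        pair_offsets=np.array(offsets),
        center=c,
    )


def regularize_orientations(
    source_space: SourceSpace,
    center: np.ndarray | None = None,
    min_angle_deg: float = 5.0,
) -> SourceSpace:
    """Tilt near-radial orientations ``min_angle_deg`` away from radial.

    Radial dipoles are silent in a spherical conductor; orientations within
    ``min_angle_deg`` of the head-centre radial direction are replaced by a
    unit vector exactly ``min_angle_deg`` off radial, tilted along the
    orientation's own tangential component (or a fixed tangent when that
    component vanishes).  Returns a new SourceSpace.
    """
    c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    pos = source_space.positions - c
    rad = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    ori = source_space.orientations.copy()
    cosang = np.einsum("ij,ij->i", ori, rad)
    alpha = np.deg2rad(min_angle_deg)
    near = np.abs(cosang) > np.cos(alpha)
    for j in np.flatnonzero(near):
        sgn = np.sign(cosang[j]) or 1.0
        tang = ori[j] - cosang[j] * rad[j]
        tn = np.linalg.norm(tang)
        if tn < 1e-12:
            ref = np.array([0.0, 0.0, 1.0]) if abs(rad[j, 2]) < 0.9 else np.array([1.0, 0.0, 0.0])
            tang = np.cross(rad[j], ref)
            tn = np.linalg.norm(tang)
        tang /= tn
        ori[j] = sgn * np.cos(alpha) * rad[j] + np.sin(alpha) * tang
    return SourceSpace(
        positions=source_space.positions.copy(),
        orientations=ori,
        hemispheres=source_space.hemispheres.copy(),
        vertex_ids=source_space.vertex_ids.copy(),
    )


def _gain_for_moments(
    positions_mm: np.ndarray,
    moments_nam: np.ndarray,
    sensors: SensorArray,
    center: np.ndarray,
    chunk: int = 2000,
) -> np.ndarray:
    """(n_channels, n_dipoles) gain for one fixed moment per dipole."""
    mag = sensors.kind_mask("mag")
    grad = sensors.kind_mask("grad")
    radial = sensors.radial_directions()
    # evaluation points: magnetometer sites, plus the +/- baseline points of
    # each gradiometer (all sensing radially)
    pts = [sensors.positions[mag]]
    dirs = [sensors.orientations[mag]]
    half = (sensors.pair_offsets[grad] / 2.0)[:, None] * sensors.orientations[grad]
    pts.append(sensors.positions[grad] + half)
    pts.append(sensors.positions[grad] - half)
    dirs.append(radial[grad])
    dirs.append(radial[grad])
    points = (np.vstack(pts) - center) * _MM
    directions = np.vstack(dirs)

    n_src = len(positions_mm)
    n_mag = int(mag.sum())
    n_grad = int(grad.sum())
    out = np.empty((sensors.n_channels, n_src))
    r0 = (positions_mm - center) * _MM
    q = moments_nam * _NAM
    for lo in range(0, n_src, chunk):
        hi = min(lo + chunk, n_src)
        B = _dipole_field(r0[lo:hi], q[lo:hi], points)  # (P, s, 3)
        proj = np.einsum("psk,pk->ps", B, directions)  # (P, s)
        vals = np.empty((sensors.n_channels, hi - lo))
        vals[mag] = proj[:n_mag]
        plus = proj[n_mag : n_mag + n_grad]
        minus = proj[n_mag + n_grad :]
        vals[grad] = (plus - minus) / (sensors.pair_offsets[grad][:, None] * _MM)
        out[:, lo:hi] = vals
    return out


def build_leadfield(
    source_space: SourceSpace,
    sensors: SensorArray,
    head_radius: float = 85.0,
    center: np.ndarray | None = None,
) -> LeadField:
    """Fixed-orientation lead field: column j = field of a 1 nA*m dipole at source j."""
    c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    inside = np.linalg.norm(source_space.positions - c, axis=1) < head_radius
    if not inside.all():
        raise ValueError(f"sources outside the head sphere: {np.flatnonzero(~inside).tolist()}")
    gain = _gain_for_moments(source_space.positions, source_space.orientations, sensors, c)
    return LeadField(gain, sensors, source_space, head_radius, c)


def build_free_gain(
    positions_mm: np.ndarray,
    sensors: SensorArray,
    head_radius: float = 85.0,
    center: np.ndarray | None = None,
) -> np.ndarray:
    """Free-orientation gain (n_channels, n_positions, 3) for unit moments along x, y, z."""
    c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    positions_mm = np.atleast_2d(positions_mm)
    if (np.linalg.norm(positions_mm - c, axis=1) >= head_radius).any():
        raise ValueError("candidate dipole positions must lie inside the head sphere")
    n = len(positions_mm)
    out = np.empty((sensors.n_channels, n, 3))
    for k in range(3):
        m = np.zeros((n, 3))
        m[:, k] = 1.0
        out[:, :, k] = _gain_for_moments(positions_mm, m, sensors, c)
    return out


def project(leadfield: LeadField, activation: np.ndarray) -> np.ndarray:
    """Sensor-space data from a source x time activation matrix (nA*m)."""
    activation = np.asarray(activation)
    if activation.shape[0] != leadfield.n_sources:
        raise ValueError(
            f"activation has {activation.shape[0]} sources, lead field expects {leadfield.n_sources}"
        )
    return leadfield.gain @ activation
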