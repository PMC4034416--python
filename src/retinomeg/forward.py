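"""Forward model: current dipole in a homogeneous conducting sphere.

Magnetometer channels measure the field component along their orientation
(radial for the default array); planar gradiometers measure a two-point
finite difference of that component along their tangential axis, divided
by the baseline.  The magnetic field of a current dipole inside a
spherically symmetric conductor has the closed Sarvas form

    B(r) = mu0 / (4 pi F^2) * (F (Q x r0) - ((Q x r0) . r) grad F)

with r0 the dipole position, Q its moment, a = r - r0,
F = a (r a + r^2 - r0 . r) and grad F the standard gradient.  The field of
a purely radial dipole vanishes identically (the "radial silence" of the
spherical conductor), so all useful sources here are tangential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SensorArray, SourceSpace

MU0_OVER_4PI = 1e-7  # T m / A


class DegenerateSourceError(ValueError):
    """Dipole at the sphere center: field direction undefined."""


@dataclass(frozen=True)
class LeadField:
    """Gain matrix mapping unit dipole currents to sensor measurements.

    ``gain`` has shape (n_sensors, n_sources) in fixed-orientation mode
    (dipoles along vertex normals) or (n_sensors, 3 * n_sources) in free
    mode (x, y, z triplets per source).  Units are T/(A m) for
    magnetometer rows and (T/m)/(A m) for gradiometer rows.
    """

    gain: np.ndarray
    orientation_mode: str  # "fixed" | "free"
    sensors: SensorArray
    space: SourceSpace

    @property
    def n_sources(self) -> int:
        k = 3 if self.orientation_mode == "free" else 1
        return self.gain.shape[1] // k


def dipole_field(
    sensor_positions: np.ndarray, dipole_position: np.ndarray, moment: np.ndarray
) -> np.ndarray:
    """Sarvas closed-form field (tesla) at points outside the conductor.

    Vectorized over sensor positions; the conductor sphere is centered at
    the origin of the head frame.
    """
    r = np.atleast_2d(sensor_positions).astype(float)
    r0 = np.asarray(dipole_position, dtype=float)
    q = np.asarray(moment, dtype=float)
    if np.linalg.norm(r0) < 1e-9:
        raise DegenerateSourceError("dipole at the sphere center")

    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    r0_dot_r = r @ r0
    f = a * (rn * a + rn**2 - r0_dot_r)
    # grad F = (a^2/r + a.r/a + 2a + 2r) r  -  (a + 2r + a.r/a) r0
    a_dot_r = np.einsum("ij,ij->i", a_vec, r)
    c1 = a**2 / rn + a_dot_r / a + 2.0 * a + 2.0 * rn
    c2 = a + 2.0 * rn + a_dot_r / a
    grad_f = c1[:, None] * r - c2[:, None] * r0[None, :]

    q_x_r0 = np.cross(q, r0)
    b = MU0_OVER_4PI / f[:, None] ** 2 * (
        f[:, None] * q_x_r0[None, :] - ((r @ q_x_r0))[:, None] * grad_f
    )
    return b


def _evaluation_points(sensors: SensorArray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Field-evaluation points and the linear map from point-field values
    (projected on sensor orientations) to channel outputs.

    Magnetometers contribute one point with weight 1; each gradiometer two
    points at +-baseline/2 along its tangential axis with weights
    +-1/baseline.
    """
    points, oris, rows, weights = [], [], [], []
    for i in range(sensors.n_sensors):
        p = sensors.positions[i]
        o = sensors.orientations[i]
        if sensors.kinds[i] == "magnetometer":
            points.append(p)
            oris.append(o)
            rows.append(i)
            weights.append(1.0)
        else:
            b = sensors.baselines[i]
            t = sensors.tangentials[i]
            for s in (+0.5, -0.5):
                points.append(p + s * b * t)
                oris.append(o)
                rows.append(i)
                weights.append(np.sign(s) / b)
    return (
        np.asarray(points),
        np.asarray(oris),
        (np.asarray(rows), np.asarray(weights)),
    )


def compute_lead_field(
    space: SourceSpace,
    sensors: SensorArray,
    sphere_radius: float | None = None,
    orientation_mode: str = "fixed",
) -> LeadField:
    """Lead-field matrix for every source under the spherical conductor."""
    if orientation_mode not in ("fixed", "free"):
        raise ValueError("orientation_mode must be 'fixed' or 'free'")
    radius = sphere_radius if sphere_radius is not None else space.sphere_radius
    pos = space.positions
    if np.any(np.linalg.norm(pos, axis=1) >= radius):
        raise ValueError("all sources must lie strictly inside the sphere")
    if np.any(np.linalg.norm(sensors.positions, axis=1) <= radius):
        raise ValueError("all sensors must lie strictly outside the sphere")

    points, oris, (rows, weights) = _evaluation_points(sensors)
    n_src = space.n_vertices
    n_comp = 1 if orientation_mode == "fixed" else 3
    gain = np.zeros((sensors.n_sensors, n_comp * n_src))
    eye = np.eye(3)
    for j in range(n_src):
        if orientation_mode == "fixed":
            moments = [space.normals[j]]
        else:
            moments = list(eye)
        for k, q in enumerate(moments):
            b = dipole_field(points, pos[j], q)
            proj = np.einsum("ij,ij->i", b, oris)
            np.add.at(gain[:, n_comp * j + k], rows, weights * proj)
    if not np.all(np.isfinite(gain)):
        raise FloatingPointError("non-finite lead-field entries")
    return LeadField(gain=gain, orientation_mode=orientation_mode,
                     sensors=sensors, space=space)
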