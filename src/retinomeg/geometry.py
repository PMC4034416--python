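"""Synthetic occipital source space and MEG sensor array.

Coordinate frame (used throughout the package): right-handed, head-centered,
+x right, +y anterior, +z superior, all positions in meters.

The source space is a pair of mirror-symmetric occipital cortical sheets,
one per hemisphere, each folded into a dorsal and a ventral bank with
opposed surface normals — the synthetic stand-in for the banks of the
calcarine sulcus.  The posterior→anterior sheet axis carries the
eccentricity representation (fovea at the occipital pole, periphery
anterior).  A small dorsal-anterior patch per hemisphere stands in for
V3A, and an optional shell of unlabeled "background" vertices represents
non-visual cortex.

The sensor array is a Neuromag-like mixture of magnetometers (radial field
component) and paired planar gradiometers (radial field differenced along
two orthogonal tangential axes), positioned on a helmet surface outside
the conductor sphere, with extra density over the occiput.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAGNETOMETER = "magnetometer"
GRADIOMETER = "planar_gradiometer"

DEFAULT_SPHERE_RADIUS = 0.09  # m, single homogeneous conductor sphere
DEFAULT_GRAD_BASELINE = 0.0168  # m, Neuromag-like planar gradiometer baseline

#: default geometry of the synthetic cortical sheets (meters)
DEFAULT_GEOMETRY = {
    "sphere_radius": DEFAULT_SPHERE_RADIUS,
    "x_medial": 0.004,       # gap between hemisphere sheets and the midline
    "y_posterior": -0.070,   # occipital pole (fovea) position
    "z_bank": 0.008,         # half-separation of dorsal/ventral banks
    "z_v3a": 0.020,          # height of the V3A patch
    "columns_per_area": 1,   # mediolateral columns per visual area strip
    "n_v3a": None,           # vertices per hemisphere for V3A (None -> n//9)
    "n_background": 0,       # unlabeled vertices per hemisphere
    "background_radius": 0.072,
}


class GeometryError(ValueError):
    """Invalid source-space or sensor-array construction parameters."""


@dataclass(frozen=True)
class SourceSpace:
    """Discrete dipole grid on the synthetic cortical sheets.

    ``df`` columns: vertex_id, hemi (L/R), x, y, z, nx, ny, nz,
    sheet (main/v3a/background), bank (dorsal/ventral/na), u, w.
    ``u`` is the normalized posterior→anterior coordinate on the main sheet
    (eccentricity axis), ``w`` the normalized mediolateral coordinate.
    """

    df: pd.DataFrame
    spacing: float  # m, grid step between neighbouring vertices
    sphere_radius: float

    @property
    def n_vertices(self) -> int:
        return len(self.df)

    @property
    def positions(self) -> np.ndarray:
        return self.df[["x", "y", "z"]].to_numpy()

    @property
    def normals(self) -> np.ndarray:
        return self.df[["nx", "ny", "nz"]].to_numpy()

    @property
    def hemispheres(self) -> np.ndarray:
        return self.df["hemi"].to_numpy()

    def mirror_index(self) -> np.ndarray:
        """For each vertex, the index of the vertex in the other hemisphere
        nearest to its midsagittal mirror image (exact partner for the
        mirror-symmetric sheets)."""
        pos = self.positions
        hemi = self.hemispheres
        mirrored = pos * np.array([-1.0, 1.0, 1.0])
        out = np.empty(self.n_vertices, dtype=int)
        for h, other in (("L", "R"), ("R", "L")):
            src = np.flatnonzero(hemi == h)
            tgt = np.flatnonzero(hemi == other)
            d = np.linalg.norm(
                mirrored[src][:, None, :] - pos[tgt][None, :, :], axis=2
            )
            out[src] = tgt[np.argmin(d, axis=1)]
        return out


@dataclass(frozen=True)
class SensorArray:
    """MEG sensor geometry shared by the forward model and all solvers.

    Positions/orientations are stored per channel; each planar gradiometer
    additionally carries the tangential unit vector along which the radial
    field component is differenced (``tangential``), derived
    deterministically from the orientation and the channel id suffix.
    """

    ids: np.ndarray          # str channel labels
    positions: np.ndarray    # (n, 3) m
    orientations: np.ndarray  # (n, 3) unit vectors, sensing direction
    kinds: np.ndarray        # MAGNETOMETER or GRADIOMETER per channel
    baselines: np.ndarray    # m; nan for magnetometers
    tangentials: np.ndarray  # (n, 3); nan rows for magnetometers

    def __post_init__(self):
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise GeometryError("sensor orientations must be unit vectors")

    @property
    def n_sensors(self) -> int:
        return len(self.ids)

    @property
    def is_mag(self) -> np.ndarray:
        return self.kinds == MAGNETOMETER

    @property
    def is_grad(self) -> np.ndarray:
        return self.kinds == GRADIOMETER


def _tangent_pair(orientation: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthogonal tangential directions for a sensor orientation,
    chosen deterministically (Gram–Schmidt against a fixed reference)."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(orientation @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    t1 = np.cross(orientation, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(orientation, t1)
    t2 /= np.linalg.norm(t2)
    return t1, t2


def _fibonacci_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    golden = np.pi * (1.0 + np.sqrt(5.0))
    theta = golden * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def build_sensor_array(
    n_magnetometers: int = 60,
    n_gradiometer_pairs: int = 60,
    helmet_radius: float = 0.102,
    occipital_fraction: float = 0.4,
    gradiometer_baseline: float = DEFAULT_GRAD_BASELINE,
    sphere_radius: float = DEFAULT_SPHERE_RADIUS,
) -> SensorArray:
    """Neuromag-like synthetic helmet.

    ``occipital_fraction`` of the magnetometer sites are concentrated in two
    rings over the occiput; the rest give full-head coverage (upper
    hemisphere of the helmet).  Each site holds one magnetometer and one
    orthogonal planar-gradiometer pair while pair counts last.
    """
    if n_magnetometers < 1 or n_gradiometer_pairs < 0:
        raise GeometryError("need at least one magnetometer")
    if helmet_radius <= sphere_radius:
        raise GeometryError("helmet must lie outside the conductor sphere")

    n_occ = int(round(occipital_fraction * n_magnetometers))
    n_head = n_magnetometers - n_occ

    # full-head coverage: upper-hemisphere quasi-uniform sites
    pts = _fibonacci_points(max(2 * n_head, 8))
    pts = pts[pts[:, 2] > -0.15][:n_head]
    sites = [p for p in pts]

    # two occipital rings (posterior, straddling the horizontal plane)
    ring_sizes = [n_occ - n_occ // 2, n_occ // 2]
    for ring, (elev,) in zip(ring_sizes, [(-0.15,), (0.25,)]):
        az = np.linspace(-0.45 * np.pi, 0.45 * np.pi, ring, endpoint=True)
        for a in az:
            # posterior direction is -y
            d = np.array(
                [np.sin(a) * np.cos(elev), -np.cos(a) * np.cos(elev), np.sin(elev)]
            )
            sites.append(d)
    sites = np.asarray(sites)[:n_magnetometers]
    positions = helmet_radius * sites
    orientations = sites  # radial, outward

    ids, pos, ori, kinds, bases, tangs = [], [], [], [], [], []
    for k in range(len(sites)):
        ids.append(f"MAG{k:04d}")
        pos.append(positions[k])
        ori.append(orientations[k])
        kinds.append(MAGNETOMETER)
        bases.append(np.nan)
        tangs.append(np.full(3, np.nan))
    for k in range(min(n_gradiometer_pairs, len(sites))):
        t1, t2 = _tangent_pair(orientations[k])
        for suffix, t in (("a", t1), ("b", t2)):
            ids.append(f"GRAD{k:04d}{suffix}")
            pos.append(positions[k])
            ori.append(orientations[k])
            kinds.append(GRADIOMETER)
            bases.append(gradiometer_baseline)
            tangs.append(t)

    arr = SensorArray(
        ids=np.array(ids),
        positions=np.array(pos),
        orientations=np.array(ori),
        kinds=np.array(kinds),
        baselines=np.array(bases),
        tangentials=np.array(tangs),
    )
    if np.any(np.linalg.norm(arr.positions, axis=1) <= sphere_radius):
        raise GeometryError("all sensors must lie strictly outside the sphere")
    return arr


def _sheet_grid(n: int, n_cols: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Row-major fill of an n_rows x n_cols grid with n vertices.

    Returns (row, col) index arrays and n_rows.  Filling is row-major so
    columns (area strips) stay balanced to within one vertex.
    """
    n_rows = int(np.ceil(n / n_cols))
    idx = np.arange(n)
    return idx // n_cols, idx % n_cols, n_rows


def build_source_space(
    n_vertices_per_hemisphere: int,
    spacing: float = 0.004,
    geometry_params: dict | None = None,
) -> SourceSpace:
    """Build the two mirror-symmetric occipital sheets.

    Each hemisphere receives ``n_vertices_per_hemisphere`` vertices split
    between a dorsal and a ventral bank (opposed normals), a V3A patch and
    optional background vertices (background vertices are *in addition to*
    the requested count).  Deterministic given the parameters.
    """
    n = n_vertices_per_hemisphere
    if n < 8:
        raise GeometryError("need at least 8 vertices per hemisphere")
    if spacing <= 0:
        raise GeometryError("spacing must be positive")
    params = dict(DEFAULT_GEOMETRY)
    if geometry_params:
        params.update(geometry_params)
    radius = params["sphere_radius"]

    n_v3a = params["n_v3a"]
    if n_v3a is None:
        n_v3a = max(1, n // 9)
    n_main = n - n_v3a
    n_dorsal = (n_main + 1) // 2
    n_ventral = n_main - n_dorsal
    if min(n_dorsal, n_ventral) < 3:
        raise GeometryError("too few vertices to populate both banks")

    n_cols = 3 * int(params["columns_per_area"])
    rows = []

    def add_bank(sign: float, bank: str, n_bank: int, z: float, nz: float):
        row, col, n_rows = _sheet_grid(n_bank, n_cols)
        u = (row + 0.5) / n_rows
        w = (col + 0.5) / n_cols
        x = sign * (params["x_medial"] + col * spacing)
        y = params["y_posterior"] + row * spacing
        for i in range(n_bank):
            rows.append(
                dict(hemi="L" if sign < 0 else "R", x=x[i], y=y[i], z=z,
                     nx=0.0, ny=0.0, nz=nz, sheet="main", bank=bank,
                     u=u[i], w=w[i])
            )
        return n_rows

    def add_v3a(sign: float, y_start: float):
        row, col, _ = _sheet_grid(n_v3a, 2)
        for i in range(n_v3a):
            rows.append(
                dict(hemi="L" if sign < 0 else "R",
                     x=sign * (params["x_medial"] + col[i] * spacing),
                     y=y_start + (row[i] + 1) * spacing,
                     z=params["z_v3a"],
                     nx=0.0, ny=0.0, nz=-1.0, sheet="v3a", bank="na",
                     u=np.nan, w=np.nan)
            )

    def add_background(sign: float):
        n_bg = int(params["n_background"])
        if n_bg == 0:
            return
        pts = _fibonacci_points(4 * n_bg) * params["background_radius"]
        keep = (np.sign(pts[:, 0]) == sign) & (pts[:, 1] > -0.03)
        keep &= np.abs(pts[:, 0]) > 0.01  # stay off the z-axis
        pts = pts[keep][:n_bg]
        if len(pts) < n_bg:
            raise GeometryError("could not place requested background vertices")
        for p in pts:
            t = np.cross(p, [0.0, 0.0, 1.0])
            t /= np.linalg.norm(t)  # tangential (azimuthal) dipole orientation
            rows.append(
                dict(hemi="L" if sign < 0 else "R", x=p[0], y=p[1], z=p[2],
                     nx=t[0], ny=t[1], nz=t[2], sheet="background",
                     bank="na", u=np.nan, w=np.nan)
            )

    for sign in (-1.0, 1.0):
        n_rows_d = add_bank(sign, "dorsal", n_dorsal, params["z_bank"], -1.0)
        add_bank(sign, "ventral", n_ventral, -params["z_bank"], 1.0)
        y_anterior = params["y_posterior"] + n_rows_d * spacing
        add_v3a(sign, y_anterior)
        add_background(sign)

    df = pd.DataFrame(rows)
    df.insert(0, "vertex_id", np.arange(len(df)))
    pos = df[["x", "y", "z"]].to_numpy()
    if np.any(np.linalg.norm(pos, axis=1) >= radius):
        raise GeometryError(
            "cortical sheet extends outside the conductor sphere; "
            "reduce n_vertices_per_hemisphere or spacing"
        )
    return SourceSpace(df=df, spacing=spacing, sphere_radius=radius)
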