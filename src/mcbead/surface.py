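"""Spherical surface resampling: particle mesh, narrow band, Mollweide maps.

The fitted sphere is discretised with a latitude--longitude particle mesh
(default 3 degrees in both the polar and azimuthal direction, i.e.
60 x 120 = 7200 particles at cell centres).  Particles are replicated
radially into a narrow band of shells spaced one voxel apart, volume
intensities are interpolated to the band particles with a
moment-conserving cubic kernel, and the band is maximum-projected
radially to give one intensity per surface particle and channel.

Conventions
-----------
theta : polar angle from the +z axis, in (0, pi); cell centres at
    ``(i + 1/2) * dtheta``.
phi : azimuth in [0, 2 pi), periodic; cell centres at ``j * dphi``.
Cell areas use the exact formula ``R^2 * dphi * (cos th_lo - cos th_hi)``,
which telescopes to ``4 pi R^2`` over the full mesh.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .sphere import SphereModel
from .volume import VolumeImage

# ---------------------------------------------------------------------------
# surface grid


@dataclass
class SurfaceGrid:
    """Latitude--longitude particle mesh on a fitted sphere.

    ``theta`` / ``phi`` are flattened per-particle angles (radians), in
    row-major (theta, phi) order; ``areas`` are the exact per-cell areas
    in µm².
    """

    sphere: SphereModel
    resolution_deg: float
    theta: np.ndarray
    phi: np.ndarray
    areas: np.ndarray
    n_theta: int
    n_phi: int

    @property
    def n_particles(self) -> int:
        return self.theta.size

    def directions(self) -> np.ndarray:
        """Unit vectors (N, 3) in (z, y, x) order."""
        st, ct = np.sin(self.theta), np.cos(self.theta)
        return np.stack([ct, st * np.sin(self.phi), st * np.cos(self.phi)], axis=1)

    def positions(self, radial_offset_um: float = 0.0) -> np.ndarray:
        """Physical (z, y, x) positions (µm) at radius R + offset."""
        r = self.sphere.radius + radial_offset_um
        return self.sphere.center[None, :] + r * self.directions()

    def geodesic_distance_um(self, theta0: float, phi0: float) -> np.ndarray:
        """Geodesic distance (µm) from each particle to (theta0, phi0)."""
        return self.sphere.radius * central_angle(self.theta, self.phi, theta0, phi0)


def central_angle(theta1, phi1, theta2, phi2) -> np.ndarray:
    """Great-circle angle between points given in polar coordinates."""
    c = (np.cos(theta1) * np.cos(theta2)
         + np.sin(theta1) * np.sin(theta2) * np.cos(phi1 - phi2))
    return np.arccos(np.clip(c, -1.0, 1.0))


def build_surface_grid(sphere: SphereModel, resolution_deg: float = 3.0) -> SurfaceGrid:
    """Build the cell-centred lat--lon mesh at the given angular resolution.

    ``resolution_deg`` must divide both 180 and 360.
    """
    if resolution_deg <= 0 or 180 % resolution_deg or 360 % resolution_deg:
        raise ValueError(f"resolution {resolution_deg} deg must divide 180 and 360")
    n_t = int(round(180 / resolution_deg))
    n_p = int(round(360 / resolution_deg))
    d = np.deg2rad(resolution_deg)
    theta_c = (np.arange(n_t) + 0.5) * d
    phi_c = np.arange(n_p) * d
    # exact band areas: R^2 * dphi * (cos th_lo - cos th_hi)
    edges = np.arange(n_t + 1) * d
    row_area = sphere.radius**2 * d * (np.cos(edges[:-1]) - np.cos(edges[1:]))
    theta = np.repeat(theta_c, n_p)
    phi = np.tile(phi_c, n_t)
    areas = np.repeat(row_area, n_p)
    return SurfaceGrid(sphere=sphere, resolution_deg=float(resolution_deg),
                       theta=theta, phi=phi, areas=areas, n_theta=n_t, n_phi=n_p)


# ---------------------------------------------------------------------------
# narrow band


@dataclass
class NarrowBand:
    """Radial replication shells around the surface grid.

    ``positions`` has shape ``(n_shells, N, 3)`` (µm); ``intensities`` maps
    channel role -> ``(n_shells, N)`` once populated.
    """

    grid: SurfaceGrid
    offsets_um: np.ndarray
    positions: np.ndarray
    intensities: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_shells(self) -> int:
        return self.offsets_um.size


def build_narrow_band(
    grid: SurfaceGrid,
    voxel_size: tuple[float, float, float],
    half_width_voxels: int = 5,
) -> NarrowBand:
    """Replicate particles radially at 1-voxel spacing, +-``half_width_voxels``.

    The band is symmetric about the fitted radius so the radial maximum
    projection captures shell signal on either side of the fit.  With
    anisotropic voxels the radial step is the smallest voxel edge.
    """
    step = float(min(voxel_size))
    offsets = np.arange(-half_width_voxels, half_width_voxels + 1) * step
    dirs = grid.directions()
    radii = grid.sphere.radius + offsets
    pos = grid.sphere.center[None, None, :] + radii[:, None, None] * dirs[None, :, :]
    return NarrowBand(grid=grid, offsets_um=offsets, positions=pos)


# ---------------------------------------------------------------------------
# moment-conserving kernels

def m4prime(s: np.ndarray) -> np.ndarray:
    """The M4' cubic particle-mesh kernel (support |s| < 2).

    Piecewise cubic with partition of unity and exact first- and
    second-moment conservation on a unit grid; reproduces constant and
    linear fields exactly.
    """
    s = np.abs(s)
    out = np.zeros_like(s)
    inner = s < 1
    outer = (s >= 1) & (s < 2)
    out[inner] = 1 - 2.5 * s[inner]**2 + 1.5 * s[inner]**3
    out[outer] = 0.5 * (2 - s[outer])**2 * (1 - s[outer])
    return out


def bspline3(s: np.ndarray) -> np.ndarray:
    """Cubic B-spline kernel (support |s| < 2, non-negative).

    Used for the normalised particle-to-voxel scatter, where the negative
    lobes of M4' would destabilise the Shepard normalisation on a particle
    set sparser than the voxel grid.
    """
    s = np.abs(s)
    out = np.zeros_like(s)
    inner = s < 1
    outer = (s >= 1) & (s < 2)
    out[inner] = (4 - 6 * s[inner]**2 + 3 * s[inner]**3) / 6
    out[outer] = (2 - s[outer])**3 / 6
    return out


def _axis_weights(x: np.ndarray, n: int, kernel) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis node indices (N, 4) and kernel weights for positions ``x``
    in voxel units; indices are clamped to [0, n-1]."""
    base = np.floor(x).astype(np.int64)
    nodes = base[:, None] + np.arange(-1, 3)[None, :]
    w = kernel(x[:, None] - nodes)
    return np.clip(nodes, 0, n - 1), w


def interpolate_to_particles(
    volume: np.ndarray,
    band: NarrowBand,
    voxel_size: tuple[float, float, float],
    channel: str = "value",
    kernel=m4prime,
    clamp: bool = True,
) -> np.ndarray:
    """Interpolate a 3D volume to the band particles (moment-conserving).

    The kernel is a separable tensor-product cubic evaluated in voxel
    units per axis (anisotropy-aware).  Positions outside the volume are
    clamped to the boundary with a warning when ``clamp`` is true, else an
    error is raised.  Returns ``(n_shells, N)`` and stores it under
    ``band.intensities[channel]``.
    """
    vol = np.asarray(volume)
    shape = np.array(vol.shape)
    pos = band.positions.reshape(-1, 3) / np.asarray(voxel_size, dtype=float)
    out_of_bounds = np.any((pos < 0) | (pos > shape - 1), axis=1)
    if out_of_bounds.all():
        raise ValueError("narrow band lies entirely outside the volume")
    if out_of_bounds.any():
        if not clamp:
            raise ValueError(f"{out_of_bounds.sum()} band positions outside the volume")
        warnings.warn(
            f"{out_of_bounds.sum()} band positions outside the volume were clamped",
            stacklevel=2,
        )
    idx = []
    wts = []
    for ax in range(3):
        i, w = _axis_weights(pos[:, ax], vol.shape[ax], kernel)
        idx.append(i)
        wts.append(w)
    vals = np.zeros(pos.shape[0])
    for a in range(4):
        for b in range(4):
            wab = wts[0][:, a] * wts[1][:, b]
            for c in range(4):
                vals += wab * wts[2][:, c] * vol[idx[0][:, a], idx[1][:, b], idx[2][:, c]]
    vals = vals.reshape(band.n_shells, band.grid.n_particles)
    band.intensities[channel] = vals
    return vals


# ---------------------------------------------------------------------------
# radial projection and scatter


@dataclass
class SurfaceField:
    """One scalar per surface particle (post radial projection)."""

    grid: SurfaceGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.grid.n_particles:
            raise ValueError("field size does not match grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite field values")

    def as_raster(self) -> np.ndarray:
        """(n_theta, n_phi) view of the field."""
        return self.values.reshape(self.grid.n_theta, self.grid.n_phi)


def radial_max_project(band: NarrowBand, channel: str = "value") -> SurfaceField:
    """Maximum over the radial shells, per surface particle."""
    if channel not in band.intensities:
        raise ValueError(f"band has no interpolated channel {channel!r}")
    return SurfaceField(grid=band.grid, values=band.intensities[channel].max(axis=0))


def scatter_to_pixels(
    positions_um: np.ndarray,
    values: np.ndarray,
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    kernel=bspline3,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised scatter of particle values back onto the voxel grid.

    Each voxel receives ``sum_p w_p v_p / sum_p w_p`` with separable cubic
    B-spline weights; voxels with zero total weight are set to 0 and
    flagged in the returned boolean mask (True = uncovered).
    Returns ``(volume, uncovered_mask)``.
    """
    positions_um = np.asarray(positions_um, dtype=float).reshape(-1, 3)
    values = np.asarray(values, dtype=float).ravel()
    num = np.zeros(shape)
    den = np.zeros(shape)
    if positions_um.size:
        pos = positions_um / np.asarray(voxel_size, dtype=float)
        idx = []
        wts = []
        for ax in range(3):
            base = np.floor(pos[:, ax]).astype(np.int64)
            nodes = base[:, None] + np.arange(-1, 3)[None, :]
            w = kernel(pos[:, ax][:, None] - nodes)
            w[(nodes < 0) | (nodes >= shape[ax])] = 0.0  # drop out-of-bounds
            idx.append(np.clip(nodes, 0, shape[ax] - 1))
            wts.append(w)
        for a in range(4):
            for b in range(4):
                for c in range(4):
                    w = wts[0][:, a] * wts[1][:, b] * wts[2][:, c]
                    flat = np.ravel_multi_index(
                        (idx[0][:, a], idx[1][:, b], idx[2][:, c]), shape)
                    np.add.at(num.ravel(), flat, w * values)
                    np.add.at(den.ravel(), flat, w)
    covered = den > 1e-12
    out = np.zeros(shape)
    out[covered] = num[covered] / den[covered]
    return out, ~covered


def scatter_band_to_volume(
    band: NarrowBand, channel: str, shape, voxel_size
) -> tuple[np.ndarray, np.ndarray]:
    """Scatter a populated band channel back to a clean voxel image."""
    vals = band.intensities[channel]
    return scatter_to_pixels(band.positions.reshape(-1, 3), vals.ravel(), shape, voxel_size)


# ---------------------------------------------------------------------------
# Mollweide projection

_SQRT2 = np.sqrt(2.0)


def mollweide_auxiliary(lat: np.ndarray, tol: float = 1e-7, max_iter: int = 50) -> np.ndarray:
    """Solve ``2 t + sin 2t = pi sin(lat)`` for the auxiliary angle t by Newton."""
    lat = np.asarray(lat, dtype=float)
    t = np.array(lat, copy=True)
    target = np.pi * np.sin(lat)
    # poles: derivative vanishes; closed form t = lat there
    interior = np.abs(np.abs(lat) - np.pi / 2) > 1e-12
    for _ in range(max_iter):
        f = 2 * t + np.sin(2 * t) - target
        df = 2 + 2 * np.cos(2 * t)
        step = np.where(interior & (np.abs(df) > 1e-15), f / np.maximum(df, 1e-15), 0.0)
        t = t - step
        if np.all(np.abs(step) < tol):
            break
    else:
        raise RuntimeError("Mollweide Newton iteration did not converge")
    return t


def mollweide_forward(lat: np.ndarray, lon: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward Mollweide map: (lat, lon) in radians -> (x, y).

    ``x`` in [-2 sqrt 2, 2 sqrt 2], ``y`` in [-sqrt 2, sqrt 2].
    """
    t = mollweide_auxiliary(lat)
    x = 2 * _SQRT2 / np.pi * np.asarray(lon) * np.cos(t)
    y = _SQRT2 * np.sin(t)
    return x, y


@dataclass
class MapImage:
    """Rendered Mollweide map with its lat/lon -> pixel transform."""

    data: np.ndarray        # (H, W), NaN outside the ellipse
    inside: np.ndarray      # (H, W) bool
    shape: tuple[int, int]

    def transform(self) -> dict:
        h, w = self.shape
        return {
            "projection": "mollweide",
            "x_range": [-2 * _SQRT2, 2 * _SQRT2],
            "y_range": [-_SQRT2, _SQRT2],
            "px_per_x": w / (4 * _SQRT2),
            "px_per_y": h / (2 * _SQRT2),
            "note": "pixel centre (r, c) -> x = (c+0.5)/W*4*sqrt2 - 2*sqrt2, "
                    "y = sqrt2 - (r+0.5)/H*2*sqrt2",
        }


def mollweide_project(field: SurfaceField, map_shape: tuple[int, int] = (360, 720)) -> MapImage:
    """Render a surface field as an equal-area Mollweide map.

    Pixels outside the projection ellipse are NaN; pixels inside are
    filled from the nearest lat--lon grid cell (exact inverse mapping,
    then nearest-cell lookup, which is the nearest particle on a regular
    mesh).  Longitude 0 (map centre) corresponds to azimuth phi = 0.
    """
    h, w = map_shape
    yy = _SQRT2 - (np.arange(h) + 0.5) / h * 2 * _SQRT2
    xx = (np.arange(w) + 0.5) / w * 4 * _SQRT2 - 2 * _SQRT2
    x, y = np.meshgrid(xx, yy)
    inside = (x / (2 * _SQRT2)) ** 2 + (y / _SQRT2) ** 2 <= 1.0
    t = np.arcsin(np.clip(y / _SQRT2, -1, 1))
    lat = np.arcsin(np.clip((2 * t + np.sin(2 * t)) / np.pi, -1, 1))
    cos_t = np.cos(t)
    lon = np.where(cos_t > 1e-9, np.pi * x / (2 * _SQRT2 * np.maximum(cos_t, 1e-9)), 0.0)
    inside &= np.abs(lon) <= np.pi + 1e-9

    grid = field.grid
    theta = np.pi / 2 - lat                      # polar angle
    phi = np.mod(lon, 2 * np.pi)                 # azimuth in [0, 2pi)
    d = np.deg2rad(grid.resolution_deg)
    ti = np.clip(np.floor(theta / d).astype(int), 0, grid.n_theta - 1)
    pj = np.mod(np.round(phi / d).astype(int), grid.n_phi)  # phi cells centred at j*d
    raster = field.as_raster()
    data = np.full(map_shape, np.nan)
    data[inside] = raster[ti[inside], pj[inside]]
    return MapImage(data=data, inside=inside, shape=(h, w))


def save_map_png(path, map_image: MapImage, cmap: str = "viridis") -> None:
    """Write a Mollweide map as PNG with a JSON sidecar for the transform."""
    import json

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = map_image.data
    finite = np.isfinite(data)
    vmin = float(np.nanmin(data)) if finite.any() else 0.0
    vmax = float(np.nanmax(data)) if finite.any() else 1.0
    plt.imsave(path, np.nan_to_num(data, nan=vmin), vmin=vmin,
               vmax=vmax if vmax > vmin else vmin + 1, cmap=cmap)
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(map_image.transform(), fh, indent=2)
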