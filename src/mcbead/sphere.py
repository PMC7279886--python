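"""Bead surface extraction and algebraic sphere fitting.

The membrane dye channel traces a thin spherical shell around each bead.
The brightest fraction of voxels (default: the upper 0.5 % intensity
percentile) hugs that shell, and the bead geometry is recovered by a
linear least-squares sphere fit to those points.

The fit solves the linearised (algebraic) sphere equation

    |p|^2 = 2 c . p + d,        R = sqrt(d + |c|^2)

which is linear in ``(c, d)`` (Coope's method).  The RMS of the signed
normal residuals ``|p - c| - R`` is reported as a post-fit diagnostic; an
optional geometric (Levenberg-Marquardt) refinement of exactly that cost
is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import least_squares


@dataclass
class SurfacePointSet:
    """Candidate membrane-surface points in physical (z, y, x) µm."""

    points: np.ndarray  # (N, 3) µm
    percentile: float

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3:
            raise ValueError("points must be (N, 3)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite surface points")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class SphereModel:
    """Fitted bead: centre (z, y, x) in µm, radius in µm."""

    center: np.ndarray
    radius: float
    rms_residual: float = 0.0
    n_points: int = 0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.radius = float(self.radius)
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["center"] = [float(v) for v in self.center]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SphereModel":
        return cls(**d)


def extract_surface_voxels(
    image: np.ndarray,
    voxel_size: tuple[float, float, float],
    percentile: float = 0.005,
) -> SurfacePointSet:
    """Select the brightest ``percentile`` fraction of voxels as surface points.

    Returns all voxels with intensity >= the ``1 - percentile`` quantile
    (ties at the threshold are all included), with voxel indices converted
    to physical µm coordinates.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if not 0 < percentile < 1:
        raise ValueError(f"percentile must be in (0, 1), got {percentile}")
    lo, hi = float(image.min()), float(image.max())
    if lo == hi:
        raise ValueError("constant image: intensity quantile is degenerate")
    thr = np.quantile(image, 1.0 - percentile)
    idx = np.argwhere(image >= thr)
    pts = idx * np.asarray(voxel_size, dtype=float)
    return SurfacePointSet(points=pts, percentile=float(percentile))


def fit_sphere(points: SurfacePointSet, refine: bool = False) -> SphereModel:
    """Fit centre and radius to surface points by algebraic least squares.

    Raises ``ValueError`` for fewer than 4 points or a rank-deficient
    (coplanar / collinear) configuration.  With ``refine=True`` the
    algebraic solution seeds a geometric least-squares refinement of the
    normal residuals.
    """
    p = points.points
    if len(points) < 4:
        raise ValueError(f"need >= 4 points to fit a sphere, got {len(points)}")
    # |p|^2 = 2 c.p + d  ->  A @ [c, d] = b
    a = np.hstack([2.0 * p, np.ones((len(points), 1))])
    b = np.einsum("ij,ij->i", p, p)
    sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < 4:
        raise ValueError("degenerate point configuration (coplanar or collinear)")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("algebraic fit produced non-positive radius")
    radius = float(np.sqrt(r2))

    if refine:
        def normal_residuals(x):
            return np.linalg.norm(p - x[:3], axis=1) - x[3]

        res = least_squares(normal_residuals, np.append(center, radius), method="lm")
        center, radius = res.x[:3], float(res.x[3])

    resid = np.linalg.norm(p - center, axis=1) - radius
    rms = float(np.sqrt(np.mean(resid**2)))
    return SphereModel(center=center, radius=radius, rms_residual=rms, n_points=len(points))
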