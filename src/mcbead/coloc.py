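"""Colocalization, equatorial ring profiles, domain tracking and FRAP.

The per-particle colocalization index is the normalized mean deviation
product

    nMDP_i = (A_i - Abar)(B_i - Bbar) / ((A_max - Abar)(B_max - Bbar))

where A and B are the two fluorescence channels of the same bead, the
bars denote per-bead means and the maxima per-bead maxima; nMDP is 1 at
a joint maximum of both channels and 0 wherever either channel sits at
its mean, and it is invariant to affine rescaling of either channel.

Equatorial quantification mirrors the manual analysis: a 10-pixel-wide
ring around the fitted radius in the equatorial slice, with the protein
channels normalised pixelwise to the membrane dye to factor out membrane
amount.  Time-lapse domains are linked frame-to-frame by greedy
nearest-geodesic-centroid matching under a distance cap, and FRAP
recovery is reported as post-bleach intensity normalised to the
pre-bleach level, together with the fraction of post-bleach domains
recovering at pre-bleach locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .quantify import DomainRecord
from .sphere import SphereModel
from .surface import SurfaceField, central_angle
from .volume import VolumeImage


@dataclass
class ColocalizationField:
    """Per-particle nMDP values plus the per-bead channel statistics."""

    nmdp: np.ndarray
    a_mean: float
    b_mean: float
    a_max: float
    b_max: float
    grid: object = None


def nmdp_map(field_a: SurfaceField, field_b: SurfaceField) -> ColocalizationField:
    """Compute the normalized mean deviation product per particle."""
    if field_a.grid.n_particles != field_b.grid.n_particles:
        raise ValueError("fields are on different grids")
    a, b = field_a.values, field_b.values
    abar, bbar = float(a.mean()), float(b.mean())
    amax, bmax = float(a.max()), float(b.max())
    if amax <= abar or bmax <= bbar:
        raise ValueError("constant channel: nMDP denominator is zero")
    nmdp = (a - abar) * (b - bbar) / ((amax - abar) * (bmax - bbar))
    return ColocalizationField(nmdp=nmdp, a_mean=abar, b_mean=bbar,
                               a_max=amax, b_max=bmax, grid=field_a.grid)


# ---------------------------------------------------------------------------
# equatorial ring profiles


@dataclass
class EquatorialProfile:
    """Ring samples at the bead equator (one row per angular bin)."""

    table: pd.DataFrame  # angle_rad, protein, membrane, ratio (per channel)
    slice_index: int
    width_px: float


def equatorial_profile(
    volume: VolumeImage,
    sphere: SphereModel,
    protein_channel: str = "protein_a",
    width_px: float = 10.0,
    n_bins: int = 360,
) -> EquatorialProfile:
    """Extract a ring profile in the equatorial slice.

    Samples an annulus of radial width ``width_px`` pixels centred on the
    fitted radius in the z-slice through the bead centre.  Per angular bin
    it reports the mean raw protein and membrane-dye intensity and the
    mean pixelwise protein/membrane ratio (over pixels with positive
    membrane signal).
    """
    dz, dy, dx = volume.voxel_size
    zi = int(round(sphere.center[0] / dz))
    if not 0 <= zi < volume.shape_zyx[0]:
        raise ValueError("equatorial slice lies outside the stack")
    prot = volume.channel(protein_channel)[zi].astype(float)
    memb = volume.channel("membrane")[zi].astype(float)
    ny, nx = prot.shape
    y = np.arange(ny) * dy - sphere.center[1]
    x = np.arange(nx) * dx - sphere.center[2]
    yy, xx = np.meshgrid(y, x, indexing="ij")
    rho = np.hypot(yy, xx)
    half_w = width_px * min(dy, dx) / 2.0
    ring = np.abs(rho - sphere.radius) <= half_w
    if not ring.any():
        raise ValueError("equatorial ring does not intersect the stack")
    ang = np.mod(np.arctan2(yy, xx), 2 * np.pi)
    bins = np.floor(ang[ring] / (2 * np.pi) * n_bins).astype(int) % n_bins
    p, m = prot[ring], memb[ring]
    valid = m > 0
    rows = []
    for b in range(n_bins):
        sel = bins == b
        if not sel.any():
            continue
        sel_ratio = sel & valid
        rows.append({
            "angle_rad": (b + 0.5) * 2 * np.pi / n_bins,
            "protein": float(p[sel].mean()),
            "membrane": float(m[sel].mean()),
            "ratio": float((p[sel_ratio] / m[sel_ratio]).mean()) if sel_ratio.any()
                     else np.nan,
        })
    return EquatorialProfile(table=pd.DataFrame(rows), slice_index=zi,
                             width_px=float(width_px))


def compare_groups(
    values_in, values_out, welch: bool = False
) -> tuple[float, float]:
    """Unpaired two-sample t-test (pooled variance; Welch behind a flag)."""
    a = np.asarray(values_in, dtype=float)
    b = np.asarray(values_out, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            raise ValueError("degenerate: zero variance and equal means")
        return float("inf"), 0.0
    t, p = sstats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# tracking


@dataclass
class DomainTrajectory:
    """One linked domain across consecutive frames."""

    trajectory_id: int
    frames: list[int] = field(default_factory=list)
    records: list[DomainRecord] = field(default_factory=list)

    def append(self, frame: int, rec: DomainRecord) -> None:
        if self.frames and frame <= self.frames[-1]:
            raise ValueError("frames must be strictly increasing")
        self.frames.append(frame)
        self.records.append(rec)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([r.mean_intensity for r in self.records])

    def centroid(self, i: int = -1) -> tuple[float, float]:
        r = self.records[i]
        return r.centroid_theta, r.centroid_phi


def track_domains(
    frame_records: list[list[DomainRecord]],
    sphere: SphereModel,
    max_geodesic_um: float = 1.0,
) -> list[DomainTrajectory]:
    """Greedy nearest-centroid linking of domains across frames.

    Candidate (trajectory, domain) pairs within the geodesic cap are
    linked in order of increasing distance (ties broken by trajectory
    then domain id); unmatched domains start new trajectories and
    unmatched trajectories terminate (no gap closing).
    """
    if len(frame_records) < 2:
        raise ValueError("need at least 2 frames to track")
    trajectories: list[DomainTrajectory] = []
    active: list[DomainTrajectory] = []
    next_id = 0
    for t, recs in enumerate(frame_records):
        recs = sorted(recs, key=lambda r: r.domain_id)
        if t == 0:
            for r in recs:
                tr = DomainTrajectory(trajectory_id=next_id)
                tr.append(t, r)
                trajectories.append(tr)
                active.append(tr)
                next_id += 1
            continue
        pairs = []
        for ti, tr in enumerate(active):
            th, ph = tr.centroid()
            for ri, r in enumerate(recs):
                d = sphere.radius * central_angle(th, ph, r.centroid_theta,
                                                  r.centroid_phi)
                if d <= max_geodesic_um:
                    pairs.append((d, ti, ri))
        pairs.sort()
        used_t: set[int] = set()
        used_r: set[int] = set()
        survivors = []
        for d, ti, ri in pairs:
            if ti in used_t or ri in used_r:
                continue
            active[ti].append(t, recs[ri])
            survivors.append(active[ti])
            used_t.add(ti)
            used_r.add(ri)
        for ri, r in enumerate(recs):
            if ri not in used_r:
                tr = DomainTrajectory(trajectory_id=next_id)
                tr.append(t, r)
                trajectories.append(tr)
                survivors.append(tr)
                next_id += 1
        active = survivors
    return trajectories


def trajectories_dataframe(trajectories: list[DomainTrajectory]) -> pd.DataFrame:
    rows = []
    for tr in trajectories:
        for f, r in zip(tr.frames, tr.records):
            rows.append({"trajectory_id": tr.trajectory_id, "frame": f,
                         "centroid_theta": r.centroid_theta,
                         "centroid_phi": r.centroid_phi,
                         "area_um2": r.area_um2,
                         "mean_intensity": r.mean_intensity})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FRAP


@dataclass
class FrapResult:
    """Per-trajectory recovery curves and the same-location fraction."""

    curves: dict[int, pd.DataFrame]      # trajectory_id -> (frame, normalized)
    same_location_fraction: float
    plateaus: dict[int, float]


def frap_recovery(
    trajectories: list[DomainTrajectory],
    bleach_frame: int,
    sphere: SphereModel,
    max_geodesic_um: float = 1.0,
    plateau_frames: int = 3,
) -> FrapResult:
    """Quantify recovery after a whole-bead photobleach.

    Post-bleach intensity is normalised per trajectory to the mean
    pre-bleach intensity; the plateau is the mean of the last
    ``plateau_frames`` normalised points.  ``same_location_fraction`` is
    the fraction of post-bleach domains whose centroid lies within the
    geodesic cap of some pre-bleach domain centroid.
    """
    pre_centroids = []
    for tr in trajectories:
        for f, r in zip(tr.frames, tr.records):
            if f < bleach_frame:
                pre_centroids.append((r.centroid_theta, r.centroid_phi))
    if not pre_centroids:
        raise ValueError("no pre-bleach frames")
    curves: dict[int, pd.DataFrame] = {}
    plateaus: dict[int, float] = {}
    post_total = 0
    post_same = 0
    seen_post: set[int] = set()
    for tr in trajectories:
        frames = np.asarray(tr.frames)
        vals = tr.intensities
        pre = vals[frames < bleach_frame]
        post_mask = frames >= bleach_frame
        if post_mask.any():
            for i in np.where(post_mask)[0]:
                key = tr.trajectory_id
                if key in seen_post:
                    break
                th, ph = tr.records[i].centroid_theta, tr.records[i].centroid_phi
                post_total += 1
                seen_post.add(key)
                for pt, pp in pre_centroids:
                    if sphere.radius * central_angle(th, ph, pt, pp) <= max_geodesic_um:
                        post_same += 1
                        break
        if pre.size == 0 or not post_mask.any():
            continue
        ref = float(pre.mean())
        if ref <= 0:
            continue
        norm = vals[post_mask] / ref
        curves[tr.trajectory_id] = pd.DataFrame(
            {"frame": frames[post_mask], "normalized": norm})
        plateaus[tr.trajectory_id] = float(norm[-min(plateau_frames, norm.size):].mean())
    frac = post_same / post_total if post_total else float("nan")
    return FrapResult(curves=curves, same_location_fraction=frac, plateaus=plateaus)
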