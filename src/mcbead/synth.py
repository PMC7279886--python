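"""Synthetic membrane-coated-bead stacks with known ground truth.

Emulates the study system: a ~10 µm silica bead carrying a supported
lipid bilayer (membrane dye channel), a membrane-bound GTPase that
reorganises into bright spherical-cap domains (protein channel A), an
optionally co-enriched effector channel B, low-dye membrane
inhomogeneities (dark patches that must *not* be called domains), a
Gaussian radial shell profile standing in for the axial PSF, and mixed
Gaussian/Poisson noise.  Every stack ships with its exact geometric
ground truth so each downstream stage is testable without microscopy
data.

The membrane signal is modelled as a Gaussian of the radial distance
``|r - R|`` with width ``shell_sigma``; in-domain shell voxels carry
exactly ``baseline_out * enrichment`` before noise.  Domain centres are
drawn by rejection sampling uniform in area on the sphere, subject to a
pairwise geodesic ``min_separation``.  All randomness flows from
``rng_seed`` through named substreams (placement, noise, per-frame), so
identical parameters give bit-identical stacks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .sphere import SphereModel
from .volume import VolumeImage

_MAX_PLACEMENT_TRIES = 10_000


class SynthParams(BaseModel):
    """Parameters of one synthetic bead stack.

    Defaults match the study geometry: 0.1 µm isotropic voxels, a 160^3
    stack and a 5 µm bead radius (10 µm microspheres), domains of
    ~1.74 µm² with ~3x enrichment over the out-of-domain shell signal.
    """

    stack_shape: tuple[int, int, int] = (160, 160, 160)
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1)
    bead_center: tuple[float, float, float] | None = None  # µm; default = stack centre
    bead_radius: float = Field(default=5.0, gt=0)
    shell_sigma: float = Field(default=0.15, gt=0)
    n_domains: int = Field(default=5, ge=0)
    cap_area: float = Field(default=1.74, gt=0)      # µm² per domain
    enrichment: float = Field(default=3.0, ge=1.0)
    baseline_out: float = Field(default=100.0, gt=0)
    membrane_intensity: float = Field(default=100.0, gt=0)
    n_dark_patches: int = Field(default=0, ge=0)
    dark_patch_factor: float = Field(default=0.4, gt=0, le=1.0)
    dark_patch_area: float = Field(default=2.0, gt=0)  # µm² per patch
    noise_gaussian_sigma: float = Field(default=0.0, ge=0)
    noise_poisson: bool = False
    min_separation: float = Field(default=2.5, ge=0)  # µm, geodesic centre-to-centre
    include_channel_b: bool = False
    enrichment_b: float | None = None
    rng_seed: int = 0

    @model_validator(mode="after")
    def _check_geometry(self) -> "SynthParams":
        extent = (np.array(self.stack_shape) - 1) * np.array(self.voxel_size)
        center = (np.array(self.bead_center) if self.bead_center is not None
                  else extent / 2.0)
        margin = self.bead_radius + 3 * self.shell_sigma
        if np.any(center - margin < 0) or np.any(center + margin > extent):
            raise ValueError(
                f"bead (R={self.bead_radius} µm + shell margin) does not fit "
                f"inside the stack extent {extent}")
        sphere_area = 4 * np.pi * self.bead_radius**2
        if self.n_domains > 0 and self.cap_area >= sphere_area / self.n_domains:
            raise ValueError("cap_area too large for the requested domain count")
        if self.n_domains > 1:
            # coarse feasibility: exclusion caps of radius min_separation/2
            # must not overfill the sphere
            half = min(self.min_separation / (2 * self.bead_radius), np.pi)
            excl = 2 * np.pi * self.bead_radius**2 * (1 - np.cos(half))
            if self.n_domains * excl > 0.9 * sphere_area:
                raise ValueError(
                    f"min_separation {self.min_separation} µm is infeasible for "
                    f"{self.n_domains} domains on this sphere")
        return self

    def center_um(self) -> np.ndarray:
        if self.bead_center is not None:
            return np.asarray(self.bead_center, dtype=float)
        return (np.array(self.stack_shape) - 1) * np.array(self.voxel_size) / 2.0


def cap_angular_radius(cap_area: float, radius: float) -> float:
    """Angular radius alpha of a spherical cap of the given area:
    ``area = 2 pi R^2 (1 - cos alpha)``."""
    c = 1.0 - cap_area / (2 * np.pi * radius**2)
    if not -1.0 <= c <= 1.0:
        raise ValueError("cap area exceeds the sphere area")
    return float(np.arccos(c))


@dataclass
class CapRecord:
    """One spherical cap: centre (theta, phi), angular radius, exact area."""

    theta: float
    phi: float
    alpha: float
    area: float
    enrichment: float = 1.0


@dataclass
class GroundTruth:
    """Exact geometry behind a synthetic stack (or sequence)."""

    sphere: SphereModel
    domains: list[CapRecord] = field(default_factory=list)
    dark_patches: list[CapRecord] = field(default_factory=list)
    frame_enrichment: list[float] | None = None    # per-frame effective enrichment
    frame_bleach_scale: list[float] | None = None  # per-frame channel-A multiplier
    bleach_frame: int | None = None

    def to_json(self, path=None) -> str:
        d = {
            "sphere": self.sphere.to_dict(),
            "domains": [asdict(c) for c in self.domains],
            "dark_patches": [asdict(c) for c in self.dark_patches],
            "frame_enrichment": self.frame_enrichment,
            "frame_bleach_scale": self.frame_bleach_scale,
            "bleach_frame": self.bleach_frame,
        }
        text = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _place_caps(n: int, alpha: float, radius: float, min_sep_um: float,
                rng: np.random.Generator, enrichment: float) -> list[CapRecord]:
    """Uniform-in-area rejection sampling under the geodesic separation."""
    caps: list[CapRecord] = []
    area = 2 * np.pi * radius**2 * (1 - np.cos(alpha))
    tries = 0
    while len(caps) < n:
        if tries >= _MAX_PLACEMENT_TRIES:
            raise RuntimeError(
                f"failed to place {n} caps with min_separation {min_sep_um} µm "
                f"after {_MAX_PLACEMENT_TRIES} tries")
        tries += 1
        z = rng.uniform(-1.0, 1.0)
        phi = rng.uniform(0.0, 2 * np.pi)
        theta = float(np.arccos(z))
        ok = True
        for c in caps:
            cosg = (np.cos(c.theta) * z
                    + np.sin(c.theta) * np.sin(theta) * np.cos(c.phi - phi))
            if radius * np.arccos(np.clip(cosg, -1, 1)) < min_sep_um:
                ok = False
                break
        if ok:
            caps.append(CapRecord(theta=theta, phi=float(phi), alpha=alpha,
                                  area=area, enrichment=enrichment))
    return caps


def _radial_fields(params: SynthParams):
    """Distance-from-centre field and unit directions for every voxel."""
    shape = params.stack_shape
    vs = params.voxel_size
    center = params.center_um()
    dz = (np.arange(shape[0]) * vs[0] - center[0]).astype(np.float32)
    dy = (np.arange(shape[1]) * vs[1] - center[1]).astype(np.float32)
    dx = (np.arange(shape[2]) * vs[2] - center[2]).astype(np.float32)
    r = np.sqrt(dz[:, None, None]**2 + dy[None, :, None]**2 + dx[None, None, :]**2)
    return r, dz, dy, dx


def _cap_mask(caps, r, dz, dy, dx) -> np.ndarray:
    """Boolean mask of voxels whose direction lies inside any cap."""
    mask = np.zeros(r.shape, dtype=bool)
    rsafe = np.maximum(r, 1e-9)
    for c in caps:
        nz, ny, nx = (np.cos(c.theta), np.sin(c.theta) * np.sin(c.phi),
                      np.sin(c.theta) * np.cos(c.phi))
        cosg = (dz[:, None, None] * nz + dy[None, :, None] * ny
                + dx[None, None, :] * nx) / rsafe
        mask |= cosg >= np.cos(c.alpha)
    return mask


def _apply_noise(data: np.ndarray, sigma: float, poisson: bool,
                 rng: np.random.Generator) -> np.ndarray:
    """Additive Gaussian first, then optional Poisson resampling of the
    non-negative intensities (order fixed)."""
    out = data
    if sigma > 0:
        out = out + rng.normal(0.0, sigma, size=out.shape).astype(np.float32)
    if poisson:
        out = rng.poisson(np.clip(out, 0.0, None)).astype(np.float32)
    return np.clip(out, 0.0, None) if sigma > 0 or poisson else out


def _render_channels(params: SynthParams, truth: GroundTruth, enrichment: float,
                     noise_rng: np.random.Generator | None,
                     bleach_scale: float = 1.0) -> tuple[np.ndarray, tuple[str, ...]]:
    r, dz, dy, dx = _radial_fields(params)
    shell = np.exp(-((r - params.bead_radius)**2)
                   / (2 * params.shell_sigma**2)).astype(np.float32)
    dom = _cap_mask(truth.domains, r, dz, dy, dx)
    a = params.baseline_out * shell * np.where(dom, enrichment, 1.0).astype(np.float32)
    a *= bleach_scale
    did = params.membrane_intensity * shell
    if truth.dark_patches:
        dark = _cap_mask(truth.dark_patches, r, dz, dy, dx)
        did = did * np.where(dark, params.dark_patch_factor, 1.0).astype(np.float32)
    channels = [a]
    names = ["protein_a"]
    if params.include_channel_b:
        enr_b = params.enrichment_b if params.enrichment_b is not None else enrichment
        b = params.baseline_out * shell * np.where(dom, enr_b, 1.0).astype(np.float32)
        channels.append(b)
        names.append("protein_b")
    channels.append(did)
    names.append("membrane")
    data = np.stack(channels).astype(np.float32)
    if noise_rng is not None:
        data = _apply_noise(data, params.noise_gaussian_sigma,
                            params.noise_poisson, noise_rng)
    return data, tuple(names)


def _seed_streams(seed: int) -> tuple[np.random.SeedSequence, np.random.SeedSequence]:
    """Named substreams of the root seed: (placement, noise)."""
    placement, noise = np.random.SeedSequence(seed).spawn(2)
    return placement, noise


def make_ground_truth(params: SynthParams) -> GroundTruth:
    """Draw the domain / dark-patch geometry for the given parameters."""
    placement_seq, _ = _seed_streams(params.rng_seed)
    rng = np.random.default_rng(placement_seq)
    sphere = SphereModel(center=params.center_um(), radius=params.bead_radius,
                         rms_residual=0.0, n_points=0)
    alpha = cap_angular_radius(params.cap_area, params.bead_radius)
    domains = _place_caps(params.n_domains, alpha, params.bead_radius,
                          params.min_separation, rng, params.enrichment)
    patches = []
    if params.n_dark_patches:
        pa = cap_angular_radius(params.dark_patch_area, params.bead_radius)
        patches = _place_caps(params.n_dark_patches, pa, params.bead_radius,
                              params.min_separation, rng, params.dark_patch_factor)
    return GroundTruth(sphere=sphere, domains=domains, dark_patches=patches)


def generate_bead_stack(params: SynthParams) -> tuple[VolumeImage, GroundTruth]:
    """Generate one multi-channel bead stack plus its ground truth."""
    truth = make_ground_truth(params)
    _, noise_seq = _seed_streams(params.rng_seed)
    noisy = params.noise_gaussian_sigma > 0 or params.noise_poisson
    data, names = _render_channels(params, truth, params.enrichment,
                                   np.random.default_rng(noise_seq) if noisy else None)
    return VolumeImage(data=data, voxel_size=params.voxel_size, channels=names), truth


def generate_timelapse(
    params: SynthParams,
    growth_profile: list[float],
    bleach_frame: int | None = None,
    bleach_factor: float = 0.1,
    recovery_tau: float = 3.0,
    recovery_plateau: float = 1.0,
) -> tuple[list[VolumeImage], GroundTruth]:
    """Generate a time-lapse sequence with fixed domain locations.

    ``growth_profile`` multiplies the domain contrast per frame: the
    effective enrichment at frame t is ``1 + (enrichment - 1) * profile_t``.
    If ``bleach_frame`` is set, channel A is multiplied by
    ``bleach_factor`` at that frame and recovers exponentially (time
    constant ``recovery_tau`` frames) toward ``recovery_plateau`` at the
    same locations.
    """
    profile = [float(g) for g in growth_profile]
    if len(profile) < 2:
        raise ValueError("need at least 2 frames")
    if bleach_frame is not None and not 0 <= bleach_frame < len(profile):
        raise ValueError(f"bleach_frame {bleach_frame} outside 0..{len(profile) - 1}")
    truth = make_ground_truth(params)
    _, noise_root = _seed_streams(params.rng_seed)
    frame_seqs = noise_root.spawn(len(profile))
    frames = []
    enr_list, scale_list = [], []
    noisy = params.noise_gaussian_sigma > 0 or params.noise_poisson
    for t, g in enumerate(profile):
        enr = 1.0 + (params.enrichment - 1.0) * g
        scale = 1.0
        if bleach_frame is not None and t >= bleach_frame:
            dt = t - bleach_frame
            scale = recovery_plateau - (recovery_plateau - bleach_factor) * np.exp(
                -dt / recovery_tau)
        rng = np.random.default_rng(frame_seqs[t]) if noisy else None
        data, names = _render_channels(params, truth, enr, rng, bleach_scale=scale)
        frames.append(VolumeImage(data=data, voxel_size=params.voxel_size,
                                  channels=names))
        enr_list.append(enr)
        scale_list.append(float(scale))
    truth.frame_enrichment = enr_list
    truth.frame_bleach_scale = scale_list
    truth.bleach_frame = bleach_frame
    return frames, truth
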