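"""nMDP colocalization, equatorial profiles, group tests, tracking, FRAP."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcbead import (
    DomainRecord,
    SphereModel,
    SurfaceField,
    SurfaceGrid,
    compare_groups,
    equatorial_profile,
    frap_recovery,
    nmdp_map,
    track_domains,
)

from conftest import small_params


def tiny_grid(n: int) -> SurfaceGrid:
    """A minimal n-particle grid for formula-level tests."""
    sphere = SphereModel(center=(0.0, 0.0, 0.0), radius=1.0)
    theta = np.linspace(0.5, 2.5, n)
    phi = np.linspace(0.0, 5.0, n)
    return SurfaceGrid(sphere=sphere, resolution_deg=0.0, theta=theta, phi=phi,
                       areas=np.full(n, 4 * np.pi / n), n_theta=1, n_phi=n)


def field(vals) -> SurfaceField:
    vals = np.asarray(vals, dtype=float)
    return SurfaceField(grid=tiny_grid(vals.size), values=vals)


class TestNmdp:
    def test_hand_computed_four_particle_example(self):
        res = nmdp_map(field([1, 2, 3, 10]), field([2, 2, 4, 8]))
        # Abar=4, Bbar=4, Amax=10, Bmax=8
        assert res.nmdp[3] == pytest.approx(1.0)
        assert res.nmdp[0] == pytest.approx(0.25)  # (1-4)(2-4) / ((10-4)(8-4))

    def test_joint_maximum_gives_one(self):
        res = nmdp_map(field([0, 1, 5]), field([2, 1, 9]))
        assert res.nmdp[2] == pytest.approx(1.0)

    def test_channel_mean_gives_zero(self):
        a = np.array([1.0, 3.0, 2.0, 2.0])  # mean 2: particles 2,3 at the mean
        b = np.array([5.0, 9.0, 7.0, 1.0])
        res = nmdp_map(field(a), field(b))
        assert res.nmdp[2] == pytest.approx(0.0)
        assert res.nmdp[3] == pytest.approx(0.0)

    def test_constant_channel_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            nmdp_map(field([1, 1, 1, 1]), field([1, 2, 3, 4]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(a=st.floats(0.1, 50), b=st.floats(-100, 100),
           c=st.floats(0.1, 50), d=st.floats(-100, 100))
    def test_affine_invariance(self, a, b, c, d):
        rng = np.random.default_rng(17)
        va = rng.uniform(0, 100, 30)
        vb = rng.uniform(0, 100, 30)
        base = nmdp_map(field(va), field(vb)).nmdp
        scaled = nmdp_map(field(a * va + b), field(c * vb + d)).nmdp
        assert np.allclose(base, scaled, atol=1e-9)


class TestEquatorialProfile:
    def test_uniform_shell_gives_constant_ratio(self, small_bead):
        params, vol, truth = small_bead
        import copy

        v2 = copy.deepcopy(vol)
        # protein = 2 * membrane everywhere
        v2.data[0] = 2.0 * v2.data[v2.channels.index("membrane")]
        prof = equatorial_profile(v2, truth.sphere)
        assert np.allclose(prof.table["ratio"].dropna(), 2.0, atol=1e-6)

    def test_dark_patch_dips_raw_but_not_ratio(self):
        from mcbead import generate_bead_stack

        # an equatorial dark patch, protein signal unchanged
        p = small_params(n_domains=0, n_dark_patches=1, dark_patch_area=1.5,
                         dark_patch_factor=0.3, rng_seed=23)
        vol, truth = generate_bead_stack(p)
        prof = equatorial_profile(vol, truth.sphere).table
        # find angular bins closest to / farthest from the patch
        patch = truth.dark_patches[0]
        raw = prof["membrane"].to_numpy()
        ratio = prof["ratio"].to_numpy()
        if raw.min() < 0.8 * np.median(raw):  # patch crosses the equator
            cv_ratio = np.nanstd(ratio) / np.nanmean(ratio)
            cv_raw = raw.std() / raw.mean()
            assert cv_ratio < cv_raw
        # the normalized ratio stays flat everywhere
        assert np.nanstd(ratio) / np.nanmean(ratio) < 0.05

    def test_sphere_outside_stack_rejected(self, small_bead):
        params, vol, truth = small_bead
        bad = SphereModel(center=(50.0, 3.0, 3.0), radius=2.0)
        with pytest.raises(ValueError, match="outside"):
            equatorial_profile(vol, bad)

    def test_scaling_both_channels_preserves_ratio_scaling_did_does_not(
            self, small_bead):
        params, vol, truth = small_bead
        import copy

        base = equatorial_profile(vol, truth.sphere).table["ratio"].to_numpy()
        both = copy.deepcopy(vol)
        both.data = both.data * 1.7  # shading on shared geometry
        r_both = equatorial_profile(both, truth.sphere).table["ratio"].to_numpy()
        assert np.allclose(r_both, base, rtol=1e-6, equal_nan=True)
        did_only = copy.deepcopy(vol)
        did_only.data[did_only.channels.index("membrane")] *= 1.7
        r_did = equatorial_profile(did_only, truth.sphere).table["ratio"].to_numpy()
        assert not np.allclose(r_did, base, rtol=1e-3, equal_nan=True)


class TestCompareGroups:
    def test_identical_groups(self):
        t, p = compare_groups([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_shifted_groups_strongly_significant(self):
        t, p = compare_groups([1, 2, 3], [11, 12, 13])
        # closed-form pooled t with n=3,3: t = -10 / sqrt(2/3)
        assert t == pytest.approx(-10 / np.sqrt(2 / 3))
        assert p < 0.001

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            compare_groups([1.0], [1, 2, 3])

    def test_degenerate_equal_constants_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            compare_groups([2.0, 2.0], [2.0, 2.0])

    def test_welch_flag(self):
        t_pooled, _ = compare_groups([1, 2, 3, 4], [2, 4, 6, 8, 10])
        t_welch, _ = compare_groups([1, 2, 3, 4], [2, 4, 6, 8, 10], welch=True)
        assert t_pooled != t_welch


def make_record(domain_id, theta, phi, area=1.5, intensity=300.0, bead="b"):
    return DomainRecord(domain_id=domain_id, bead_id=bead, centroid_theta=theta,
                        centroid_phi=phi, area_um2=area,
                        equivalent_diameter_um=np.sqrt(area),
                        mean_intensity=intensity, n_particles=20)


SPHERE = SphereModel(center=(0, 0, 0), radius=5.0)


class TestTracking:
    CENTROIDS = [(1.0, 1.0), (2.0, 3.0), (1.5, 5.0)]

    def frames(self, n=5, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for t in range(n):
            recs = []
            for i, (th, ph) in enumerate(self.CENTROIDS):
                recs.append(make_record(i + 1, th + jitter * rng.normal(),
                                        ph + jitter * rng.normal(),
                                        intensity=100.0 + 10 * t))
            out.append(recs)
        return out

    def test_static_domains_one_full_trajectory_each(self):
        trajs = track_domains(self.frames(), SPHERE, max_geodesic_um=1.0)
        assert len(trajs) == 3
        assert all(len(t.frames) == 5 for t in trajs)

    def test_permutation_invariance(self):
        frames = self.frames()
        shuffled = [list(reversed(f)) for f in frames]
        t1 = track_domains(frames, SPHERE)
        t2 = track_domains(shuffled, SPHERE)
        key = lambda trs: sorted(
            tuple((f, round(r.centroid_theta, 6)) for f, r in zip(t.frames, t.records))
            for t in trs)
        assert key(t1) == key(t2)

    def test_gap_splits_trajectory(self):
        frames = self.frames()
        frames[2] = [r for r in frames[2] if r.domain_id != 1]  # domain 1 absent
        trajs = track_domains(frames, SPHERE)
        lengths = sorted(len(t.frames) for t in trajs)
        assert lengths == [2, 2, 5, 5]  # no gap closing: split into two

    def test_needs_two_frames(self):
        with pytest.raises(ValueError, match="2 frames"):
            track_domains([[]], SPHERE)


class TestFrap:
    def recovery_frames(self, scales, intensity=300.0):
        frames = []
        for s in scales:
            frames.append([make_record(1, 1.0, 1.0, intensity=intensity * s),
                           make_record(2, 2.0, 4.0, intensity=intensity * s)])
        return frames

    def test_same_location_recovery(self):
        scales = [1.0, 1.0, 0.1, 0.4, 0.7, 0.8, 0.8]
        trajs = track_domains(self.recovery_frames(scales), SPHERE)
        res = frap_recovery(trajs, bleach_frame=2, sphere=SPHERE)
        assert res.same_location_fraction == 1.0
        for plateau in res.plateaus.values():
            assert abs(plateau - scales[-1]) / scales[-1] < 0.10

    def test_no_pre_bleach_rejected(self):
        trajs = track_domains(self.recovery_frames([1.0, 1.0]), SPHERE)
        with pytest.raises(ValueError, match="pre-bleach"):
            frap_recovery(trajs, bleach_frame=0, sphere=SPHERE)

    def test_relocated_domains_not_counted_as_same_location(self):
        frames = [[make_record(1, 1.0, 1.0)], [make_record(1, 1.0, 1.0)],
                  [make_record(1, 2.5, 4.0, intensity=100.0)]]
        trajs = track_domains(frames, SPHERE)
        res = frap_recovery(trajs, bleach_frame=2, sphere=SPHERE)
        assert res.same_location_fraction == 0.0
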