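import numpy as np
import pytest

from myodti import (
    ImageGrid,
    Streamline,
    Tensor,
    TrackingParams,
    TractSet,
    track_muscle,
    tract_properties,
    tract_sample,
)
from myodti.tensor_model import TensorField


def _uniform_field(shape, voxel_size, direction, l1=1.97, rd=1.39):
    """Constant tensor field with the principal axis along ``direction``."""
    direction = np.asarray(direction, dtype=float)
    direction /= np.linalg.norm(direction)
    basis = np.linalg.qr(
        np.column_stack([direction, [1, 0, 0], [0, 1, 0]])
    )[0]
    t = Tensor.from_eigen([l1, rd, rd], basis)
    grid = ImageGrid.from_voxel_size(shape, voxel_size)
    d = np.broadcast_to(t.d, shape + (6,)).copy()
    return TensorField(
        d, np.ones(shape), grid,
        np.ones(shape, bool), np.zeros(shape, bool),
    )


def _fa_of(l1, rd):
    lams = np.array([l1, rd, rd])
    md = lams.mean()
    return float(np.sqrt(1.5) * np.sqrt(((lams - md) ** 2).sum() / (lams**2).sum()))


class TestTrackMuscle:
    def test_uniform_z_field_tracks_straight_to_mask_exit(self):
        # FA ~ 0.3 field along +z in a 30 mm cube of 1.5 mm voxels
        field = _uniform_field((20, 20, 20), (1.5, 1.5, 1.5), [0, 0, 1],
                               l1=2.2, rd=1.35)
        assert 0.25 < _fa_of(2.2, 1.35) < 0.35
        mask = np.ones((20, 20, 20), dtype=bool)
        ts = track_muscle(field, mask)
        assert len(ts) > 0
        for s in ts.streamlines:
            xy_drift = np.ptp(s.points[:, :2], axis=0)
            assert np.all(xy_drift < 1e-6)  # straight
            assert s.reason_start == "mask-exit"
            assert s.reason_end == "mask-exit"
            # length approaches the 30 mm cube extent (within one step each end)
            assert s.length <= 30.0
        assert max(s.length for s in ts.streamlines) >= 27.0

    def test_low_fa_field_yields_no_streamlines(self):
        field = _uniform_field((10, 10, 10), (3, 3, 3), [0, 0, 1],
                               l1=1.6, rd=1.5)
        assert _fa_of(1.6, 1.5) < 0.1
        ts = track_muscle(field, np.ones((10, 10, 10), bool))
        assert len(ts) == 0

    def test_spiral_field_terminates_on_angle_at_critical_curvature(self):
        """Inward-spiral field: curvature grows along each streamline until
        the per-step turn (~atan(step/r)) exceeds max_angle, which happens
        near the critical radius r* = step / tan(max_angle)."""
        shape = (30, 5, 30)
        grid = ImageGrid.from_voxel_size(shape, (1.0, 1.0, 1.0))
        cx, cz = 14.5, 14.5
        beta = np.radians(20.0)  # inward pitch of the spiral
        d = np.zeros(shape + (6,))
        for i in range(shape[0]):
            for k in range(shape[2]):
                rho = np.array([i - cx, 0.0, k - cz])
                r = max(np.linalg.norm(rho), 1e-9)
                rhohat = rho / r
                tang = np.array([-rhohat[2], 0.0, rhohat[0]])
                fiber = np.cos(beta) * tang - np.sin(beta) * rhohat
                t = Tensor.from_eigen(
                    [2.2, 1.35, 1.35],
                    np.linalg.qr(np.column_stack([fiber, [0, 1, 0], rhohat]))[0],
                )
                d[i, :, k] = t.d
        field = TensorField(d, np.ones(shape), grid,
                            np.ones(shape, bool), np.zeros(shape, bool))
        disk = np.zeros(shape, dtype=bool)
        for i in range(shape[0]):
            for k in range(shape[2]):
                disk[i, :, k] = np.hypot(i - cx, k - cz) < 14.0
        params = TrackingParams(max_angle=15, min_length=0, max_steps=200)
        ts = track_muscle(field, disk, params)
        assert len(ts) > 0
        reasons = [s.reason_start for s in ts.streamlines] + [
            s.reason_end for s in ts.streamlines
        ]
        assert "angle" in reasons
        r_crit = params.step_size / np.tan(np.radians(params.max_angle))
        for s in ts.streamlines:
            for pt, reason in ((s.points[0], s.reason_start),
                               (s.points[-1], s.reason_end)):
                if reason == "angle":
                    r_end = np.hypot(pt[0] - cx, pt[2] - cz)
                    assert abs(r_end - r_crit) < 2.5

    def test_step_spacing_and_turning_invariants(self, clean_field):
        params = TrackingParams()
        mask = np.zeros(clean_field.grid.shape, dtype=bool)
        mask_src = clean_field.fitted
        mask |= mask_src
        ts = track_muscle(clean_field, mask, params)
        assert len(ts) > 0
        cos_min = np.cos(np.radians(params.max_angle)) - 1e-9
        for s in ts.streamlines[::25]:
            steps = np.diff(s.points, axis=0)
            norms = np.linalg.norm(steps, axis=1)
            np.testing.assert_allclose(norms, params.step_size, atol=1e-6)
            if len(steps) > 1:
                unit = steps / norms[:, None]
                cos_turn = np.sum(unit[:-1] * unit[1:], axis=1)
                assert np.all(cos_turn >= cos_min)

    def test_every_point_inside_mask(self, clean_field, clean_subject):
        lab = clean_subject.labels.present_labels[0]
        mask = clean_subject.labels.mask(lab)
        ts = track_muscle(clean_field, mask)
        grid = clean_field.grid
        for s in ts.streamlines[::10]:
            vox = np.round(grid.world_to_voxel(s.points)).astype(int)
            assert np.all(mask[vox[:, 0], vox[:, 1], vox[:, 2]])

    def test_tracking_is_deterministic(self, clean_field, clean_subject):
        mask = clean_subject.labels.mask(5)
        a = track_muscle(clean_field, mask)
        b = track_muscle(clean_field, mask)
        assert len(a) == len(b)
        for sa, sb in zip(a.streamlines, b.streamlines):
            np.testing.assert_array_equal(sa.points, sb.points)

    def test_empty_mask_gives_empty_tractset(self, clean_field):
        ts = track_muscle(clean_field, np.zeros(clean_field.grid.shape, bool))
        assert len(ts) == 0 and ts.n_seeds == 0

    def test_mtl_converges_to_mask_extent_with_step_size(self):
        field = _uniform_field((8, 8, 40), (3, 3, 3), [0, 0, 1], l1=2.4, rd=1.3)
        mask = np.ones((8, 8, 40), dtype=bool)  # 120 mm z extent
        mtls = []
        for step in (3.0, 1.5, 0.75):
            ts = track_muscle(field, mask, TrackingParams(step_size=step))
            mtls.append(np.mean([s.length for s in ts.streamlines]))
        errs = [abs(120.0 - m) for m in mtls]
        assert errs[0] >= errs[1] >= errs[2]
        assert errs[2] < 3.0


class TestTractSample:
    def _maps(self, grid, fa):
        shape = grid.shape
        from myodti.tensor_model import ScalarMaps

        return ScalarMaps(
            fa=fa, md=np.full(shape, 1.58), lambda1=np.full(shape, 1.97),
            lambda2=np.full(shape, 1.39), lambda3=np.full(shape, 1.39),
            rd=np.full(shape, 1.39), grid=grid,
            valid=np.ones(shape, dtype=bool),
        )

    def test_constant_map_gives_constant_mean(self):
        grid = ImageGrid.from_voxel_size((5, 5, 5), (1, 1, 1))
        maps = self._maps(grid, np.full((5, 5, 5), 0.22))
        pts = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 1.0], [1.2, 1.1, 2.0]])
        ts = TractSet([Streamline(pts, "mask-exit", "mask-exit")], 1)
        assert tract_sample(ts, maps)["fa"] == pytest.approx(0.22)

    def test_visitation_weighting_hand_count(self):
        """Voxel A (FA 0.1) visited once, voxel B (FA 0.3) three times:
        tract-weighted FA 0.25, plain voxel mean 0.2."""
        grid = ImageGrid.from_voxel_size((2, 1, 1), (1, 1, 1))
        fa = np.array([0.1, 0.3]).reshape(2, 1, 1)
        maps = self._maps(grid, fa)
        pts = np.array(
            [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.1, 0.0, 0.0], [0.9, 0.0, 0.0]]
        )
        ts = TractSet([Streamline(pts, "mask-exit", "mask-exit")], 1)
        assert tract_sample(ts, maps)["fa"] == pytest.approx(0.25)
        assert fa.mean() == pytest.approx(0.2)

    def test_equals_msb_when_each_voxel_visited_once(self, clean_maps, clean_subject):
        from myodti import extract_msb
        from myodti.io_formats import LabelMap

        lab = 5
        mask = clean_subject.labels.mask(lab)
        vox = np.argwhere(mask)
        pts = clean_maps.grid.voxel_to_world(vox.astype(float))
        # one two-point streamline per voxel, both points in the same voxel
        lines = [
            Streamline(np.stack([p, p + [0.0, 0.0, 0.1]]), "max-steps", "max-steps")
            for p in pts
        ]
        ts = TractSet(lines, len(lines))
        sampled = tract_sample(ts, clean_maps)
        lm = LabelMap(
            np.where(mask, 1, 0).astype(np.int32), clean_maps.grid, {1: "m"}
        )
        msb = extract_msb(clean_maps, lm)
        assert sampled["fa"] == pytest.approx(msb.loc[0, "fa"], abs=1e-12)
        assert sampled["md"] == pytest.approx(msb.loc[0, "md"], abs=1e-12)

    def test_empty_tract_set_warns(self, clean_maps):
        with pytest.warns(UserWarning, match="empty tract set"):
            out = tract_sample(TractSet([], 0), clean_maps)
        assert out == {}


class TestTractProperties:
    def test_constructed_geometry(self):
        # 100 straight 60 mm z-aligned tracts in a 4 cm^3 mask
        grid = ImageGrid.from_voxel_size((10, 10, 10), (2.0, 2.0, 10.0))
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask.flat[:100] = True  # 100 voxels x 40 mm^3 = 4 cm^3
        lines = [
            Streamline(
                np.array([5.0, 5.0, 0.0]) + np.outer(np.arange(41), [0, 0, 1.5]),
                "mask-exit", "mask-exit",
            )
            for _ in range(100)
        ]
        props = tract_properties(TractSet(lines, 100), mask, grid)
        assert props["vol"] == pytest.approx(4.0)
        assert props["td"] == pytest.approx(25.0)
        assert props["mtl"] == pytest.approx(60.0)
        assert props["mean_angle"] == pytest.approx(0.0, abs=1e-9)

    def test_oblique_tracts_angle(self):
        grid = ImageGrid.from_voxel_size((5, 5, 5), (3, 3, 3))
        mask = np.ones((5, 5, 5), dtype=bool)
        d = np.array([np.sin(np.radians(30)), 0.0, np.cos(np.radians(30))])
        lines = [
            Streamline(np.outer(np.arange(10), d * 1.5), "mask-exit", "mask-exit")
        ]
        props = tract_properties(TractSet(lines, 1), mask, grid)
        assert props["mean_angle"] == pytest.approx(30.0, abs=1e-9)

    def test_zero_volume_mask_rejected(self):
        grid = ImageGrid.from_voxel_size((3, 3, 3), (3, 3, 3))
        with pytest.raises(ValueError, match="zero-volume"):
            tract_properties(TractSet([], 0), np.zeros((3, 3, 3), bool), grid)

    def test_phantom_pennation_recovered(self, clean_field, clean_subject):
        """Tracking the noise-free phantom recovers each muscle's pennation."""
        truth = clean_subject.truth.set_index("label")
        for lab in clean_subject.labels.present_labels:
            mask = clean_subject.labels.mask(lab)
            ts = track_muscle(clean_field, mask)
            if len(ts) == 0:
                continue
            props = tract_properties(ts, mask, clean_field.grid)
            assert props["mean_angle"] == pytest.approx(
                truth.loc[lab, "pennation_deg"], abs=1.0
            )


def test_tracking_params_validation():
    with pytest.raises(ValueError):
        TrackingParams(max_angle=95)
    with pytest.raises(ValueError):
        TrackingParams(fa_min=0.5, fa_max=0.3)
    with pytest.raises(ValueError):
        TrackingParams(step_size=-1)
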