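"""Synthetic organoid generator: geometry, ablation, motion, labels, rendering."""

import dataclasses

import numpy as np
import pytest

import orgwound as ow
from orgwound.synthgen import ConfigurationError, _wrap_angle


class TestMakeOrganoid:
    def test_jitter_free_ring_has_exact_radius(self):
        spec = ow.OrganoidSpec(n_cells=100, radial_jitter_um=0.0, seed=1)
        t = ow.make_organoid(spec)
        tbl = t.frame_table(0)
        cx, cy = t.circle_center_xy_um
        r = np.hypot(tbl["x_um"] - cx, tbl["y_um"] - cy)
        assert np.allclose(r, spec.radius_um, atol=1e-9)

    def test_default_diameter_matches_cohort_mean(self):
        """Default geometry reproduces the 148-µm pre-ablation organoid."""
        assert 2 * ow.OrganoidSpec().radius_um == pytest.approx(148.0)

    def test_seeded_determinism_of_truth_table(self):
        a = ow.make_organoid(ow.OrganoidSpec(seed=7)).cells
        b = ow.make_organoid(ow.OrganoidSpec(seed=7)).cells
        assert a.equals(b)

    def test_invalid_spec_names_the_field(self):
        with pytest.raises(ConfigurationError, match="n_cells"):
            ow.make_organoid(ow.OrganoidSpec(n_cells=2))
        with pytest.raises(ConfigurationError, match="radius_um"):
            ow.make_organoid(ow.OrganoidSpec(radius_um=-1))


class TestApplyAblation:
    def test_count_conservation(self):
        t = ow.make_organoid(ow.OrganoidSpec(n_cells=100, seed=2))
        t = ow.apply_ablation(t, 10)
        t = ow.simulate_timelapse(t, ow.MotionSpec())
        later = t.frame_table(5)
        assert len(later) == 90
        assert not later["ablated"].any()

    def test_single_cell_center_is_cell_position(self):
        t = ow.make_organoid(ow.OrganoidSpec(n_cells=50, seed=3))
        t = ow.apply_ablation(t, 1)
        victim = t.frame_table(0).query("ablated").iloc[0]
        cx, cy = t.circle_center_xy_um
        r = t.circle_radius_um_per_frame[0]
        expected = (cx + r * np.cos(victim["angle_rad"]),
                    cy + r * np.sin(victim["angle_rad"]))
        assert t.ablation_center_xy_um == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_two_cell_center_is_circular_midpoint(self, seed):
        """k = 2 adjacent cells at θ and θ+Δ: site angle is θ+Δ/2."""
        t = ow.make_organoid(ow.OrganoidSpec(n_cells=40, seed=seed))
        t = ow.apply_ablation(t, 2)
        ang = np.sort(t.frame_table(0).query("ablated")["angle_rad"].to_numpy())
        th1, th2 = ang
        delta = float(_wrap_angle(th2 - th1))
        expected = float(_wrap_angle(th1 + delta / 2.0))
        assert float(_wrap_angle(t.ablation_theta_rad - expected)) == \
            pytest.approx(0.0, abs=1e-9)

    def test_k_must_be_below_n_cells(self):
        t = ow.make_organoid(ow.OrganoidSpec(n_cells=10, seed=0))
        with pytest.raises(ConfigurationError):
            ow.apply_ablation(t, 10)


class TestSimulateTimelapse:
    def test_frozen_dynamics(self):
        spec = ow.OrganoidSpec(seed=4, growth_rate_per_h=0.0, n_frames=6)
        t = ow.simulate_timelapse(ow.make_organoid(spec),
                                  ow.MotionSpec(sigma_tangential_um=0.0))
        piv = t.cells.pivot_table(index="cell_id", columns="frame",
                                  values=["x_um", "y_um"])
        assert np.allclose(piv["x_um"].std(axis=1), 0, atol=1e-12)
        assert np.allclose(piv["y_um"].std(axis=1), 0, atol=1e-12)

    def test_pure_advection_monotone_until_wound(self):
        """Drift only: arc distance to the wound decreases every frame."""
        spec = ow.OrganoidSpec(n_cells=50, seed=5, growth_rate_per_h=0.0,
                               n_frames=20, radial_jitter_um=0.0)
        t = ow.apply_ablation(ow.make_organoid(spec), 1)
        t = ow.simulate_timelapse(
            t, ow.MotionSpec(sigma_tangential_um=0.0,
                             drift_speed_um_per_frame=3.0, drift_range_um=60.0))
        r = spec.radius_um
        theta0 = t.ablation_theta_rad
        cells0 = t.frame_table(0)
        d0 = r * np.abs(_wrap_angle(cells0["angle_rad"].to_numpy() - theta0))
        mover = cells0["cell_id"].to_numpy()[
            (d0 > 30) & (d0 < 60) & ~cells0["ablated"].to_numpy()][0]
        traj = t.cells[t.cells["cell_id"] == mover].sort_values("frame")
        d = r * np.abs(_wrap_angle(traj["angle_rad"].to_numpy() - theta0))
        arrived = False
        for a, b in zip(d[:-1], d[1:]):
            if arrived:
                assert b == pytest.approx(0, abs=1e-9)
            else:
                assert b < a or b == pytest.approx(0, abs=1e-9)
            arrived = arrived or b == pytest.approx(0, abs=1e-9)
        assert d[-1] == pytest.approx(0, abs=1e-9)

    def test_path_length_matches_half_normal_expectation(self):
        """Pure tangential diffusion: per-step length is half-normal with
        mean σ·√(2/π), so the expected per-cell path over k steps is
        k·σ·√(2/π); the sample mean must fall within 3 SE."""
        sigma = 1.0
        spec = ow.OrganoidSpec(n_cells=200, radius_um=200.0, seed=6,
                               growth_rate_per_h=0.0, n_frames=48,
                               radial_jitter_um=0.0)
        t = ow.simulate_timelapse(ow.make_organoid(spec),
                                  ow.MotionSpec(sigma_tangential_um=sigma))
        piv = t.cells.pivot_table(index="cell_id", columns="frame",
                                  values=["x_um", "y_um"])
        xy = np.stack([piv["x_um"].to_numpy(), piv["y_um"].to_numpy()], axis=-1)
        steps = np.linalg.norm(np.diff(xy, axis=1), axis=2)
        paths = steps.sum(axis=1)
        k = 47
        expected = k * sigma * np.sqrt(2 / np.pi)
        step_var = sigma ** 2 * (1 - 2 / np.pi)
        se = np.sqrt(k * step_var / len(paths))
        assert abs(paths.mean() - expected) < 3 * se

    def test_ablated_cells_absent_after_ablation_frame(self):
        spec = ow.OrganoidSpec(n_cells=30, seed=8, n_frames=5)
        t = ow.apply_ablation(ow.make_organoid(spec), 3)
        t = ow.simulate_timelapse(t, ow.MotionSpec())
        victims = set(t.frame_table(0).query("ablated")["cell_id"])
        for f in range(1, 5):
            assert victims.isdisjoint(t.frame_table(f)["cell_id"])


class TestAssignEduLabels:
    def _truth(self, n=400, seed=0):
        t = ow.make_organoid(ow.OrganoidSpec(n_cells=n, seed=seed, n_frames=1))
        return ow.apply_ablation(t, 5)

    def test_baseline_zero_no_boost_means_no_labels(self):
        t = ow.assign_edu_labels(self._truth(), ow.LabelSpec(baseline_rate=0.0))
        assert not t.cells["edu_label"].any()

    def test_baseline_one_labels_everything(self):
        t = ow.assign_edu_labels(self._truth(), ow.LabelSpec(baseline_rate=1.0))
        assert t.cells["edu_label"].all()

    def test_probability_overflow_rejected(self):
        with pytest.raises(ConfigurationError):
            ow.LabelSpec(baseline_rate=0.9, bin_boosts={1: 0.2}).validate()

    def test_boosts_require_ablation(self):
        t = ow.make_organoid(ow.OrganoidSpec(n_cells=20, seed=1, n_frames=1))
        with pytest.raises(ConfigurationError):
            ow.assign_edu_labels(t, ow.LabelSpec(bin_boosts={1: 0.1}))

    def test_label_rates_within_binomial_envelope(self):
        """Across 50 seeds × 1000 cells the empirical per-bin rates stay in
        the 99% binomial envelope of the specified probabilities."""
        from scipy.stats import binom

        base, boost = 0.13, 0.14
        pos = {0: 0, 1: 0}
        tot = {0: 0, 1: 0}
        for seed in range(50):
            t = ow.make_organoid(ow.OrganoidSpec(n_cells=1000, seed=seed,
                                                 n_frames=1))
            t = ow.apply_ablation(t, 5)
            t = ow.assign_edu_labels(
                t, ow.LabelSpec(baseline_rate=base, bin_boosts={1: boost}))
            tbl = t.frame_table(0).query("~ablated")
            theta0 = t.ablation_theta_rad
            d = 74.0 * np.abs(_wrap_angle(tbl["angle_rad"].to_numpy() - theta0))
            bins = np.floor(d / 30.0).astype(int)
            lab = tbl["edu_label"].to_numpy()
            for b in (0, 1):
                pos[b] += int(lab[bins == b].sum())
                tot[b] += int((bins == b).sum())
        for b, p in ((0, base), (1, base + boost)):
            lo, hi = binom.interval(0.99, tot[b], p)
            assert lo <= pos[b] <= hi


class TestRenderStack:
    def test_single_cell_argmax_at_cell_pixel(self):
        spec = ow.OrganoidSpec(n_cells=3, radius_um=20.0, radial_jitter_um=0.0,
                               seed=9, n_frames=1)
        t = ow.make_organoid(spec)
        # keep a single cell
        t = dataclasses.replace(t, cells=t.cells.iloc[:1].copy(),
                                radial_offset_um=t.radial_offset_um[:1])
        stack = ow.render_stack(t, render=ow.RenderSpec(noise=False))
        proj = stack[0, :, 0].max(axis=0)
        iy, ix = np.unravel_index(np.argmax(proj), proj.shape)
        row = t.cells.iloc[0]
        assert ix == pytest.approx(row["x_um"] / spec.pixel_size_um, abs=1)
        assert iy == pytest.approx(row["y_um"] / spec.pixel_size_um, abs=1)

    def test_zero_cells_gives_flat_background(self):
        spec = ow.OrganoidSpec(seed=10, n_frames=1)
        t = ow.make_organoid(spec)
        t = dataclasses.replace(t, cells=t.cells.iloc[:0].copy(),
                                radial_offset_um=t.radial_offset_um[:0])
        stack = ow.render_stack(t, render=ow.RenderSpec(noise=False))
        assert np.allclose(stack, ow.RenderSpec().background)

    def test_equal_integrated_intensity_per_nucleus(self):
        """Identical rendering kernel: total signal per nucleus equal to 1%.

        Nuclei are spaced widely so each ±4σ integration window contains a
        single nucleus; with overlapping windows the per-nucleus integral is
        not separable."""
        spec = ow.OrganoidSpec(n_cells=12, seed=11, n_frames=1)
        t = ow.make_organoid(spec)
        render = ow.RenderSpec(noise=False, background=0.0)
        stack = ow.render_stack(t, render=render)
        proj = stack[0].sum(axis=0)[0]  # sum over z, nuclear channel
        px = spec.pixel_size_um
        tbl = t.frame_table(0)
        sums = []
        half = int(4 * spec.nucleus_sigma_um / px)
        for _, row in tbl.iterrows():
            cx, cy = int(row["x_um"] / px), int(row["y_um"] / px)
            sums.append(proj[cy - half:cy + half + 1,
                             cx - half:cx + half + 1].sum())
        sums = np.array(sums)
        assert sums.std() / sums.mean() < 0.01

    def test_fov_too_small_is_an_error(self):
        spec = ow.OrganoidSpec(seed=12, n_frames=1)
        t = ow.make_organoid(spec)
        t = dataclasses.replace(t, fov_um=50.0)
        with pytest.raises(ConfigurationError, match="field of view"):
            ow.render_stack(t)

    def test_seeded_determinism_of_stack(self):
        spec = ow.OrganoidSpec(n_cells=20, radius_um=30.0, seed=13, n_frames=2)
        t = ow.simulate_timelapse(ow.make_organoid(spec), ow.MotionSpec())
        a = ow.render_stack(t)
        b = ow.render_stack(t)
        assert np.array_equal(a, b)

    def test_scar_rendered_then_fades(self):
        spec = ow.OrganoidSpec(n_cells=30, radius_um=40.0, seed=14, n_frames=6)
        t = ow.apply_ablation(ow.make_organoid(spec), 3)
        t = ow.simulate_timelapse(t, ow.MotionSpec())
        render = ow.RenderSpec(noise=False, scar_frames=2)
        stack = ow.render_stack(t, render=render)
        sx, sy = t.ablation_center_xy_um
        px = spec.pixel_size_um
        ix, iy = int(sx / px), int(sy / px)
        mid = stack.shape[1] // 2
        early = stack[0, mid, 0, iy, ix]
        late = stack[4, mid, 0, iy, ix]
        assert early > 5 * late


class TestIO:
    def test_truth_roundtrip(self, tmp_path):
        t = ow.make_organoid(ow.OrganoidSpec(n_cells=10, seed=15, n_frames=1))
        path = tmp_path / "truth.csv"
        ow.write_truth(path, t)
        back = ow.read_truth(path)
        assert back["cell_id"].tolist() == t.cells["cell_id"].tolist()
        assert np.allclose(back["x_um"], t.cells["x_um"])

    def test_stack_roundtrip_with_axes_metadata(self, tmp_path):
        spec = ow.OrganoidSpec(n_cells=10, radius_um=20.0, seed=16, n_frames=1)
        t = ow.make_organoid(spec)
        stack = ow.render_stack(t)
        path = tmp_path / "stack.tif"
        ow.write_stack(path, stack, spec)
        arr, meta = ow.read_stack(path)
        assert arr.shape == stack.shape
        assert np.allclose(arr, stack)
        assert meta["axes"] == "TZCYX"
        assert meta["pixel_size_um"] == spec.pixel_size_um
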