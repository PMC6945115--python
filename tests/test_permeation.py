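"""Permeation state machine, unwrapping, selectivity, wetting, densities."""

import numpy as np
import pytest

from porelock.channel import ChannelAxis
from porelock.errors import ConfigurationError
from porelock.fixtures import (
    ToyPoreSpec,
    TrajectorySpec,
    build_trajectory,
    selections_for_fixture,
    toy_axis,
    toy_cylinder,
)
from porelock.permeation import (
    AxialTrace,
    PoreCylinder,
    axial_traces,
    count_permeations,
    density_grid,
    scan_events,
    selectivity_ratio,
    unwrap_axial,
    wetting_analysis,
)

CYL = PoreCylinder(z_lo=-15.0, z_hi=15.0, r_cyl=5.0)


def trace_from_z(z, lateral=0.0, species="Cl", pid=0) -> AxialTrace:
    z = np.asarray(z, dtype=float)
    lat = np.broadcast_to(np.asarray(lateral, dtype=float), z.shape).copy()
    return AxialTrace(
        particle_id=pid, species=species, s=z, lateral=lat,
        in_cylinder=lat <= CYL.r_cyl,
    )


def brute_force_recount(z, in_cyl, z_lo, z_hi):
    """Independent oracle: literal compartment scan (non-periodic),
    counting completed below->inside->above / above->inside->below runs
    with all inside frames inside the cylinder."""
    comp = ["below" if s < z_lo else "above" if s > z_hi else "inside" for s in z]
    events = 0
    last_bulk = None
    inside_ok = True
    for state, ok in zip(comp, in_cyl):
        if state == "inside":
            inside_ok = inside_ok and bool(ok)
            continue
        if last_bulk is None:
            last_bulk = state
        elif state != last_bulk:
            if inside_ok:
                events += 1
            last_bulk = state
        inside_ok = True
    return events


class TestTraces:
    def test_particle_on_axis_is_in_cylinder_every_frame(self):
        t = trace_from_z(np.linspace(-20, 20, 10), lateral=0.0)
        assert t.in_cylinder.all()

    def test_particle_six_angstrom_off_axis_is_masked(self):
        t = trace_from_z(np.linspace(-20, 20, 10), lateral=6.0)
        assert not t.in_cylinder.any()

    def test_pbc_jump_unwraps_without_spurious_discontinuity(self):
        # steady upward drift emitted wrapped into a 50 A box
        true_z = np.linspace(0.0, 120.0, 61)
        wrapped = np.mod(true_z, 50.0)
        unwrapped = unwrap_axial(wrapped, 50.0)
        np.testing.assert_allclose(unwrapped, true_z, atol=1e-9)
        assert np.abs(np.diff(unwrapped)).max() < 25.0

    def test_unwrap_identity_without_period(self):
        z = np.array([0.0, 40.0, -40.0])
        np.testing.assert_allclose(unwrap_axial(z, None), z)


class TestCounting:
    def test_monotone_traversal_counts_one_up_event(self):
        t = trace_from_z(np.linspace(-20, 20, 21))
        events, states = scan_events(t.s, t.in_cylinder, CYL)
        assert len(events) == 1
        assert events[0].direction == 1
        assert states[0] == "below" and states[-1] == "above"

    def test_downward_traversal_counts_one_down_event(self):
        t = trace_from_z(np.linspace(20, -20, 21))
        events, _ = scan_events(t.s, t.in_cylinder, CYL)
        assert [e.direction for e in events] == [-1]

    def test_incomplete_entry_and_return_counts_zero(self):
        z = np.concatenate([np.linspace(-20, 0, 11), np.linspace(0, -20, 11)])
        t = trace_from_z(z)
        events, _ = scan_events(t.s, t.in_cylinder, CYL)
        assert events == []

    def test_cylinder_exit_mid_traversal_voids_event(self):
        z = np.linspace(-20, 20, 21)
        lat = np.zeros(21)
        lat[10] = 8.0  # steps outside the 5 A cylinder while inside the pore
        t = AxialTrace(0, "Cl", z, lat, in_cylinder=lat <= CYL.r_cyl)
        assert scan_events(t.s, t.in_cylinder, CYL)[0] == []
        # one tolerated excursion frame restores the event
        assert len(scan_events(t.s, t.in_cylinder, CYL, tolerance_frames=1)[0]) == 1

    def test_counts_invariant_to_stride_refinement_on_monotone_path(self):
        for n in (9, 21, 81, 321):
            t = trace_from_z(np.linspace(-20, 20, n))
            assert len(scan_events(t.s, t.in_cylinder, CYL)[0]) == 1

    def test_periodic_laps_count_once_per_traversal(self):
        # three laps through a 60 A box, pore slab [-15, 15]
        z = np.linspace(-20.0, -20.0 + 3 * 60.0, 200)
        t = trace_from_z(z)
        events, _ = scan_events(t.s, t.in_cylinder, CYL, period=60.0)
        assert len(events) == 3
        assert all(e.direction == 1 for e in events)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_brute_force_rescan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # random-walk path that wanders across the compartments
        z = np.cumsum(rng.normal(0.0, 6.0, 400))
        lat = np.abs(rng.normal(2.0, 2.0, 400))
        t = AxialTrace(0, "Cl", z, lat, in_cylinder=lat <= CYL.r_cyl)
        events, _ = scan_events(t.s, t.in_cylinder, CYL)
        assert len(events) == brute_force_recount(z, t.in_cylinder, CYL.z_lo, CYL.z_hi)

    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_up_minus_down_equals_net_displacement(self, seed):
        rng = np.random.default_rng(1000 + seed)
        z = np.concatenate([[-20.0], -20.0 + np.cumsum(rng.normal(1.0, 8.0, 300))])
        z[-1] = z[-1] if abs(z[-1]) > 16 else 40.0  # end in bulk
        t = trace_from_z(z)
        events, _ = scan_events(t.s, t.in_cylinder, CYL)
        net = sum(e.direction for e in events)
        start_bulk = 0 if z[0] < CYL.z_lo else 1
        end_bulk = 0 if z[-1] < CYL.z_lo else (1 if z[-1] > CYL.z_hi else None)
        if end_bulk is not None:
            assert net == end_bulk - start_bulk

    def test_short_trace_rejected(self):
        t = trace_from_z([0.0])
        with pytest.raises(ConfigurationError):
            count_permeations([t], CYL)


class TestFixtureGroundTruth:
    def test_reference_fixture_counts_52_chloride_1_sodium(self):
        pspec = ToyPoreSpec()
        tspec = TrajectorySpec()  # 300 frames, Cl: 52 traversals, Na: 1
        universe, truth = build_trajectory(tspec, pspec)
        traces = axial_traces(
            universe, selections_for_fixture(), toy_axis(pspec), toy_cylinder(pspec)
        )
        counts, _ = count_permeations(traces, toy_cylinder(pspec), period=pspec.box[2])
        assert counts["Cl"] == truth["species"]["Cl"]["events"] == 52
        assert counts["Na"] == truth["species"]["Na"]["events"] == 1
        assert counts["water"] == 0

    def test_selectivity_of_reference_fixture(self):
        sel = selectivity_ratio(52, 1)
        assert sel["ratio"] == pytest.approx(52.0)

    @pytest.mark.parametrize("wrapped", [False, True])
    @pytest.mark.parametrize("seed", range(15))
    def test_counts_match_ground_truth_across_seeds(self, wrapped, seed):
        rng = np.random.default_rng(seed)
        pspec = ToyPoreSpec(seed=seed)
        tspec = TrajectorySpec(
            n_frames=120,
            roster={"water": 45, "Cl": 4, "Na": 2},
            traversals={
                "water": 0,
                "Cl": int(rng.integers(0, 30)),
                "Na": int(rng.integers(0, 5)),
            },
            wrapped=wrapped,
            seed=seed,
        )
        universe, truth = build_trajectory(tspec, pspec)
        traces = axial_traces(
            universe, selections_for_fixture(), toy_axis(pspec), toy_cylinder(pspec)
        )
        counts, _ = count_permeations(
            traces, toy_cylinder(pspec), period=pspec.box[2]
        )
        for sp in ("Cl", "Na", "water"):
            assert counts[sp] == truth["species"][sp]["events"]

    def test_empty_selection_raises(self):
        pspec = ToyPoreSpec()
        universe, _ = build_trajectory(TrajectorySpec(), pspec)
        with pytest.raises(ConfigurationError):
            axial_traces(universe, {"K": "name K"}, toy_axis(pspec),
                         toy_cylinder(pspec))


class TestSelectivity:
    def test_counts_from_reported_repeats(self):
        assert selectivity_ratio(52, 1)["ratio"] == 52.0
        out = selectivity_ratio(49, 0)
        assert out["ratio"] == float("inf") and out["flag"] == "no_sodium_events"

    def test_no_events_undefined(self):
        out = selectivity_ratio(0, 0)
        assert np.isnan(out["ratio"]) and out["flag"] == "undefined"

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            selectivity_ratio(-1, 0)


class TestWetting:
    def _water(self, z_values, n_frames=20):
        traces = []
        for i, z in enumerate(z_values):
            traces.append(
                AxialTrace(i, "water", np.full(n_frames, float(z)),
                           np.zeros(n_frames), np.ones(n_frames, dtype=bool))
            )
        return traces

    def test_filled_cylinder_fully_wetted(self):
        traces = self._water(np.arange(-14.5, 15.0, 1.0))
        report = wetting_analysis(traces, CYL, bin_width=1.0)
        assert report.fraction_frames_fully_wetted == 1.0
        assert not report.dewetted.any()

    def test_exclusion_band_maps_to_dewetted_bins(self):
        z = [z for z in np.arange(-14.5, 15.0, 1.0) if abs(z) >= 3.0]
        report = wetting_analysis(self._water(z), CYL, bin_width=1.0)
        centres = 0.5 * (report.bin_edges[:-1] + report.bin_edges[1:])
        expected = np.abs(centres) < 3.0
        assert report.fraction_frames_fully_wetted == 0.0
        np.testing.assert_array_equal(report.dewetted[0], expected)
        assert len(report.stretches) == 1  # one contiguous band, all frames

    def test_no_water_means_all_bins_dewetted(self):
        report = wetting_analysis([], CYL, bin_width=1.0)
        assert report.dewetted.all()
        assert report.fraction_frames_fully_wetted == 0.0

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            wetting_analysis([], CYL, bin_width=0.0)


class TestDensity:
    def test_single_static_particle_in_unit_nm_voxel(self):
        pos = [np.array([[5.0, 5.0, 5.0]])] * 4
        grid = density_grid(pos, bounds=((0, 10), (0, 10), (0, 10)), voxel=10.0)
        assert grid.density.shape == (1, 1, 1)
        assert grid.density[0, 0, 0] == pytest.approx(1.0)

    def test_empty_selection_gives_zero_grid(self):
        pos = [np.empty((0, 3))] * 3
        grid = density_grid(pos, bounds=((0, 10), (0, 10), (0, 10)), voxel=5.0)
        assert np.all(grid.density == 0.0)

    def test_duplicating_frames_leaves_density_unchanged(self):
        rng = np.random.default_rng(3)
        frame = rng.uniform(0, 20, (50, 3))
        g1 = density_grid([frame], bounds=((0, 20),) * 3, voxel=2.0)
        g2 = density_grid([frame, frame], bounds=((0, 20),) * 3, voxel=2.0)
        np.testing.assert_allclose(g1.density, g2.density)

    @pytest.mark.parametrize("seed", range(3))
    def test_integral_equals_mean_in_box_count(self, seed):
        rng = np.random.default_rng(seed)
        frames = [rng.uniform(0, 20, (rng.integers(10, 80), 3)) for _ in range(5)]
        grid = density_grid(frames, bounds=((0, 20),) * 3, voxel=2.0)
        mean_count = np.mean([len(f) for f in frames])
        assert grid.integral == pytest.approx(mean_count, rel=1e-9)

    def test_zero_voxel_rejected(self):
        with pytest.raises(ValueError):
            density_grid([np.zeros((1, 3))], bounds=((0, 10),) * 3, voxel=0.0)

    def test_isosurface_threshold_mask(self):
        pos = [np.array([[5.0, 5.0, 5.0]])]
        grid = density_grid(pos, bounds=((0, 10),) * 3, voxel=10.0)
        assert grid.voxels_at_least(0.5).sum() == 1
        assert grid.voxels_at_least(1.5).sum() == 0
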