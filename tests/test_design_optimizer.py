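"""Grid-search optimizers, jaw schedules and jaw-plane calibration."""

import numpy as np
import pytest

from ecollim import (GridSpec, build_applicator, calibrate_jaw_z,
                     calibrate_jaw_z_from_projection, incremental_designs,
                     interpolated_oar, jaw_schedule, oar_offset,
                     optimize_inner_oars, optimize_trimmer_z, project_to_plane,
                     sigma_penumbra)
from ecollim.design_optimizer import default_inner_edge_gridspec


class TestTrimmerZSearch:
    def test_degenerate_single_feasible_point(self, machine, beam, material):
        """A grid with exactly one feasible combination returns it."""
        res = optimize_trimmer_z(10.0, machine, beam, material,
                                 z_range=(64.0, 66.0), step=2.0,
                                 min_separation=2.0)
        assert res.best_params == {"z_upper": 64.0, "z_middle": 66.0}

    def test_empty_feasible_set_raises(self, machine, beam, material):
        from ecollim import InfeasibleGeometryError
        with pytest.raises(InfeasibleGeometryError):
            optimize_trimmer_z(10.0, machine, beam, material,
                               z_range=(66.0, 66.0), step=0.5)

    def test_matches_brute_force_reenumeration(self, machine, beam, material):
        """The optimizer's result equals an independent nested-loop minimum
        over the same grid."""
        res = optimize_trimmer_z(10.0, machine, beam, material,
                                 z_range=(60.0, 70.0), step=1.0)
        best = None
        for zu in np.arange(60.0, 70.1, 1.0):
            for zm in np.arange(60.0, 70.1, 1.0):
                if zm - zu < 2.0 or 95.0 - zm < 2.0:
                    continue
                d = build_applicator(10.0, machine, beam, material,
                                     trimmer_z=(zu, zm, 95.0))
                if best is None or d.total_trimmer_mass < best[0]:
                    best = (d.total_trimmer_mass, zu, zm)
        assert res.best_mass == pytest.approx(best[0], abs=1e-12)
        assert (res.best_params["z_upper"], res.best_params["z_middle"]) \
            == (best[1], best[2])

    def test_isomass_grid_covers_feasible_points(self, machine, beam, material):
        res = optimize_trimmer_z(10.0, machine, beam, material,
                                 z_range=(60.0, 66.0), step=2.0)
        grid = res.isomass_grid()
        assert len(grid) == len(res.evaluations)
        assert all(m >= res.best_mass - 1e-12 for _, _, m in grid if m is not None)


class TestInnerOarSearch:
    def _tiny_grid(self):
        return GridSpec(
            initial_bounds={"oar_upper": (0.90, 0.95), "oar_middle": (0.90, 0.95),
                            "oar_lower": (0.92, 0.95), "z_upper": (66.0, 66.0),
                            "z_middle": (79.0, 79.0)},
            steps=({"oar_upper": 0.025, "oar_middle": 0.025, "oar_lower": 0.015,
                    "z_upper": 1.0, "z_middle": 1.0},))

    def test_trivial_constraint_collapses_to_mass_minimum(self, machine, beam,
                                                          material):
        class AlwaysFlat:
            passed, margin = True, 0.02

        res = optimize_inner_oars(10.0, machine, beam, material,
                                  self._tiny_grid(), lambda d: AlwaysFlat())
        assert res.best_params["oar_upper"] == pytest.approx(0.90)
        assert res.best_params["oar_middle"] == pytest.approx(0.90)
        assert res.best_params["oar_lower"] == pytest.approx(0.92)

    def test_tighter_threshold_never_lighter(self, machine, beam, material):
        """A stricter flatness threshold cannot reduce the optimal mass."""
        from ecollim import evaluate_flatness, transport_fluence

        def flat_fn(threshold):
            def fn(design):
                prof = transport_fluence(machine, beam, design, beam.e_min,
                                         "inplane", grid_spacing=0.1)
                return evaluate_flatness(prof, 10.0, threshold=threshold)
            return fn

        masses = []
        for thr in (0.03, 0.02, 0.01):
            res = optimize_inner_oars(10.0, machine, beam, material,
                                      self._tiny_grid(), flat_fn(thr))
            masses.append(res.best_mass)
        assert masses[0] <= masses[1] + 1e-12 <= masses[2] + 2e-12

    def test_infeasible_iteration_reports_margin(self, machine, beam, material):
        class NeverFlat:
            passed, margin = False, -0.5

        with pytest.raises(Exception, match="margin"):
            optimize_inner_oars(10.0, machine, beam, material,
                                self._tiny_grid(), lambda d: NeverFlat())

    def test_gridspec_schedule_recenters_within_bounds(self):
        spec = default_inner_edge_gridspec()
        axes0 = spec.grid_axes(0, None)
        assert axes0["oar_upper"][0] == pytest.approx(0.875)
        axes1 = spec.grid_axes(1, {"oar_upper": 0.875, "oar_middle": 0.9,
                                   "oar_lower": 0.9, "z_upper": 58.5,
                                   "z_middle": 74.5})
        assert axes1["oar_upper"][0] >= 0.80 - 1e-12
        assert np.diff(axes1["z_upper"])[0] == pytest.approx(1.0)


class TestIncrementalDesigns:
    def test_identical_sets_zero_delta(self, machine, beam, material):
        s = {"upper": 0.9, "middle": 0.92, "lower": 0.94}
        out = incremental_designs(10.0, machine, beam, material, [s, dict(s)])
        assert out[0][1] is None
        assert out[1][1] == pytest.approx(0.0, abs=1e-12)

    def test_increasing_sets_positive_deltas(self, machine, beam, material):
        sets = [{"upper": .85, "middle": .90, "lower": .92},
                {"upper": .90, "middle": .92, "lower": .94},
                {"upper": .93, "middle": .94, "lower": .95}]
        out = incremental_designs(10.0, machine, beam, material, sets)
        assert all(d > 0 for _, d in out[1:])

    def test_non_monotone_sets_warn(self, machine, beam, material):
        sets = [{"upper": .90, "middle": .92, "lower": .94},
                {"upper": .85, "middle": .90, "lower": .92}]
        with pytest.warns(UserWarning):
            incremental_designs(10.0, machine, beam, material, sets)


class TestJawSchedule:
    def test_constant_oar_varies_only_through_sigma(self, machine, beam):
        sched = jaw_schedule(0.9, 0.9, beam.energies, machine, beam,
                             upper_inner_edge=5.0, z_upper=66.0)
        k = oar_offset(0.9)
        for E in beam.energies:
            for axis in ("inplane", "crossplane"):
                zj = machine.z_jaw(axis)
                sigma = sigma_penumbra(E, zj, 66.0, machine, beam)
                expected = project_to_plane(5.0 - k * sigma, 66.0, zj, machine)
                assert sched[E][axis]["aperture"] == pytest.approx(expected, abs=1e-12)

    def test_linear_interpolation_endpoints_and_midpoint(self):
        fn = interpolated_oar(0.965, 0.55)
        assert fn(6.0) == pytest.approx(0.965)
        assert fn(20.0) == pytest.approx(0.55)
        assert fn(13.0) == pytest.approx(0.5 * (0.965 + 0.55))

    def test_lower_oar_moves_jaws_inward(self, machine, beam):
        tight = jaw_schedule(0.965, 0.55, beam.energies, machine, beam,
                             upper_inner_edge=5.0, z_upper=66.0)
        wide = jaw_schedule(0.965, 0.965, beam.energies, machine, beam,
                            upper_inner_edge=5.0, z_upper=66.0)
        assert (tight[20.0]["inplane"]["aperture"]
                < wide[20.0]["inplane"]["aperture"])


class TestJawCalibration:
    def test_projection_round_trip(self, machine):
        z = calibrate_jaw_z_from_projection(5.1, 12.1, machine)
        zeta = machine.zeta(z)
        assert 12.1 * zeta / machine.zeta(machine.z_isocenter) == pytest.approx(5.1)

    def test_penumbra_calibration_round_trip(self, machine, beam):
        """Positions generated from assumed jaw planes are recovered to
        0.1 cm."""
        x_inner, z_upper, E, oar_t = 4.9, 66.0, 7.0, 0.95
        printed = {}
        for axis, z_true in (("inplane", 41.0), ("crossplane", 50.0)):
            sigma = sigma_penumbra(E, z_true, z_upper, machine, beam)
            edge = x_inner - oar_offset(oar_t) * sigma
            printed[axis] = edge * machine.zeta(100.0) / machine.zeta(z_upper)
        z_ip, z_cp = calibrate_jaw_z(printed, E, oar_t, x_inner, z_upper,
                                     machine, beam)
        assert z_ip == pytest.approx(41.0, abs=0.1)
        assert z_cp == pytest.approx(50.0, abs=0.1)

    def test_axes_calibrate_to_different_planes(self, machine, beam):
        """Printed in-plane/cross-plane positions differing at equal OAR
        imply different jaw plane heights."""
        printed = {"inplane": 12.7, "crossplane": 9.8}
        z_ip, z_cp = calibrate_jaw_z(printed, 7.0, 0.95, 4.9, 66.0,
                                     machine, beam)
        assert z_ip < z_cp
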