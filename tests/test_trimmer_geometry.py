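"""Cross-section construction rules and the bottom-up collimating chain."""

import numpy as np
import pytest

from ecollim import (ElectronBeamModel, InfeasibleGeometryError, build_applicator,
                     build_bevel_profile, oar, oar_offset, project_to_plane,
                     scale_profile_thickness, sigma_penumbra, stopping_thickness)
from ecollim.trimmer_geometry import aperture_for_downstream_match


class TestApertureMatch:
    def test_half_oar_is_pure_projection(self, machine, beam):
        ap = aperture_for_downstream_match(4.0, 0.5, 6.0, 80.0, 95.0, machine, beam)
        assert ap == pytest.approx(project_to_plane(4.0, 95.0, 80.0, machine))

    def test_95_percent_offset(self, machine, beam):
        sigma = sigma_penumbra(6.0, 80.0, 95.0, machine, beam)
        ap = aperture_for_downstream_match(4.0, 0.95, 6.0, 80.0, 95.0, machine, beam)
        edge_at_95 = project_to_plane(ap, 80.0, 95.0, machine)
        assert edge_at_95 == pytest.approx(4.0 + 1.645 * sigma, abs=1e-3)

    @pytest.mark.parametrize("target", [0.95, 0.9, 0.75, 0.5, 0.2, 0.02])
    def test_round_trip_oar_at_inner_edge(self, machine, beam, target):
        """Evaluating the penumbra OAR at the downstream inner edge for the
        matched aperture reproduces the target to 1e-9."""
        sigma = sigma_penumbra(6.0, 80.0, 95.0, machine, beam)
        ap = aperture_for_downstream_match(4.0, target, 6.0, 80.0, 95.0,
                                           machine, beam)
        edge = project_to_plane(ap, 80.0, 95.0, machine)
        assert oar(4.0 - edge, sigma) == pytest.approx(target, abs=1e-9)

    def test_infeasible_chain_raises(self, machine, beam):
        with pytest.raises(InfeasibleGeometryError):
            aperture_for_downstream_match(0.01, 0.02, 6.0, 80.0, 95.0,
                                          machine, beam)


class TestBevelProfile:
    def _sigma(self, machine, beam):
        return lambda E: sigma_penumbra(E, 80.0, 95.0, machine, beam)

    def test_single_energy_is_rectangular(self, machine, beam, material):
        sig = self._sigma(machine, beam)
        prof = build_bevel_profile(4.0, [20.0], lambda E: 4.5, sig,
                                   lambda E: 0.02, material)
        assert prof.max_thickness == pytest.approx(0.53)
        assert prof.x_outer == pytest.approx(4.5 + oar_offset(0.02) * sig(20.0))
        assert prof.thickness(0.5 * (prof.x_inner + prof.x_outer)) == pytest.approx(0.53)

    def test_full_grid_extent_and_thickness_steps(self, machine, beam, material):
        sig = self._sigma(machine, beam)
        energies = [float(e) for e in range(6, 21)]
        prof = build_bevel_profile(4.0, energies, lambda E: 4.5, sig,
                                   lambda E: 0.02, material)
        assert prof.x_outer == pytest.approx(4.5 + oar_offset(0.02) * sig(6.0),
                                             abs=1e-9)
        assert prof.max_thickness == pytest.approx(0.53)
        # outer boundary carries the lowest-energy stopping thickness, not 0
        assert prof.points[-1][1] == pytest.approx(
            float(stopping_thickness(6.0, material)))

    def test_envelope_equals_brute_force(self, machine, beam, material):
        """Profile thickness equals a per-position maximization over the
        energy grid at 0.01-cm resolution (staircase construction)."""
        sig = self._sigma(machine, beam)
        energies = [float(e) for e in range(6, 21)]
        edge = lambda E: 4.5
        prof = build_bevel_profile(4.0, energies, edge, sig, lambda E: 0.02,
                                   material, style="staircase")
        xs = np.arange(prof.x_inner, prof.x_outer - 1e-9, 0.01)
        anchors = {E: edge(E) + oar_offset(0.02) * sig(E) for E in energies}
        expected = [max((float(stopping_thickness(E, material))
                         for E in energies if anchors[E] >= x_), default=0.0)
                    for x_ in xs]
        np.testing.assert_allclose(prof.thickness(xs), expected, atol=1e-9)

    def test_taper_dominates_staircase(self, machine, beam, material):
        """The smooth taper through the anchors is a conservative cover of
        the exact per-energy staircase requirement."""
        sig = self._sigma(machine, beam)
        energies = [float(e) for e in range(6, 21)]
        taper = build_bevel_profile(4.0, energies, lambda E: 4.5, sig,
                                    lambda E: 0.02, material, style="taper")
        stair = build_bevel_profile(4.0, energies, lambda E: 4.5, sig,
                                    lambda E: 0.02, material, style="staircase")
        xs = np.linspace(4.0, taper.x_outer - 1e-9, 400)
        assert np.all(taper.thickness(xs) >= stair.thickness(xs) - 1e-9)

    def test_outer_oar_pullin_keeps_width(self, machine, beam, material):
        """Raising the highest-energy outer OAR pulls the bevel toward the
        axis while the overall bar width (lowest-energy anchor) is kept."""
        sig = self._sigma(machine, beam)
        energies = [float(e) for e in range(6, 21)]
        flat2 = build_bevel_profile(4.0, energies, lambda E: 4.5, sig,
                                    lambda E: 0.02, material)
        sched = lambda E: 0.02 + (0.48 - 0.02) * (E - 6.0) / 14.0
        pulled = build_bevel_profile(4.0, energies, lambda E: 4.5, sig,
                                     sched, material)
        assert pulled.x_outer == pytest.approx(flat2.x_outer, abs=1e-9)
        assert pulled.area() < flat2.area()

    def test_scale_preserves_extent(self, machine, beam, material):
        sig = self._sigma(machine, beam)
        prof = build_bevel_profile(4.0, [6.0, 13.0, 20.0], lambda E: 4.5, sig,
                                   lambda E: 0.02, material)
        scaled = scale_profile_thickness(prof, 0.51)
        assert scaled.x_inner == prof.x_inner
        assert scaled.x_outer == prof.x_outer
        assert scaled.area() == pytest.approx(0.51 * prof.area(), rel=1e-12)
        with pytest.raises(ValueError):
            scale_profile_thickness(prof, 1.2)


class TestBuildApplicator:
    def test_beveling_never_increases_mass(self, machine, beam, material):
        flat = build_applicator(10.0, machine, beam, material, bevel=False)
        bev = build_applicator(10.0, machine, beam, material, bevel=True)
        assert bev.total_trimmer_mass <= flat.total_trimmer_mass
        for name in ("upper", "middle", "lower"):
            assert (bev.mass_report.trimmers[name].total
                    <= flat.mass_report.trimmers[name].total + 1e-12)

    def test_raising_inner_oars_increases_mass(self, machine, beam, material):
        ladder = [{"upper": .85, "middle": .90, "lower": .92},
                  {"upper": .90, "middle": .92, "lower": .94},
                  {"upper": .95, "middle": .96, "lower": .965}]
        masses = [build_applicator(10.0, machine, beam, material,
                                   trimmer_z=(66.0, 79.0, 95.0),
                                   inner_oars=oars).total_trimmer_mass
                  for oars in ladder]
        assert masses[0] < masses[1] < masses[2]

    def test_restricting_energy_range_decreases_mass(self, machine, material):
        wide = ElectronBeamModel(energies=tuple(float(e) for e in range(4, 23)))
        narrow = ElectronBeamModel()
        m_wide = build_applicator(10.0, machine, wide, material,
                                  bevel=True).total_trimmer_mass
        m_narrow = build_applicator(10.0, machine, narrow, material,
                                    bevel=True).total_trimmer_mass
        assert m_narrow < m_wide

    def test_mass_grows_with_field_size(self, machine, beam, material):
        masses = [build_applicator(s, machine, beam, material).total_trimmer_mass
                  for s in (6.0, 10.0, 14.0, 20.0, 25.0)]
        assert np.all(np.diff(masses) > 0)

    def test_upper_trimmer_axes_differ_lower_symmetric(self, machine, beam, material):
        d = build_applicator(10.0, machine, beam, material)
        up = d.profiles["upper"]
        assert up["inplane"].x_outer != pytest.approx(up["crossplane"].x_outer)
        lo = d.profiles["lower"]
        assert lo["inplane"].points == lo["crossplane"].points

    def test_jaw_schedule_covers_energy_grid(self, machine, beam, material):
        d = build_applicator(10.0, machine, beam, material)
        assert sorted(d.jaw_schedule) == [float(e) for e in range(6, 21)]

    def test_zero_field_rejected(self, machine, beam, material):
        with pytest.raises(InfeasibleGeometryError):
            build_applicator(0.0, machine, beam, material)

    def test_divergent_inner_faces_add_small_shear_mass(self, machine, beam, material):
        with_shear = build_applicator(10.0, machine, beam, material)
        without = build_applicator(10.0, machine, beam, material,
                                   include_shear=False)
        extra = with_shear.total_trimmer_mass - without.total_trimmer_mass
        assert 0.0 < extra < 0.05
        assert with_shear.mass_report.trimmers["lower"].shear == 0.0
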