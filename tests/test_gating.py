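"""Forces, transition chimeras, path works, outliers and thermodynamics."""

import numpy as np
import pytest

import wlcgating as wg
from wlcgating.geometry import LinkerGeometry


def anchors_from_lengths(lz_lxy, structure_id="s", azimuth0=0.0):
    """AnchorSet with one subunit per (L_z, L_xy) pair on a C4 layout."""
    pore, ring = [], []
    az = np.radians([0, 90, 180, 270][:len(lz_lxy)]) + azimuth0
    for (lz, lxy), a in zip(lz_lxy, az):
        p = np.array([10 * np.cos(a), 10 * np.sin(a), 0.0])
        r = p + np.array([lxy * np.cos(a), lxy * np.sin(a), -lz])
        pore.append(p)
        ring.append(r)
    ids = ["A", "B", "C", "D"][:len(lz_lxy)]
    return wg.AnchorSet(structure_id, ids, np.array(pore), np.array(ring),
                        aligned=True)


class TestLinkerMechanics:
    def test_45_degree_decomposition(self, params16):
        L = 29.4
        geom = LinkerGeometry("A", L, L / np.sqrt(2), L / np.sqrt(2))
        m = wg.linker_mechanics(geom, params16)
        assert m.F_z == pytest.approx(m.F_xy)
        assert m.F_z == pytest.approx(m.F / np.sqrt(2), rel=1e-12)

    def test_purely_radial_outlier(self, params16):
        m = wg.linker_mechanics(LinkerGeometry("A", 36.2, 0.0, 36.2), params16)
        assert m.F_xy == pytest.approx(20.3, abs=0.05)
        assert m.F_z == 0.0

    def test_force_decomposition_closes(self, params16, rng):
        for _ in range(1000):
            L = rng.uniform(1.0, 55.0)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            lz, lxy = abs(L * u[2]), L * np.hypot(u[0], u[1])
            m = wg.linker_mechanics(LinkerGeometry("A", L, lz, lxy), params16)
            assert m.F ** 2 - m.F_z ** 2 - m.F_xy ** 2 == pytest.approx(
                0.0, abs=1e-6)

    def test_zero_length_all_zero(self, params16):
        m = wg.linker_mechanics(LinkerGeometry("A", 0.0, 0.0, 0.0), params16)
        assert m.F == m.U == 0.0 and m.F_z == m.F_xy == 0.0

    def test_beyond_contour_rejected(self, params16):
        with pytest.raises(wg.WLCDomainError):
            wg.linker_mechanics(LinkerGeometry("A", 61.0, 0.0, 61.0), params16)

    def test_near_contour_flagged(self, params16):
        m = wg.linker_mechanics(LinkerGeometry("A", 60.0, 0.0, 60.0), params16)
        assert "near_contour" in m.warning_flags


class TestStructureSummary:
    def test_identical_linkers_zero_sd(self, params16):
        geom = LinkerGeometry("A", 29.0, 20.0, np.sqrt(29.0**2 - 400))
        ms = [wg.linker_mechanics(geom, params16)] * 4
        s = wg.structure_summary(ms, "x")
        assert s.mean["F"] == pytest.approx(ms[0].F)
        assert s.sd["F"] == 0.0 and s.n_linkers == 4

    def test_empty_input_rejected(self):
        with pytest.raises(wg.WLCDomainError):
            wg.structure_summary([], "x")

    def test_tilt_series_mean_force_stability(self, params16):
        """Rigid-ring tilts barely move the per-structure mean force."""
        base = wg.SyntheticSpec(ring_center_depth=18.3, azimuthal_offset=8.5,
                                structure_id="TS")
        means = []
        for model, _ in wg.tilt_series(base, [0, 5, 10, 15, 20, 25]):
            anchors = wg.extract_anchors(model)
            ms = [wg.linker_mechanics(g, params16)
                  for g in wg.linker_lengths(anchors)]
            means.append(wg.structure_summary(ms, model.id).mean["F"])
        assert np.std(means, ddof=1) < 1.5

    def test_diagonal_subunit_compensation(self, params16):
        """In a tilted ring, the deeper subunit trades radial for vertical pull."""
        base = wg.SyntheticSpec(ring_center_depth=18.3, azimuthal_offset=8.5,
                                structure_id="TS")
        for model, _ in wg.tilt_series(base, [8, 16, 24]):
            anchors = wg.extract_anchors(model)
            ms = {m.chain_id: m for m in
                  (wg.linker_mechanics(g, params16)
                   for g in wg.linker_lengths(anchors))}
            for a, b in (("B", "D"),):
                dz = ms[a].F_z - ms[b].F_z
                dxy = ms[a].F_xy - ms[b].F_xy
                assert dz * dxy <= 0.0


class TestTransitionChimera:
    def test_identity_chimera_preserves_lengths(self):
        a = anchors_from_lengths([(20, 21)] * 4)
        for which in ("TS1", "TS2"):
            chim = wg.build_transition_chimera(a, a, which)
            l0 = [g.L for g in wg.linker_lengths(a)]
            l1 = [g.L for g in wg.linker_lengths(chim)]
            assert np.allclose(sorted(l0), sorted(l1), atol=1e-9)

    def test_hand_computed_chimera_lengths(self):
        open_a = anchors_from_lengths([(19, 22)] * 4)
        closed_a = anchors_from_lengths([(17, 12)] * 4)
        ts1 = wg.build_transition_chimera(open_a, closed_a, "TS1")
        # ring anchor from open, pore anchor from closed, same azimuth:
        # radial separation = (10+22) - 10 = 22 + (10-10) ... direct vector
        expected = np.linalg.norm(open_a.ring[0] - closed_a.pore[0])
        for g in wg.linker_lengths(ts1):
            assert g.L == pytest.approx(expected, abs=1e-9)
        ts2 = wg.build_transition_chimera(open_a, closed_a, "TS2")
        expected2 = np.linalg.norm(closed_a.ring[0] - open_a.pore[0])
        for g in wg.linker_lengths(ts2):
            assert g.L == pytest.approx(expected2, abs=1e-9)

    def test_pairing_invariance_for_c4_closed(self, params16):
        """Rotating the closed state's chain labels changes nothing."""
        open_a = anchors_from_lengths([(19, 22), (15, 25), (23, 18), (20, 21)])
        closed_a = anchors_from_lengths([(17, 12)] * 4)
        ref = wg.path_work(
            wg.build_transition_chimera(open_a, closed_a, "TS1"), open_a,
            params16, "p2")
        for shift in range(1, 4):
            rolled = wg.AnchorSet("c", list(closed_a.chain_ids),
                                  np.roll(closed_a.pore, shift, axis=0),
                                  np.roll(closed_a.ring, shift, axis=0),
                                  aligned=True)
            got = wg.path_work(
                wg.build_transition_chimera(open_a, rolled, "TS1"), open_a,
                params16, "p2")
            assert got.mean == pytest.approx(ref.mean, abs=1e-9)

    def test_unaligned_inputs_rejected(self):
        a = anchors_from_lengths([(20, 21)] * 4)
        b = wg.AnchorSet(a.structure_id, list(a.chain_ids), a.pore, a.ring,
                         aligned=False)
        with pytest.raises(ValueError, match="aligned"):
            wg.build_transition_chimera(b, a, "TS1")


class TestPathWork:
    def test_zero_for_identical_states(self, params16):
        a = anchors_from_lengths([(20, 21)] * 4)
        pw = wg.path_work(a, a, params16, "p")
        assert pw.mean == 0.0 and pw.per_tetramer == 0.0

    def test_known_energy_difference(self, params16):
        """29.1 -> 36.2 A on all four chains loads ~2.75 kBT per subunit."""
        frm = anchors_from_lengths([(0.0, 29.1)] * 4)
        to = anchors_from_lengths([(0.0, 36.2)] * 4)
        pw = wg.path_work(frm, to, params16, "stretch")
        expected = wg.wlc_energy(wg.angstrom(29.1), wg.angstrom(36.2), params16)
        assert pw.mean == pytest.approx(expected, rel=1e-12)
        assert pw.mean == pytest.approx(2.75, abs=0.01)
        assert pw.per_tetramer == pytest.approx(4 * expected, rel=1e-12)

    def test_loop_closure_and_telescoping(self, params16):
        open_a = anchors_from_lengths([(19, 22), (15, 25), (23, 18), (20, 21)],
                                      azimuth0=0.13)
        closed_a = anchors_from_lengths([(17, 12)] * 4)
        paths = wg.gating_paths(open_a, closed_a, params16)
        total = sum(p.mean for p in paths.values())
        assert total == pytest.approx(0.0, abs=1e-9)
        # path1 + path2 telescopes to closed -> open per subunit
        p12 = np.array(paths["path1"].per_subunit) + np.array(
            paths["path2"].per_subunit)
        closed_native = [wg.wlc_energy(0, wg.angstrom(g.L), params16)
                         for g in wg.linker_lengths(closed_a)]
        open_native = [wg.wlc_energy(0, wg.angstrom(g.L), params16)
                       for g in wg.linker_lengths(open_a)]
        assert np.allclose(np.sort(p12),
                           np.sort(np.array(open_native) - closed_native),
                           atol=1e-9)

    def test_canonical_signs(self, ensemble_report):
        for pw in ensemble_report.paths.values():
            assert pw["path1"].mean >= 0.0
            assert pw["path2"].mean <= 0.0
            assert pw["path3"].mean <= 0.0


class TestOutliers:
    def mechanics_pool(self, lengths, params):
        return [wg.linker_mechanics(
            LinkerGeometry(f"c{i}", L, 0.7 * L, np.sqrt(L * L - 0.49 * L * L)),
            params) for i, L in enumerate(lengths)]

    def test_all_equal_no_outliers(self, params16):
        rep = wg.detect_outliers(self.mechanics_pool([29.0] * 8, params16))
        assert rep.outlier_ids == () and rep.n_normal == 8

    def test_stretched_linker_flagged_with_excess_energy(self, params16, rng):
        lengths = list(np.clip(rng.normal(29.1, 2.8, 22), 22, 34.5)) + [36.2]
        rep = wg.detect_outliers(self.mechanics_pool(lengths, params16))
        assert ("", "c22") in rep.outlier_ids
        mean_normal = rep.normal_mean_L
        expected = wg.wlc_energy(wg.angstrom(mean_normal), wg.angstrom(36.2),
                                 params16)
        assert rep.excess_energy[("", "c22")] == pytest.approx(expected,
                                                               rel=1e-9)

    def test_spiked_length_at_4_mad_exactly_one_flag(self, params16, rng):
        # bounded spread: no pool value can exceed 2.5 * MAD on its own
        lengths = list(29.0 + rng.uniform(-2.0, 2.0, 19))
        med = np.median(lengths)
        mad = np.median(np.abs(np.array(lengths) - med))
        lengths.append(med + 4 * mad + 1.0)
        rep = wg.detect_outliers(self.mechanics_pool(lengths, params16))
        assert len(rep.outlier_ids) == 1 and rep.outlier_ids[0][1] == "c19"

    def test_folded_subunits_reported_separately(self, params16):
        pool = self.mechanics_pool([29.0] * 6, params16)
        rep = wg.detect_outliers(pool, folded_flags={("s6", "B"): True})
        assert rep.folded_ids == (("s6", "B"),)
        assert rep.n_pooled == 6


class TestPerturbedLinker:
    def test_shortened_and_lengthened_predictions(self, params16):
        f_short, u_short = wg.perturbed_linker_prediction(
            -3, wg.angstrom(29.1), params16)
        assert f_short == pytest.approx(19.7, abs=0.05)
        assert u_short == pytest.approx(5.0, abs=0.05)
        f_long, u_long = wg.perturbed_linker_prediction(
            +3, wg.angstrom(29.1), params16)
        assert f_long == pytest.approx(9.3, abs=0.1)
        assert u_long == pytest.approx(2.8, abs=0.1)

    def test_zero_delta_is_identity(self, params16):
        f, u = wg.perturbed_linker_prediction(0, wg.angstrom(29.4), params16)
        assert f == wg.wlc_force(wg.angstrom(29.4), params16)
        assert u == wg.wlc_energy(0, wg.angstrom(29.4), params16)

    def test_overshortening_is_domain_error(self, params16):
        with pytest.raises(wg.WLCDomainError):
            wg.perturbed_linker_prediction(-9, wg.angstrom(29.1), params16)


class TestThermodynamics:
    @pytest.mark.parametrize("po, expected", [
        (0.994, -5.1), (0.5, 0.0), (0.0001, 9.2), (0.0003, 8.1), (0.95, -2.9),
        (0.96, -3.2),
    ])
    def test_open_probability_conversions(self, po, expected):
        assert wg.delta_g_from_open_probability(po).delta_g == pytest.approx(
            expected, abs=0.05)

    def test_round_trip_identity(self, rng):
        for po in rng.uniform(1e-6, 1 - 1e-6, 50):
            dg = wg.delta_g_from_open_probability(po).delta_g
            assert wg.open_probability_from_delta_g(dg) == pytest.approx(
                po, abs=1e-12)

    @pytest.mark.parametrize("po", [0.0, 1.0, -0.1, 1.5])
    def test_probability_domain(self, po):
        with pytest.raises(wg.WLCDomainError):
            wg.delta_g_from_open_probability(po)

    def test_binding_energy_from_kd(self):
        one = wg.binding_energy_from_kd(1e-3, 1)
        assert one.delta_g == pytest.approx(6.9, abs=0.05)
        assert wg.binding_energy_from_kd(1.0, 1).delta_g == 0.0
        six = wg.binding_energy_from_kd(1e-3, 6)
        assert six.delta_g == pytest.approx(41.4, abs=0.1)

    def test_kd_domain(self):
        with pytest.raises(wg.WLCDomainError):
            wg.binding_energy_from_kd(0.0, 1)
        with pytest.raises(wg.WLCDomainError):
            wg.binding_energy_from_kd(1e-3, 0)
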