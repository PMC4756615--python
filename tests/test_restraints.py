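"""Restraint generation with trans-peptide gating, the weighted objective,
analytic gradients, and macrocycle idealization."""

import numpy as np
import pytest

import cdlkit as ck
from cdlkit.cdl_library import CDLKey, CDLTable, default_svl
from cdlkit.params import spans_next, spans_prev
from cdlkit.restraints import energy_and_grad


def svl_peptide(n=6, **kw):
    """Peptide built exactly at the SVL default internals."""
    return ck.build_peptide(ck.InternalSpec(["ALA"] * n, **kw))


@pytest.fixture(scope="module")
def svl_table():
    return ck.svl_only_table()


@pytest.fixture()
def two_bin_table():
    """General-class N-CA-C targets differing across the φ = −60 boundary."""
    entries = {
        (CDLKey("General", False), (-70.0, -50.0), "N-CA-C"): (112.5, 1.0, 100),
        (CDLKey("General", False), (-60.0, -50.0), "N-CA-C"): (109.5, 0.8, 100),
    }
    return CDLTable(entries=entries, svl=default_svl(), min_count=20)


class TestGenerate:
    def test_all_trans_interior_residues_get_cdl(self, two_bin_table):
        s = svl_peptide(6, phi=-65.0, psi=-45.0)
        rs = ck.generate_restraints(s, two_bin_table, "CDL")
        ncac = {r.residue_index: r for r in rs.restraints if r.param == "N-CA-C"}
        for i in range(1, 5):
            assert ncac[i].target.source == "CDL"
            assert ncac[i].target.mean == 112.5
        assert ncac[0].target.source == "SVL"
        assert ncac[5].target.source == "SVL"

    def test_weight_is_inverse_sigma_squared(self, two_bin_table):
        s = svl_peptide(4, phi=-65.0, psi=-45.0)
        rs = ck.generate_restraints(s, two_bin_table, "CDL")
        for r in rs.restraints:
            assert r.weight == pytest.approx(1.0 / r.target.sigma**2)

    def test_cis_bond_forces_svl_locally(self, two_bin_table):
        omega = [180.0] * 10
        omega[4] = 0.0  # cis bond 4->5
        s = svl_peptide(10, phi=-65.0, psi=-45.0, omega=omega)
        rs = ck.generate_restraints(s, two_bin_table, "CDL")
        by = {(r.residue_index, r.param): r for r in rs.restraints}
        # parameters spanning the cis bond carry SVL targets
        for param in ("C-N", "CA-C-N", "O-C-N"):
            assert by[(4, param)].target.source == "SVL"
        assert by[(5, "C-N-CA")].target.source == "SVL"
        # residues flanking the cis bond lose their phi/psi context entirely
        assert by[(4, "N-CA-C")].target.source == "SVL"
        assert by[(5, "N-CA-C")].target.source == "SVL"
        # distant residues keep conformation-dependent targets
        for i in (2, 3, 7):
            assert by[(i, "N-CA-C")].target.source == "CDL"

    def test_svl_mode_forces_single_values(self, two_bin_table):
        s = svl_peptide(6, phi=-65.0, psi=-45.0)
        rs = ck.generate_restraints(s, two_bin_table, "SVL")
        assert all(r.target.source == "SVL" for r in rs.restraints)
        svl = default_svl()
        for r in rs.restraints:
            assert r.target.mean == svl[("General", r.param)][0]


class TestEvaluate:
    def test_zero_energy_at_targets(self, svl_table):
        s = svl_peptide(5)
        rs = ck.generate_restraints(s, svl_table, "SVL")
        assert ck.evaluate(s, rs).energy == pytest.approx(0.0, abs=1e-16)

    def test_single_two_sigma_deviation_closed_form(self, svl_table):
        sigma = default_svl()[("General", "N-CA-C")][1]
        mean = default_svl()[("General", "N-CA-C")][0]
        internals = {"N-CA-C": [mean, mean + 2 * sigma, mean]}
        s = ck.build_peptide(ck.InternalSpec(["ALA"] * 3, internals=internals))
        rs = ck.generate_restraints(s, svl_table, "SVL", overall_weight=1.5)
        assert ck.evaluate(s, rs).energy == pytest.approx(1.5 * 4.0, abs=1e-8)

    def test_brute_force_term_sum_oracle(self, svl_table):
        s = ck.perturb(svl_peptide(6), 0.05, seed=9)
        rs = ck.generate_restraints(s, svl_table, "SVL", overall_weight=0.7)
        coords = np.array([a.xyz for a in s.flat_atoms()])
        expected = 0.0
        for r in rs.restraints:
            pts = coords[list(r.atom_indices)]
            v = ck.distance(pts[0], pts[1]) if len(pts) == 2 else ck.bond_angle(*pts)
            expected += ((v - r.target.mean) / r.target.sigma) ** 2
        expected *= 0.7
        assert ck.evaluate(s, rs).energy == pytest.approx(expected, abs=1e-9)

    def test_rigid_motion_invariance(self, svl_table):
        s = ck.perturb(svl_peptide(5), 0.03, seed=1)
        rs = ck.generate_restraints(s, svl_table, "SVL")
        e0 = ck.evaluate(s, rs).energy
        rng = np.random.default_rng(2)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = s.copy()
        for atom in moved.flat_atoms():
            atom.xyz = q @ atom.xyz + np.array([5.0, -3.0, 8.0])
        assert ck.evaluate(moved, rs).energy == pytest.approx(e0, abs=1e-9 * max(e0, 1))


class TestUpdateTargets:
    def test_idempotent_at_fixed_coordinates(self, two_bin_table):
        s = svl_peptide(5, phi=-65.0, psi=-45.0)
        rs = ck.generate_restraints(s, two_bin_table, "CDL")
        rs2 = ck.update_targets(s, rs, two_bin_table)
        assert [(r.param, r.atom_indices, r.target) for r in rs.restraints] == [
            (r.param, r.atom_indices, r.target) for r in rs2.restraints
        ]

    def test_bin_crossing_updates_targets(self, two_bin_table):
        s1 = svl_peptide(5, phi=-61.0, psi=-45.0)
        s2 = svl_peptide(5, phi=-59.0, psi=-45.0)
        rs1 = ck.generate_restraints(s1, two_bin_table, "CDL")
        rs2 = ck.update_targets(s2, rs1, two_bin_table)
        m1 = {r.residue_index: r.target.mean for r in rs1.restraints if r.param == "N-CA-C"}
        m2 = {r.residue_index: r.target.mean for r in rs2.restraints if r.param == "N-CA-C"}
        assert m1[2] == 112.5 and m2[2] == 109.5

    def test_omega_drive_switches_cdl_to_svl(self, two_bin_table):
        s1 = svl_peptide(6, phi=-65.0, psi=-45.0, omega=[160.0] * 6)
        omega = [160.0] * 6
        omega[2] = 20.0
        s2 = svl_peptide(6, phi=-65.0, psi=-45.0, omega=omega)
        rs1 = ck.generate_restraints(s1, two_bin_table, "CDL")
        rs2 = ck.update_targets(s2, rs1, two_bin_table)
        src1 = {(r.residue_index, r.param): r.target.source for r in rs1.restraints}
        src2 = {(r.residue_index, r.param): r.target.source for r in rs2.restraints}
        assert src1[(2, "N-CA-C")] == "CDL"
        assert src2[(2, "N-CA-C")] == "SVL"
        assert src2[(2, "CA-C-N")] == "SVL"


class TestGradients:
    def test_analytic_matches_central_differences(self, svl_table):
        s = ck.perturb(svl_peptide(4), 0.04, seed=5)
        rs = ck.generate_restraints(s, svl_table, "SVL")
        x0 = np.array([a.xyz for a in s.flat_atoms()]).ravel()
        _, g = energy_and_grad(x0, rs)
        h = 1e-6
        num = np.zeros_like(x0)
        for i in range(len(x0)):
            xp, xm = x0.copy(), x0.copy()
            xp[i] += h
            xm[i] -= h
            num[i] = (energy_and_grad(xp, rs)[0] - energy_and_grad(xm, rs)[0]) / (2 * h)
        scale = np.maximum(np.abs(num), 1.0)
        assert np.max(np.abs(g - num) / scale) <= 1e-5


class TestIdealize:
    def test_fixed_point_at_targets(self, svl_table):
        s = svl_peptide(5)
        x0 = np.array([a.xyz for a in s.flat_atoms()])
        final, trace = ck.idealize(s, svl_table, "SVL", macrocycles=3)
        assert all(t["e_start"] <= 1e-12 and t["e_end"] <= 1e-12 for t in trace)
        x1 = np.array([a.xyz for a in final.flat_atoms()])
        assert np.abs(x1 - x0).max() <= 1e-8

    def test_convergence_and_monotone_iterates(self, svl_table):
        s = ck.perturb(svl_peptide(6), 0.02, seed=3)
        final, trace = ck.idealize(s, svl_table, "SVL", macrocycles=3)
        for t in trace:
            energies = [t["e_start"]] + t["iterates"]
            diffs = np.diff(energies)
            assert (diffs <= 1e-9 * np.maximum(np.abs(energies[:-1]), 1)).all()
            assert t["e_end"] <= t["e_start"] + 1e-12
        rs = ck.generate_restraints(final, svl_table, "SVL")
        rep = ck.evaluate(final, rs)
        angle_devs = [
            d for d, r in zip(rep.deviations, rs.restraints)
            if len(r.atom_indices) == 3
        ]
        assert np.sqrt(np.mean(np.square(angle_devs))) < 0.1

    def test_cdl_and_svl_modes_reach_their_own_targets(self, sinusoid_table):
        n = 6
        rng = np.random.default_rng(8)
        phi = rng.uniform(-68.0, -32.0, n).tolist()
        psi = rng.uniform(-48.0, -12.0, n).tolist()
        s0 = ck.build_peptide(
            ck.InternalSpec(["ALA"] * n, phi, psi, 180.0, internals="use-table",
                            table=sinusoid_table)
        )
        start = ck.perturb(s0, 0.01, seed=4)
        out_cdl, _ = ck.idealize(start, sinusoid_table, "CDL", macrocycles=3)
        out_svl, _ = ck.idealize(start, sinusoid_table, "SVL", macrocycles=3)
        for out, mode in ((out_cdl, "CDL"), (out_svl, "SVL")):
            rs = ck.generate_restraints(out, sinusoid_table, mode)
            assert ck.evaluate(out, rs).energy < 1e-4
        # the CDL run sits closer to CDL targets than to SVL targets
        rep = ck.validate(out_cdl, sinusoid_table)
        assert (
            rep.per_library["CDL"].rmsd_angles_all
            < rep.per_library["SVL"].rmsd_angles_all
        )

    def test_invalid_macrocycles(self, svl_table):
        with pytest.raises(ValueError):
            ck.idealize(svl_peptide(3), svl_table, "SVL", macrocycles=0)


def test_span_helpers_consistent_with_vocabulary():
    assert spans_next("C-N") and spans_next("CA-C-N") and spans_next("O-C-N")
    assert spans_prev("C-N-CA")
    assert not spans_next("N-CA-C") and not spans_prev("N-CA")
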