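"""Geometric primitives against independent oracles, and backbone
measurement round trips."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import cdlkit as ck
from cdlkit.errors import GeometryError
from cdlkit.geometry import conformer_ids, measure_backbone, segment_contexts

RNG = np.random.default_rng(20240917)


def rigid_transform(rng):
    """Random rotation (QR of a Gaussian matrix) + translation."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.normal(scale=10.0, size=3)
    return lambda x: q @ x + t


class TestDistance:
    def test_345_triangle(self):
        assert ck.distance((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0)

    def test_identity(self):
        assert ck.distance((1.5, -2, 3), (1.5, -2, 3)) == 0.0

    def test_sum_of_squares_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            p, q = rng.normal(scale=5, size=(2, 3))
            oracle = math.sqrt(math.fsum((a - b) ** 2 for a, b in zip(p, q)))
            assert abs(ck.distance(p, q) - oracle) <= 1e-12


class TestBondAngle:
    def test_orthogonal(self):
        assert ck.bond_angle((1, 0, 0), (0, 0, 0), (0, 1, 0)) == pytest.approx(90.0)

    def test_collinear_between(self):
        assert ck.bond_angle((-1, 0, 0), (0, 0, 0), (2, 0, 0)) == pytest.approx(180.0)

    def test_zero_ray_raises(self):
        with pytest.raises(GeometryError):
            ck.bond_angle((0, 0, 0), (0, 0, 0), (1, 0, 0))

    def test_arccos_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            p, q, r = rng.normal(scale=3, size=(3, 3)).astype(np.longdouble)
            u, v = p - q, r - q
            c = np.dot(u, v) / (np.sqrt(np.dot(u, u)) * np.sqrt(np.dot(v, v)))
            oracle = float(np.degrees(np.arccos(np.clip(c, -1, 1))))
            assert abs(ck.bond_angle(p, q, r) - oracle) <= 1e-9


class TestDihedral:
    def test_planar_trans_is_minus_180(self):
        # zigzag: p and s on opposite sides of the q-r axis, all coplanar
        assert ck.dihedral((1, 1, 0), (0, 0, 0), (1, -1, 0), (0, -2, 0)) == pytest.approx(-180.0)

    def test_planar_cis_is_zero(self):
        assert ck.dihedral((1, 1, 0), (0, 0, 0), (0, -1, 0), (1, -2, 0)) == pytest.approx(0.0)

    def test_constructive_rotation_oracle(self):
        """Place the fourth atom by explicit rotation of a known angle about
        the central bond and recover that angle."""
        rng = np.random.default_rng(3)
        for _ in range(1000):
            q = rng.normal(scale=3, size=3)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            r = q + axis * rng.uniform(1, 3)
            # reference direction perpendicular to the axis
            ref = np.cross(axis, rng.normal(size=3))
            ref /= np.linalg.norm(ref)
            p = q + ref * rng.uniform(1, 3)  # p in the reference half-plane
            theta = rng.uniform(-180.0, 180.0)
            th = math.radians(theta)
            # rotate ref by theta about axis (Rodrigues), IUPAC sign: looking q->r
            rot = (
                ref * math.cos(th)
                + np.cross(axis, ref) * math.sin(th)
            )
            s = r + rot * rng.uniform(1, 3)
            got = ck.dihedral(p, q, r, s)
            want = ((theta + 180.0) % 360.0) - 180.0
            diff = abs(((got - want) + 180.0) % 360.0 - 180.0)
            assert diff <= 1e-9

    def test_collinear_raises(self):
        with pytest.raises(GeometryError):
            ck.dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    @given(st.integers(0, 10_000))
    def test_reversal_symmetry_and_mirror_antisymmetry(self, seed):
        """Reversing the atom order preserves a torsion; mirror reflection
        negates it (up to the [-180, 180) wrap)."""
        rng = np.random.default_rng(seed)
        pts = rng.normal(scale=4, size=(4, 3))
        mirror = pts * np.array([1.0, 1.0, -1.0])
        try:
            a = ck.dihedral(*pts)
            b = ck.dihedral(*pts[::-1])
            c = ck.dihedral(*mirror)
        except GeometryError:
            return
        assert abs(((a - b) + 180.0) % 360.0 - 180.0) == pytest.approx(0.0, abs=1e-9)
        assert abs(((a + c) + 180.0) % 360.0 - 180.0) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            pts = rng.normal(scale=4, size=(4, 3))
            T = rigid_transform(rng)
            try:
                a = ck.dihedral(*pts)
            except GeometryError:
                continue
            b = ck.dihedral(*(T(x) for x in pts))
            assert abs(((a - b) + 180.0) % 360.0 - 180.0) <= 1e-9
            assert abs(ck.bond_angle(*pts[:3]) - ck.bond_angle(*(T(x) for x in pts[:3]))) <= 1e-9
            assert abs(ck.distance(*pts[:2]) - ck.distance(*(T(x) for x in pts[:2]))) <= 1e-9


class TestClassifyOmega:
    @pytest.mark.parametrize(
        "omega,cls",
        [(179.5, "trans"), (-179.5, "trans"), (150.0, "trans"),
         (-3.0, "cis"), (0.0, "cis"), (30.0, "cis"),
         (90.0, "twisted"), (-100.0, "twisted")],
    )
    def test_classification(self, omega, cls):
        assert ck.classify_omega(omega).cls == cls


class TestBackboneTorsions:
    def test_builder_round_trip(self):
        s = ck.build_peptide(ck.InternalSpec(["ALA"] * 5, phi=-60, psi=-45, omega=180))
        seg = ck.link_residues(s)[0]
        for idx, pair, om in ck.backbone_torsions(seg):
            if idx > 0:
                assert pair.phi == pytest.approx(-60.0, abs=1e-4)
            if idx < 4:
                assert pair.psi == pytest.approx(-45.0, abs=1e-4)
                assert abs(om.omega) == pytest.approx(180.0, abs=1e-4)
                assert om.cls == "trans"

    def test_terminal_rule_two_residues(self):
        s = ck.build_peptide(ck.InternalSpec(["ALA", "ALA"]))
        seg = ck.link_residues(s)[0]
        tors = ck.backbone_torsions(seg)
        assert tors[0][1].phi is None and tors[0][1].psi is not None
        assert tors[1][1].phi is not None and tors[1][1].psi is None
        assert tors[1][2] is None

    def test_deleted_ca_localizes_undefined_torsions(self):
        s = ck.build_peptide(ck.InternalSpec(["ALA"] * 6))
        s.residues[2].atoms = [a for a in s.residues[2].atoms if a.name != "CA"]
        seg = ck.link_residues(s)[0]
        tors = {idx: (pair, om) for idx, pair, om in ck.backbone_torsions(seg)}
        assert tors[1][1] is None  # omega(1->2) = CA(1)-C(1)-N(2)-CA(2) needs CA(2)
        assert tors[2][0].phi is None and tors[2][0].psi is None
        assert tors[2][1] is None  # omega(2->3) = CA(2)-C(2)-N(3)-CA(3) needs CA(2)
        # neighbours keep their own torsions
        assert tors[0][0].psi is not None
        assert tors[1][0].phi is not None and tors[1][0].psi is not None
        assert tors[3][0].phi is not None  # phi(3) = C(2)-N(3)-CA(3)-C(3), unaffected
        assert tors[4][0].phi is not None and tors[4][0].psi is not None


class TestMeasureBackbone:
    def test_tripeptide_observation_count(self):
        # per residue with full atoms: 8 intra params (non-GLY); per bond: 4
        s = ck.build_peptide(ck.InternalSpec(["ALA", "ALA", "ALA"]))
        obs = measure_backbone(ck.link_residues(s)[0])
        assert len(obs) == 8 * 3 + 4 * 2

    def test_glycine_omits_cb_params(self):
        s = ck.build_peptide(ck.InternalSpec(["ALA", "GLY", "ALA"]))
        obs = measure_backbone(ck.link_residues(s)[0])
        assert len(obs) == 8 * 3 + 4 * 2 - 3
        assert not any("CB" in o.param and o.residue_index == 1 for o in obs)

    def test_builder_value_round_trip(self):
        s = ck.build_peptide(
            ck.InternalSpec(["ALA"] * 3, internals={"N-CA-C": 111.0})
        )
        obs = [o for o in measure_backbone(ck.link_residues(s)[0]) if o.param == "N-CA-C"]
        assert all(o.value == pytest.approx(111.0, abs=1e-4) for o in obs)

    def test_isolated_residue_no_inter_observations(self):
        s = ck.build_peptide(ck.InternalSpec(["ALA"]))
        obs = measure_backbone(ck.link_residues(s)[0])
        assert {o.param for o in obs} == {
            "N-CA", "CA-C", "C-O", "CA-CB", "N-CA-C", "N-CA-CB", "CB-CA-C", "CA-C-O"
        }

    def test_altloc_conformers_measured_separately(self):
        s = ck.build_peptide(ck.InternalSpec(["ALA"] * 3))
        res = s.residues[1]
        ca = res.get_atom("CA")
        ca.altloc = "A"
        shifted = ck.Atom("CA", ca.xyz + [0.05, 0, 0], "C", "B", 0.5, 10.0)
        res.atoms.append(shifted)
        seg = ck.link_residues(s)[0]
        assert conformer_ids(seg) == ["A", "B"]
        obs_a = {(o.residue_index, o.param): o.value for o in measure_backbone(seg, "A")}
        obs_b = {(o.residue_index, o.param): o.value for o in measure_backbone(seg, "B")}
        assert obs_a.keys() == obs_b.keys()
        assert obs_a[(1, "N-CA")] != pytest.approx(obs_b[(1, "N-CA")], abs=1e-6)


def test_contexts_flank_classification():
    s = ck.build_peptide(
        ck.InternalSpec(["ALA"] * 4, omega=[180.0, 0.0, 180.0, 180.0])
    )
    ctxs = segment_contexts(ck.link_residues(s)[0])
    assert ctxs[0].omega_prev is None and not ctxs[0].flanks_trans
    assert ctxs[1].omega_next.cls == "cis" and not ctxs[1].flanks_trans
    assert ctxs[2].omega_prev.cls == "cis" and not ctxs[2].flanks_trans
    assert not ctxs[3].flanks_trans  # terminal: no omega_next
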