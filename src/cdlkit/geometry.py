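"""Backbone internal-coordinate measurement.

Primitives (distance, bond angle, signed torsion in the IUPAC convention),
the φ/ψ/ω backbone torsions, trans/cis/twisted classification of peptide
bonds, and extraction of the twelve restrained backbone parameters per
residue.  Angles are reported in degrees, lengths in Angstrom; torsions lie
in the half-open range [-180, 180) with +180 mapped to -180.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .model_io import Segment
from .params import PARAM_ATOMS, param_kind, params_for

#: |omega| at or above which a peptide bond is trans, at or below which cis.
OMEGA_TRANS_MIN = 150.0
OMEGA_CIS_MAX = 30.0


def distance(p, q) -> float:
    """Euclidean distance between two points (Angstrom)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return float(np.linalg.norm(p - q))


def bond_angle(p, q, r) -> float:
    """Angle at ``q`` between rays q->p and q->r, in degrees within [0, 180]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    r = np.asarray(r, dtype=float)
    u = p - q
    v = r - q
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise GeometryError("bond_angle: zero-length ray")
    c = np.dot(u, v) / (nu * nv)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def dihedral(p, q, r, s) -> float:
    """Signed torsion p-q-r-s (IUPAC 1970: clockwise positive looking q->r;
    trans = ±180, cis = 0), wrapped to [-180, 180)."""
    p, q, r, s = (np.asarray(v, dtype=float) for v in (p, q, r, s))
    b0 = p - q
    b1 = r - q
    b2 = s - r
    nb1 = np.linalg.norm(b1)
    if nb1 == 0.0:
        raise GeometryError("dihedral: coincident central atoms")
    b1h = b1 / nb1
    v = b0 - np.dot(b0, b1h) * b1h
    w = b2 - np.dot(b2, b1h) * b1h
    if np.linalg.norm(v) < 1e-10 or np.linalg.norm(w) < 1e-10:
        raise GeometryError("dihedral: collinear atom triple, torsion undefined")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1h, v), w)
    ang = np.degrees(np.arctan2(y, x))
    # wrap to [-180, 180): +180 maps to -180
    return float(((ang + 180.0) % 360.0) - 180.0)


@dataclass(frozen=True)
class DihedralPair:
    """Backbone φ/ψ of one residue; ``None`` marks an undefined angle
    (chain termini or missing atoms)."""

    phi: float | None
    psi: float | None

    @property
    def defined(self) -> bool:
        return self.phi is not None and self.psi is not None


@dataclass(frozen=True)
class OmegaClass:
    omega: float
    cls: str  # trans | cis | twisted


def classify_omega(
    omega: float,
    trans_min: float = OMEGA_TRANS_MIN,
    cis_max: float = OMEGA_CIS_MAX,
) -> OmegaClass:
    """Classify a peptide-bond torsion: |ω| ≥ trans_min → trans,
    |ω| ≤ cis_max → cis, otherwise twisted."""
    a = abs(omega)
    if a >= trans_min:
        cls = "trans"
    elif a <= cis_max:
        cls = "cis"
    else:
        cls = "twisted"
    return OmegaClass(omega, cls)


def conformer_ids(seg: Segment) -> list[str]:
    """Altloc identifiers present in a segment; [""] when all atoms are
    single-conformer."""
    ids = sorted({a.altloc for li in range(len(seg)) for a in seg.residue(li).atoms if a.altloc})
    return ids or [""]


def _xyz(seg: Segment, local: int, name: str, altloc: str):
    if local < 0 or local >= len(seg):
        return None
    atom = seg.residue(local).get_atom(name, altloc)
    return None if atom is None else atom.xyz


def _safe_dihedral(*pts) -> float | None:
    if any(p is None for p in pts):
        return None
    try:
        return dihedral(*pts)
    except GeometryError:
        return None


def backbone_torsions(
    seg: Segment, altloc: str = ""
) -> list[tuple[int, DihedralPair, OmegaClass | None]]:
    """Per-residue (global residue index, φ/ψ pair, ω class of the bond to
    the next residue).

    φ(i) = C(i−1)–N(i)–CA(i)–C(i); ψ(i) = N(i)–CA(i)–C(i)–N(i+1);
    ω(i→i+1) = CA(i)–C(i)–N(i+1)–CA(i+1).  The first residue has φ
    undefined, the last has ψ and ω undefined; a missing backbone atom marks
    the affected torsions undefined rather than raising.
    """
    out = []
    n = len(seg)
    for i in range(n):
        phi = _safe_dihedral(
            _xyz(seg, i - 1, "C", altloc), _xyz(seg, i, "N", altloc),
            _xyz(seg, i, "CA", altloc), _xyz(seg, i, "C", altloc),
        )
        psi = _safe_dihedral(
            _xyz(seg, i, "N", altloc), _xyz(seg, i, "CA", altloc),
            _xyz(seg, i, "C", altloc), _xyz(seg, i + 1, "N", altloc),
        )
        omega = _safe_dihedral(
            _xyz(seg, i, "CA", altloc), _xyz(seg, i, "C", altloc),
            _xyz(seg, i + 1, "N", altloc), _xyz(seg, i + 1, "CA", altloc),
        )
        out.append(
            (seg.indices[i], DihedralPair(phi, psi),
             None if omega is None else classify_omega(omega))
        )
    return out


@dataclass(frozen=True)
class GeometryObservation:
    """One measured backbone parameter, owned by a residue."""

    param: str
    value: float
    residue_index: int  # index into structure.residues
    atom_refs: tuple[tuple[int, str], ...]  # (residue_index, atom_name)
    altloc: str = ""

    @property
    def kind(self) -> str:
        return param_kind(self.param)


def measure_backbone(seg: Segment, altloc: str = "") -> list[GeometryObservation]:
    """Measure the restrained-parameter set for every residue of a segment.

    Inter-residue parameters resolve their ±1 neighbours within the segment
    (peptide-bonded runs only); observations with missing atoms are skipped.
    """
    obs: list[GeometryObservation] = []
    for i in range(len(seg)):
        res = seg.residue(i)
        for param in params_for(res.res_name):
            spec = PARAM_ATOMS[param]
            pts = []
            refs = []
            ok = True
            for off, name in spec:
                li = i + off
                xyz = _xyz(seg, li, name, altloc)
                if xyz is None:
                    ok = False
                    break
                pts.append(xyz)
                refs.append((seg.indices[li], name))
            if not ok:
                continue
            if len(pts) == 2:
                value = distance(*pts)
            else:
                try:
                    value = bond_angle(*pts)
                except GeometryError:
                    continue
            obs.append(
                GeometryObservation(param, value, seg.indices[i], tuple(refs), altloc)
            )
    return obs


@dataclass(frozen=True)
class ResidueContext:
    """Everything the CDL lookup needs to know about one residue in a
    segment: the name triplet, φ/ψ, and the ω classes of the flanking
    peptide bonds."""

    residue_index: int
    local_index: int
    prev_name: str | None
    name: str
    next_name: str | None
    pair: DihedralPair
    omega_prev: OmegaClass | None
    omega_next: OmegaClass | None
    is_standard: bool
    altloc: str = ""

    @property
    def flanks_trans(self) -> bool:
        """True iff both flanking peptide bonds exist and are trans (the
        gating condition for conformation-dependent targets)."""
        return (
            self.omega_prev is not None and self.omega_prev.cls == "trans"
            and self.omega_next is not None and self.omega_next.cls == "trans"
        )


def segment_contexts(seg: Segment, altloc: str = "") -> list[ResidueContext]:
    """Build a :class:`ResidueContext` for every residue of a segment."""
    tors = backbone_torsions(seg, altloc)
    out = []
    n = len(seg)
    for i in range(n):
        res = seg.residue(i)
        out.append(
            ResidueContext(
                residue_index=seg.indices[i],
                local_index=i,
                prev_name=seg.residue(i - 1).res_name if i > 0 else None,
                name=res.res_name,
                next_name=seg.residue(i + 1).res_name if i < n - 1 else None,
                pair=tors[i][1],
                omega_prev=tors[i - 1][2] if i > 0 else None,
                omega_next=tors[i][2],
                is_standard=res.is_standard,
                altloc=altloc,
            )
        )
    return out
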