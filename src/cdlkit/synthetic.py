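"""Synthetic backbones and corpora with known ground truth.

``build_peptide`` constructs a polypeptide backbone (N, CA, C, O, CB) from
internal coordinates by natural extension: each new atom is placed from
three previously placed atoms at a prescribed bond length, bond angle and
torsion.  At zero noise the construction is exact, so measuring the result
with :mod:`cdlkit.geometry` reproduces the input internal coordinates — the
round trip that anchors every downstream test.

``simulate_corpus`` generates whole corpora whose bond-angle means vary
smoothly with (φ, ψ), together with a manifest of every true value drawn,
so the empirical table builder's parameter recovery is testable without any
external data.

Construction conventions (these make the round trip well defined):

* placement order per residue is N → CA → C, then O and CB; the next N is
  placed from (N, CA, C) with torsion ψ, the next CA from (CA, C, N′) with
  torsion ω, the next C from (C, N′, CA′) with torsion φ′;
* O is placed at torsion ψ+180 relative to the N(+1) plane, which makes the
  carbonyl carbon exactly planar — O–C–N(+1) is therefore a derived
  quantity, 360° − (CA–C–O) − (CA–C–N), not an independent input;
* CB is placed to satisfy both N–CA–CB and CB–CA–C simultaneously (the
  improper torsion is solved from the spherical law of cosines), with the
  sign convention of an L-amino acid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cdl_library import CDLTable, assign_key, default_svl, lookup, residue_group
from .errors import GeometryError
from .model_io import Atom, Residue, Structure
from .params import ALL_PARAMS, CB_PARAMS, params_for

#: Internal coordinates that are independent inputs of the construction
#: (O-C-N is derived from carbonyl planarity).
CONSTRUCTIVE_PARAMS: tuple[str, ...] = tuple(p for p in ALL_PARAMS if p != "O-C-N")

_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError("degenerate frame: zero-length vector")
    return v / n


def place_atom(a, b, c, length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom d with |d−c| = length, angle(b,c,d) = angle_deg and
    dihedral(a,b,c,d) = torsion_deg (natural-extension reference frame)."""
    a, b, c = (np.asarray(v, dtype=float) for v in (a, b, c))
    if not (0.0 < angle_deg < 180.0):
        raise GeometryError(f"placement angle {angle_deg} must lie strictly in (0, 180)")
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    bc = _normalize(c - b)
    n = np.cross(b - a, bc)
    if np.linalg.norm(n) < 1e-10:
        raise GeometryError("placement frame atoms are collinear")
    n = _normalize(n)
    m = np.cross(n, bc)
    d = (
        c
        - length * math.cos(theta) * bc
        + length * math.sin(theta) * (math.cos(chi) * m + math.sin(chi) * n)
    )
    return d


def _cb_improper(n_ca_c: float, n_ca_cb: float, cb_ca_c: float) -> float:
    """Torsion dihedral(C, N, CA, CB) that realizes both CB angles.

    From the spherical law of cosines, cos(CB-CA-C) = cos(N-CA-C)·cos(N-CA-CB)
    + sin(N-CA-C)·sin(N-CA-CB)·cos(t); the negative branch is the L-amino
    acid chirality (≈ −120° for tetrahedral angles, matching ideal L-Ala).
    """
    a0, a1, a2 = (math.radians(x) for x in (n_ca_c, n_ca_cb, cb_ca_c))
    denom = math.sin(a0) * math.sin(a1)
    if denom < 1e-12:
        raise GeometryError("CB placement: degenerate CA angles")
    cos_t = (math.cos(a2) - math.cos(a0) * math.cos(a1)) / denom
    if not -1.0 <= cos_t <= 1.0:
        raise GeometryError(
            f"CB placement infeasible: N-CA-C={n_ca_c}, N-CA-CB={n_ca_cb}, CB-CA-C={cb_ca_c}"
        )
    return -math.degrees(math.acos(cos_t))


@dataclass
class InternalSpec:
    """Recipe for one synthetic peptide.

    ``phi``/``psi``/``omega`` are per-residue in degrees (φ of the first
    residue and ω of the last are unused by construction; ψ of the last
    residue only orients its carbonyl O).  ``internals`` overrides the
    built-in SVL default values per parameter: a scalar applies to every
    residue, a sequence gives one value per residue; ``"use-table"`` with a
    ``table`` pulls each residue's values from a CDL lookup at its (φ, ψ).
    ``noise_sigma`` adds Gaussian noise to internal values (never to
    torsions), per parameter or as one scalar for all.
    """

    sequence: Sequence[str]
    phi: Sequence[float] | float = -60.0
    psi: Sequence[float] | float = -45.0
    omega: Sequence[float] | float = 180.0
    internals: dict[str, float | Sequence[float]] | str | None = None
    table: CDLTable | None = None
    noise_sigma: dict[str, float] | float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("sequence must be non-empty")


def _per_residue(value, n: int) -> list[float]:
    if np.isscalar(value):
        return [float(value)] * n
    vals = [float(v) for v in value]
    if len(vals) != n:
        raise ValueError(f"expected {n} per-residue values, got {len(vals)}")
    return vals


def internals_from_table(
    table: CDLTable, sequence: Sequence[str], phi: Sequence[float], psi: Sequence[float]
) -> list[dict[str, float]]:
    """Per-residue internal values pulled from a CDL lookup at each residue's
    (φ, ψ); terminal residues resolve to the SVL slice via the normal
    fallback.  O-C-N is replaced by the planarity-derived value."""
    n = len(sequence)
    out = []
    for i, name in enumerate(sequence):
        prev = sequence[i - 1] if i > 0 else None
        nxt = sequence[i + 1] if i < n - 1 else None
        key = assign_key(prev, name, nxt)
        pair = (phi[i] if i > 0 else None, psi[i] if i < n - 1 else None)
        vals = {
            param: lookup(table, key, pair, param).mean for param in params_for(name)
        }
        vals["O-C-N"] = 360.0 - vals["CA-C-O"] - vals["CA-C-N"]
        out.append(vals)
    return out


def resolve_internals(spec: InternalSpec, rng: np.random.Generator) -> list[dict[str, float]]:
    """Per-residue realized internal values (base + Gaussian noise)."""
    n = len(spec.sequence)
    svl = default_svl()
    phi = _per_residue(spec.phi, n)
    psi = _per_residue(spec.psi, n)

    if spec.internals == "use-table":
        if spec.table is None:
            raise ValueError("internals='use-table' requires a table")
        base = internals_from_table(spec.table, spec.sequence, phi, psi)
    else:
        base = []
        for i, name in enumerate(spec.sequence):
            group = residue_group(name)
            vals = {}
            for param in params_for(name):
                vals[param] = svl[(group, param)][0]
            overrides = spec.internals if isinstance(spec.internals, dict) else {}
            for param, v in overrides.items():
                if param in vals:
                    vals[param] = _per_residue(v, n)[i] if not np.isscalar(v) else float(v)
            base.append(vals)

    noise = spec.noise_sigma
    realized = []
    for i, vals in enumerate(base):
        out = {}
        for param, v in vals.items():
            if param == "O-C-N":
                continue  # derived below
            sig = noise.get(param, 0.0) if isinstance(noise, dict) else float(noise)
            out[param] = v + (rng.normal(0.0, sig) if sig > 0 else 0.0)
        out["O-C-N"] = 360.0 - out["CA-C-O"] - out["CA-C-N"]
        realized.append(out)
    return realized


def build_peptide(spec: InternalSpec, _internals: list[dict[str, float]] | None = None) -> Structure:
    """Build a backbone structure from internal coordinates.

    With ``noise_sigma=0`` the construction is exact: ``measure_backbone``
    on the result reproduces every constructive internal and every defined
    φ/ψ/ω to numerical precision.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(spec.sequence)
    internals = _internals if _internals is not None else resolve_internals(spec, rng)
    phi = _per_residue(spec.phi, n)
    psi = _per_residue(spec.psi, n)
    omega = _per_residue(spec.omega, n if np.isscalar(spec.omega) else len(spec.omega))
    if len(omega) not in (n, n - 1):
        raise ValueError("omega must cover all peptide bonds (n-1 values, or n with last unused)")

    coords: list[dict[str, np.ndarray]] = [dict() for _ in range(n)]
    g0 = internals[0]
    # first residue: N at origin, CA on +x, C in the xy plane
    coords[0]["N"] = np.zeros(3)
    coords[0]["CA"] = np.array([g0["N-CA"], 0.0, 0.0])
    a = math.radians(g0["N-CA-C"])
    coords[0]["C"] = coords[0]["CA"] + g0["CA-C"] * np.array([-math.cos(a), math.sin(a), 0.0])

    for i in range(n - 1):
        gi, gj = internals[i], internals[i + 1]
        ni, cai, ci = coords[i]["N"], coords[i]["CA"], coords[i]["C"]
        n_next = place_atom(ni, cai, ci, gi["C-N"], gi["CA-C-N"], psi[i])
        ca_next = place_atom(cai, ci, n_next, gj["N-CA"], gj["C-N-CA"], omega[i])
        c_next = place_atom(ci, n_next, ca_next, gj["CA-C"], gj["N-CA-C"], phi[i + 1])
        coords[i + 1]["N"] = n_next
        coords[i + 1]["CA"] = ca_next
        coords[i + 1]["C"] = c_next

    for i in range(n):
        gi = internals[i]
        ni, cai, ci = coords[i]["N"], coords[i]["CA"], coords[i]["C"]
        # carbonyl O opposite the next N (psi + 180): exact sp2 planarity
        coords[i]["O"] = place_atom(ni, cai, ci, gi["C-O"], gi["CA-C-O"], psi[i] + 180.0)
        if spec.sequence[i] != "GLY":
            t = _cb_improper(gi["N-CA-C"], gi["N-CA-CB"], gi["CB-CA-C"])
            coords[i]["CB"] = place_atom(ci, ni, cai, gi["CA-CB"], gi["N-CA-CB"], t)

    residues = []
    for i, name in enumerate(spec.sequence):
        atoms = [
            Atom(aname, coords[i][aname], _ELEMENTS[aname])
            for aname in ("N", "CA", "C", "O", "CB")
            if aname in coords[i]
        ]
        residues.append(Residue("A", i + 1, "", name, atoms))
    return Structure(residues, resolution=None, id="synthetic")


def conformation_dependent_ncac(phi: float, psi: float) -> float:
    """Default true N-CA-C surface: a smooth several-degree modulation of the
    tetrahedral-region mean with (φ, ψ), the size of variation observed in
    high-resolution protein structures."""
    return 111.0 + 5.0 * math.sin(math.radians(phi)) * math.cos(math.radians(psi))


#: Per-observation Gaussian noise on N-CA-C (degrees), the scatter a
#: high-resolution corpus shows within one conformational bin.
DEFAULT_NCAC_NOISE = 1.2


@dataclass
class CorpusSpec:
    """Recipe for a corpus of synthetic structures with known ground truth.

    ``phi_psi`` is a sampling scheme: ``{"kind": "uniform", "phi": (lo, hi),
    "psi": (lo, hi)}`` or ``{"kind": "clusters", "centers": [...],
    "sigma": s, "weights": [...]}`` (default: helical and sheet clusters).
    ``mu`` maps parameter names to callables μ(φ, ψ) giving the true
    conformation-dependent mean; unlisted parameters use the SVL default.
    By default the N-CA-C mean varies sinusoidally with (φ, ψ) and carries
    1.2° observation noise; the other parameters stay at their single
    values.  ``resolution`` is a scalar, a (lo, hi) uniform range, or
    ``None`` (no metadata).
    """

    n_structures: int = 100
    length: int | tuple[int, int] = 10
    sequence: Sequence[str] | None = None  # fixed sequence; default poly-ALA
    phi_psi: dict | None = None
    mu: dict[str, Callable[[float, float], float]] = field(
        default_factory=lambda: {"N-CA-C": conformation_dependent_ncac}
    )
    noise: dict[str, float] | float = field(
        default_factory=lambda: {"N-CA-C": DEFAULT_NCAC_NOISE}
    )
    omega: float = 180.0
    resolution: float | tuple[float, float] | None = 0.9
    seed: int = 0


def _sample_phi_psi(scheme: dict | None, rng: np.random.Generator) -> tuple[float, float]:
    if scheme is None:
        scheme = {
            "kind": "clusters",
            "centers": [(-63.0, -43.0), (-120.0, 130.0)],
            "sigma": 12.0,
            "weights": [0.5, 0.5],
        }
    if scheme["kind"] == "uniform":
        phi = rng.uniform(*scheme["phi"])
        psi = rng.uniform(*scheme["psi"])
        return phi, psi
    if scheme["kind"] == "clusters":
        centers = scheme["centers"]
        weights = np.asarray(scheme.get("weights", [1.0] * len(centers)), dtype=float)
        weights = weights / weights.sum()
        sig = float(scheme.get("sigma", 12.0))
        for _ in range(1000):
            c = centers[rng.choice(len(centers), p=weights)]
            phi = rng.normal(c[0], sig)
            psi = rng.normal(c[1], sig)
            if -180.0 <= phi < 180.0 and -180.0 <= psi < 180.0:
                return phi, psi
        raise ValueError("phi/psi cluster sampling failed to land in range")
    raise ValueError(f"unknown phi/psi scheme {scheme['kind']!r}")


def simulate_corpus(spec: CorpusSpec) -> tuple[list[Structure], pd.DataFrame]:
    """Generate structures plus a ground-truth manifest.

    The manifest has one row per (structure, residue, parameter) with the
    sampled φ/ψ, the true conformation-dependent mean, and the realized
    (noisy) value actually built into the coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    svl = default_svl()
    structures: list[Structure] = []
    rows: list[dict] = []
    for s_idx in range(spec.n_structures):
        if isinstance(spec.length, tuple):
            length = int(rng.integers(spec.length[0], spec.length[1] + 1))
        else:
            length = int(spec.length)
        sequence = list(spec.sequence) if spec.sequence is not None else ["ALA"] * length
        length = len(sequence)
        phi = []
        psi = []
        for _ in range(length):
            a, b = _sample_phi_psi(spec.phi_psi, rng)
            phi.append(a)
            psi.append(b)
        internals = []
        for i, name in enumerate(sequence):
            group = residue_group(name)
            vals = {}
            for param in params_for(name):
                if param == "O-C-N":
                    continue
                base = spec.mu[param](phi[i], psi[i]) if param in spec.mu else svl[(group, param)][0]
                sig = (
                    spec.noise.get(param, 0.0)
                    if isinstance(spec.noise, dict)
                    else float(spec.noise)
                )
                value = base + (rng.normal(0.0, sig) if sig > 0 else 0.0)
                vals[param] = value
                rows.append(
                    {
                        "structure_id": f"sim{s_idx:05d}",
                        "res_index": i,
                        "res_name": name,
                        "phi": phi[i],
                        "psi": psi[i],
                        "param": param,
                        "true_mean": base,
                        "value": value,
                    }
                )
            vals["O-C-N"] = 360.0 - vals["CA-C-O"] - vals["CA-C-N"]
            rows.append(
                {
                    "structure_id": f"sim{s_idx:05d}",
                    "res_index": i,
                    "res_name": name,
                    "phi": phi[i],
                    "psi": psi[i],
                    "param": "O-C-N",
                    "true_mean": vals["O-C-N"],
                    "value": vals["O-C-N"],
                }
            )
            internals.append(vals)
        pspec = InternalSpec(sequence, phi, psi, spec.omega, seed=int(rng.integers(2**31)))
        structure = build_peptide(pspec, _internals=internals)
        structure.id = f"sim{s_idx:05d}"
        if spec.resolution is None:
            structure.resolution = None
        elif isinstance(spec.resolution, tuple):
            structure.resolution = float(rng.uniform(*spec.resolution))
        else:
            structure.resolution = float(spec.resolution)
        for res in structure.residues:
            for atom in res.atoms:
                atom.b_factor = 10.0
        structures.append(structure)
    manifest = pd.DataFrame(rows)
    return structures, manifest


def perturb(s: Structure, coordinate_noise: float, seed: int = 0) -> Structure:
    """Isotropic Gaussian displacement of every atom (Angstrom), deterministic
    under the seed; noise 0 returns an identical copy."""
    if coordinate_noise < 0:
        raise ValueError("coordinate noise must be >= 0")
    rng = np.random.default_rng(seed)
    out = s.copy()
    if coordinate_noise == 0:
        return out
    for atom in out.flat_atoms():
        atom.xyz = atom.xyz + rng.normal(0.0, coordinate_noise, size=3)
    return out
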