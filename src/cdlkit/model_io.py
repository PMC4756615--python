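"""Minimal coordinate model and fixed-column PDB reading/writing.

The model holds exactly what the restraint machinery needs: ordered residues
with named atoms, altloc identifiers, occupancies, B factors and (optionally)
the crystallographic resolution parsed from ``REMARK   2``.  Chains are
segmented into peptide-bonded runs by a C(i)-N(i+1) distance test.

Units: coordinates and lengths in Angstrom, B factors in Angstrom^2.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import ParseError

STANDARD_RESIDUES: frozenset[str] = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU "
    "LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Default C(i)-N(i+1) distance below which consecutive residues are treated
#: as peptide-bonded (comfortably above the ~1.33 A bond, below any
#: non-bonded approach).
PEPTIDE_LINK_CUTOFF = 2.0

_RESOLUTION_RE = re.compile(
    r"REMARK\s+2\s+RESOLUTION\.\s+(\d+(?:\.\d+)?)\s+ANGSTROM"
)


@dataclass
class Atom:
    name: str
    xyz: np.ndarray
    element: str = ""
    altloc: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    insertion_code: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    het: bool = False  # any record was HETATM

    @property
    def is_standard(self) -> bool:
        """Standard amino acid eligible for CDL lookup (HETATM entries such
        as MSE are treated as non-standard and fall back to SVL targets)."""
        return self.res_name in STANDARD_RESIDUES and not self.het

    def get_atom(self, name: str, altloc: str = "") -> Atom | None:
        """Atom by name for a conformer: exact altloc match wins, blank-altloc
        atoms are shared across conformers."""
        blank = None
        for atom in self.atoms:
            if atom.name != name:
                continue
            if atom.altloc == altloc:
                return atom
            if atom.altloc == "":
                blank = atom
        return blank

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.res_name}{self.seq_num}{self.insertion_code}".strip()


@dataclass
class Structure:
    residues: list[Residue] = field(default_factory=list)
    resolution: float | None = None
    id: str = ""

    def flat_atoms(self) -> list[Atom]:
        """All atoms in file order; the enumeration index is the stable atom
        identifier used by restraints and the minimizer."""
        return [a for res in self.residues for a in res.atoms]

    def copy(self) -> "Structure":
        residues = [
            Residue(
                r.chain_id, r.seq_num, r.insertion_code, r.res_name,
                [Atom(a.name, a.xyz.copy(), a.element, a.altloc, a.occupancy, a.b_factor)
                 for a in r.atoms],
                r.het,
            )
            for r in self.residues
        ]
        return Structure(residues, self.resolution, self.id)

    def set_coordinates(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        atoms = self.flat_atoms()
        if len(atoms) != coords.shape[0]:
            raise ValueError("coordinate array does not match atom count")
        for atom, xyz in zip(atoms, coords):
            atom.xyz = xyz.copy()


@dataclass(frozen=True)
class Segment:
    """A contiguous peptide-bonded run of residues (indices into
    ``structure.residues``)."""

    structure: Structure
    indices: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.indices)

    def residue(self, local: int) -> Residue:
        return self.structure.residues[self.indices[local]]


def _infer_element(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def parse_pdb(text: str, structure_id: str = "", model: int | None = None) -> Structure:
    """Parse fixed-column PDB content into a :class:`Structure`.

    Multi-model files are refused unless ``model`` selects one explicitly
    (silent selection hides errors).  Malformed ATOM/HETATM records raise
    :class:`ParseError` naming the offending line.
    """
    lines = text.splitlines()
    n_models = sum(1 for ln in lines if ln.startswith("MODEL "))
    if n_models > 1 and model is None:
        raise ParseError(
            f"input contains {n_models} models; select one explicitly "
            f"(model=<serial> / --model)"
        )

    resolution: float | None = None
    structure = Structure(id=structure_id)
    current_key: tuple | None = None
    current: Residue | None = None
    seen: set[tuple[str, str]] = set()
    in_model: int | None = None

    for lineno, line in enumerate(lines, start=1):
        rec = line[:6]
        if rec == "MODEL ":
            try:
                in_model = int(line[6:].split()[0])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"line {lineno}: malformed MODEL record") from exc
            continue
        if rec == "ENDMDL":
            in_model = None
            continue
        if line.startswith("REMARK") and resolution is None:
            m = _RESOLUTION_RE.search(line)
            if m:
                resolution = float(m.group(1))
            continue
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if model is not None and in_model != model:
            continue
        try:
            name = line[12:16].strip()
            altloc = line[16].strip()
            res_name = line[17:20].strip()
            chain_id = line[21].strip()
            seq_num = int(line[22:26])
            icode = line[26].strip()
            xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            occ_s = line[54:60].strip()
            b_s = line[60:66].strip()
            occupancy = float(occ_s) if occ_s else 1.0
            b_factor = float(b_s) if b_s else 0.0
            element = line[76:78].strip() if len(line) >= 78 else ""
        except (ValueError, IndexError) as exc:
            raise ParseError(f"line {lineno}: malformed fixed-column record: {line!r}") from exc
        if not element:
            element = _infer_element(name)

        key = (chain_id, seq_num, icode, res_name)
        if key != current_key:
            current = Residue(chain_id, seq_num, icode, res_name)
            structure.residues.append(current)
            current_key = key
            seen = set()
        assert current is not None
        if (name, altloc) in seen:
            raise ParseError(
                f"line {lineno}: duplicate atom {name!r} altloc {altloc!r} "
                f"in residue {res_name} {chain_id}{seq_num}"
            )
        seen.add((name, altloc))
        try:
            atom = Atom(name, np.array(xyz), element, altloc, occupancy, b_factor)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        current.atoms.append(atom)
        if rec == "HETATM":
            current.het = True

    structure.resolution = resolution
    return structure


def write_pdb(s: Structure) -> str:
    """Serialize a :class:`Structure` as fixed-column PDB text.

    Coordinates are written to 3 decimals, occupancy and B to 2; the output
    re-parses to the same structure up to that precision.
    """
    lines: list[str] = []
    if s.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {s.resolution:7.2f} ANGSTROMS.")
    serial = 1
    prev_chain: str | None = None
    for res in s.residues:
        if prev_chain is not None and res.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = res.chain_id
        rec = "HETATM" if res.het else "ATOM  "
        for atom in res.atoms:
            if len(atom.name) > 4:
                raise ValueError(f"atom name {atom.name!r} exceeds 4 characters")
            name4 = atom.name if len(atom.name) == 4 else f" {atom.name:<3}"
            x, y, z = atom.xyz
            lines.append(
                f"{rec}{serial:>5} {name4}{atom.altloc or ' '}{res.res_name:>3} "
                f"{res.chain_id or ' '}{res.seq_num:>4}{res.insertion_code or ' '}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
                f"          {atom.element:>2}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def link_residues(s: Structure, cutoff: float = PEPTIDE_LINK_CUTOFF) -> list[Segment]:
    """Segment a structure into peptide-bonded runs.

    Consecutive protein-like residues i, i+1 of one chain join a segment iff
    C(i) and N(i+1) both exist and are closer than ``cutoff``.  Non-protein
    residues (no N/CA/C) become singleton segments and never interrupt a
    peptide run interleaved in file order.
    """
    segments: list[tuple[int, ...]] = []
    run: list[int] = []

    def flush() -> None:
        nonlocal run
        if run:
            segments.append(tuple(run))
            run = []

    for idx, res in enumerate(s.residues):
        protein_like = any(res.get_atom(n) is not None for n in ("N", "CA", "C"))
        if not protein_like:
            segments.append((idx,))
            continue
        if run:
            prev = s.residues[run[-1]]
            linked = False
            if prev.chain_id == res.chain_id:
                c = prev.get_atom("C")
                n = res.get_atom("N")
                if c is not None and n is not None:
                    linked = float(np.linalg.norm(c.xyz - n.xyz)) < cutoff
            if not linked:
                flush()
        run.append(idx)
    flush()
    segments.sort(key=lambda t: t[0])
    return [Segment(s, t) for t in segments]
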