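"""The restrained-parameter vocabulary for the protein backbone.

Twelve parameters per residue: five bond lengths and seven bond angles.
Atom references use residue offsets: 0 is the owning residue, -1 the
preceding residue, +1 the following one.  Cross-residue parameters are named
from the owner's point of view: in ``C-N-CA`` the C belongs to the previous
residue (the angle sits at the owner's N); in ``C-N``, ``CA-C-N`` and
``O-C-N`` the N belongs to the next residue (the owner contributes the
carbonyl).  Glycine has no CB, so the three CB-involving parameters do not
apply to it.
"""

from __future__ import annotations

# param -> tuple of (residue offset, atom name)
PARAM_ATOMS: dict[str, tuple[tuple[int, str], ...]] = {
    # bond lengths (Angstrom)
    "N-CA": ((0, "N"), (0, "CA")),
    "CA-C": ((0, "CA"), (0, "C")),
    "C-O": ((0, "C"), (0, "O")),
    "CA-CB": ((0, "CA"), (0, "CB")),
    "C-N": ((0, "C"), (1, "N")),
    # bond angles (degrees)
    "C-N-CA": ((-1, "C"), (0, "N"), (0, "CA")),
    "N-CA-C": ((0, "N"), (0, "CA"), (0, "C")),
    "N-CA-CB": ((0, "N"), (0, "CA"), (0, "CB")),
    "CB-CA-C": ((0, "CB"), (0, "CA"), (0, "C")),
    "CA-C-O": ((0, "CA"), (0, "C"), (0, "O")),
    "CA-C-N": ((0, "CA"), (0, "C"), (1, "N")),
    "O-C-N": ((0, "O"), (0, "C"), (1, "N")),
}

LENGTH_PARAMS: tuple[str, ...] = ("N-CA", "CA-C", "C-O", "CA-CB", "C-N")
ANGLE_PARAMS: tuple[str, ...] = (
    "C-N-CA", "N-CA-C", "N-CA-CB", "CB-CA-C", "CA-C-O", "CA-C-N", "O-C-N",
)
ALL_PARAMS: tuple[str, ...] = LENGTH_PARAMS + ANGLE_PARAMS

CB_PARAMS: frozenset[str] = frozenset({"CA-CB", "N-CA-CB", "CB-CA-C"})

# Backbone-proper bonds (CA-CB points into the side chain).
BACKBONE_BOND_PARAMS: frozenset[str] = frozenset({"N-CA", "CA-C", "C-O", "C-N"})


def param_kind(param: str) -> str:
    """Return ``"length"`` or ``"angle"`` for a vocabulary parameter."""
    if param in LENGTH_PARAMS:
        return "length"
    if param in ANGLE_PARAMS:
        return "angle"
    raise KeyError(f"unknown parameter {param!r}")


def params_for(res_name: str) -> tuple[str, ...]:
    """Parameters applicable to a residue type (glycine omits CB parameters)."""
    if res_name == "GLY":
        return tuple(p for p in ALL_PARAMS if p not in CB_PARAMS)
    return ALL_PARAMS


def spans_next(param: str) -> bool:
    """True if the parameter involves an atom of the following residue."""
    return any(off == 1 for off, _ in PARAM_ATOMS[param])


def spans_prev(param: str) -> bool:
    """True if the parameter involves an atom of the preceding residue."""
    return any(off == -1 for off, _ in PARAM_ATOMS[param])
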