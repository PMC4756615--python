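"""The conformation-dependent library (CDL) lookup core.

A CDL maps (residue-class key, φ/ψ bin, parameter) to a restraint target
(mean, σ, observation count).  The residue-class key reduces the amino-acid
triplet (i−1, i, i+1) to the central residue's group — Gly, Pro, Ile/Val, or
General — plus a flag for a following proline, which perturbs the carbonyl
geometry of residue i.  φ/ψ space is tiled by half-open square bins
(default 10°).  Lookup is total: any miss falls back through progressively
more general keys and finally to the single-value library (SVL) slice, so
every standard residue in any conformational state receives exactly one
target.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple

from .errors import TableError
from .model_io import STANDARD_RESIDUES
from .params import ALL_PARAMS, CB_PARAMS, param_kind

GROUPS: tuple[str, ...] = ("Gly", "Pro", "IleVal", "General")

DEFAULT_BIN_WIDTH = 10.0
DEFAULT_MIN_COUNT = 20
DEFAULT_SIGMA_FLOOR_ANGLE = 0.5    # degrees
DEFAULT_SIGMA_FLOOR_LENGTH = 0.005  # Angstrom


def residue_group(res_name: str) -> str:
    """Residue-class group of a standard amino acid."""
    if res_name == "GLY":
        return "Gly"
    if res_name == "PRO":
        return "Pro"
    if res_name in ("ILE", "VAL"):
        return "IleVal"
    if res_name in STANDARD_RESIDUES:
        return "General"
    raise TableError(f"{res_name!r} is not a standard amino acid")


class CDLKey(NamedTuple):
    """Residue-class key: central residue's group and whether the next
    residue is proline."""

    group: str
    next_is_pro: bool


def assign_key(prev: str | None, cur: str, next: str | None) -> CDLKey | None:
    """Key for the (prev, cur, next) residue-name triplet; ``None`` signals
    a non-standard central residue (SVL-only)."""
    if cur not in STANDARD_RESIDUES:
        return None
    return CDLKey(residue_group(cur), next == "PRO")


class PhiPsiBin(NamedTuple):
    phi_lo: float
    psi_lo: float
    width: float


def bin_of(phi: float | None, psi: float | None, width: float = DEFAULT_BIN_WIDTH) -> PhiPsiBin | None:
    """Half-open φ/ψ bin [lo, lo+width)² containing the pair; ``None`` for an
    undefined angle (terminal residues)."""
    if phi is None or psi is None:
        return None
    return PhiPsiBin(width * math.floor(phi / width), width * math.floor(psi / width), width)


@dataclass(frozen=True)
class RestraintTarget:
    param: str
    mean: float
    sigma: float
    source: str  # "CDL" | "SVL"
    count: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise TableError(f"target for {self.param}: sigma must be positive")


@dataclass
class CDLTable:
    """Conformation-dependent targets plus the SVL fallback slice.

    ``entries`` maps (CDLKey, (phi_lo, psi_lo), param) to (mean, sigma,
    count); ``svl`` maps (group, param) to (mean, sigma) and must be total
    over the applicable (group, param) pairs so that lookup never fails.
    """

    entries: dict[tuple[CDLKey, tuple[float, float], str], tuple[float, float, int]] = field(
        default_factory=dict
    )
    svl: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    bin_width: float = DEFAULT_BIN_WIDTH
    min_count: int = DEFAULT_MIN_COUNT
    sigma_floor_angle: float = DEFAULT_SIGMA_FLOOR_ANGLE
    sigma_floor_length: float = DEFAULT_SIGMA_FLOOR_LENGTH
    provenance: str = ""

    def sigma_floor(self, param: str) -> float:
        return self.sigma_floor_angle if param_kind(param) == "angle" else self.sigma_floor_length

    def svl_target(self, group: str, param: str) -> RestraintTarget:
        try:
            mean, sigma = self.svl[(group, param)]
        except KeyError as exc:
            raise TableError(f"SVL slice missing ({group}, {param})") from exc
        return RestraintTarget(param, mean, sigma, "SVL", 0)


def required_svl_pairs() -> list[tuple[str, str]]:
    """(group, param) pairs the SVL slice must cover (glycine has no CB)."""
    out = []
    for group in GROUPS:
        for param in ALL_PARAMS:
            if group == "Gly" and param in CB_PARAMS:
                continue
            out.append((group, param))
    return out


def _unpack_pair(pair) -> tuple[float | None, float | None]:
    if pair is None:
        return None, None
    if hasattr(pair, "phi"):
        return pair.phi, pair.psi
    phi, psi = pair
    return phi, psi


def lookup(table: CDLTable, key: CDLKey | None, pair, param: str) -> RestraintTarget:
    """Retrieve the restraint target for one parameter instance.

    Fallback chain: (1) the exact (key, bin, param) cell if its count meets
    ``min_count``; (2) the same bin under the (General, next_is_pro) key;
    (3) the same bin under (General, False); (4) the SVL slice.  A missing
    key (non-standard residue) or an undefined φ or ψ goes directly to (4).
    """
    if param not in ALL_PARAMS:
        raise TableError(f"unknown parameter {param!r}")
    group = key.group if key is not None else "General"
    phi, psi = _unpack_pair(pair)
    if key is None or phi is None or psi is None:
        return table.svl_target(group, param)
    b = bin_of(phi, psi, table.bin_width)
    assert b is not None
    chain = [key, CDLKey("General", key.next_is_pro), CDLKey("General", False)]
    tried = set()
    for k in chain:
        if k in tried:
            continue
        tried.add(k)
        cell = table.entries.get((k, (b.phi_lo, b.psi_lo), param))
        if cell is not None and cell[2] >= table.min_count:
            mean, sigma, count = cell
            return RestraintTarget(param, mean, sigma, "CDL", count)
    return table.svl_target(group, param)


# ---------------------------------------------------------------------------
# Serialization: TSV (primary) and a JSON mirror with identical content.

_META_FIELDS = {
    "width": ("bin_width", float),
    "min_count": ("min_count", int),
    "sigma_floor_angle": ("sigma_floor_angle", float),
    "sigma_floor_length": ("sigma_floor_length", float),
    "provenance": ("provenance", str),
}

_HEADER = "key_group\tnext_is_pro\tphi_lo\tpsi_lo\tparam\tmean\tsigma\tcount"


def save_table(table: CDLTable) -> str:
    """Serialize a table to the TSV schema (``#meta`` lines, header, CDL rows,
    SVL rows with ``*`` placeholders).  Deterministic: rows are sorted."""
    lines = [
        f"#meta width={table.bin_width!r}",
        f"#meta min_count={table.min_count}",
        f"#meta sigma_floor_angle={table.sigma_floor_angle!r}",
        f"#meta sigma_floor_length={table.sigma_floor_length!r}",
    ]
    if table.provenance:
        lines.append(f"#meta provenance={table.provenance}")
    lines.append(_HEADER)
    for (key, (phi_lo, psi_lo), param), (mean, sigma, count) in sorted(
        table.entries.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
    ):
        lines.append(
            f"{key.group}\t{int(key.next_is_pro)}\t{phi_lo:g}\t{psi_lo:g}\t"
            f"{param}\t{mean!r}\t{sigma!r}\t{count}"
        )
    for (group, param), (mean, sigma) in sorted(table.svl.items()):
        lines.append(f"{group}\t*\t*\t*\t{param}\t{mean!r}\t{sigma!r}\t0")
    return "\n".join(lines) + "\n"


def save_table_json(table: CDLTable) -> str:
    """JSON mirror of the TSV schema."""
    doc = {
        "meta": {
            "width": table.bin_width,
            "min_count": table.min_count,
            "sigma_floor_angle": table.sigma_floor_angle,
            "sigma_floor_length": table.sigma_floor_length,
            "provenance": table.provenance,
        },
        "entries": [
            {
                "key_group": key.group,
                "next_is_pro": key.next_is_pro,
                "phi_lo": phi_lo,
                "psi_lo": psi_lo,
                "param": param,
                "mean": mean,
                "sigma": sigma,
                "count": count,
            }
            for (key, (phi_lo, psi_lo), param), (mean, sigma, count) in sorted(
                table.entries.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
            )
        ],
        "svl": [
            {"group": group, "param": param, "mean": mean, "sigma": sigma}
            for (group, param), (mean, sigma) in sorted(table.svl.items())
        ],
    }
    return json.dumps(doc, indent=1) + "\n"


def _validate_table(table: CDLTable) -> None:
    for (key, (phi_lo, psi_lo), param), (mean, sigma, count) in table.entries.items():
        if key.group not in GROUPS:
            raise TableError(f"unknown residue group {key.group!r}")
        if param not in ALL_PARAMS:
            raise TableError(f"unknown parameter {param!r}")
        if sigma <= 0:
            raise TableError(f"cell ({key}, {phi_lo}, {psi_lo}, {param}): sigma must be > 0")
        if count < 0:
            raise TableError(f"cell ({key}, {phi_lo}, {psi_lo}, {param}): negative count")
        for lo in (phi_lo, psi_lo):
            if not (-180.0 <= lo < 180.0):
                raise TableError(f"bin origin {lo} outside [-180, 180)")
            if abs(lo / table.bin_width - round(lo / table.bin_width)) > 1e-9:
                raise TableError(f"bin origin {lo} is not a multiple of width {table.bin_width}")
    missing = [
        pair for pair in required_svl_pairs() if pair not in table.svl
    ]
    if missing:
        raise TableError(f"SVL slice incomplete; missing: {missing}")
    for (group, param), (mean, sigma) in table.svl.items():
        if sigma <= 0:
            raise TableError(f"SVL ({group}, {param}): sigma must be > 0")


def load_table(content: str) -> CDLTable:
    """Parse TSV or JSON table content; integrity checks (σ > 0, bin tiling,
    SVL completeness) run here so that lookup never fails later."""
    stripped = content.lstrip()
    if stripped.startswith("{"):
        return _load_table_json(content)
    table = CDLTable(svl={})
    header_seen = False
    for lineno, raw in enumerate(content.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#meta"):
            body = line[len("#meta"):].strip()
            if "=" not in body:
                raise TableError(f"row {lineno}: malformed #meta line")
            k, v = body.split("=", 1)
            k = k.strip()
            if k in _META_FIELDS:
                attr, conv = _META_FIELDS[k]
                try:
                    setattr(table, attr, conv(v.strip()))
                except ValueError as exc:
                    raise TableError(f"row {lineno}: bad #meta value for {k}") from exc
            continue
        if line.startswith("#"):
            continue
        if not header_seen:
            if line.split("\t") != _HEADER.split("\t"):
                raise TableError(f"row {lineno}: expected header {_HEADER!r}")
            header_seen = True
            continue
        fields = line.split("\t")
        if len(fields) != 8:
            raise TableError(f"row {lineno}: expected 8 tab-separated fields")
        group, next_is_pro, phi_lo, psi_lo, param, mean, sigma, count = fields
        try:
            mean_f = float(mean)
            sigma_f = float(sigma)
        except ValueError as exc:
            raise TableError(f"row {lineno}: non-numeric mean/sigma") from exc
        if sigma_f <= 0:
            raise TableError(f"row {lineno}: sigma must be > 0")
        if phi_lo == "*":
            table.svl[(group, param)] = (mean_f, sigma_f)
        else:
            try:
                key = CDLKey(group, bool(int(next_is_pro)))
                cell = ((float(phi_lo), float(psi_lo)))
                count_i = int(count)
            except ValueError as exc:
                raise TableError(f"row {lineno}: malformed CDL row") from exc
            table.entries[(key, cell, param)] = (mean_f, sigma_f, count_i)
    if not header_seen:
        raise TableError("no table header found")
    _validate_table(table)
    return table


def _load_table_json(content: str) -> CDLTable:
    try:
        doc = json.loads(content)
    except json.JSONDecodeError as exc:
        raise TableError(f"invalid JSON table: {exc}") from exc
    meta = doc.get("meta", {})
    table = CDLTable(
        svl={},
        bin_width=float(meta.get("width", DEFAULT_BIN_WIDTH)),
        min_count=int(meta.get("min_count", DEFAULT_MIN_COUNT)),
        sigma_floor_angle=float(meta.get("sigma_floor_angle", DEFAULT_SIGMA_FLOOR_ANGLE)),
        sigma_floor_length=float(meta.get("sigma_floor_length", DEFAULT_SIGMA_FLOOR_LENGTH)),
        provenance=str(meta.get("provenance", "")),
    )
    for row in doc.get("entries", []):
        key = CDLKey(row["key_group"], bool(row["next_is_pro"]))
        table.entries[(key, (float(row["phi_lo"]), float(row["psi_lo"])), row["param"])] = (
            float(row["mean"]), float(row["sigma"]), int(row["count"])
        )
    for row in doc.get("svl", []):
        table.svl[(row["group"], row["param"])] = (float(row["mean"]), float(row["sigma"]))
    _validate_table(table)
    return table


def default_svl() -> dict[tuple[str, str], tuple[float, float]]:
    """The built-in SVL defaults shipped with the package."""
    text = resources.files("cdlkit").joinpath("data/svl_defaults.tsv").read_text()
    svl: dict[tuple[str, str], tuple[float, float]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#") or line.startswith("group\t"):
            continue
        group, param, mean, sigma = line.split("\t")
        svl[(group, param)] = (float(mean), float(sigma))
    return svl


def svl_only_table(**metadata) -> CDLTable:
    """A table with no conformation-dependent entries: every lookup resolves
    to the built-in SVL defaults (the cdl-off behaviour)."""
    table = CDLTable(entries={}, svl=default_svl(), **metadata)
    _validate_table(table)
    return table
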