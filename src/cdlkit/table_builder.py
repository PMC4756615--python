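"""Empirical derivation of a CDL table from a structure corpus.

Mirrors, at desk scale, how a conformation-dependent library is codified
from high-resolution structures: filter the corpus (resolution cutoff,
occupancy, B factor, single conformer, trans-flanked residues), measure the
backbone parameters, pool them per (residue-class key, φ/ψ bin, parameter),
trim outliers, and emit cells with enough observations.  The pooled
per-group statistics over the same observations form the table's SVL slice,
so the result is a self-contained library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import numpy as np

from .cdl_library import (
    CDLKey,
    CDLTable,
    DEFAULT_BIN_WIDTH,
    DEFAULT_MIN_COUNT,
    DEFAULT_SIGMA_FLOOR_ANGLE,
    DEFAULT_SIGMA_FLOOR_LENGTH,
    assign_key,
    bin_of,
    default_svl,
    residue_group,
)
from .errors import TableError
from .geometry import measure_backbone, segment_contexts
from .model_io import Structure, link_residues
from .params import param_kind


@dataclass
class BuilderConfig:
    """Corpus filter and table-derivation settings.

    Defaults: structures at 1.0 Å resolution or better; residues with full
    occupancy, B ≤ 30 Å², a single conformer and trans flanking peptide
    bonds; 10° bins; cells kept at ≥ 20 observations after two rounds of
    4σ trimming.
    """

    resolution_cutoff: float = 1.0
    max_b: float = 30.0
    min_occ: float = 1.0
    bin_width: float = DEFAULT_BIN_WIDTH
    min_count: int = DEFAULT_MIN_COUNT
    sigma_floor_angle: float = DEFAULT_SIGMA_FLOOR_ANGLE
    sigma_floor_length: float = DEFAULT_SIGMA_FLOOR_LENGTH
    trim_k: float = 4.0
    trim_rounds: int = 2

    def __post_init__(self) -> None:
        if self.trim_rounds < 0:
            raise ValueError("trim_rounds must be >= 0")
        for name in ("resolution_cutoff", "max_b", "min_occ", "bin_width", "trim_k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be positive")


_BACKBONE_ATOMS = ("N", "CA", "C", "O")


def _residue_passes(res, cfg: BuilderConfig) -> bool:
    altlocs = {a.altloc for a in res.atoms if a.altloc}
    if len(altlocs) > 1:
        return False
    for name in _BACKBONE_ATOMS:
        atom = res.get_atom(name)
        if atom is None:
            return False
        if atom.occupancy < cfg.min_occ or atom.b_factor > cfg.max_b:
            return False
    return True


def filter_corpus(
    structures: Iterable[Structure], cfg: BuilderConfig
) -> Iterator[tuple[Structure, list[int]]]:
    """Yield (structure, accepted residue indices) for structures passing the
    resolution cutoff.  Accepted residues are standard amino acids with
    clean, single-conformer backbones whose flanking peptide bonds are all
    trans; structures without resolution metadata are rejected outright."""
    for s in structures:
        if s.resolution is None or s.resolution > cfg.resolution_cutoff:
            continue
        accepted: list[int] = []
        for seg in link_residues(s):
            for ctx in segment_contexts(seg):
                res = s.residues[ctx.residue_index]
                if not ctx.is_standard:
                    continue
                if not _residue_passes(res, cfg):
                    continue
                omegas = [o for o in (ctx.omega_prev, ctx.omega_next) if o is not None]
                if any(o.cls != "trans" for o in omegas):
                    continue
                accepted.append(ctx.residue_index)
        yield s, accepted


class KeyedObservation(NamedTuple):
    key: CDLKey
    cell: tuple[float, float]  # (phi_lo, psi_lo)
    group: str
    param: str
    value: float


def keyed_observations(
    s: Structure, accepted: list[int], cfg: BuilderConfig
) -> Iterator[KeyedObservation]:
    """Measured backbone parameters of accepted residues with defined φ/ψ,
    keyed for accumulation."""
    accepted_set = set(accepted)
    for seg in link_residues(s):
        contexts = {c.residue_index: c for c in segment_contexts(seg)}
        for obs in measure_backbone(seg):
            ctx = contexts[obs.residue_index]
            if obs.residue_index not in accepted_set:
                continue
            if not ctx.pair.defined:
                continue
            key = assign_key(ctx.prev_name, ctx.name, ctx.next_name)
            if key is None:
                continue
            b = bin_of(ctx.pair.phi, ctx.pair.psi, cfg.bin_width)
            assert b is not None
            yield KeyedObservation(
                key, (b.phi_lo, b.psi_lo), residue_group(ctx.name), obs.param, obs.value
            )


@dataclass
class BinAccumulator:
    """Running statistics for one (key, bin, param) cell: Welford mean/M2
    for the one-pass statistics, plus the retained values needed for the
    trimming pass."""

    count: int = 0
    mean: float = 0.0
    m2: float = 0.0
    values: list[float] = field(default_factory=list)

    def add(self, value: float) -> None:
        self.count += 1
        delta = value - self.mean
        self.mean += delta / self.count
        self.m2 += delta * (value - self.mean)
        self.values.append(value)

    @property
    def variance(self) -> float:
        """Sample variance (ddof=1)."""
        return self.m2 / (self.count - 1) if self.count > 1 else 0.0


def accumulate(
    observations: Iterable[KeyedObservation],
) -> dict[tuple[CDLKey, tuple[float, float], str], BinAccumulator]:
    """Pool observations per cell with stable one-pass updates."""
    acc: dict[tuple[CDLKey, tuple[float, float], str], BinAccumulator] = {}
    for obs in observations:
        acc.setdefault((obs.key, obs.cell, obs.param), BinAccumulator()).add(obs.value)
    return acc


def _trim(values: np.ndarray, k: float, rounds: int) -> np.ndarray:
    for _ in range(rounds):
        if len(values) < 2:
            break
        mean = values.mean()
        sigma = values.std(ddof=1)
        if sigma == 0:
            break
        keep = np.abs(values - mean) <= k * sigma
        if keep.all():
            break
        values = values[keep]
    return values


def finalize(
    acc: dict[tuple[CDLKey, tuple[float, float], str], BinAccumulator],
    cfg: BuilderConfig,
    base_svl: dict[tuple[str, str], tuple[float, float]] | None = None,
) -> CDLTable:
    """Trim, threshold and assemble the final table.

    Per cell: ``trim_rounds`` rounds of ``trim_k``·σ trimming, then emit the
    cell iff the surviving count meets ``min_count``, with σ clamped up to
    the floor.  The SVL slice pools the post-trim values of *all* cells
    (including sub-threshold ones) per (group, param); groups absent from
    the corpus are filled from ``base_svl`` (default: the shipped SVL
    defaults) so lookup stays total.
    """
    if not acc:
        raise TableError("empty corpus: no accepted observations to build a table from")
    table = CDLTable(
        entries={},
        svl={},
        bin_width=cfg.bin_width,
        min_count=cfg.min_count,
        sigma_floor_angle=cfg.sigma_floor_angle,
        sigma_floor_length=cfg.sigma_floor_length,
        provenance="cdlkit.table_builder",
    )
    pooled: dict[tuple[str, str], list[np.ndarray]] = {}
    for (key, cell, param), a in sorted(
        acc.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
    ):
        values = _trim(np.asarray(a.values, dtype=float), cfg.trim_k, cfg.trim_rounds)
        pooled.setdefault((key.group, param), []).append(values)
        if len(values) < cfg.min_count:
            continue
        floor = (
            cfg.sigma_floor_angle if param_kind(param) == "angle" else cfg.sigma_floor_length
        )
        sigma = max(float(values.std(ddof=1)), floor)
        table.entries[(key, cell, param)] = (float(values.mean()), sigma, int(len(values)))

    for (group, param), chunks in pooled.items():
        values = np.concatenate(chunks)
        if len(values) == 0:
            continue
        floor = (
            cfg.sigma_floor_angle if param_kind(param) == "angle" else cfg.sigma_floor_length
        )
        sigma = max(float(values.std(ddof=1)) if len(values) > 1 else floor, floor)
        table.svl[(group, param)] = (float(values.mean()), sigma)

    fill = base_svl if base_svl is not None else default_svl()
    for pair, target in fill.items():
        table.svl.setdefault(pair, target)
    return table


def build_table(structures: Iterable[Structure], cfg: BuilderConfig | None = None) -> CDLTable:
    """Filter → measure → accumulate → finalize, in one call."""
    cfg = cfg or BuilderConfig()

    def stream() -> Iterator[KeyedObservation]:
        for s, accepted in filter_corpus(structures, cfg):
            yield from keyed_observations(s, accepted, cfg)

    return finalize(accumulate(stream()), cfg)


def cell_histogram(
    acc: dict[tuple[CDLKey, tuple[float, float], str], BinAccumulator]
) -> list[tuple[str, bool, float, float, str, int]]:
    """Per-cell observation counts (for the build-table report)."""
    return [
        (key.group, key.next_is_pro, cell[0], cell[1], param, a.count)
        for (key, cell, param), a in sorted(
            acc.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
        )
    ]
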