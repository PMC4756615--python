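"""Validation of structures against CDL and SVL targets.

For every measured backbone parameter the deviation is computed twice —
against the conformation-dependent target (with its trans-peptide gating
and fallback) and against the single-value target — giving directly
comparable RMSDs, the "CDL-unique" subset restricted to angles whose
targets actually differ between the two libraries, and counts of k·σ
outliers (default 6σ, judged against the σ of the library being validated
against).  Per-structure reports can be averaged in half-open resolution
bins, with thin bins flagged low-confidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cdl_library import CDLTable, residue_group
from .geometry import conformer_ids, measure_backbone, segment_contexts
from .model_io import Structure, link_residues
from .params import BACKBONE_BOND_PARAMS, param_kind
from .restraints import target_for


@dataclass
class ValidationConfig:
    outlier_k: float = 6.0
    resolution_bin_width: float = 0.1
    min_bin_n: int = 50

    def __post_init__(self) -> None:
        if self.outlier_k <= 0 or self.resolution_bin_width <= 0 or self.min_bin_n <= 0:
            raise ValueError("validation config values must be positive")


@dataclass
class LibraryStats:
    """Validation statistics of one structure against one target library."""

    rmsd_angles_all: float = float("nan")
    rmsd_angles_cdl_unique: float = float("nan")
    rmsd_bonds_all: float = float("nan")
    rmsd_bonds_backbone: float = float("nan")
    n_angle_outliers: int = 0
    n_bond_outliers: int = 0
    n_angles: int = 0
    n_bonds: int = 0
    n_cdl_unique_angles: int = 0


STAT_FIELDS = (
    "rmsd_angles_all", "rmsd_angles_cdl_unique", "rmsd_bonds_all",
    "rmsd_bonds_backbone", "n_angle_outliers", "n_bond_outliers",
)


@dataclass
class ValidationReport:
    structure_id: str
    resolution: float | None
    per_library: dict[str, LibraryStats]
    detail: pd.DataFrame = field(repr=False, default=None)


def _rmsd(values: list[float]) -> float:
    if not values:
        return float("nan")
    return float(np.sqrt(np.mean(np.square(values))))


def validate(
    s: Structure, table: CDLTable, cfg: ValidationConfig | None = None
) -> ValidationReport:
    """Score one structure against both libraries of ``table``.

    The CDL column uses the gated conformation-dependent lookup (cis-linked
    and terminal residues resolve to SVL, exactly as restraint generation
    would assign them); the SVL column uses the single-value slice
    throughout.  ``detail`` carries one row per observation for downstream
    aggregation.
    """
    cfg = cfg or ValidationConfig()
    rows = []
    for seg in link_residues(s):
        for altloc in conformer_ids(seg):
            contexts = {c.residue_index: c for c in segment_contexts(seg, altloc)}
            for obs in measure_backbone(seg, altloc):
                ctx = contexts[obs.residue_index]
                cdl_t = target_for(table, ctx, obs.param, "CDL")
                svl_t = target_for(table, ctx, obs.param, "SVL")
                rows.append(
                    {
                        "residue_index": obs.residue_index,
                        "altloc": altloc,
                        "param": obs.param,
                        "kind": obs.kind,
                        "value": obs.value,
                        "cdl_mean": cdl_t.mean,
                        "cdl_sigma": cdl_t.sigma,
                        "cdl_source": cdl_t.source,
                        "svl_mean": svl_t.mean,
                        "svl_sigma": svl_t.sigma,
                        "cdl_unique": abs(cdl_t.mean - svl_t.mean) > 1e-9
                        or abs(cdl_t.sigma - svl_t.sigma) > 1e-9,
                        "backbone_bond": obs.param in BACKBONE_BOND_PARAMS,
                    }
                )
    detail = pd.DataFrame(rows)
    report = ValidationReport(s.id, s.resolution, {}, detail)
    for lib in ("CDL", "SVL"):
        stats = LibraryStats()
        if not detail.empty:
            dev = detail["value"] - detail[f"{lib.lower()}_mean"]
            sigma = detail[f"{lib.lower()}_sigma"]
            angles = detail["kind"] == "angle"
            bonds = ~angles
            unique = detail["cdl_unique"] & angles
            stats.rmsd_angles_all = _rmsd(dev[angles].tolist())
            stats.rmsd_angles_cdl_unique = _rmsd(dev[unique].tolist())
            stats.rmsd_bonds_all = _rmsd(dev[bonds].tolist())
            stats.rmsd_bonds_backbone = _rmsd(dev[bonds & detail["backbone_bond"]].tolist())
            outlier = dev.abs() > cfg.outlier_k * sigma
            stats.n_angle_outliers = int((outlier & angles).sum())
            stats.n_bond_outliers = int((outlier & bonds).sum())
            stats.n_angles = int(angles.sum())
            stats.n_bonds = int(bonds.sum())
            stats.n_cdl_unique_angles = int(unique.sum())
        report.per_library[lib] = stats
    return report


@dataclass
class ResolutionSummary:
    """Per-resolution-bin means of validation statistics."""

    table: pd.DataFrame
    n_excluded: int  # reports without resolution metadata


def summarize_by_resolution(
    reports: list[ValidationReport], cfg: ValidationConfig | None = None
) -> ResolutionSummary:
    """Average per-structure statistics in half-open resolution bins.

    Bins with fewer than ``min_bin_n`` structures are kept but flagged
    ``low_confidence``; reports lacking resolution metadata are excluded and
    counted."""
    cfg = cfg or ValidationConfig()
    rows = []
    n_excluded = 0
    for rep in reports:
        if rep.resolution is None:
            n_excluded += 1
            continue
        w = cfg.resolution_bin_width
        bin_lo = w * math.floor(rep.resolution / w)
        row = {"bin_lo": round(bin_lo, 9)}
        for lib, stats in rep.per_library.items():
            for f in STAT_FIELDS:
                row[f"{lib}_{f}"] = getattr(stats, f)
        rows.append(row)
    if not rows:
        return ResolutionSummary(pd.DataFrame(), n_excluded)
    df = pd.DataFrame(rows)
    grouped = df.groupby("bin_lo", sort=True).agg(["mean", "size"])
    out = pd.DataFrame(index=grouped.index)
    for col in df.columns:
        if col == "bin_lo":
            continue
        out[col] = grouped[(col, "mean")]
    out["n_structures"] = grouped[(df.columns[1], "size")]
    out["low_confidence"] = out["n_structures"] < cfg.min_bin_n
    return ResolutionSummary(out.reset_index(), n_excluded)


def compare_libraries(report: ValidationReport) -> dict[str, float]:
    """Per-category deltas rmsd(SVL) − rmsd(CDL) and outlier-count deltas;
    positive values mean the structure sits closer to the CDL targets."""
    cdl = report.per_library["CDL"]
    svl = report.per_library["SVL"]

    def delta(a: float, b: float) -> float:
        # an empty category (NaN under both libraries) has zero difference
        if math.isnan(a) and math.isnan(b):
            return 0.0
        return a - b

    return {
        "delta_rmsd_angles_all": delta(svl.rmsd_angles_all, cdl.rmsd_angles_all),
        "delta_rmsd_angles_cdl_unique": delta(
            svl.rmsd_angles_cdl_unique, cdl.rmsd_angles_cdl_unique
        ),
        "delta_rmsd_bonds_all": delta(svl.rmsd_bonds_all, cdl.rmsd_bonds_all),
        "delta_rmsd_bonds_backbone": delta(svl.rmsd_bonds_backbone, cdl.rmsd_bonds_backbone),
        "delta_n_angle_outliers": svl.n_angle_outliers - cdl.n_angle_outliers,
        "delta_n_bond_outliers": svl.n_bond_outliers - cdl.n_bond_outliers,
    }
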