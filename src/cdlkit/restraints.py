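"""Weighted harmonic geometry restraints and macrocycle idealization.

Each restrained parameter instance becomes a harmonic term with weight 1/σ²
taken from its target's standard deviation, so tighter targets pull harder.
The objective is

    E = overall_weight · Σ_r ((value_r − mean_r) / σ_r)²

over bond-length and bond-angle terms.  ``idealize`` runs macrocycles: at
the start of each, targets are re-looked-up from the *current* φ/ψ/ω (the
conformation-dependent update), then held fixed while E is minimized over
Cartesian coordinates with analytic gradients.

Trans-peptide gating: in CDL mode a residue's parameters receive
conformation-dependent targets only when its φ and ψ are defined and both
flanking peptide bonds are trans; cis and twisted linkages, chain termini
and non-standard residues fall back to the single-value library.  SVL mode
forces single-value targets everywhere (the cdl-off switch).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .cdl_library import CDLTable, RestraintTarget, assign_key, lookup, residue_group
from .errors import GeometryError
from .geometry import ResidueContext, bond_angle, distance, segment_contexts
from .model_io import Structure, link_residues
from .params import PARAM_ATOMS, params_for


def target_for(
    table: CDLTable, ctx: ResidueContext, param: str, mode: str = "CDL"
) -> RestraintTarget:
    """Resolve the target for one parameter instance under the gating rules."""
    if mode not in ("CDL", "SVL"):
        raise ValueError(f"mode must be 'CDL' or 'SVL', got {mode!r}")
    group = residue_group(ctx.name) if ctx.is_standard else "General"
    if mode == "SVL" or not ctx.is_standard:
        return table.svl_target(group, param)
    key = assign_key(ctx.prev_name, ctx.name, ctx.next_name)
    if key is None or not ctx.pair.defined or not ctx.flanks_trans:
        return table.svl_target(group, param)
    return lookup(table, key, ctx.pair, param)


@dataclass(frozen=True)
class Restraint:
    param: str
    atom_indices: tuple[int, ...]  # indices into Structure.flat_atoms()
    atom_labels: tuple[tuple[int, str], ...]  # (residue_index, atom_name)
    target: RestraintTarget
    residue_index: int
    altloc: str = ""

    @property
    def weight(self) -> float:
        return 1.0 / self.target.sigma**2


@dataclass
class RestraintSet:
    restraints: list[Restraint]
    overall_weight: float = 1.0
    mode: str = "CDL"


@dataclass
class ResidualReport:
    """Per-restraint deviations and the weighted objective."""

    deviations: list[float]  # natural units (value - mean)
    sigma_deviations: list[float]  # (value - mean) / sigma
    skipped: list[Restraint]
    energy: float


def _atom_index_map(s: Structure) -> dict[tuple[int, str, str], int]:
    idx = {}
    flat = 0
    for ri, res in enumerate(s.residues):
        for atom in res.atoms:
            idx[(ri, atom.name, atom.altloc)] = flat
            flat += 1
    return idx


def generate_restraints(
    s: Structure,
    table: CDLTable,
    mode: str = "CDL",
    overall_weight: float = 1.0,
) -> RestraintSet:
    """Build the restraint set for every measurable parameter instance.

    Altloc conformers each get their own restraint stream; blank-altloc
    atoms are shared.  Parameters with missing atoms are simply absent.
    """
    from .geometry import conformer_ids

    index = _atom_index_map(s)
    restraints: list[Restraint] = []
    for seg in link_residues(s):
        for altloc in conformer_ids(seg):
            for ctx in segment_contexts(seg, altloc):
                res = s.residues[ctx.residue_index]
                for param in params_for(res.res_name):
                    spec = PARAM_ATOMS[param]
                    indices = []
                    labels = []
                    ok = True
                    for off, name in spec:
                        li = ctx.local_index + off
                        if li < 0 or li >= len(seg):
                            ok = False
                            break
                        nres_idx = seg.indices[li]
                        atom = s.residues[nres_idx].get_atom(name, altloc)
                        if atom is None:
                            ok = False
                            break
                        indices.append(index[(nres_idx, atom.name, atom.altloc)])
                        labels.append((nres_idx, name))
                    if not ok:
                        continue
                    target = target_for(table, ctx, param, mode)
                    restraints.append(
                        Restraint(
                            param, tuple(indices), tuple(labels), target,
                            ctx.residue_index, altloc,
                        )
                    )
    return RestraintSet(restraints, overall_weight, mode)


def evaluate(s: Structure, rs: RestraintSet) -> ResidualReport:
    """Residuals of the current coordinates against the set's targets."""
    coords = np.array([a.xyz for a in s.flat_atoms()])
    n = coords.shape[0]
    devs: list[float] = []
    sdevs: list[float] = []
    skipped: list[Restraint] = []
    energy = 0.0
    for r in rs.restraints:
        if any(i >= n for i in r.atom_indices):
            skipped.append(r)
            continue
        pts = coords[list(r.atom_indices)]
        value = distance(pts[0], pts[1]) if len(pts) == 2 else bond_angle(*pts)
        dev = value - r.target.mean
        devs.append(dev)
        sdevs.append(dev / r.target.sigma)
        energy += (dev / r.target.sigma) ** 2
    return ResidualReport(devs, sdevs, skipped, rs.overall_weight * energy)


def update_targets(s: Structure, rs: RestraintSet, table: CDLTable) -> RestraintSet:
    """Re-look-up every target from the structure's current φ/ψ/ω (the
    per-macrocycle update).  Idempotent at fixed coordinates; restraints
    whose trans/cis gating changed switch source accordingly."""
    return generate_restraints(s, table, rs.mode, rs.overall_weight)


# ---------------------------------------------------------------------------
# Analytic gradients

_RAD = np.pi / 180.0


def _distance_term(p, q):
    d = p - q
    r = np.linalg.norm(d)
    if r < 1e-12:
        raise GeometryError("coincident atoms in distance restraint")
    g = d / r
    return r, (g, -g)


def _angle_term(p, q, r):
    u = p - q
    v = r - q
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise GeometryError("zero-length ray in angle restraint")
    uh = u / nu
    vh = v / nv
    c = float(np.clip(np.dot(uh, vh), -1.0, 1.0))
    s = np.sqrt(max(1.0 - c * c, 1e-16))
    theta = np.degrees(np.arccos(c))
    # d(theta_rad)/dx, converted to degrees
    gp = (c * uh - vh) / (nu * s) / _RAD
    gr = (c * vh - uh) / (nv * s) / _RAD
    gq = -(gp + gr)
    return theta, (gp, gq, gr)


def energy_and_grad(coords: np.ndarray, rs: RestraintSet) -> tuple[float, np.ndarray]:
    """Objective E and its analytic gradient with respect to coordinates."""
    coords = coords.reshape(-1, 3)
    grad = np.zeros_like(coords)
    energy = 0.0
    for r in rs.restraints:
        pts = [coords[i] for i in r.atom_indices]
        if len(pts) == 2:
            value, gs = _distance_term(*pts)
        else:
            value, gs = _angle_term(*pts)
        dev = value - r.target.mean
        w = 1.0 / r.target.sigma**2
        energy += w * dev * dev
        coeff = 2.0 * w * dev
        for i, g in zip(r.atom_indices, gs):
            grad[i] += coeff * g
    energy *= rs.overall_weight
    grad *= rs.overall_weight
    return energy, grad.ravel()


def idealize(
    s: Structure,
    table: CDLTable,
    mode: str = "CDL",
    macrocycles: int = 5,
    overall_weight: float = 1.0,
    gtol: float = 1e-10,
    maxiter: int = 1000,
) -> tuple[Structure, list[dict]]:
    """Idealize geometry against the library over ``macrocycles`` outer
    iterations.

    Each macrocycle re-derives targets from the current coordinates, then
    minimizes E with targets fixed (L-BFGS with analytic gradients).
    Returns the final structure and a per-macrocycle trace with the starting
    and ending objective plus the objective at every accepted iterate.
    """
    if macrocycles < 1:
        raise ValueError("macrocycles must be >= 1")
    out = s.copy()
    trace: list[dict] = []
    for cycle in range(macrocycles):
        rs = generate_restraints(out, table, mode, overall_weight)
        x0 = np.array([a.xyz for a in out.flat_atoms()]).ravel()

        def fun(x, _rs=rs):
            e, g = energy_and_grad(x, _rs)
            if not np.isfinite(e) or not np.all(np.isfinite(g)):
                raise GeometryError(f"non-finite objective in macrocycle {cycle}")
            return e, g

        iterates: list[float] = []

        def callback(xk, _rs=rs):
            iterates.append(energy_and_grad(xk, _rs)[0])

        e_start = fun(x0)[0]
        res = minimize(
            fun, x0, jac=True, method="L-BFGS-B", callback=callback,
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-14},
        )
        if not np.isfinite(res.fun):
            raise GeometryError(f"minimizer diverged in macrocycle {cycle}")
        out.set_coordinates(res.x.reshape(-1, 3))
        trace.append(
            {
                "macrocycle": cycle,
                "e_start": float(e_start),
                "e_end": float(res.fun),
                "n_iter": int(res.nit),
                "iterates": iterates,
            }
        )
    return out, trace
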