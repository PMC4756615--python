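# Methods

This note documents the models, conventions and numerical choices behind
`cdlkit`, in the order data flows through the package.

## Coordinate model and segmentation

Structures are ordered lists of residues holding named atoms with
Cartesian coordinates (Å), altloc identifiers, occupancies and B factors
(Å²); the crystallographic resolution is read from `REMARK   2` when
present. The reader is a strict fixed-column PDB v3.3 parser: malformed
ATOM/HETATM records fail with the offending line number, and multi-model
files are refused unless a model is selected explicitly — silent selection
of the first model hides errors. HETATM amino acids (e.g. MSE) are carried
through but flagged non-standard; they never receive conformation-dependent
targets.

Chains are segmented into peptide-bonded runs by the C(i)–N(i+1) distance:
consecutive residues join a segment iff both atoms exist and are closer
than 2.0 Å (comfortably above the ~1.33 Å bond, below any non-bonded
approach; configurable). A chain-id change always breaks a segment.
Residues with no backbone atoms at all (waters, ligands) become singleton
segments and do not interrupt a peptide run even when interleaved in file
order.

## Measured parameters and torsions

Twelve backbone parameters are restrained and measured per residue — five
bond lengths (N–CA, CA–C, C–O, CA–CB, C–N(+1)) and seven bond angles
(C(−1)–N–CA, N–CA–C, N–CA–CB, CB–CA–C, CA–C–O, CA–C–N(+1), O–C–N(+1)).
Cross-residue parameters are owned by the residue whose unprimed atoms
they contain: the carbonyl-side parameters (C–N, CA–C–N, O–C–N) belong to
the residue contributing C/CA/O, while C(−1)–N–CA belongs to the residue
contributing N and CA. This puts every parameter under the φ/ψ of the
residue whose conformation physically determines it. Glycine has no CB, so
the three CB parameters do not apply to it; proline is measured like any
other residue.

Torsions follow the IUPAC 1970 convention (clockwise positive looking down
the central bond; trans = ±180°) and are reported in the half-open range
[−180, 180) with +180 mapped to −180, which makes φ/ψ binning unambiguous.
φ(i) = C(i−1)–N(i)–CA(i)–C(i), ψ(i) = N(i)–CA(i)–C(i)–N(i+1),
ω(i→i+1) = CA(i)–C(i)–N(i+1)–CA(i+1). Peptide bonds are classified trans
(|ω| ≥ 150°), cis (|ω| ≤ 30°) or twisted (between); the cutoffs are
conventions and configurable. A missing backbone atom marks the affected
torsions undefined rather than raising.

Alternate locations: torsions and observations are computed per altloc
conformer, matching atoms by altloc id with blank-altloc atoms shared
across conformers; each conformer yields its own observation and restraint
stream. No averaging across conformers is ever performed.

## The lookup model

A CDL table maps (residue-class key, φ/ψ bin, parameter) →
(mean, σ, count). The key reduces the residue triplet (i−1, i, i+1) to the
central residue's group — Gly, Pro, Ile/Val or General — plus a flag for a
following proline, which perturbs the carbonyl geometry of residue i. The
preceding residue needs no slot of its own: the parameters that span the
(i−1)→i bond are owned by residue i−1 and therefore keyed by *its* class.
This keeps the key space small enough for desk-scale tables while
preserving the class structure conformation-dependent libraries use.

φ/ψ space is tiled by half-open square bins, `lo = width·floor(angle/width)`,
default width 10°. Lookup falls back in order: (1) the exact (key, bin,
parameter) cell if its count reaches `min_count` (default 20); (2) the same
bin under (General, next-is-Pro); (3) the same bin under (General, False);
(4) the single-value (SVL) slice. Undefined φ or ψ (termini, missing atoms)
and non-standard residues go directly to (4), so lookup is total by
construction — table integrity (σ > 0, bin alignment, SVL completeness) is
checked at load time, never at lookup time. Bins are step-wise; no
interpolation is performed between them (a possible extension, deliberately
not implemented).

The shipped SVL defaults are conventional per-group single values in the
Engh & Huber spirit (round-number means and σ, with the three carbonyl
angles of each group summing to 360°); they are an editable TSV, not a
reproduction of any published library's exact content.

## Empirical table derivation

The builder mirrors, at desk scale, how such libraries are codified from
high-resolution structures. Corpus filter: structures must carry resolution
metadata and pass the cutoff (default ≤ 1.0 Å; structures without metadata
are excluded rather than assumed good). Within accepted structures a
residue contributes only if it is a standard amino acid with all backbone
atoms at occupancy ≥ 1.0 and B ≤ 30 Å², a single conformer, and all
existing flanking peptide bonds trans. Observations with undefined φ/ψ are
dropped (they could not be binned).

Accumulation is a one-pass Welford update per (key, bin, parameter) cell;
per-cell value lists are retained so that trimming is exact (a two-pass
design rather than a streaming approximation — exactness and testability
matter more than memory at this scale). Finalization applies `trim_rounds`
(default 2) rounds of `trim_k`·σ (default 4σ) trimming — empirical
libraries need outlier rejection even though the procedure is a design
choice here, so it is default-on and disable-able — then emits cells whose
surviving count reaches `min_count`, with σ clamped up to a floor (0.5° for
angles, 0.005 Å for lengths) so no restraint can become pathologically
stiff. The SVL slice is the conformation-pooled per-group mean/σ over the
post-trim values of all cells, including sub-threshold ones; groups absent
from the corpus are filled from the shipped defaults so the resulting
table keeps lookup total. With trimming disabled the SVL slice equals the
count-weighted mean of cell means exactly (tested to 1e-6).

## Restraints and idealization

Each measurable parameter instance becomes a harmonic restraint with
weight 1/σ² from its target, so tighter targets pull harder; the objective
is E = overall_weight · Σ((x − μ)/σ)². `overall_weight` is a plain
user-facing scalar (default 1.0); no automatic weight optimization and no
crystallographic term are implemented — the objective is purely geometric,
and there are no non-bonded, torsional or planarity terms. `idealize` is a
demonstration of the conformation-dependent update loop, not a full
regularizer.

Gating: in CDL mode a residue's parameters receive conformation-dependent
targets only when its φ and ψ are defined and both flanking peptide bonds
are trans; twisted ω is treated as non-trans and falls back to SVL. A cis
bond therefore forces single-value targets for both residues it links
(their φ/ψ context involves that bond) and nothing else. SVL mode forces
single-value targets everywhere — the cdl-off switch.

Idealization runs macrocycles: targets are re-looked-up from the current
coordinates at the start of each macrocycle (bins chosen by the half-open
rule at those coordinates; no hysteresis at bin boundaries), then held
fixed while E is minimized over Cartesian coordinates by L-BFGS with
analytic gradients (the standard length/angle derivative formulas; angle
gradients guarded by clamping sin θ away from zero at 1e-8). Freezing
targets within a macrocycle keeps each inner problem a smooth well-defined
minimization. Convergence uses gradient tolerance 1e-10 and up to 1000
iterations per macrocycle; analytic gradients agree with central finite
differences (step 1e-6 Å) to better than 1e-5 relative. Because all terms
depend on internal coordinates only, E is exactly invariant under
rigid-body motion; the minimum E = 0 is attainable for a chain because the
restrained parameters are independent internal coordinates (the three
carbonyl angles can all be met since nothing forces the carbonyl carbon
planar in Cartesian space).

## Validation

Every observation is scored against two targets at once: the gated CDL
lookup (cis-linked and terminal residues resolve to SVL exactly as
restraint generation would assign them) and the SVL slice. Reported per
structure: angle and bond RMSDs, the "CDL-unique" subset (angles whose
targets differ between the libraries beyond 1e-9), backbone-bond RMSD
(excluding CA–CB, which points into the side chain), and counts of
deviations beyond k·σ (default 6σ). The outlier σ is that of the library
being validated against — the natural reading of per-library outlier
plots. RMSDs are per-structure (observations pooled within a structure);
resolution summaries then average structures in half-open 0.1 Å bins,
flagging bins with fewer than 50 structures as low-confidence. Structures
with no defined φ/ψ anywhere yield SVL-only statistics and an empty
CDL-unique category, which is treated as a zero difference when comparing
libraries.

## Synthetic data

`build_peptide` constructs backbones from internal coordinates by natural
extension (each atom placed from three predecessors at prescribed length,
angle, torsion). Placement order is N → CA → C per residue; the next N is
placed with torsion ψ, the next CA with ω, the next C with φ. The carbonyl
O is placed at torsion ψ + 180°, which makes the carbonyl carbon exactly
planar — O–C–N(+1) is therefore derived (360° − CA–C–O − CA–C–N), not an
independent input. CB is placed to satisfy N–CA–CB and CB–CA–C
simultaneously by solving the improper torsion from the spherical law of
cosines, taking the negative branch (≈ −120° for tetrahedral angles),
which is the L-amino-acid chirality of ideal residue templates. At zero
noise the construction is exact: re-measuring reproduces every
constructive internal and every defined torsion to ~1e-13, the round trip
that anchors the test suite.

`simulate_corpus` draws per-residue (φ, ψ) from a sampling scheme (default:
helical and sheet Gaussian clusters at (−63, −43) and (−120, 130), σ = 12°,
truncated to range — a test convenience, configurable), evaluates true
parameter means μ(φ, ψ), adds Gaussian observation noise, builds each
structure exactly at those values, and records every draw in a manifest.
The default conditions give N–CA–C a smooth conformation-dependent surface,
111 + 5·sin φ·cos ψ degrees with 1.2° noise — variation of the size seen in
high-resolution structures — while other parameters stay at single values.
All randomness flows from a single seed.

What the generator does *not* emulate: real side chains beyond CB,
correlated parameter deviations, resolution-dependent coordinate error
models, packing, hydrogens, and alternate conformations. Passing tests
therefore demonstrate that the mechanism — measurement, binning,
derivation, per-macrocycle updating, gated lookup, dual-library scoring —
is correct and self-consistent, not that any particular numerical table
matches libraries derived from real crystal structures.

## Problem sizes and determinism

The recovery experiment uses 450 structures of length 12 sampled uniformly
over a 4×4-bin region, giving ≥ 200 accepted observations per populated
bin — enough that the 3·σ/√n bin-mean criterion is a ~0.25° test and the
per-bin σ estimate has ~5% standard error. The idealization experiment uses
a 10-mer perturbed by 0.02 Å over 5 macrocycles; the cohort comparison
uses eight 6-mers over 3 macrocycles. Identical corpus, configuration and
seed produce byte-identical saved tables; all CLI subcommands are
bit-reproducible under `--seed`.

## Known limitations

* Cis-peptide and side-chain conformation dependence are out of scope; cis
  linkages always fall back to single values.
* No mmCIF input, anisotropic B, symmetry or multi-model handling beyond
  explicit model selection.
* The idealizer restrains lengths and angles only; torsions are free to
  drift slightly between macrocycles, which is why targets are refreshed.
* Step-wise bins introduce target discontinuities at bin boundaries during
  idealization; with per-macrocycle freezing this is benign but visible as
  small objective jumps between macrocycles.
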