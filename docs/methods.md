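# Methods

## The triad model

A catalytic triad candidate is a triple of positions (Ser, His, Asp|Glu) on
a fixed backbone, together with the side-chain conformations that realise a
serine-hydrolase-like hydrogen-bond network. The network is measured on
explicit geometry:

- **d(Ser–His)** — distance from Ser OG to the His imidazole nitrogen
  facing Ser. The facing nitrogen (NE2 or ND1) is a per-candidate choice:
  both tautomers are searched as separate branches and folded into one
  unique triad at deduplication. The opposite nitrogen is taken as
  protonated and faces the acid.
- **d(His–acid)** — distance from the His polar hydrogen (HD1 or HE2,
  constructed in the ring plane on the external bisector of the two ring
  neighbours, N–H 1.01 Å) to the nearest carboxylate oxygen (OD1/OD2 or
  OE1/OE2; the pair is chemically symmetric, so the minimum is taken).
- **ang(Ser)** — the OG–HG–N angle at the hydroxyl hydrogen. The Ser HG is
  rotatable, so it is sampled on the same grid as the chi angles
  (O–H 0.96 Å, C–O–H 109.5°) with *any-placement-satisfies* semantics: a
  pair passes if at least one HG placement puts the angle inside the
  window, and the best in-window placement (largest angle) is reported.
- **ang(His)** — the N–H⋯O angle at the His polar hydrogen, computed with
  the nearest oxygen.
- **coplanarity** — RMS deviation of the six constraint atoms (OG, HG, both
  His ring nitrogens, both acid oxygens) from their least-squares plane
  (SVD). **collinearity** — the angle Ser OG – His ring centroid –
  carboxylate midpoint. Both are reported for every candidate but no
  threshold is applied by default, because no validated acceptance range is
  available for these two metrics; thresholds can be enabled in config.

Stage-specific competence windows:

| stage   | d(Ser–His) | d(His–acid) | d(Ser–lig) | angles      |
|---------|-----------:|------------:|-----------:|-------------|
| design  | ≤ 4.0 Å    | ≤ 4.0 Å     | –          | 100°–180°   |
| relax   | ≤ 4.0 Å    | ≤ 4.0 Å     | –          | not applied |
| md      | ≤ 3.5 Å    | ≤ 3.5 Å     | ≤ 5.0 Å*   | not applied |

*checked only when a ligand distance is available (holo frames); apo
ensembles are gated on the two hydrogen bonds alone. Applying the angle
windows only at design time is a deliberate choice: the gating stages
follow the distance-based persistence criteria, and the angles are already
guaranteed by construction at design time.

The pose-classification predicate (used on sampled substrate poses) is
strict: Ser–lig < 5.0, Ser–His < 3.5, His–acid < 3.5 Å. When validating
docking poses the two hydrogen-bond distances are treated inclusively
(≤ 3.5 Å); both readings are configurable.

## Side-chain construction

Side chains are built from the existing backbone by idealised internal
coordinates (Engh–Huber-like bond lengths and angles, NeRF placement); CB
is reused when present and synthesised at the ideal tetrahedral position
otherwise (Gly included). Chi angles are sampled on a uniform grid anchored
at 0° (0, 20, …, 340 at the default 20° step), giving 18 Ser, 324 His/Asp
and 5832 Glu rotamers. No statistical rotamer library is involved: the scan
is a grid search, and library priors would bias the completeness guarantee.
The His ring is closed with fixed ring internal coordinates; the residual
CD2–NE2 closure error (~0.07 Å) does not enter any constraint atom.

Steric feasibility is scored with a soft-sphere penalty
Σ max(0, (0.8·(rᵢ+rⱼ) − d)/(rᵢ+rⱼ))² over heavy-atom pairs between the
placed side chain and its environment, with van der Waals radii by element.
The environment of each placement excludes its own residue and the His
position (the triad's common anchor); inter-placement clashes within one
candidate are not counted. This score is an explicit surrogate for the
all-atom force-field score used by the original selection protocol, which
is not recoverable; only its relative ordering within one site matters
(choosing a representative rotamer combination per unique triad), and the
cutoff (default 2.0, dimensionless) only discards grossly overlapping
rotamers. On ideal scaffolds native packing scores exactly 0.

## The design scan

Positions are surface-filtered by relative side-chain-inclusive SASA
(≥ 0.2 by default). SASA is Shrake–Rupley with a deterministic Fibonacci
(golden-spiral) point lattice, 960 points per atom and probe 1.4 Å —
deterministic by construction, no RNG; relative SASA divides per-residue
totals by the Tien et al. theoretical maxima (capped at 1.5).

The pair scan enumerates ordered (Ser, His) position pairs within a
CB–CB ≤ 12 Å prefilter — a reachability bound for grid side chains that
does not affect completeness (verified against a prefilter-free brute-force
oracle in the tests) — and tests all 18 × 324 rotamer combinations per
tautomer with vectorised distance/angle checks. Acid extension exploits the
fact that the His-H⋯O constraints and the acid clash score are independent
of the Ser rotamer: extensions are decided once per distinct His rotamer,
using a KD-tree fixed-radius query over carboxylate oxygen positions, and
joined back to the Ser side.

Deduplication keeps one rotamer combination per unique
(ser, his, acid, kind). The representative is chosen by ordering Ser/His
pairs on (pair clash, d(Ser–His), chi tuples) and then acid rotamers on
(clash, d(His–acid), chi tuples). This two-stage ordering is deterministic
and usually—but not provably always—coincides with the globally minimal
clash sum; since the clash score is itself a declared surrogate ordering,
the distinction has no downstream meaning. The emitted *set* of triads is
exactly the brute-force set (asserted in the acceptance tests).

The PSSM gate requires, at every position whose native residue differs
from the triad role, a log-odds score ≥ 0 for the introduced residue
(positions already matching the role are exempt and reduce the
substitution count). The published protocol states the threshold both as
"greater than zero" and as "≥ 0"; the inclusive reading is the default and
the strict one is a config switch. The exclusion gate drops any candidate
with a triad heavy atom within 6 Å of a flagged native catalytic residue.

## Ensemble gates

The relax gate consumes one structure per relaxation trajectory (30 by
default in the fixtures) and passes a triad when the fraction of
trajectories with competent geometry is ≥ 0.5 — inclusive, so exactly half
passes. The MD gate passes at a persistence fraction ≥ 0.37 over simulation
frames — also inclusive by default ("at least 37%"), with a strict (>)
mode available since the threshold is also quoted exclusively. Counting is
per trajectory at the relax stage and per frame at the MD stage.

## Boltzmann pose scoring

kT defaults to 0.593 kcal/mol (298.15 K); the temperature never appears in
the published equations, so it is exposed as a parameter. Weights are
computed over *all* poses and the catalytic sum is not renormalised — the
literal composition of Pᵢ = e^(−Eᵢ/kT)/Q and ⟨Eᵦ⟩ = Σ Pᵢ Eᵢᵇ over catalytic
poses — so an ensemble that rarely reaches catalytic arrangements is
penalised through the missing weight. A renormalised variant exists behind
a flag for sensitivity analysis. Evaluation subtracts min(E) before
exponentiating; this is exactly shift-invariant and agrees with the naive
formula to 1e-9 relative at moderate energies (asserted). With zero
catalytic poses the score is undefined (NaN with an explicit flag), never
0, because 0 would outrank genuinely favourable candidates.

## Synthetic fixtures

The generators emulate the *shapes* of upstream-engine outputs with exact
ground truth:

- `make_scaffold` — ideal poly-Ala helix (φ = −57°, ψ = −47°) or strand
  backbones; fully deterministic.
- `plant_triad` — installs Ser/His/acid side chains whose measured
  geometry matches a target (default 3.0 Å hydrogen bonds) within
  0.05 Å / 2°, by continuous chi optimisation (coarse seeded starts +
  Nelder-Mead); infeasible targets raise rather than silently degrade.
  Planted chis are intentionally off-grid: recovery tests check that the
  on-grid search re-finds the triad under its windows, not that it
  reproduces the exact conformation.
- `make_ensemble` — exactly round(n·fraction) frames competent at the
  stage thresholds (small verified jitter, σ = 0.05 Å); incompetent frames
  displace the acid side chain rigidly to ≥ threshold + 0.5 Å, so the
  per-frame mask is unambiguous. Frame order is seed-shuffled.
- `make_pose_table` — energies/binding energies from stated laws; distance
  columns satisfy or violate the pose predicate exactly per flag.
- `make_pssm` — S/H/D/E non-negative at listed tolerant positions,
  strongly negative elsewhere; round-trips through the PSI-BLAST ASCII
  dialect.

What the fixtures do **not** emulate: force-field energetics, correlated
backbone motion, realistic rotamer distributions, sequence-profile
statistics, or substrate chemistry. Passing tests therefore demonstrate
correctness of the geometry, filtering, counting and scoring machinery —
not that any particular real protein will yield active designs.

## Problem sizes and numerical choices

The test suite and acceptance script run on 8–12-residue helical scaffolds
(a deliberate desk-scale choice: an 8-residue helix already yields ~20,000
geometry-compatible Ser/His rotamer pairs and ~300 unique triads, which
exercises every code path), 30-trajectory relax and 100-frame MD
ensembles, and 2–50-pose tables. Recovery recall is measured over 50
planted fixtures spanning both acids and hydrogen-bond targets of
3.0–3.32 Å.

Tie-breaks are lexicographic and documented wherever an ordering exists
(deduplication, docking-pose selection, ranking), so identical inputs give
byte-identical outputs; the funnel report asserts monotone stage counts on
every run. Degenerate plane fits (collinear constraint atoms) report
coplanarity 0. Author residue numbering from the input file is used
verbatim everywhere; nothing is ever renumbered, and for AlphaFold models
this numbering is full-length UniProt numbering.

## Known limitations

- The clash surrogate has no attractive or electrostatic terms; it cannot
  reproduce force-field-based rotamer rankings, only exclude overlaps.
- Backbones are rigid during the scan; neighbouring native side chains are
  kept fixed (not repacked).
- Only the triad's polar hydrogens are modelled; no general protonation
  handling.
- The Ser–ligand distance requires either pose-table columns or hetero
  records with carbonyl carbons; arbitrary ligand chemistry perception is
  out of scope (every hetero carbon is a candidate carbonyl carbon unless
  names are given).
- Multi-model PDB is the only ensemble dialect, PSI-BLAST ASCII the only
  PSSM dialect, and insertion codes are rejected outright.
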