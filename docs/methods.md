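# Methods

## Problem and model

`rgflex` generates candidate ligand-bound (holo-like) receptor conformations
from an unbound (apo) crystal structure plus one experimental observable: the
radius of gyration of the bound state (obtainable from SAXS/SANS or from NMR
rotational correlation times).  The underlying model is geometric, not
energetic: interactions that are conserved across a conformational change --
covalent structure, buried hydrogen bonds, hydrophobic packing -- are
translated into pairwise distance bounds, and any conformation satisfying all
bounds is considered accessible.  A mass-weighted radius of gyration

    Rg = sqrt( sum_i m_i |r_i - r_com|^2 / sum_i m_i )

restrains global compactness.  For proteins that close around their ligand
(hinge-bending, Venus-flytrap domain closure) the holo state is more compact
than the apo state, so restraining Rg to the holo value concentrates sampling
near the bound conformation without prescribing which contacts form.
Experimental Rg values are systematically slightly larger than coordinate-
derived ones because of the solvation shell; no solvation-shell model is
applied here, so experimentally derived targets should be corrected by the
user if that bias matters.

## Constraint generation

For a heavy-atom structure (hydrogens dropped, waters removed, first model of
multi-model files) the generator emits, per atom pair, at most one constraint
of the tightest applicable class:

| class      | pairs                                  | bounds (relative to measured distance)   |
|------------|----------------------------------------|------------------------------------------|
| bond       | covalent bonds (residue templates, peptide links, disulfides < 2.5 A) | +-0.5% |
| angle13    | second covalent neighbours             | +-1.5%                                   |
| pair14     | third covalent neighbours              | -3% / +5% (torsional freedom); +-1% across peptide bonds and sp2-planar groups |
| hbond      | stable hydrogen bonds                  | +-10%                                    |
| hydrophobic| within-cluster apolar pairs <= 6 A     | +-20%                                    |
| excluded volume | every remaining pair              | lower = 0.8 x Bondi-radius sum, capped at the measured distance; no upper bound |

The tolerance hierarchy (bond < angle13 < pair14 < hbond < hydrophobic)
mirrors constraint-based samplers of the CONCOORD family; all values sit in
`ConstraintConfig` and are configurable.  Capping excluded-volume lower
bounds at the measured distance guarantees that the input structure satisfies
its own constraint set exactly -- the feasibility anchor every rebuild relies
on.

Hydrogen bonds are detected on heavy atoms only: N/O donor and acceptor
within 3.5 A, at least one donor-antecedent-donor-acceptor angle >= 90 deg,
covalent graph distance > 3 bonds.  Whether a bond is *conserved* is decided
by a desolvation-stability proxy: the count of apolar (C/S) minus polar (N/O)
heavy atoms within 5 A of the donor-acceptor midpoint, excluding the donor
and acceptor residues; a bond is stable (and becomes a constraint) when the
excess is >= 2.  This is a deliberately cheap stand-in for full
solvent-shielding analysis: buried, apolar-wrapped hydrogen bonds survive
conformational change, solvent-exposed ones are left free.

Hydrophobic clusters are connected components of side-chain C/S atoms of
ALA/VAL/LEU/ILE/MET/PHE/TRP/PRO/CYS under a 4.5 A edge cutoff.  A component
must span at least two residues and three atoms; a lone side chain is always
"connected" to itself and is not evidence of packing, which is why the
two-residue rule exists.

## Conformation rebuild

Each frame is rebuilt independently (seed = base seed + frame index) by:

1. **Randomized start.** Input coordinates deformed by 3 random
   low-frequency sinusoidal modes along the chain (amplitude 1.0 A / mode
   order) plus 1.0 A white noise.  The coherent modes randomize soft
   collective degrees of freedom (hinge bends, loop displacements) while
   local geometry stays repairable; the amplitudes emulate thermal-scale
   structural uncertainty, so unbiased ensembles fluctuate around the input
   conformation and large transitions are reached through the Rg restraint
   rather than by luck of the start.
2. **Outer rounds** (default 12): uniform rescale about the centre of mass
   exactly onto the target Rg (biased mode only), then FIRE descent on the
   sum of squared bound violations over an *active set* (all structural
   constraints plus excluded-volume pairs within 1.5 A of activation), then
   local repair: any atom involved in a persistently violated structural
   constraint is re-placed next to a random bonded partner.  The repair step
   breaks the characteristic sp3 trap in which a side-chain centre settles
   into the mirror image of its feasible geometry -- pure distance
   information cannot distinguish the two, and smooth descent cannot cross
   between them.
3. **Exact-feasibility sweeps** (default <= 500): Gauss-Seidel pair
   corrections visiting all constraints in random order, each violated pair
   moved along its separation vector to a point 30% inside its allowed
   window (both atoms displaced equally; pinned atoms absorb nothing), with
   a per-sweep Rg rescale clipped to [0.99, 1.01] while outside the Rg
   tolerance.
4. **Convergence**: every pair within bounds to 1e-3 A, |Rg - target| <=
   tolerance (default 0.1 A), and backbone handedness matching the input
   (mean signed volume of the N/C/CB frame about each CA).  A globally
   mirrored solution -- distance-feasible by construction -- is flipped back
   by reflection and re-checked.  Non-convergence triggers a restart with a
   derived seed (up to 10); unconverged frames are dropped and logged.

A design note: a plain scheme -- atoms scattered uniformly in a box, pair
corrections only -- does not converge at these bound widths.  On the test
systems it stalls with hundreds of violations that neither damping, random
correction order, phased constraint activation nor metric-matrix embedding
starts resolve, because assembling a dense hydrogen-bonded helix from
scratch by local pair moves is a cooperative search problem.  The
perturbed-start + FIRE + repair combination above converges in 60% of
single attempts (>99% with restarts) at ~0.1-0.2 s per 124-atom frame, and
is the package's own design.  Its trade-off is honest and documented: frames
are fluctuations of the *input* fold, so transitions that require refolding
(helix-to-loop and similar) are out of reach -- which matches the known
limitation of conserved-interaction constraint samplers.

Sidechain resampling pins every backbone atom and every non-flexible residue
(weight 0), widens the 1-4 windows across flexible side chains
(lower >= 2.4 A, upper x1.5) to free their torsions, and reruns the same
relaxation; output backbones equal the input bitwise.  A side chain counts
as flexible when it has rotatable atoms beyond CB, joins no stable hydrogen
bond or hydrophobic cluster, and has fewer than 14 non-self heavy-atom
neighbours within 5 A per side-chain atom on average.

## Ensemble operations and protocol

Clustering is greedy leader clustering on fitted backbone RMSD
(deterministic in frame order), with a cutoff binary search available to
land a requested pool size (+-10%).  Ranking sorts by |Rg - target|
ascending, ties by frame index.  The compliance filter keeps frames with
relative Rg deviation < 1% and doubles the cutoff (logged) while fewer than
`min_keep` survive, up to 0.16.  Assessment pairs atoms with a reference by
(chain, residue number, insertion code, atom name), drops unmatched atoms
with a logged count, and reports global backbone RMSD plus binding-site RMSD
(backbone-only and all-heavy-atom).  The binding site is every receptor
residue with a heavy atom within 6 A (inclusive) of any ligand atom.
Site RMSD defaults to a local fit (superposition on the site atoms
themselves), because a local fit measures pocket geometry rather than
domain placement; a global-fit flag is provided since either convention is
found in the literature.

The staged protocol runs: biased sampling (default 1000 frames) -> RMSD
clustering (to ~200) -> optional external refine/score hook -> top-50 by Rg
compliance -> sidechain resampling (100 per model, <= 5000 total) ->
optional external docking/MD hook -> 1% Rg filter -> Rg ranking, then a
second refinement cycle (resampling + filter + ranking) on the 10 best
models.  External engines (energy minimization, statistical scoring,
docking, MD, Rosetta-style refinement) are *hooks*: shell-command templates
exchanging multi-model PDB; the pipeline validates frame counts and runs
end-to-end without them.  With hooks disabled a run is byte-for-byte
reproducible for a fixed seed.

## Synthetic test system

`make_hinge_protein` builds two LEU-rich helical domains (default 8 residues
each, sequence pattern LALS...) joined by a 3-residue extended hinge, from
ideal backbone geometry (helix phi/psi = -57/-47, strand -139/135,
Engh-Huber-like bonds and angles, most-common rotamers).  Open and closed
states differ only by a rigid rotation of the second domain about an axis
through the central hinge CA (default inter-domain centroid angles 150 and
85 deg, giving Rg 9.4 -> 7.6 A and backbone RMSD ~3.4 A); a 4-atom
pseudo-ligand sits in the closed cleft.  Stored ground-truth numbers are
recomputed from coordinates at construction.

What the toy does and does not show: it has genuine helical hydrogen-bond
networks, a hydrophobic spine, a soft hinge and a cleft that closes around
a ligand, so it exercises every constraint class and the closure-under-
Rg-bias mechanism.  It is far smaller than a real receptor, single-chain,
has no crystallographic noise, no missing atoms, no refolding transition
and a one-dimensional soft mode, so passing tests demonstrate mechanism,
not field performance on crystal structures.

## Numerical choices and degenerate inputs

Convergence tolerance 1e-3 A (PDB coordinate precision); ties in ranking
and clustering broken by ascending frame index; coincident atoms during
sweeps separated along a deterministic index-derived direction; altloc
resolution keeps the highest occupancy (ties: first letter); residue
numbering is taken verbatim from the file; unknown elements are an error
rather than a silent default mass.  Two-point fitted RMSD uses the analytic
|d1 - d2| / 2 value (the Kabsch path needs >= 3 points).  All randomness
flows from explicit integer seeds through `numpy.random.SeedSequence`;
frame k of an ensemble uses seed + k, restart r spawns key (r,).

## Known limitations

- Conformational changes involving secondary-structure refolding are not
  sampled (conserved-interaction constraints forbid them by design).
- Local chirality of individual side-chain centres is enforced only
  indirectly (repair + the global handedness check); distance information
  alone cannot forbid isolated inversions.
- The desolvation-stability score is a proxy, not a calibrated solvation
  model; its threshold (2) is a configurable default.
- Excluded-volume generation enumerates all atom pairs (O(N^2) memory),
  appropriate for desk-scale systems up to a few thousand atoms.
- External-engine stages are executed only through user-supplied command
  templates; no scoring function is bundled.
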