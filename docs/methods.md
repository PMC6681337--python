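# Methods

## Scope and model

`axialkit` implements the desk-scale modelling workflow for bacterial
flagellar axial structures — the distal rod and the hook of *Salmonella*
and their homologs. The workflow has four computational stages:

1. **Screw-symmetry algebra.** An axial assembly is generated by one screw
   operator: rotation θ (twist, degrees) about the helix axis plus
   translation z (rise, Å) along it, per subunit of the 1-start helix. The
   working frame places the axis on +z with the distal end toward +z;
   positive twist is a right-handed screw about +z. This handedness is a
   configuration flag, with right-handed as the default, because the
   neighbour numbering used in the literature (−5, −10, −11, −16 positions,
   counted proximally along the 1-start) is then reproduced directly as
   integer lattice offsets. The built-in parameter sets are the distal rod
   (θ = 64.75°, z = 4.13 Å) and the hook (θ = 64.78°, z = 4.12 Å). Because
   rotation about z and translation along z commute, the n-th power of the
   generator is computed in closed form (rotation nθ, rise nz), which keeps
   lattice placement exact for negative indices.

2. **Lattice counting.** Subunits per t turns is `round(t·360/θ)` — the
   counting convention of the field (11 subunits per two turns, 22 per
   four). The protofilament count is the offset n ∈ [2, 30] whose
   cumulative rotation `wrap(n·θ)` (wrapped to (−180°, 180°]) is closest to
   axial, ties broken toward smaller n; the signed residual is reported.
   The search bound of 30 is a practical one: start families beyond ~30
   have no structural meaning in an 11-protofilament lattice. n-start
   families (±5, ±6, ±11) are reported with their wrapped rotation and net
   rise.

3. **Superposition.** Rigid-body fitting is the standard SVD (Kabsch)
   solution with the reflection branch corrected by the determinant sign,
   no outlier trimming, Cα atoms by default. Degenerate (collinear or
   <3-point) inputs are an error rather than an ill-conditioned answer.
   Symmetry inference fits the rigid step transform between consecutive
   subunits, averages the step rotations (quaternion mean) and
   translations into one mean screw operator, and reads twist and rise off
   that operator, orienting the screw axis so the rise is positive. The
   reported per-step residual is the RMSD between subunit i+1 and the mean
   operator applied to subunit i. This deliberately differs from the
   per-step *fit* RMSD: identical rigid copies superpose exactly in any
   order, so only the consistency residual flags a scrambled subunit order
   or broken symmetry.

4. **Contacts.** A contact is any heavy-atom pair from different subunits
   within a cutoff, 4.0 Å by default (the usual van der Waals contact
   criterion; the source models were described without a stated cutoff, so
   fingerprint reports include a 3.5/4.0/4.5 Å sensitivity series). Pair
   search uses a uniform spatial grid with cell size equal to the cutoff
   (27-cell neighbourhood scan); a brute-force O(N²) scan is kept in the
   package as the oracle and the two are asserted identical in the tests.
   Edges are aggregated per (subunit pair, segment pair) with atom-pair
   count and minimum distance, emitted symmetrically in both directions.
   The per-segment fingerprint — the set of (lattice offset, partner
   segment) a segment touches — requires an interior reference subunit:
   all neighbours out to the largest observed |offset| (or an explicit
   margin) must be present, otherwise the fingerprint would be silently
   truncated by the assembly boundary.

## Grafting

Chimeric subunits are built by superposing a donor homolog onto the
acceptor over a shared domain (default D1, Cα atoms) and rigidly copying
the donor's missing segments into the acceptor. Design choices:

* "Sidechain replacement" is relabeling to the target sequence plus
  truncation to the atom set shared between the old and new residue type
  (backbone always kept). This is deterministic and exactly testable;
  rotamer rebuilding belongs to downstream refinement tools and is out of
  scope.
* Splice junctions are reported, never regularised — no peptide-bond
  geometry is invented at the joins.
* Regions without experimental support are explicit deletion masks
  (residue ranges removed, numbering gap preserved), never interpolated.
  For full-length FlgG the packaged default segment boundaries are
  D0N 1–46, L_STRETCH 47–84, D1 85–221, D0C 222–260, with the disordered
  l-stretch tip 53–64 as the standard mask. These boundaries are inferred
  from the crystallised core-fragment construct (residues 47–227) and the
  terminal β-stretch landmarks (N85–T89, Y218–T221); they are
  configuration values, not constants, because no deposited annotation
  fixes them exactly.

## Sequence comparison

Global alignment is Needleman–Wunsch with affine gaps via
`Bio.Align.PairwiseAligner` (BLOSUM62, gap open 10, extend 0.5 —
EMBOSS-needle-style defaults, the convention under which FlgG and FlgE
show ~39% identity). Identity is identical pairs divided by aligned
columns, excluding terminal overhangs but including internal gaps; the
convention is printed in every report because published identity figures
rarely state theirs. Tie-breaking among co-optimal alignments is the
aligner's deterministic first-alignment order. The test suite checks the
affine-gap score against an exhaustive enumeration of all alignment paths
on short sequences, so the library call is cross-checked, not trusted.

Structure-based alignment pairs residues whose Cα atoms are mutual nearest
neighbours within 3.0 Å after superposition; crossing pairs are resolved
shortest-distance-first so the pairing is monotone and one-to-one.

## Synthetic data

The toy subunit mimics the axial-protein architecture with a Cα-only
trace: two antiparallel ideal-helix traces near the axis (D0N/D0C; 1.5 Å
rise and 100° twist per residue, 2.3 Å trace radius, 10 residues each by
default), a globular D1 ball (20 seeded points, radius 3 Å) at 25 Å from
the axis, and a taut arm (the l-stretch analog, Cα spacing ≤ 3.5 Å) from
14 Å above the subunit's own D1 centroid to the D1 centroid of a designed
lattice neighbour (offset −5 by default, matching the rod's l-stretch
direction; lattice defaults to the rod symmetry). The arm errors out if
shorter than the anchor-to-target distance, so the designed contact is
guaranteed by construction and the contact stage can be tested against
exact ground truth. The 14 Å anchor lift keeps the arms of ±5 and ±6
neighbours clear of each other's anchor regions at the 4 Å cutoff; for
near-protofilament arm directions (|offset| ≈ 11) the ±offset arms run
almost parallel to the axis and unavoidably overlap, so fingerprint
exactness is only guaranteed for cross-protofilament designs.

What the toys do *not* emulate: sidechains and realistic packing density,
domain shape, the D2 domain, sequence content, and any physical energetics.
Passing synthetic tests therefore demonstrates the correctness of the
geometry, indexing and bookkeeping, not the biological realism of a
contact network; conclusions about real rod/hook contact patterns require
the deposited models (fetched by `scripts/fetch_data.py`, exercised by the
data-gated tests).

Noisy assemblies add i.i.d. Gaussian displacement per atom after
placement, with a seeded generator; all synthetic output is bitwise
deterministic for a fixed seed.

## Numerical choices

* Rotation matrices are validated orthonormal to 1e-9 and re-polished by
  SVD after Kabsch to stay inside that tolerance.
* Angle wrapping maps to (−180°, 180°]; protofilament ties break toward
  smaller n with a 1e-12 comparison guard.
* PDB round-trips are coordinate-exact to the format's 1e-3 Å field
  precision; mmCIF is used for assemblies beyond the 62-character PDB
  chain alphabet (hard error, no silent renaming). Alternate locations
  keep the lexicographically smallest altloc id; hydrogens are dropped on
  read; waters are recognised by residue name HOH/WAT.
* The mutation-site mapper labels sites inside deletion masks as
  unmodeled and reports the merged contact environment of their flanking
  modeled residues, flagged approximate — an envelope, not a prediction.

## Problem sizes

The synthetic analyses use 33-subunit assemblies (interior subunit with
±16 neighbours present, enough to observe every offset family the rod
fingerprint involves) of ~50-residue Cα-only toys, i.e. a few thousand
atoms; symmetry-recovery suites use 22-subunit assemblies, matching the
four-turn segment convention for rod models. These sizes give exact,
fast-to-verify ground truth; nothing in the implementation is specific to
them.

## Known limitations

* No density-map I/O or fitting, no crystallographic phasing or
  refinement, no validation statistics — the pipeline starts from
  deposited or synthetic coordinates.
* Grafted chimeras are geometrically spliced, not energy-minimised.
* Segment boundaries for real proteins are user configuration; the
  defaults above are documented estimates.
* The published descriptions of the hook's l-stretch contacts differ
  between sections of the source literature (−5/−11 versus −5/−10); the
  data-gated hook test asserts the −5/−11 reading and the discrepancy is
  surfaced rather than reconciled.
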