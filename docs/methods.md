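# Methods

This note documents the models, conventions, numerical choices and known
limitations of porescope. Units are Å for lengths (nm for the 1D ion
coordinate), ns for time, kJ/mol for energies.

## Structures, trajectories, conventions

Coordinates are read with gemmi (PDB v3.3 and mmCIF) into flat numpy-backed
records. Residue numbers are the author-assigned numbers from the coordinate
file, since the literature on this receptor cites author numbering (e.g.
αV257); mmCIF `label_seq` is ignored for user-facing selections. When a file
carries alternate locations, the highest-occupancy altloc is kept, ties
broken alphabetically, so downstream geometry always sees one conformer.
Insertion codes are carried verbatim, but prime-map arithmetic refuses M2
spans containing them, because the anchor+offset rule assumes contiguous
numbering. Atom indices are 0-based half-open internally; residue numbers
1-based — stated here once, used everywhere.

Trajectories are multi-model PDB (one MODEL block per frame over a fixed
topology); binary formats (DCD/XTC/TRR) are accepted through an optional
MDAnalysis reader. The default frame interval is 0.4 ns, the production
sampling rate of the simulations this package post-processes; it is a label
for time axes, not used in any computation.

**Prime numbering.** M2 pore-lining residues are indexed −2′ (intracellular,
desensitisation gate) to 20′ (extracellular). The map is anchored at the 9′
activation-gate leucine per subunit class: residue(k′) = anchor + (k − 9).
Shipped anchors for α1β2γ2: α 264, β 259, γ 274. The α/β values follow
directly from the published 2′ residues (V257, A252); the γ anchor is the
package's own derivation from the 20′-level pull residues (β2-270, α1-275,
γ2-285 are each anchor+11, hence γ = 274). A non-leucine anchor warns rather
than errors, so engineered gate mutants (αV257S, βA252S systems) pass
through.

**Superposition** is classical Kabsch, computed via
`scipy.spatial.transform.Rotation.align_vectors` on centred coordinates; the
rmsd is recomputed from the actual residuals, which is accurate near zero
where the optimiser's reported residual norm loses precision.

**Pore axis.** The pseudo-C5 axis is the normal of the plane through the
five per-subunit M2 Cα centroids (eigenvector of the centroid ring's
smallest principal moment), signed so the bulk of the receptor mass beyond
the ring — the ECD — lies at +z, and the ring centroid becomes the origin.
This is robust to missing side chains and reproducible; it is not a full
symmetry detection, which is out of scope.

## Pore profiling

The profile follows the classic HOLE definition: at each z, the radius of
the largest sphere centred in that plane touching no atom,
r(z) = max over centres c of min_i(|c − a_i| − vdW_i), with c confined to a
lateral search disc (default 8 Å) about the axis. Instead of simulated
annealing, the maximisation is a deterministic coarse grid (0.5 Å) followed
by Nelder–Mead refinement (xatol 1e-4), making profiles bit-stable across
runs. The refined value is validated in the tests against an exhaustive
dense-grid oracle (0.05 Å step over the whole disc).

Defaults: axial step 0.25 Å; hydrogens ignored (deposited models are
heavy-atom); vdW radii from the HOLE "simple" set (C 1.85, O 1.65, N 1.75,
S 2.00, H 1.00, P 2.10 Å; 1.85 Å fallback), with the set name recorded in
every output because printed diameters depend on it. Since the upstream tool
is typically cited without its parameter set, agreement with published
diameters is promised only to ±0.5 Å. A slice whose atom slab is empty, or
whose maximal sphere exceeds the lateral disc (an open vestibule or a gap in
the wall), is flagged as a gap (NaN) rather than silently clamped or zeroed.

Gate diameters: for each prime ring, the ring plane is the mean z of the
five residues' heavy atoms; the reported diameter is twice the minimal
profile radius within ±1.5 Å of that plane (half-width chosen to capture the
ring constriction without the neighbouring helical turn). Missing rings are
omitted with a warning.

## Ligand dynamics

The rmsd trace superposes each frame onto the reference (frame 0, the
experimentally derived pose, by default) via the align selection — protein
Cα — then measures rmsd over ligand heavy atoms with no further fitting. No
symmetry correction is applied (the steroids concerned have no symmetric
atoms). A crop rule is available for unbinding events: raw values above a
threshold are stored as a fixed value and flagged; the shipped preset
(60 Å → 10 Å) matches the plotting convention for free agonist diffusion
after escape. Cropping defaults off.

The z trace is the ligand centre-of-mass displacement along +z relative to
frame 0 (mass-weighted, after the same alignment), positive toward the outer
membrane leaflet; a least-squares slope summarises the net tendency (e.g.
the intracellular slip of a sulfate-down pose is a negative slope).

Pose clustering is greedy quality-threshold clustering on the pairwise
ligand-rmsd matrix: repeatedly extract the unassigned frame with the most
cutoff-neighbours (ties → lowest frame index) plus its neighbours, until the
cluster budget (default 10) is spent; leftovers are noise. Populations are
non-increasing by construction; the exemplar of a cluster is its medoid.
The pairwise matrix is computed after aligning every frame to the common
reference rather than by mutual pairwise fitting — this matches the trace
definition and keeps the cost at O(n) superpositions. The cited clustering
plugin's exact objective is not documented; this greedy rule is declared,
not inferred.

## Contacts

A residue contacts the ligand in a frame iff any residue heavy atom is
within the cutoff (default 4.5 Å) of any ligand heavy atom; the frequency is
the fraction of contacting frames. This plain distance criterion stands in
for typed interaction fingerprints because the reported quantity is a single
aggregate frequency per residue and a distance rule is reproducible without
parameterised chemistry; consequently no numerical agreement with
fingerprints computed by typed-interaction tools is promised. Waters and
lipids are excluded from the residue universe by default. Replicate
summaries use the sample mean and sd (n−1); absent residues count as
frequency 0 in the union universe. The frequent-contact rule keeps residues
with mean ≥ 50 %, inclusive at the boundary.

## Hydration and upper-ECD spread

Hydration counts distinct water molecules (residues named HOH/WAT/TIP3/SOL,
located by their oxygen) within 3 Å of any atom of the 9′ leucine ring,
per frame. Identity is tracked by residue so a molecule straddling the
cutoff counts once. Distances are plain Cartesian — inputs are expected as
whole-molecule frames; minimum-image treatment under an orthorhombic box is
available behind a flag for raw MD input.

Upper-ECD spread: frames are Cα-aligned to frame 0, then each subunit's
upper-ECD mass-weighted centre of mass is computed over the shipped residue
intervals (α1 10–45, 66–102, 107–133, 157–180, 200–213; β2 7–43, 62–99,
104–130, 154–176, 194–208; γ2 25–57, 77–113, 119–145, 169–189, 210–223).
Because "spread" admits two readings, both ship and the mode is recorded in
every output: `radial_spread` (default; mean distance of the five COMs from
their centroid — contraction lowers it directly, matching the
spread/contraction language used for activation-like ECD motion) and
`com_displacement` (mean per-subunit |COM(t) − COM(0)|). Neither mode is
claimed to reproduce any published spread value numerically. Missing
residues inside the ranges are tolerated and the used subset is recorded; a
subunit resolving zero atoms is an error naming the chain.

## PMF post-processing

Only the 1D output of adaptive-bias ion-permeation simulations is modelled;
the biasing machinery itself (multi-walker adaptive weights) requires
cluster-scale MD and is out of scope. Profiles are oriented extracellular →
cytoplasmic left → right with the −2′ gate at 0 nm. Boltzmann inversion
builds a histogram at the requested bin width (0.02 nm typical), reweights
by exp(+bias/k_BT) when per-sample bias energies are supplied, masks bins
with fewer than 5 raw counts as gaps, and offsets the curve so the minimum
inside the reference window is zero. Published profiles do not state their
zero region; the bulk-solution flank is assumed and the window is recorded
on the profile. Barrier height is max F inside the gate window minus the
lowest sampled F outside it (both flanks pooled). k_B·T at the default
300 K is 2.494 kJ/mol.

The built-in Metropolis sampler (Gaussian proposals, reflecting bounds
mimicking a flat-bottom confinement, seed-reproducible, burn-in 1000 steps)
exists as the recovery oracle for the inversion: tests verify that a
programmed 18 kJ/mol double-well barrier is recovered within 1 kJ/mol from
10⁶ samples and harmonic curvature within 10 % from 10⁵ samples, with error
decreasing in n.

## Synthetic data

The generator emulates the statistical structure of the MD observables, not
the physics. A toy channel is five pseudo-subunits of carbon rings stacked
every 0.75 Å (two rings per M2-like residue, 1.5 Å/residue axial pitch,
matching an α-helical rise), with ring atoms at distance R(z) + r_C from the
axis so the on-axis inscribed radius is exactly R(z); between ring planes
the radius bulges by at most ≈ 0.02 Å, the fixture's analytic tolerance.
Two design points matter for the profiler oracle: rings carry 20 atoms
(staggered 9° between stacked rings) so the maximal sphere cannot slip
azimuthally off-axis, and a second concentric shell 3 Å out (overlapping the
first into a solid wall) mimics the thick transmembrane domain so the
disc-wide search cannot escape into the open exterior of a hollow
single-shell wall. Residue numbering follows the shipped prime anchors, so
the same prime-map machinery used on deposited structures applies to toys;
the 9′ residues are LEU and the 2′ residues VAL/ALA on α/β as in the real
receptor.

Toy trajectories hold the wall static and program, per frame: a rigid ligand
displacement (Gaussian jitter plus linear drift; frame 0 pinned to the start
pose so traces are anchored), a contact schedule (scheduled residues park
side-chain pseudo-atoms 3 Å from the ligand centre in the first
round(f·n) frames and 30 Å radially out otherwise — never moving an
alignment atom), a water plan (waters occupy slots 2.5 Å inward of distinct
9′ ring atoms or park far away), and ECD breathing (five C5-symmetric
pseudo-domains scaled radially about the axis; symmetry makes the Cα
alignment exactly the identity, so the radial spread scales exactly with the
factor). Scheduling a 9′ residue as a ligand contact while a water plan is
active is rejected as contradictory. Generation is a pure function of
(spec, seed); the spec serialises alongside every CLI dataset.

What the toys do **not** emulate: force-field physics, membrane/lipids,
correlated protein motion, rotameric side chains, periodic boundaries, or
realistic water dynamics. Passing tests therefore demonstrate correctness of
the measurements (geometry, counting, clustering, inversion), not fidelity
of any simulation.

## Problem sizes in tests and the acceptance script

Toy channels carry ~1.8k pseudo-atoms; trajectories 10–200 frames; the
brute-force profiler oracle scans a 0.05 Å dense grid at a handful of z
slices per channel; PMF recovery uses 10⁵–10⁶ Metropolis samples. These
sizes were chosen so each oracle comparison is decisive (discretisation
error well under the asserted tolerance, Poisson error per histogram bin a
few percent of k_BT) while a full run stays at minutes on one CPU.

## Known limitations

- The pore search assumes a straight, axis-aligned pore; curved pathfinding
  and conductance prediction are out of scope.
- Published gate diameters depend on the upstream tool's unstated parameter
  set; ±0.5 Å is the honest comparison tolerance.
- Checks against deposited receptor models require the coordinate files to
  be supplied locally (`data/deposited/`); they are too large to ship.
- PMF error bars (block averaging) are flagged future work; profiles carry
  gap masks but no per-bin uncertainties.
- Biological-assembly expansion and sequence-based prime assignment are
  deliberately not implemented (config-driven chain maps and anchors only).
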