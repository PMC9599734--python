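# Methods

This note documents the models, rules, numerical choices and limitations
behind `ploopkit`. Everything quantitative below is computed by the code
(tests or `scripts/acceptance.py`); nothing is asserted from data the
package does not process itself.

## Structure reduction

Structures are parsed with gemmi and reduced to a single-conformer,
heavy-atom view: first model only; hydrogens/deuteriums dropped (the
corpus of interest is X-ray structures, where hydrogen positions are
generally not observed, so every distance in the pipeline is a heavy-atom
distance); one altloc per atom, chosen as highest occupancy with ties
broken by the alphabetically first altloc code. Waters (HOH/WAT/DOD) are
normalised to HOH. Residues are identified by author numbering so that
reported labels match the numbers used in the structural literature. The
structure id is the file stem; the 4-character PDB HEADER field cannot
carry synthetic ids.

## Site detection and ligand classes

Each bound nucleotide hetero-residue (component lists shipped in
`ploopkit/data/components.yaml`, user-editable) is one candidate site; a
structure with several nucleotides contributes several sites.
Diphosphates acquire the nearest γ-mimic residue whose central atom
(Al/Be/Mg/V) lies within **3.5 Å of O3B** — the bond being mimicked is
the O3B–P^G covalent bond, so the association cutoff is a
covalent-geometry scale rather than a contact cutoff; a free phosphate in
the same range marks a post-hydrolysis site (class `ndp_only`,
`pi_present`), used only by the β-phosphate–Pi distance.

Metal-fluoride species are re-identified from geometry: four fluorines
within 0.3 Å of their common least-squares plane → AlF4 (square-planar);
three fluorines coplanar with the central atom → AlF3/MgF3/BeF3 by
element; V with four O → vanadate. Geometry overrides the deposited
component code because misassigned fluorides occur in the archive; the
distinction is load-bearing (AlF4 is a transition-state mimic, AlF3/BeF3
are ground-state mimics). The four classes — native, non-hydrolyzable,
substrate analog, TS analog — partition the accepted sites.

The cofactor ion (Mg/Mn/Ca) is the candidate nearest the midpoint of the
O2B and O1G-role anchors, accepted within 3.0 Å of either anchor. For a
mimic, the O1G role falls to the peripheral atom nearest O2B (positions
#1 and #2 are cis neighbours in the shell, so the coordinating fluorine
is the one closest to O2B).

## Motif annotation

Annotation is geometric, not sequence-based, which is what lets one
pipeline handle kinases, GTPases and ATPases alike.

* **Walker A.** Lys^WA is the lysine whose NZ is nearest to (and within
  5 Å of) any β-phosphate oxygen. NZ specifically, because it is the
  chemically interacting atom (the terminal amine contacts O1B/O2G);
  using the whole side chain instead would be a one-line change. K+1 is
  the next residue in chain order (flagged when not Ser/Thr — e.g. Gly in
  adenylate kinases), K−3 the residue three earlier. Ties break by
  (chain, residue number, atom name), everywhere.
* **Walker B.** Candidates are Asp/Glu *in K+1's own chain* whose nearest
  carboxylate O is within 5 Å of the K+1 hydroxyl O. The primary rule
  takes the nearest candidate whose residues i−1..i−3 (N-terminal
  neighbours, matching the *hhhh*D motif) are all outside the ionizable
  set {Glu, Asp, Ser, Thr, Tyr, Lys, Arg, His}; if none qualifies, the
  plain nearest is returned with a fallback flag; an empty candidate set
  means "absent at the threshold distance" (a fully open site).
  Restricting the search to one chain reflects that Walker A and B belong
  to a single P-loop domain in every structure discussed; with an empty
  ionizable set the rule degenerates to plain-nearest (tested as an
  oracle equivalence).
* **Switch I** is the Ser/Thr (other than K+1) whose side-chain O is a
  shell ligand; absent when water occupies position #3.
* **W_cat** is the water oxygen 2–4 Å from the γ central atom X that
  maximises the O3B–X–O_w angle, provided the angle is ≥ 140° (apical to
  the scissile-bond axis). In vanadate complexes the apical vanadate
  oxygen occupies that position and is returned as a surrogate. Polar
  (N/O) atoms within 3.6 Å of W_cat are inventoried; the nearest Asp/Glu
  carboxylate among them is the "catalytic" carboxylate.

## Measurements

Distances are recorded at 0.01 Å and displayed at 0.1 Å when compared
with published per-structure values. The Walker-B–K+1 distance is the
minimum over {OD1,OD2}/{OE1,OE2} × {OG/OG1}. H-bonds are classed short
(< 2.7 Å), typical (2.7–3.2 Å, boundaries inclusive) or long. The ΔpKa
estimate maps the O–O distance linearly through (2.4 Å, 0) and
(2.9 Å, 20), clamped to [0, 20]; note the often-quoted slope of
0.02 Å per pKa unit is inconsistent with those endpoints (they imply
0.025), and the endpoints are used here.

The Mg²⁺ shell is the six nearest O/N/F atoms within **2.6 Å** of the ion
(standard first-shell Mg–O distances are 2.05–2.15 Å; no cutoff is
a convention this package sets). Labels: #1 = O2B, #2 = the γ-moiety
ligand, #4 = the K+1 hydroxyl; the ligand trans to #1 is #6; of the
remaining trans pair, #3 is the one nearer the Walker-B carboxylate
(reproducing the conserved connectivity in which #3/#6 are the proton
entry points) and #5 the other. The #4-trans-to-#2 arrangement is
verified and recorded. Shell edges are the distances of cis pairs
(Mg-centred angle < 120°): 12 per complete octahedron, b·√2 for bond
length b, i.e. 2.9–3.0 Å for b in 2.05–2.12 Å.

Superposition uses Kabsch least-squares on backbone N/CA/C/O of the
20-residue window K−12..K+7 (β1-strand, P-loop, α1-helix start) — the
window a reference alignment of the fold uses, anchored at the Walker-A
lysine. Contact inventories list all γ-moiety/W_cat to protein N/O pairs
at ≤ 3.6 Å, labelled moderate (≤ 3.2 Å) or weak (3.2–3.6 Å); these two
thresholds are this package's own convention, consistent with standard
H-bond taxonomy.

## SASA

Shrake–Rupley with a deterministic golden-spiral quadrature (default 960
points per atom, probe 1.4 Å): each atom's sphere is expanded by the
probe radius and a test point is accessible iff strictly outside every
other expanded sphere. The quadrature makes site records bit-reproducible
(a `seed` argument is accepted and ignored). Van der Waals radii are a
shipped, configurable table (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80,
Mg 1.73, F 1.47, Al 1.84, V 2.00 Å, plus common ions). Relative SASA
divides a residue's heavy-atom SASA by a shipped theoretical
maximum-accessibility table (whole-residue Gly-X-Gly maxima; Asp 193 Å²).
Whole-residue rather than side-chain-only normalisation is a documented
choice (side-chain-only maxima could be swapped in via the configurable
table). A residue
extracted with no context at all exceeds its Gly-X-Gly maximum by
~25–30% (the flanking-residue shadow is gone), so values above 100% are
possible and are reported, not clipped. Verification is three-way:
closed-form isolated spheres (< 1%), a 5·10⁴-sample Monte-Carlo surface
oracle on seeded clusters (2% on cluster totals, with a 2%-of-isolated-
sphere absolute floor per atom to absorb MC counting noise on
nearly-buried atoms), and biotite's independent implementation (~1% on a
whole synthetic site).

## Statistics

Records are filtered (resolution ≤ 2.5 Å by default for headline
aggregates — the corpus-inclusion threshold of 5 Å is looser and both are
configuration, not hard-coded truth; QC pass required) and grouped by
class; summaries report n, mean, median, quartiles, sd and the share of
short H-bonds. Pairwise class comparisons use the two-sided Mann–Whitney
U (asymptotic, midranks) with Benjamini–Hochberg adjustment across all
pairs in a report. The rank test was chosen because the measured distance
distributions are visibly non-normal; published per-corpus p-values
obtained with other routines are not expected to reproduce exactly and no
such claim is made. Groups below 3
observations yield NA with a warning. A permutation test on the mean
difference serves as the oracle in tests.

## Synthetic sites

The generator builds, analytically, the conserved arrangement: Mg at the
origin, octahedral O ligands at ±b on the axes (b = 2.1 Å default, the
canonical Mg–O bond), an extended di-/tri-phosphate with IUPAC atom
names constructed from standard bond lengths (P–O ≈ 1.5–1.6 Å,
near-tetrahedral phosphorus, P–P ≈ 2.9 Å across the bridging O3B), mimics
built square-planar/trigonal/tetrahedral on the γ-centre position, a
P-loop-like peptide whose constrained atoms (Lys NZ, K+1 hydroxyl, K−3
amide N) sit at exactly the blueprint's planted distances, a Walker-B
strand whose carboxylate O is exactly `wb_k1_target` from the K+1
hydroxyl, and optional decoy carboxylates/lysines, Switch-I block,
catalytic water and distractor waters. Peptide geometry is
minimal-but-legal: bond lengths are standard, but there is no
Ramachandran realism, no sequence realism, no B-factors and no crystal
packing — the pipeline consumes only distances and angles, and passing
tests on these fixtures demonstrates the *rules*, not robustness to
real-data pathologies (alternate conformations beyond altlocs, missing
atoms, low-resolution noise above ~0.2 Å, multi-chain composite sites).
Gaussian jitter (per-axis sd, seeded) emulates coordinate uncertainty;
ground truth records planted labels and pre-jitter distances.

Batch generation draws per-class Walker-B–K+1 targets from normals
(TS analog μ = 2.50, σ = 0.05; other classes μ = 2.65, σ = 0.08 Å) —
chosen to echo the *ordering* of the published class distributions
(TS analogues shortest), explicitly not their data; the truth-table
header says so. Batch jitter default is 0.02 Å.

## Problem sizes and tolerances in the test suite

Recovery properties run 200 seeded replicates at jitter sd 0.1/0.2 Å
(annotation) and 100 at 0.1 Å (shell membership, Switch I); the MC-SASA
oracle uses 20 clusters of 10 atoms at 5·10⁴ samples each; statistical
checks use n = 50 per group with 100 seeded repetitions and a
2000-permutation oracle. These sizes make the full suite run in well
under a minute while leaving the binomial/quadrature margins comfortable.

## Known limitations

* Worked examples on deposited entries (1OW3, 6JIM, 2GJ8, 3KQL, 3HQD,
  4PJK) require the files locally (`ploopkit.fetch_structure`); the
  corresponding test fails with an explicit message when they are absent
  rather than skipping.
* No NMR-ensemble handling, no assembly/symmetry expansion, no hydrogen
  placement, no sequence-profile motif search, no pKa computation (the
  ΔpKa calibration is an empirical distance map, not an electrostatics
  model), no InterPro/Pfam class assignment, and no automated PDB-wide
  retrieval: the pipeline consumes user-supplied files, so corpus-scale
  counts depend on the corpus the user supplies.
* Walker-B candidates are searched only in K+1's chain; inter-chain
  composite sites would need the search widened.
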