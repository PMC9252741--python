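# Methods

`surfpatch` predicts, from a protein's 3D structure alone, (a) which surface
regions are likely to mediate protein–protein interactions and (b) which of
seven recurring biological cofactors (ADP, CoA, FAD, heme, NAD, NADP, SAM) a
candidate surface pocket most plausibly binds.  Both tasks share one trunk: the
molecular surface is triangulated, decomposed into overlapping geodesic
patches, featurized geometrically and chemically, and embedded through
learnable Gaussian kernels feeding a small task head.  This note records the
model, the numerical choices, and what the synthetic test corpora do and do
not establish.

## Surface construction

The molecular surface is the iso-level-1 surface of the scalar field
`f(x) = Σ_i exp((R_i − |x − c_i|)/w)`, with `R_i = r_vdw,i + r_probe`
(probe 1.4 Å) and blending length `w = 0.5 Å`, extracted by marching cubes on
a cubic grid (default 0.8 Å edge; the learning corpora use 1.1 Å — roughly
half the vertex count at no measurable cost in the tasks below).  For an
isolated atom the surface is the sphere of radius `R_i` exactly; overlapping
atoms blend smoothly on the scale of `w`.  This is a deliberate smooth
approximation to the solvent-excluded surface: reentrant regions are rounded
rather than traced exactly, which is adequate here because every downstream
quantity is either patch-averaged or residue-aggregated.  Normals come from
the density gradient and are oriented outward; each vertex is mapped to its
nearest heavy atom (ties to the lower atom index) and through it to a residue.

Interior cavity shells, when present, are retained as separate mesh
components rather than removed; geodesic patches never cross between
components, so they are inert for prediction.

## Solvent accessibility and the interface definition

SASA uses the Shrake–Rupley construction: each heavy atom's expanded sphere
(`r_vdw + 1.4 Å`) is sampled at `n` quasi-uniform Fibonacci directions
(default 960 for standalone area computations), and a sample survives iff it
lies outside every other expanded sphere.  Two non-standard but consequential
choices:

* **Intrinsic sample frame.** Sample directions are expressed in the
  principal-axis frame of the heavy-atom cloud (eigenvectors of the coordinate
  covariance, signs fixed by the third moment, right-handed completion).  The
  frame co-rotates with the structure, so computed areas are *exactly*
  invariant under rigid motion instead of merely converging to invariance
  with sample density.
* **Shared frame across a complex.** `delta_sasa` evaluates protomer A,
  protomer B and the merged complex with the complex's frame and the same
  point set.  Burial is then pointwise monotone: per-residue
  ΔSASA = SASA_unbound − SASA_bound is non-negative by construction and
  exactly zero for non-interacting protomers.

A residue is flagged as interface when ΔSASA exceeds 1.0 Å² *and* the residue
is solvent-exposed in its unbound protomer (relative SASA above 5% of a
fixed per-residue-type maximum, Tien et al. theoretical values).  Both
thresholds are configurable; the defaults are the package's operating point.
`delta_sasa` samples at 4000 points per atom by default: interface labelling
compares per-residue areas at sub-Å² resolution, and at 960 points the
sampling error alone approaches 1 Å².

## Per-vertex features

* **Shape index and curvedness** from principal curvatures, estimated per
  vertex by least-squares quadric fit over the 2-ring in the tangent frame of
  the vertex normal.  Shape index is `(2/π)·arctan((κ1+κ2)/(κ1−κ2))`
  (umbilic points resolved by the sign of the mean curvature):  ±1 on
  spheres, ±0.5 on cylinders, 0 on saddles, verified against analytic meshes
  to 0.1.
* **Hydropathy**: Kyte–Doolittle value of the vertex's residue, scaled by
  1/4.5 into [−1, 1].
* **Electrostatic potential proxy**: Coulomb sum over template charges on
  ionisable side-chain termini (Asp/Glu −0.5 per carboxylate oxygen, Lys +1,
  Arg +0.5 per NH) with distance-dependent dielectric ε = 4d and a tanh
  squash.  This stands in for a Poisson–Boltzmann solution; it preserves sign
  and locality of the field but not its magnitude in buried or high-salt
  environments.
* **Hydrogen-bond propensity**: ± cos(angle to the group axis) summed over
  donors (+) and acceptors (−) within 3.5 Å, clipped to [−1, 1].

* **Distance signatures.** Per residue, atoms are classed into six
  pharmacophore roles (hydrophobic, aromatic, donor, acceptor, positive,
  negative; "neutral" atoms are excluded).  For each of the 21 unordered role
  pairs, the signature counts heavy-atom pairs — one atom within 30 Å of the
  residue's Cα (heavy-atom centroid when Cα is absent), partner anywhere —
  whose distance falls below each of the bin edges 2, 4, …, 30 Å.  Rows are
  cumulative by construction.  Each surface vertex inherits its residue's
  flattened signature, concatenated to the five scalar features; scaling to
  unit maximum per column happens at model level over the training corpus,
  and columns that are identically zero over that corpus are dropped from the
  model input (the column mask is stored with the trained parameters).

## Patches and the learnable kernel embedding

Patches are geodesic: all vertices within 12 Å along-surface distance of a
center, computed by Dijkstra on the mesh edge graph (Euclidean edge weights).
Graph geodesics overestimate true surface distance by a mesh-quality factor;
on the test icosphere the pole-to-pole distance is within 6% of π, which is
the scale of error accepted throughout.  Each member gets an angular
coordinate by projection onto the center's tangent plane, measured from the
projection of the center's first incident edge — an arbitrary reference, by
design.

The embedding layer places K = 12 Gaussian kernels on a 3-ring × 4-spoke
polar grid (learnable centers μ_ρ, μ_θ and log-widths).  Kernel k weights
member v by
`exp(−(ρ_v−μ_ρk)²/2σ_ρk² − wrap(θ_v−μ_θk)²/2σ_θk²)`,
normalised so each kernel's weights sum to one over the patch (an all-zero
kernel falls back to uniform weights).  Kernel-weighted feature sums pass
through a linear map to a 16-dimensional embedding and a leaky ReLU
(negative-side slope 0.1: a plain ReLU layer can land in a fully dead state
from which desk-scale full-batch training cannot recover, while symmetric
saturating activations compress the patch-to-patch variation the rotation
max-pool needs).  To remove the
arbitrary angular reference, the embedding is evaluated at 8 equally spaced
global θ offsets and max-pooled elementwise; shifting every θ by one offset
step leaves the result unchanged to numerical precision, which is asserted in
tests.  Patches are thinned to at most 32 members (evenly spaced in ρ order,
center always kept) before embedding.

Heads are single hidden layers (16 units, leaky ReLU): a sigmoid scalar for the
site task, a softmax over classes for the ligand task.  Final-layer weights
initialise to zero, so an untrained model scores 0.5 everywhere (site) or
uniform class probabilities (ligand).  All gradients are hand-derived and
checked against finite differences to 1e-5 relative.

Training uses Adam (learning rate 0.02, full batch) on binary or categorical
cross-entropy for 100 epochs by default; the scaled-down ligand experiments
converge to near-zero loss within 40.  Site
training balances classes per protein — every interface vertex plus an equal
uniform sample of non-interface vertices — then caps both classes at 32
centers per protein.  Ligand training draws one 32-vertex sample per pocket
per epoch; inference averages the softmax over 100 such draws (drawing with
replacement when the pocket is smaller than 32 vertices).  A residue's site
score is the maximum over its surface vertices, favouring sensitivity.  All
randomness flows from explicit seeds (default 17); two same-seed runs are
bitwise identical in single-threaded execution.

## Pocket detection

Candidate pockets come from a buried-probe heuristic: solvent grid points
(1 Å spacing) with clearance between 1.4 and 4 Å of the nearest atom surface
are scored by burial — the fraction of 30 Fibonacci ray directions that hit
the protein within 8 Å.  Probes with burial ≥ 0.5 are clustered by grid
connectivity (26-neighbourhood); clusters of ≥ 4 probes are mapped to surface
vertices within 3 Å and ranked by cluster size.  This is a simple geometric
detector adequate for concave synthetic pockets and for seeding the
classifier; it is not a calibrated cavity-volume method.

## Synthetic corpora: what they emulate, and what passing means

No experimental structures are used anywhere.  Two generators supply all
training and test data, bit-reproducible from their seeds:

* **Toy dimers** are pairs of ideal α-helices (φ = −57°, ψ = −47°; backbone
  N, CA, C, O + CB) placed at van der Waals contact (closest approach 3.6 Å)
  with a controlled axial overlap, jittered by 0.05 Å, and randomly posed.
  The planted truth is the residue set with any inter-chain heavy-atom
  distance < 5 Å — intentionally a different rule than the ΔSASA labelling,
  so their ≥ 0.7 Jaccard agreement on the corpus is a genuine cross-check.
  Corpus geometries are restricted to (length, overlap) pairs where the two
  definitions sit in register; at other axial phases the buried-area band
  extends half a helical turn past the 5 Å band and the agreement
  legitimately degrades.  Contact-facing residues are assigned LEU, the rest
  LYS: real interfaces are marked by hydrophobic surface patches, and a
  monomer-only predictor needs that chemical asymmetry — a geometrically
  perfect but chemically uniform dimer would make the task unlearnable from
  the unbound structure.
* **Toy pockets** are concave shells of single-residue stubs (backbone plus
  inward-pointing side-chain tip atoms) around a schematic cofactor template
  with roughly correct atom counts and element composition.  The lining
  palette is class-specific (e.g. heme: Phe/Leu/Trp; ADP: Lys/Arg/Ser),
  giving the classifier a learnable chemical signal through hydropathy,
  charge and signatures.

Passing the scaled-down learning checks (held-out site AUC ≥ 0.8 over three
seeds on 20 + 5 dimers; ≥ 80% top-1 on 9 held-out pockets over three
classes) therefore demonstrates that the pipeline — labelling, featurization,
patch embedding, training, pooled inference — transmits planted signal end to
end.  It does not demonstrate performance on real proteins: the fixtures have
no conformational variability, no composition diversity beyond the planted
palettes, idealised secondary structure only, and interfaces that are
chemically marked by construction.

## Numerical and degenerate-case choices

* Altloc conformers resolve to highest occupancy (ties: first listed);
  multi-model files keep model 1; waters are dropped; MSE is treated as MET;
  hydrogens are kept if present but all geometry uses heavy atoms only.
* Unknown residues type by element; unknown elements raise.
* Marching-cubes bounding box always includes the largest atom radius plus
  the density cutoff, so single-atom inputs never produce a degenerate grid.
* Vertices with fewer than five 2-ring neighbours get zero curvature;
  patches whose center has fewer than two neighbours get zero angular
  coordinates.
* MCC with a zero denominator is reported as 0; ROC AUC with a single class
  present is reported as missing, never as 0; medians of even-length lists
  are the midpoint of the central pair.
* The classification threshold for confusion metrics defaults to 0.5.

## Known limitations

* The surface is a smoothed union-of-spheres, not an exact solvent-excluded
  surface; curvature features inherit that smoothing.
* Electrostatics is a screened-Coulomb proxy, not Poisson–Boltzmann.
* Graph geodesics overestimate on coarse meshes; patch membership near the
  12 Å rim is correspondingly approximate.
* The pocket detector is a burial heuristic without volume calibration.
* Trained parameters shipped by the test pipeline are desk-scale artifacts
  of synthetic corpora and carry no information about real proteins.
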