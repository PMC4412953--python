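# Methods

This note records the models, parameter choices and numerical
conventions behind `tazstruct`, and what the synthetic-data validation
does and does not establish about real structures.

## Solvent accessibility and burial

SASA is computed with the Shrake–Rupley point-sampling method: each
heavy atom is inflated by a probe radius (default 1.4 Å, water) and
sampled with 960 quasi-uniform sphere points (golden-section spiral);
points inside any neighbouring inflated atom are occluded. Van der Waals
radii are the Bondi set (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å);
unknown elements either raise or fall back to 1.70 Å, configurable.
Hydrogens are ignored throughout.

Sampling directions are expressed in the molecule's principal-axis frame
(covariance eigenvectors, signs fixed by third central moments). Because
the frame co-rotates with the molecule, computed areas are exactly
invariant under rigid motion rather than merely converging to invariance
with the point count; for fewer than three atoms the frame falls back to
the identity. At 960 points the single-sphere error against
4π(r + probe)² is below 0.1%.

Relative accessibility divides residue SASA by a residue-type
theoretical maximum (Tien et al. 2013 Gly-X-Gly values); nonstandard
residues ('X') use the table mean, since no reference maximum exists for
them. A residue is **buried** when relative accessibility is *strictly*
below 0.1 — a residue exactly at 0.1 is exposed. The burial set is
monotone non-increasing in the threshold.

## Contacts and the structural core

Two residues are in contact when their minimum heavy-atom distance is at
most 4.5 Å (sequence neighbours included). The structural core is the
set of connected components of the contact graph induced on buried
residues; singleton components are discarded, because a core is defined
by buried residues in mutual contact. Hydrophobic core statistics use
the residue classes {C, I, L, M, V} ∪ {F, W, Y} ∪ {A} by default; the
set is an argument because published core-composition counts depend on
it.

## Accessibility-weighted alignment

Global alignment uses the Gotoh three-state recursion with a
position-specific gap-open penalty on the template side:
`open(i) = g_min + (g_max − g_min)·(1 − min(rsa_i, 1))` with defaults
g_max = 12, g_min = 4, extend = 1 (BLOSUM62 units). A fully exposed
template position costs g_min to gap, a fully buried one g_max; the
original penalty function of the accessibility-dependent-gap-penalty
approach is not published in reusable form, so this linear map is the
package's own formulation, exposed in full through configuration.

Conventions: a gap run of length L costs `open + extend·(L − 1)`;
deleting template residue *j* opens at `open(j)`; inserting target
residues between template positions *j* and *j+1* opens at the penalty
of position *j+1* (terminal insertions use the last position's penalty);
terminal gaps are penalised like internal ones (true global alignment);
traceback ties prefer diagonal over target-consuming over
template-consuming moves, making output deterministic. With a uniform
profile the method reduces exactly to textbook affine-gap alignment,
which is how it is validated (exhaustive enumeration for short pairs,
Biopython's `PairwiseAligner` for longer ones). Percent identity counts
identical pairs over both-non-gap columns, optionally restricted to
biological-number ranges on either sequence.

## Cleft detection and mouths

The structure is rasterised onto a cubic grid (default spacing 1.0 Å);
a voxel is protein if it lies within vdW + probe of any heavy atom. Each
solvent voxel is scanned along 7 directions (3 axes, 4 cube diagonals);
a voxel enclosed by protein on both sides in ≥ 4 directions is a pocket
candidate. Candidates are clustered by 26-connectivity; clusters under
30 voxels are dropped; pockets are sorted by volume (voxels × spacing³).
Lowering the enclosure threshold can only grow the candidate set. The
grid is capped at 4×10⁷ voxels; exceeding it raises an error suggesting
a larger spacing. This grid scan replaces the alpha-shape web service
used in the original analysis, whose parameters were never published;
openness is made quantitative here: **mouths** are the 26-connected
patches of pocket voxels adjacent to the bulk-solvent component (the
solvent component touching the bounding box, with pocket voxels
excluded). A closed cavity has 0 mouths, a cup 1, an open tube 2.

Cleft-lining residues are those with a heavy atom within 4.0 Å of any
pocket voxel (the original work gives no definition of "forming the
cleft"). Per-exon tabulation reports counts and one-decimal percentage
fractions; residues outside every exon range go to an "unassigned" list
rather than being silently dropped.

## Charge, patches, segments

Net formal charge sums K/R = +1 and D/E = −1; His contributes 0. For
mutation flags, however, His forms its own *charge class* alongside
negative {D,E}, positive {K,R} and neutral: this is the only scheme
consistent with flagging His→Gln and His→Arg exchanges as electrostatic
while a neutral→neutral substitution is not.

Positive patches are single-linkage clusters of exposed (non-buried)
Lys/Arg whose side-chain terminal nitrogens (Nζ; Nη1/Nη2) come within
15 Å; clusters of ≥ 3 residues are reported with their terminal-N
centroid. Histidine can be included optionally.

Transmembrane segments: runs of 19-residue window centres whose mean
Kyte–Doolittle hydropathy reaches 1.6, merged across gaps of ≤ 3.
Disorder: a 21-residue window is disordered when its mean absolute net
charge strictly exceeds the charge–hydropathy boundary
`2.785·⟨H⟩ − 1.151`, ⟨H⟩ being the window-mean Kyte–Doolittle value
rescaled to [0, 1]; equality classifies as ordered. These two simple
published heuristics stand in for multi-predictor consensus servers;
externally computed annotations can be substituted wherever a
`SegmentAnnotation` is accepted. They capture strongly hydrophobic
anchors and strongly charged/hydrophilic segments (the exon-5 case) but
not the subtler cases consensus servers disagree on.

## Mutation classification

Location classes are assigned with precedence catalytic > cleft >
buried > surface. Catalytic positions come from HX4D motif hits
(His at *i*, Asp at *i* + 5; His69/Asp74 in human tafazzin). A non-buried
position is membrane-associated surface if it belongs to a basic patch
or lies within 10 Å of a patch centroid; other exposed positions are
surface with a `distal` qualifier rather than a separate class, keeping
the classification total.

The stability flag fires on any of: (a) alt = Pro (breaks helix/strand
hydrogen bonding); (b) alt = Gly inside cleft or core (flexibility);
(c) ref = Gly (backbone strain); (d) charge-class change in the buried
core; (e) |ΔV| ≥ 20 Å³ (Zamyatnin side-chain volumes) inside cleft or
core; (f) hydrophobic→polar on the membrane surface, with hydrophobic
{A,V,L,I,M,F,W,C} and polar {S,T,N,Q,Y,H}. The electrostatic flag is a
charge-class change. The proposed effect is a function of location
alone: catalytic → catalytic activity, cleft → substrate binding,
surface → membrane association, buried → destabilization. All
thresholds and location gates are configuration values; the packaged
39-variant table pins the defaults — the full rule set reproduces every
printed flag and effect, and each emitted row lists the rules that
fired so flags are auditable.

Secondary structure (used for reporting, not for the flags themselves)
is assigned from backbone torsions: helix for φ ∈ [−100°, −30°],
ψ ∈ [−80°, −5°] in runs of ≥ 4; strand for φ ∈ [−180°, −40°],
ψ ∈ [60°, 180°] in runs of ≥ 3; otherwise coil; termini and residues
with missing backbone atoms are coil.

## Ligand geometry

"Spacing between the two phosphate groups" of a dimeric phospholipid is
ambiguous; the default convention is the distance between the two
groups' oxygen centroids, with minimum O–O and P–P offered as
alternatives. Aggregate statistics use the sample mean and
(n−1)-denominator SD. Basic-residue pairs are compatible with a
reference spacing when their minimal terminal-N distance falls within
mean ± 3.0 Å — a tolerance chosen to admit the 9.2–13.9 Å amino-group
separations observed to coordinate CL head groups against the 8.1 Å
reference only at its upper end, which is the intended behaviour for
flagging plausible two-point anchoring.

## Synthetic data: what it emulates, and what it does not

* Ideal backbones are built by natural-extension-reference-frame chain
  growth with standard bond geometry (N–CA 1.458, CA–C 1.525, C–N
  1.329 Å; ω = 180°), Cβ placed geometrically and a coarse Cγ/terminal-N
  extension for side-chain-dependent stages. The four-helix bundle
  (radius 6 Å, 18 residues per helix) has a genuinely buried interior
  face, recorded as ground truth from the construct's own geometry.
* Pocket constructs are single-layer atom lattices (2 Å spacing) whose
  inflated atoms seal the wall: a closed shell of radius 8 Å, the same
  shell with a 45° cap removed, and an open cylinder (radius 6 Å,
  length 24 Å). Their mouth counts (0/1/2) and lining sets are known by
  construction.
* CL-like ligands place two randomly oriented tetrahedral phosphate
  groups at a Normal(8.1 Å, 0.4 Å) centroid separation — the surveyed
  spacing distribution — so the aggregation statistics can be checked
  against the generator's parameters.

These constructs validate the *operations* (burial logic, connectivity,
enclosure, mouth topology, spacing statistics, alignment optimality) at
full stringency. They do not validate conclusions about real tafazzin:
real side-chain packing, irregular cleft shapes and model-quality
effects are absent, and quantities tied to the original (unavailable)
homology-model coordinates — the specific 57-residue lining, Nζ/Nη
distances, the hydrophobic core count of the template — are exercised
only through their packaged tabulated values or left to users who
supply their own model.

## Problem sizes and determinism

Default validation sizes: 960 sphere points per atom, constructs of
~200–250 atoms, 1 Å pocket grids, 200 generated ligands, 50 enumeration
pairs (length ≤ 6) and 200 affine-oracle pairs (length ≤ 30). All
generators draw from one seeded `numpy` generator per call; identical
seeds give byte-identical output, and the pipeline report body is
reproducible modulo timings.

## Known limitations

* The aligner is pairwise only; multiple-sequence alignment is out of
  scope.
* Altloc resolution keeps the highest-occupancy conformer (ties by
  altloc letter); only the first model of multi-model files is read;
  mmCIF and nucleic acids are unsupported.
* The disorder and TM heuristics are intentionally simple stand-ins for
  consensus predictors (see above).
* Pocket volumes are grid-quantised; rigid-motion invariance of volumes
  holds only to a few grid cells, unlike SASA which is exactly
  invariant by construction.
* The exon map's unconstrained boundaries are approximate (the exon-5
  range and all variant→exon assignments are exact); one variant
  position (Gly80) sits at the exon 2/3 boundary and is kept in exon 2,
  matching the curated table even though a by-site count would assign
  the boundary differently.
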