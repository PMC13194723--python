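# Methods

This note documents the models, estimators and design choices behind
helixgate: what each quantity means, what the synthetic generators do and do
not emulate, and the numerical conventions that affect results.

## Local twist and deviation maps

The local twist of a 4-Cα window (p₁…p₄) is the angle between the unit
internal bisectors b₂ = (p₁−p₂)+(p₃−p₂) and b₃ = (p₂−p₃)+(p₄−p₃). For a
circular helix the bisectors are exactly radial, so θ equals the per-residue
rotation; this identity is what makes the statistic a local unwinding
detector. Windows whose bisector norm falls below 10⁻⁶ Å (collinear or
coincident points — far below physical coordinate noise) raise a geometry
error rather than returning a silent value.

θ from window (i, i+1, i+2, i+3) is assigned to residue i+1, the residue
whose bisector opens the angle. The mapping is a convention, not a physical
fact; `assign_to=2` shifts it one residue down the chain. The first residue
and the last two residues of a selection carry no value.

The deviation Δθ = θ − reference is signed and wrapped to (−180°, 180°].
Wrapping only matters for distortions beyond ±180°, which do not occur for
physically meaningful helices; it is applied for robustness and windows are
never masked, however large the distortion. The reference defaults to the
ideal α-helical 100°/residue and is overridable.

**Reference twist and backbone geometry.** `build_alpha_backbone` constructs
N/Cα/C coordinates by internal-coordinate chaining with Engh–Huber covalent
geometry (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å; N–Cα–C 111.2°, Cα–C–N
116.2°, C–N–Cα 121.7°) and the canonical α-helical dihedrals φ = −57.8°,
ψ = −47.0°, ω = 180°. The resulting Cα local twist is 98.85°/residue — 99 to
the nearest degree. The value is sensitive to the tabulated N–Cα–C angle
(109.5° would give 99.9°); the conventional 100°/residue reference sits
within this tabulation spread, which is why the deviation reference is a
configurable constant rather than derived from a backbone build.

**Time integration.** ∫|Δθ| dt uses the rectangle rule, |Δθ| × Δt per frame,
reported in °·μs. This matches a per-frame sum under the uniform 50 ps
snapshot spacing the package assumes (non-uniform spacing beyond a relative
tolerance of 10⁻⁶ is an error). Because the integrand is an absolute value,
coordinate noise contributes a strictly positive floor to every residue:
with σ = 0.1 Å isotropic noise on the standard helix geometry the floor is
≈ 1.4°/frame, i.e. ≈ 0.07 °·μs over a 0.05 μs trajectory. Event magnitudes
should therefore be read relative to the off-event baseline; the validation
suite estimates the floor as the median integral over off-event residues and
corrects for the fraction of frames the event occupies.

## Synthetic generators

The generators emulate the statistical structure of the real analyses'
inputs, not their physics. All are deterministic given spec + seed, and all
return their exact generative schedule in `Trajectory.ground_truth`.

* **Helix with unwinding events.** One Cα per residue on a circular helix
  (radius 2.3 Å, rise 1.5 Å, 100°/residue — standard α-helical Cα geometry),
  frames every 50 ps. An unwinding event replaces the per-turn rotation over
  a residue span and frame window with a different value (square pulse;
  instantaneous transitions make the time-integrated deviation analytically
  predictable). Isotropic Gaussian noise (per atom, per frame) is added
  after exact placement, so σ = 0 reproduces the analytic geometry to
  machine precision and RMSF has the closed-form expectation σ√3.
* **Two-state flipping loop.** A rigid helical core of 50 residues plus a
  10-residue loop displaced 8 Å along a fixed direction in state-1 frames,
  σ = 0.3 Å everywhere — the regime in which one conformational mode
  dominates a pooled PCA. Replicas share topology and schedule but draw
  independent noise from seeds derived from the spec seed.
* **Engagement schedules.** A rigid 3-atom pseudo-ligand (donor N, central
  C, carboxylate-like O; +1/−1 formal charges) placed per frame according to
  a label schedule: `engaged` (donor 2.9 Å from a motif Cα), 
  `disengaged_in_site` (> 5 Å from every motif atom, inside the site shell),
  `escaped` (beyond the 10 Å escape radius from the site centre). An
  optional bridging-water particle sits midway between the donor and a
  designated motif partner in bridging frames. Ligand and water placement is
  exact (no noise) so the geometric postconditions hold by construction.

What the generators do **not** emulate: force-field energetics, solvent,
periodic boundaries, correlated backbone motion, gradual (non-square)
transitions, and rotameric side-chain detail. Passing tests therefore
demonstrate that the estimators recover known signals of realistic magnitude
under Gaussian positional noise — not that they are robust to every artefact
of real MD data.

## Engagement metrics and fate calls

Hydrogen bonds use the standard geometric criterion (donor–acceptor ≤ 3.5 Å;
D–H···A ≥ 130° when donor hydrogens are available). Topologies without
explicit hydrogens — including all synthetic systems here — fall back to the
distance-only criterion. Occupancy is the percentage of frames with at least
one bond; it is monotone under criterion relaxation. Minimum distances are
heavy-atom only.

Binding fates are judged on the trailing 20% of frames (fates are defined by
end-state behaviour): `bound` if terminal occupancy ≥ 50%, otherwise
`diffused_out` if the ligand centre of mass sits more than 10 Å (the
binding-site shell radius used throughout) from the site centre in the
median of the terminal window, otherwise `disengaged_in_site`. All three
thresholds are parameters of `FateThresholds`; the defaults are decisions,
not inferences of any published protocol's exact settings.

Water-bridge occupancy pools all supplied replicas by concatenation ("gross
simulation time" = the union of frames).

## Fingerprints

Rules and default cutoffs: salt bridge 4.5 Å between opposite formal
charges; π-cation 4.5 Å from the aromatic ring centroid with ≤ 30° axial
offset (ring normal from an SVD plane fit); hydrophobic 4.5 Å between apolar
carbons; hydrogen bond as above; water bridge via a shared water within
H-bond distance of both partners. Charges, rings and apolar-carbon sets come
from a built-in template table (standard amino acids plus ornithine);
explicit topology charges take precedence. Missing template entries raise an
error naming the rule rather than silently skipping atoms.

Per replicate, each (residue, type) row is the fraction of frames with the
interaction present; rows observed in any replicate are scored in all
(absent = 0). Across replicates the mean and sample s.d. (ddof = 1) are
reported; identical replicate frequencies give exactly 0, and a single
replicate reports 0 by convention. The bar heights of published interaction
profiles are not machine-readable, so validation of this module is
property-based (oracle recounts, monotonicity, invariances) rather than
value-matching.

## Ensembles

Kabsch superposition computes the least-squares proper rotation via SVD with
the determinant correction; reflections are never returned, so mirror-image
point sets fit with nonzero RMSD. Configurations with fewer than 3 points or
collinear spread raise errors (the rotation is not unique).

Pooled PCA concatenates all replicas, superposes every frame on the stated
superposition selection (pass the rigid core when analysing a mobile loop,
otherwise the fit absorbs the signal), and decomposes the coordinate
covariance about the *pooled* mean — per-replica means are deliberately not
removed, since between-replica offsets are part of the ensemble. The
implementation is scikit-learn's full-SVD PCA; variance fractions are
eigenvalue/trace and sum to 1 exactly.

Loop-state classification thresholds the PC projection at the midpoint of
the two largest modes of a Gaussian kernel density estimate (peaks must
exceed 5% prominence relative to the maximum); a unimodal distribution
yields a warning and a single state. The sign of a principal component is
arbitrary, so label identity (which state is "flipped_out") is not defined
by the decomposition alone.

Gromos clustering: repeatedly take the frame with the most neighbours within
the RMSD cutoff (1 Å default) as a centre, assign and remove its
neighbourhood. Pairwise RMSD superposes each pair on the clustering
selection before measuring (a no-fit mode exists). Ties in neighbour counts
and in the representative's mean-RMSD are broken by lowest frame index, for
determinism. The representative of the most populated cluster is the member
with minimal mean RMSD to the other members.

## Static comparisons

Cross-conformation Cα RMSD pairs residues by (chain, residue number,
insertion code) intersection; a chain restriction handles depositions whose
transporter chain differs from co-bound binders. Superposition-set choice
(whole chain vs scaffold-only) changes both RMSD and apparent per-atom
displacements, so `state_displacement` takes the superposition selection
explicitly. Identity/similarity use global alignment (BLOSUM62, gap open 10,
extend 0.5) with the alignment length (gap columns included) as denominator;
the shorter-sequence denominator is reported in metadata because published
percentages rarely state their convention. Similarity counts pairs with a
positive substitution score, identities included.

Structure reading (gemmi) keeps blank/'A' altlocs and logs dropped
alternates; residue numbering follows the file and is never renumbered.

## Validation problem sizes

The test suite and acceptance script run at desk scale: 600–1000-frame
trajectories of 30–60 Cα atoms, three replicas for pooled analyses, ≤ 12
frames for exhaustive clustering oracles. These sizes were chosen so the
statistics of interest (event recovery, PC1 dominance ≥ 80%, fate recovery)
are stable across seeds while the full suite completes in well under a
minute; they are the package's fixed study conditions, not tunable knobs.
Event-recovery validation uses σ = 0.1 Å positional noise — at that level
the noise-floor-corrected event integral is unbiased to within a few
percent, while the |Δθ| folding bias grows quadratically in σ and becomes
material above ≈ 0.15 Å for 13° events.

## Known limitations

* The twist statistic needs four consecutive Cα atoms per window; chain
  breaks or missing residues are errors, not gaps.
* Fingerprint typing covers the five listed interaction classes only (no
  halogen bonds, π-stacking or metal coordination) and relies on template
  annotations for non-standard residues.
* `engagement_series` uses the distance-only H-bond criterion when the
  topology lacks hydrogens, which overcounts bonds relative to an
  angle-aware analysis of all-atom data.
* The plain trajectory format stores coordinates at 10⁻⁶ Å precision;
  binary-format round-trips are limited by the underlying format (10⁻³ Å
  for PDB).
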