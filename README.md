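# helixgate

Analysis toolkit for molecular-dynamics studies of ligand-gated transporters
in the APC superfamily, where substrate binding locally unwinds a
transmembrane helix (the TM1 "GAG" di-glycine motif) and mobile extracellular
loops toggle between discrete conformations. The package provides the full
post-processing chain for such studies — helix-geometry statistics, ligand
engagement metrics, interaction fingerprints, ensemble decomposition and
clustering, and static structure/sequence comparisons — together with
synthetic-trajectory generators that carry exact ground truth, so every stage
can be validated without multi-microsecond simulation data.

It is written for structural bioinformaticians and simulation scientists who
want these analyses as a tested, reusable library rather than one-off
notebook code.

## What it computes

**Local helical twist and deviation maps.** For a sliding window of four
consecutive Cα atoms (p₁…p₄), the local twist is the angle between the two
internal bisector vectors

&nbsp;&nbsp;&nbsp;&nbsp;b₂ = (p₁−p₂)+(p₃−p₂), b₃ = (p₂−p₃)+(p₄−p₃),
&nbsp;&nbsp;&nbsp;&nbsp;θ = arccos(b̂₂·b̂₃),

which on an exact helix equals the per-residue rotation — 100°/residue for an
ideal α-helix (the HELANAL construction). The signed deviation Δθ = θ − 100°
(wrapped to (−180°, 180°]) localises unwinding along the helix and over time,
and the per-residue time integral ∫|Δθ| dt (°·μs) summarises its magnitude.

**Ligand engagement and binding fates.** Per-frame hydrogen-bond counts
(donor–acceptor ≤ 3.5 Å, D–H···A ≥ 130° when hydrogens exist), minimum
heavy-atom distances, percent H-bond occupancy, water-bridge occupancy, and a
three-way end-state fate call per replica: `bound`, `disengaged_in_site`, or
`diffused_out`.

**Interaction fingerprints.** Per-residue typing of hydrogen bonds, salt
bridges, π-cation, hydrophobic contacts and water bridges per frame, with
across-replicate mean and sample standard deviation per (residue, type) row.

**Ensembles.** Kabsch superposition, pooled-replica Cα PCA with variance
fractions and two-state loop classification, and gromos RMSD clustering
(default 1 Å cutoff) with the cluster-median representative (minimal mean
RMSD to the other members of the most populated cluster).

**Static comparisons.** Cα RMSD between conformations, binding-site residue
shells, minimum heavy-atom contact distances, apo-vs-bound per-atom
displacements, and global sequence identity/similarity (Needleman–Wunsch,
BLOSUM62, affine gaps).

## Worked example

Generate a 1000-frame helix trajectory (30 residues, 50 ps/frame, 0.1 Å
noise) with one seeded unwinding event — 87°/residue across residues 13–16
for frames 200–799 (0.03 μs of simulated time at 13° deviation) — and
quantify it:

```python
from helixgate.synthgen import HelixSpec, UnwindEvent, generate_helix_trajectory
from helixgate.helixgeom import twist_map, integrate_deviation

spec = HelixSpec(n_residues=30, n_frames=1000, noise_sigma=0.1, seed=42)
event = UnwindEvent(residue_span=(12, 15), event_twist=87.0,
                    start_frame=200, end_frame=799)
traj = generate_helix_trajectory(spec, [event])

tmap = twist_map(traj)                  # Δθ per residue per frame
integ = integrate_deviation(tmap)       # ∫|Δθ| dt per residue, °·μs
print("argmax residue:", integ.argmax_residue())
print("max integral  :", round(float(integ.value.max()), 3))
```

prints

```
argmax residue: 15
max integral  : 0.46
```

The profile peaks inside the seeded span, and the integral matches the
analytic expectation 13° × 0.03 μs = 0.39 °·μs plus the trajectory-wide
noise floor (≈ 0.07 °·μs at this noise level; see `docs/methods.md`).

The same analyses are available from the shell:

```sh
helixgate generate helix --seed 1 --n-frames 200 --out demo/
helixgate twist --traj demo/helix_0.traj --plot --out demo/twist/
helixgate run --seed 1 --out demo/full/      # all stages + manifest
```

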