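# Methods

This note documents the models, numerical choices and limitations of
`gmmrefine` at the level a maintainer needs to reason about its behavior.

## Model representation and map loss

Each non-hydrogen atom carries one isotropic 3D Gaussian (amplitude,
width σ, center). Amplitudes are initialized proportional to atomic number
(carbon = 1); the global width is calibrated to the working resolution as
σ = max(0.5 Å, 0.3·d) for target resolution d — chosen so that rendered
maps are band-limited near d and voxelization aliasing stays below the FRC
tolerances at the voxel sizes used here. Amplitudes and widths become
refinable (as per-atom log-deltas) only in the full-atom stage.

Map–model similarity is evaluated on 2D projections: the analytic
line-integral projection of the mixture (each atom contributes a 2D
Gaussian scaled by σ√(2π)/pixel) against real-space projections of the map
(cubic-spline resampling, content rotated by the same operator). The FRC
averages per-ring normalized cross-correlations from the first ring (DC
excluded) to the ring at the cutoff resolution; rings with vanishing power
contribute zero rather than NaN. Orientations come from a fixed
quasi-uniform set of random unit quaternions (default 24, seeded); map
projections are cached per orientation. Gradients of the FRC with respect
to projection pixels are obtained from the Wirtinger derivative through the
FFT, then chained to centers/amplitudes/widths through the separable
Gaussian splats; all gradient paths are verified against central finite
differences in the test suite.

## Geometry dictionary and topology

Ideal intra-residue bond lengths and angles are derived at run time from
the ideal coordinates of the chemical component definitions bundled with
biotite, with shipped standard deviations (bonds 0.021 Å, angles 2.0°) and
a small link table for peptide and phosphodiester junctions. Chain breaks
(residue-index gaps or link bonds stretched beyond 2.5 Å) suppress
inter-residue restraints. Planar groups are restrained through torsions
whose planar value is 0° or 180°; peptide ω uses the 30° threshold and all
other planar groups 10°. The per-model topology (bond pairs, angle triples,
dihedral quads, χ quads with their rotating atom sets, RNA suite quads, and
the bonded-within-3 exclusion set) is compiled once into flat index arrays.

Hydrogens ride on their parent heavy atoms: in-plane amide H on the
external bisector of C(i−1)–N–CA, frame-based placement from ideal
component geometry where the parent has two heavy neighbors, and internal
coordinate construction for torsionally free groups (CH3/OH/NH3) at a fixed
default torsion — first H anti to the reference atom, siblings evenly
spaced — which makes placement deterministic and idempotent, matching the
convention that validation re-places hydrogens at default torsions.
Clash-loss gradients landing on hydrogens are transferred to their parents
(riding-atom approximation); everywhere else gradients are exact.

## Histogram mixtures (Ramachandran and rotamers)

Discrete validation histograms become differentiable by fitting periodic
Gaussian mixtures to ln(R + C), C = e⁻¹⁰, so the tiny outlier threshold
(R < 0.0005) stays resolvable. The 2D Ramachandran fit uses 2500 components:
roughly 40% on a uniform torus grid solved by ridge least squares with an
explicit intercept (flat regions and the floor level are absorbed exactly),
then rounds of residual-driven placement with decreasing widths
(8° → 2.4°, floored at 1.2 grid steps), each followed by a joint re-solve.
A final iteratively-reweighted pass adds a one-sided penalty on
histogram-outlier cells whose fitted score exceeds the outlier contour,
guaranteeing that histogram outliers remain outliers under the fitted
surface. On the package's default synthetic histogram (five peaks emulating
the α/β/left-handed regions) the fit reaches a grid RMSD of ~3×10⁻⁴ on the
log scale with 100% outlier-cell agreement. Denser targets fit less
tightly; see Limitations. This direct linear-algebra fit replaces a
stochastic network-based fit; it is deterministic given the seed and
considerably faster on one CPU.

Rotamer histograms (1–4 χ dimensions; 4/25/64/160 components) are fitted by
seeding components at detected histogram peaks (wrap-aware local maxima),
placing any surplus at the largest residuals, and optimizing weights and
widths with full-batch Adam while centers stay anchored within a fraction
of a grid step of their peaks — the optimization is local by construction,
so library peaks remain meaningful anchors for rotamer enumeration. The
rotamer outlier threshold on the original score scale defaults to 0.003 (a
MolProbity-style convention; the exact validation value is not published).

Periodicity is handled by minimum-image angle differences; component widths
are capped well below 90°, which makes this identical to replicating
components across torus images. Scoring classifies Ramachandran residues
into General/Gly/trans-Pro/cis-Pro/pre-Pro/Ile classes (cis/trans resolved
from the preceding ω at score time; the favored boundary R ≥ 0.02 follows
the MolProbity convention). The training surrogate is a sum of sigmoids on
the log score at the outlier and favored thresholds, weighted 10:1 in favor
of outliers.

## Clashes

Candidate pairs come from a KD-tree within 6 Å, excluding pairs bonded or
connected within three bonds, capped at 128 partners per atom and refreshed
every 100 iterations. A pair clashes when its distance falls below
r₁ + r₂ − 0.4 Å; for H paired with an O/N acceptor the threshold drops by a
further 0.4 Å (atom-type pairing only — no H-bond angle test). The
differentiable penalty is the sum of squared softplus-smoothed overlaps
(β = 0.05 Å); reported clash counts use the hard threshold.

## RNA suites

Each base step yields the (δ₋₁, ε₋₁, ζ₋₁, α, β, γ, δ) vector, assigned to
the nearest of 46 named cluster centers under a per-dimension scaled
circular RMS distance. Suiteness follows the suitename convention
((cos πd + 1)/2)³ for scaled distance d < 1. The reported mean skips steps
with suiteness < 0.001 (validation convention); the training loss is a
pseudo-Huber function of the distance to the assigned center over *all*
steps, so outlier steps keep nonzero gradient and cannot be traded away for
a few perfect ones. The shipped center table is a constructed stand-in
following the suitename conventions (46 names, A-form as cluster 1a,
per-dimension widths); the published table can be substituted as plain-text
package data. δ-pucker gating is deliberately omitted — assignment is plain
nearest-center in the scaled 7D space.

## Single-model refinement

Three 4-layer dense ReLU networks (hidden width 64 by default at desk
scale) map the conformation input — constant ones, 4D, for a single
model — to (1) per-patch rigid transforms (small-angle Euler rotations
about the patch centroid plus translations; patches from seeded K-means on
residue centers, atoms always following their residue), (2) per-residue
rigid transforms, and (3) per-atom coordinate offsets plus
amplitude/width log-deltas. Outputs are additive on top of the input
model; final layers are zero-initialized so the untrained decoder
reproduces the input bit-for-bit.

Stages: (1) topology compilation; (2) D1 against the FRC only at
max(target, 10 Å); (3) D1+D2 with bond/angle/clash added at
max(target, 6 Å); (4) optional rotamer rebuild plus direct Adam
optimization of all χ angles (enabled when the target resolution ≤ 3.5 Å or
by flag); (5) D1+D2+D3 with every stereochemical term at the target
resolution.

The geometry weight follows the reciprocal rule: two geometry-free
iterations measure Δ(map score)/Δ(geometry score), and the weight is the
reciprocal of that ratio, after which the networks are re-initialized. Two
stabilizations were necessary at desk scale and are exposed as
configuration: the auto weight is clamped to [0.01, 10] (heavily distorted
synthetic inputs produce geometry scales thousands of times the FRC scale,
and an unclamped weight silences the map entirely), and per iteration the
weighted geometry gradient norm is capped at twice the map gradient norm so
neither term goes silent. Every 25 iterations the full-orientation
objective is evaluated — with the map term always at the *target*
resolution, because the few Fourier rings of a coarse stage are degenerate
and cannot detect wandering — and the best decoder state is restored at
stage end. This implements the stage-boundary guarantee that a stage never
leaves the model worse than its best visited state, and recovers cleanly
from non-finite losses.

Desk-scale defaults (iterations 300/200/300, width 64, learning rate 1e-2
with Adam) reflect the problem sizes this package is exercised at
(10–30-residue fixtures, 24–40-pixel boxes); they are ordinary
configuration fields and scale up straightforwardly.

The inverted-geometry mode (the validation-metric sensitivity experiment)
trains D3 alone, map off, to *maximize* a saturating surrogate of the
outlier counts — sigmoids on |z| around 5.5 σ for bonds/angles, the planar
thresholds plus 2°, the Ramachandran outlier surrogate, and a smooth count
of overlapping pairs — under a proximal displacement penalty (0.5 Å⁻²) and
a hard 0.3 Å per-atom displacement cap. Saturation is the point: validation
metrics are counts, so once a restraint is an outlier nothing is gained by
pushing further, and atoms stop moving — tiny displacements (mean ≈
0.15–0.2 Å here) are enough to destroy every metric.

## Series refinement

Inputs are (map, latent coordinate) pairs from any heterogeneity analysis.
Training mirrors the single-model procedure but feeds each batch the latent
of the sampled reconstruction plus Gaussian jitter (default 5% of the
trajectory path length) and pairs it with that sample's projections. After
the map-driven phase, geometry-only polishing rounds update D3 alone at
latents drawn along the trajectory, with the gradient batched over all
emission latents plus a random one per step (per-frame corrections
otherwise fight each other through the shared weights); a trust radius
(default 1 Å, probed every 20 rounds) reverts polishing that drifts the
series away from its map-trained state. Frames are emitted at arc-length
uniform points along the latent path; closed paths wrap. The target
resolution for series refinement is a required user input — no estimator
for the resolution of heterogeneity trajectories exists.

## Synthetic fixtures

Peptides are built by internal-coordinate chaining using exactly the
dictionary's ideal values (helix φ/ψ = −57/−47, strand −139/+135; carbonyl
O anti to the next amide N; ω = 180°), with sidechains grafted by rigid
superposition of ideal component coordinates onto the built N/CA/C frame
and χ set to canonical staggered rotamers. RNA strands chain ideal
nucleotides through the phosphodiester link at near-A-form torsions
(ε, ζ, α = −148°, −90°, −90°, adjusted so the ideal-component sugar
conformation yields a clash-free strand), with the free phosphate oxygens
rebuilt around the P tetrahedron. Generated models score zero geometry
outliers and zero clashes by construction — the cross-module consistency
anchor of the test suite. The two-state fixture applies a hinge rotation
about a chosen residue's CA with a ±2-residue linear ramp so local geometry
stays within restraint tolerances. Simulated maps voxelize the mixture at
the resolution-calibrated width with no separate filter (per-ring FRC
normalization makes any radial filter irrelevant). Synthetic histograms are
known mixtures over a uniform floor, max-normalized, with ground-truth
peaks retained for recovery tests.

What fixtures do not emulate: experimental noise, CTF effects, solvent
background, B-factor heterogeneity, map anisotropy, or real conformational
ensembles. Passing tests therefore demonstrate correctness of the machinery
and recoverability under idealized signal, not performance on experimental
reconstructions.

## Known limitations

* The Ramachandran fitter reaches the ~10⁻³ log-RMSD regime on histograms
  with a handful of broad basins (the realistic case). Synthetic targets
  with many separated peaks spread structure over most of the torus; with
  the 2500-component budget the fit plateaus near 3×10⁻³ there. The
  boundary guarantee (all histogram outliers stay outliers) holds in every
  case tested.
* The auto-balance rule assumes map and geometry scores of comparable
  scale; the clamp and gradient cap above are engineering guards, not part
  of the rule.
* Rigid-patch additivity: when several decoders are active their rigid
  deltas add, so the composition is only approximately rigid; exact
  rigidity holds when a single rigid decoder is active (asserted in tests).
* Unknown residue types pass through unrestrained (no ligand dictionaries);
  DNA is restrained only through bonds/angles; B-factors, occupancies and
  symmetry are out of scope.
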