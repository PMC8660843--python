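# Methods

This note documents the models and numerical choices behind `lhcquench`,
what the synthetic generators do and do not emulate, and the limits of what
the test suite demonstrates.

## Conformational landscape (dPCA + clustering)

**Featurization.** The ensemble is reduced to backbone φ (C′₋₁–N–Cα–C′),
ψ (N–Cα–C′–N₊₁) and sidechain χ₁ (N–Cα–Cβ–Cγ) torsions. Torsion signs
follow the IUPAC right-hand rule; values live in (−π, π]. Which sidechain
torsions to include is genuinely open — χ₂ and beyond vary by residue type
and add little discriminating power for compact states — so the default set
is φ/ψ/χ₁ with the set configurable (`dihedrals.include`). Dihedrals whose
atoms do not exist (chain termini) are silently dropped; torsions with
collinear central atoms are flagged NaN per frame rather than failing the
run.

**Circular embedding.** Each angle θ maps to the pair (cos θ, sin θ),
interleaved per feature. This removes the ±π branch cut before any linear
statistics; the map is invertible up to angle identity via atan2.

**PCA.** Weighted-mean-centered covariance (normalized by total weight,
i.e. the ddof=0 convention — projected column variances equal eigenvalues
exactly), full symmetric eigendecomposition, eigenvalues clipped at zero
and sorted descending. Component sign is otherwise arbitrary; it is fixed
by requiring the largest-magnitude loading of each component to be
positive (ties → lowest feature index), which makes projections and plots
reproducible across runs and BLAS builds. Three components are retained by
default; the leading two or three carry the basin structure in practice.

**Clustering.** Ward linkage on Euclidean distance in retained-PC space
(`scipy.cluster.hierarchy`), cut at a configured number of clusters — no
automatic model selection in the core, since the right number of states is
a scientific choice. Labels are relabeled by descending cluster size so
cluster 0 is always the dominant state. Ward suits the compact,
variance-defined basins the dPCA projection produces; the linkage is
config-overridable.

**Residue importance.** Per feature, an F-like statistic on the embedded
(cos, sin) pair: between-cluster scatter of per-cluster means over
within-cluster scatter, each divided by its degrees of freedom. The
denominator carries a tiny relative epsilon (10⁻¹² of total scatter) so a
perfectly separated, noise-free feature yields a very large but finite
score and still dominates the ranking. A residue scores the maximum over
its features; ties rank the lower residue number first.

**Representatives.** Greedy farthest-point (max-min) sampling within each
cluster, seeded at the cluster medoid, ties toward the lower frame index.
Greedy max-min is a 2-approximation to the optimal-dispersion subset; the
tests assert that provable bound by brute force on small instances.

**Free-energy surfaces.** F(bin) = −kT ln(w(bin)/w_max) on a weighted 2-D
histogram, so min F = 0 by construction and empty bins are +∞ (undefined,
never negative). Scaling all weights by a constant leaves F unchanged.
kT = 1 by default (surfaces in thermal units).

**RMSF.** Frames are superposed on the mean structure by Kabsch alignment,
the mean recomputed, and the cycle run twice (a second iteration changes
the mean negligibly for well-behaved ensembles). Per-residue RMSF is the
root mean square deviation of the residue's atoms from the converged mean.

## Collective variables

**P1 torsions.** The torsion of the centers of geometry of four atom
groups (nodes A2–A1–B1–B2) on helices A and B, in degrees, with lumenal
and stromal variants. The residue ranges defining the nodes are
config-supplied: published figures place the nodes on the helices but the
exact ranges are not part of the main-text record, so the synthetic
fixture uses four disjoint Cα windows along the chain and real runs must
set their own (the run config echoes them into the manifest).

**Carotenoid chain dihedrals.** All consecutive 4-atom torsions along an
ordered atom list, named d1…dN from the declared (lumenal) end. The
s-cis/s-trans rule is |θ| < 90° → s-cis, boundary to trans: no published
threshold exists, and the symmetric midpoint is the only choice that
treats both wells identically and is exactly testable.

**Distribution summaries.** Box-plot statistics with linear-interpolation
(type-7) quartiles and whiskers at the most extreme point within 1.5 IQR
of the box. For angular data, `circular="auto"` switches to circular
statistics (recenter on the circular mean, take quartiles in the shifted
frame, map back) when a group's linear spread exceeds 90° — the regime
where the ±180° wrap would corrupt linear quartiles.

## Pigment couplings

**Coulomb (TrEsp).** V = K Σᵢⱼ qᵢqⱼ/rᵢⱼ over all cross pairs, computed via
a distance-matrix contraction and verified against a naive double loop to
1e−12 relative. K converts e²/Å to cm⁻¹ and is assembled once from CODATA
2022 constants (Hartree→cm⁻¹ × Bohr→Å = 219474.6313… × 0.5291772105… ≈
1.16141 × 10⁵). No distance cutoff is applied — pigments are small and a
cutoff would bias far-field tails, which matter for the 1/r³ dipole regime
the tests check.

**Overlap parameter.** O = Σᵢⱼ v(rᵢⱼ; Rᵢ, Rⱼ) where v is the analytic
sphere–sphere intersection volume (zero beyond contact, spherical-lens
formula in between, full containment of the smaller sphere handled
exactly). Radii are Bondi van der Waals radii times one global scale
factor (default 1.0, config-exposed) — the scale is the acknowledged free
parameter of this geometric proxy. Hydrogens are excluded by default
(heavy-atom convention, config-exposed). This lens-volume sum is the
package's declared stand-in for electron-density overlap: it reproduces
the qualitative behaviour that matters (zero at no contact, monotone
growth with interpenetration) but is not an ab initio overlap.

## Marcus rates

Classical high-temperature expression only — no quantum modes — because the
inputs (ΔG, λ, V) arrive as externally computed tables and the classical
form is the one those energetics support. Rates are maximal at ΔG = −λ,
where the returned activation term is exactly zero. Unit handling: V in
cm⁻¹ → J via hc, energies in eV → J, all constants CODATA 2022 from scipy
(note: the 2022 adjustment moved the Bohr radius by ~7 × 10⁻¹⁰ relative;
the SI-defined constants h, c, k_B, e are exact and edition-independent).
A channel is "active" when k ≥ ratio × competing decay rate (boundary
inclusive, default ratio 1).

## Synthetic generators

`generate_ensemble` grows an ideal polyalanine-like scaffold (6 atoms per
residue: N, Cα, C′, O, Cβ, Cγ) by NeRF from fixed bond lengths and angles;
the φ/ψ/χ₁ torsions are the only degrees of freedom. Planted features are
drawn per frame from per-cluster von Mises distributions (κ = ∞ pins the
angle exactly); every other torsion sits at ideal helix values plus
von Mises jitter with circular std `noise_level` (default 0.08 rad — tight
thermal jitter, small against the planted π separation). Cluster
membership is drawn from the configured weight vector. One integer seed
drives all draws; identical spec + seed is bitwise-identical output.

Defaults for the planted landscape (2 equal-weight basins separated by π
on three χ₁ torsions, κ = 50, 500 frames) put basin separation ≈ 22×
the circular std — comfortably in the regime where state recovery should
be exact, which is the point: the generator tests the machinery, not the
difficulty of real landscapes. What it does **not** emulate: excluded
volume, correlated backbone motions, solvent, realistic energetics, or
the slow interconversion kinetics of a real LHC. Passing tests therefore
demonstrate correctness of the analysis chain, not that real trajectories
will cluster as cleanly.

`generate_conjugated_chain_series` builds a 10-carbon zigzag (bond 1.45 Å,
angle 120°) whose first torsion is drawn near 0° with the planted s-cis
probability and near 180° otherwise (von Mises, 10° circular spread; the
remaining torsions get 5° spread about 180°). `generate_pigment_pair`
places two rigid planar 4-atom chromophores with a charged edge (+q/+q
vs −q/−q ⇒ net zero, dipole 1.4·2q e Å) at an exact separation along z
and in-plane rotation — net-neutral with a clean leading dipole so the
far-field 1/r³ law is testable.

## Pipeline and determinism

Stages run in fixed order; each writes TSV through one writer with a fixed
float format (`%.8g`), so reruns with identical inputs are byte-identical
and the manifest's SHA-256 digests match. Any stage failure aborts with
the stage name. Validation reports all config problems at once (schema,
dangling selections, missing files) before any compute. The default
synthetic fixture (200 frames, ~500 atoms, one pigment pair) runs the full
pipeline in a few seconds on one CPU; test problem sizes throughout
(500-frame ensembles, 10⁵-sample free-energy checks) were chosen as the
smallest sizes at which the statistical assertions have comfortable
margins.

## Known limitations

* The overlap parameter is a geometric proxy; its absolute scale is only
  meaningful relative to a calibrated sphere-scale factor.
* Circular quartiles are well-defined only for unimodal angular groups;
  bimodal groups (e.g. a mixed cis/trans population) should be split by
  conformer label first, as the pipeline's summaries do.
* Binary trajectory formats are out of scope; ensembles enter as
  multi-model PDB (3-decimal coordinate precision).
* Marcus rates use the classical expression; strongly exergonic channels
  with high-frequency modes would need a quantum-corrected form.
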