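# lhcquench

Analysis pipeline for the conformational control of quenching in plant
light-harvesting complexes (LHCs). Given a conformational ensemble of a
pigment–protein complex such as CP29 — a multi-model PDB from enhanced-sampling
MD — the package answers the questions that decide between a light-harvesting
and a quenched state:

* **Which conformational states does the protein visit?** Dihedral principal
  component analysis (dPCA): backbone φ/ψ and sidechain χ₁ torsions are
  embedded circularly as (cos θ, sin θ), a weighted PCA is fitted, and frames
  are grouped into states by Ward hierarchical clustering in the space of the
  leading components. Free-energy surfaces F = −kT ln(ρ/ρ_max) are built on
  any 2-D projection, residues are ranked by how strongly their dihedrals
  discriminate the states, and farthest-point sampling picks representative
  frames per state.
* **How do the states move the pigments?** Bespoke collective variables: the
  inter-helical torsions P1_l / P1_s (torsion of four node centroids
  A2–A1–B1–B2 on helices A and B, lumenal and stromal variants), all
  conjugated-chain dihedrals d1…dN of a carotenoid, and the s-cis/s-trans
  conformer classification (|θ| < 90° → s-cis) that captures the "pedaling"
  flip of the chain ends.
* **What do the pigments feel?** For each carotenoid–chlorophyll pair, the
  TrEsp Coulomb coupling V = K Σᵢⱼ qᵢqⱼ/rᵢⱼ (transition charges in e,
  distances in Å, K ≈ 1.1614 × 10⁵ cm⁻¹ Å/e²) and the rigid-sphere **overlap
  parameter** — the summed intersection volume of atom-centered van der Waals
  spheres — a geometric proxy for the short-range (exchange/CT-mediated)
  coupling the Coulomb term misses.
* **Is a charge-transfer quenching channel open?** Classical Marcus rates
  k = (2π/ħ)|V|²(4πλk_BT)^(−1/2) exp(−(ΔG+λ)²/4λk_BT) from user-supplied
  energetics tables, with an active/inactive call against a competing decay
  rate.

A synthetic-data module generates ensembles with *planted* ground truth —
multi-basin von Mises dihedral distributions on an ideal helical scaffold, a
conjugated chain with a planted s-cis fraction, toy pigment pairs at exact
separations — so the whole pipeline is testable without trajectory data.

## Worked example

```python
import lhcquench as lq
from sklearn.metrics import adjusted_rand_score

spec = lq.make_basin_spec(n_clusters=2, n_frames=500, n_residues=20, seed=0)
ensemble, truth = lq.generate_ensemble(spec)
features = lq.compute_dihedrals(ensemble, lq.standard_dihedral_quadruples(ensemble))
embedded = lq.circular_embed(features)
model = lq.fit_pca(embedded)
proj = lq.project(model, embedded, n_components=3)
clusters = lq.hierarchical_cluster(proj, n_clusters=2)
print(adjusted_rand_score(truth.labels, clusters.labels))
```

Running `python examples/conformational_landscape.py` prints:

```
frames: 500, dihedral features: 58
PC1/PC2 explained variance: 0.876 / 0.007
cluster sizes: [277, 223]
ARI vs planted labels: 1.000
top-3 discriminating residues: [5, 15, 10] (planted: [5, 10, 15])
free-energy surface: 47 occupied bins, max barrier 3.26 kT
```

PC1 carries 88% of the embedded variance because the two planted basins
differ by a 180° flip of three χ₁ torsions; clustering in that space
reproduces the planted state labels exactly (ARI 1.0), and the residue
ranking singles out exactly the three residues whose torsions were flipped.
The other scripts in `examples/` walk through conformer classification
(`carotenoid_conformers.py`), coupling/overlap behaviour
(`pigment_couplings.py`), Marcus rates (`marcus_rates.py`) and the full
orchestrated run (`full_pipeline.py`).

## Command line

The same pipeline is scriptable from a shell:

```bash
lhcquench simulate run_dir --n-frames 200 --seed 0   # synthetic fixture + config
lhcquench validate run_dir/config.yaml               # exit 2 on config errors
lhcquench run run_dir/config.yaml                    # all stages -> TSV + manifest
```

Outputs are plain TSV tables plus a `manifest.json` with a SHA-256 per
artifact; a rerun with the same seed is byte-identical.

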