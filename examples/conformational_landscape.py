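"""Recover planted conformational states with dihedral PCA + clustering.

Generates a 500-frame two-basin ensemble (three chi1 dihedrals flipped by
180 deg between basins), runs the dPCA -> Ward clustering -> residue
ranking chain, and compares against the planted truth.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

import lhcquench as lq

spec = lq.make_basin_spec(n_clusters=2, n_frames=500, n_residues=20, seed=0)
ensemble, truth = lq.generate_ensemble(spec)

quads = lq.standard_dihedral_quadruples(ensemble)
features = lq.compute_dihedrals(ensemble, quads)
embedded = lq.circular_embed(features)
model = lq.fit_pca(embedded, ensemble.frame_weights)
proj = lq.project(model, embedded, n_components=3)
clusters = lq.hierarchical_cluster(proj, n_clusters=2)
importance = lq.residue_importance(features, clusters.labels)

explained = model.eigenvalues / model.eigenvalues.sum()
print(f"frames: {ensemble.n_frames}, dihedral features: {len(features.labels)}")
print(f"PC1/PC2 explained variance: {explained[0]:.3f} / {explained[1]:.3f}")
print(f"cluster sizes: {clusters.counts.tolist()}")
print(f"ARI vs planted labels: {adjusted_rand_score(truth.labels, clusters.labels):.3f}")
print(f"top-3 discriminating residues: {importance.top_residues(3)} (planted: [5, 10, 15])")
# ARI 1.0 means the hierarchical clustering in dPCA space reproduces the
# planted basins exactly; the top-ranked residues are the ones whose
# sidechain torsion was flipped between basins.

fes = lq.free_energy_surface(proj.scores[:, :2], ensemble.frame_weights, bins=30)
occupied = np.isfinite(fes.free_energy)
print(f"free-energy surface: {occupied.sum()} occupied bins, "
      f"max barrier {fes.free_energy[occupied].max():.2f} kT")
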