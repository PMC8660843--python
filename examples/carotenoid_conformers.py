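"""Classify s-cis / s-trans conformers of a pedaling conjugated chain.

The first torsion of a toy carotenoid chain is planted near 0 deg
(s-cis) in 30% of 2000 frames and near 180 deg (s-trans) otherwise;
classification of the computed d1 torsion recovers that fraction.
"""

import numpy as np

import lhcquench as lq

ensemble = lq.generate_conjugated_chain_series(n_frames=2000, s_cis_fraction=0.3, seed=1)
record = lq.compute_car_dihedrals(ensemble, [f"C{i+1}" for i in range(10)])

recovered = float(np.mean(record.conformer[:, 0] == "s-cis"))
se = np.sqrt(0.3 * 0.7 / 2000)
print(f"planted s-cis fraction: 0.300, recovered: {recovered:.4f} "
      f"(3 SE band: +-{3*se:.4f})")

summary = lq.distribution_summary(
    record.values_deg[:, 0],
    groups=np.asarray(record.conformer[:, 0]),
    circular="auto",
)
print(summary[["group", "n", "median", "q1", "q3", "circular"]].to_string(index=False))
# The s-cis group's circular median sits near 0 deg and the s-trans group's
# near +-180 deg — the two wells of the pedaling coordinate.
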