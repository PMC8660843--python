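"""Synthetic ensembles with planted ground truth.

Three generators feed the downstream analyses:

* :func:`generate_ensemble` — a two-helix polyalanine-like scaffold whose
  backbone (phi, psi) and sidechain (chi1) torsions are the only degrees of
  freedom.  Selected "planted" dihedrals are drawn per frame from
  per-cluster von Mises distributions, creating a multi-basin conformational
  landscape with known frame labels.
* :func:`generate_conjugated_chain_series` — a toy conjugated chain whose
  first torsion flips between s-cis (near 0 deg) and s-trans (near 180 deg)
  with a planted fraction, mimicking the pedaling motion of a carotenoid
  chain end.
* :func:`generate_pigment_pair` — two rigid planar toy chromophores with
  net-neutral transition charges at an exactly controlled separation and
  relative rotation, for coupling/overlap analyses.

All randomness flows from a single integer seed; identical spec + seed
gives bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import nerf_place, rotation_about_axis
from .io import ConformationalEnsemble, PigmentChargeSet, write_table

__all__ = [
    "EnsembleSpec",
    "PlantedTruth",
    "PigmentPair",
    "generate_ensemble",
    "generate_conjugated_chain_series",
    "generate_pigment_pair",
    "make_basin_spec",
    "write_truth_labels",
]

# Ideal scaffold internal coordinates (Angstrom / degrees): standard
# peptide values; alpha-helical base dihedrals.
_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
         "CA-CB": 1.530, "CB-CG": 1.520}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7,
          "CA-C-O": 120.5, "N-CA-CB": 110.5, "CA-CB-CG": 114.0}
_BASE_DIHEDRAL_DEG = {"phi": -57.0, "psi": -47.0, "chi1": -60.0}
_CB_PLACEMENT_TORSION_DEG = 122.0  # fixed improper-like torsion C-N-CA-CB
_OMEGA_DEG = 180.0

RESIDUE_ATOMS = ("N", "CA", "C", "O", "CB", "CG")
_ATOM_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "CG": "C"}
DIHEDRAL_NAMES = ("phi", "psi", "chi1")


@dataclass(frozen=True)
class EnsembleSpec:
    """Recipe for a planted multi-basin dihedral ensemble.

    ``planted_features`` lists (residue number, dihedral name) pairs;
    ``cluster_means``/``concentrations`` are [cluster][feature] arrays in
    radians / dimensionless von Mises kappa.  ``concentration = inf`` means
    the angle is pinned exactly at its mean.  ``noise_level`` is the
    circular standard deviation (radians) of the jitter on every
    non-planted dihedral; 0 disables it.
    """

    n_frames: int
    n_residues: int
    cluster_weights: tuple[float, ...]
    planted_features: tuple[tuple[int, str], ...]
    cluster_means: tuple[tuple[float, ...], ...]
    concentrations: tuple[tuple[float, ...], ...]
    seed: int
    noise_level: float = 0.08

    def __post_init__(self):
        w = np.asarray(self.cluster_weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-12 or np.any(w < 0):
            raise ValueError("cluster_weights must be a probability vector (sum 1)")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.n_residues < 4:
            raise ValueError("scaffold needs at least 4 residues")
        k = len(self.cluster_weights)
        f = len(self.planted_features)
        if len(self.cluster_means) != k or len(self.concentrations) != k:
            raise ValueError("cluster_means/concentrations must have one row per cluster")
        for row in self.cluster_means:
            if len(row) != f:
                raise ValueError("cluster_means rows must match planted_features")
        for row in self.concentrations:
            if len(row) != f:
                raise ValueError("concentrations rows must match planted_features")
            if any(c <= 0 for c in row):
                raise ValueError("concentrations must be > 0")
        for res_id, name in self.planted_features:
            if name not in DIHEDRAL_NAMES:
                raise ValueError(f"unknown dihedral name {name!r}")
            if not (1 <= res_id <= self.n_residues):
                raise ValueError(f"planted residue {res_id} outside chain")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_weights)


@dataclass
class PlantedTruth:
    """Ground truth planted by a generator; fields unused by a generator are None."""

    labels: np.ndarray | None = None
    s_cis_fraction: float | None = None
    is_cis: np.ndarray | None = None
    pair_separation_A: float | None = None
    pair_rotation_deg: float | None = None
    metadata: dict = field(default_factory=dict)


@dataclass
class PigmentPair:
    """Two rigid toy pigments with transition charges at a known geometry."""

    coords_a: np.ndarray
    charges_a: PigmentChargeSet
    coords_b: np.ndarray
    charges_b: PigmentChargeSet
    elements_a: tuple[str, ...]
    elements_b: tuple[str, ...]
    truth: PlantedTruth


def _draw_circular(rng: np.random.Generator, mean: float, kappa: float, size: int) -> np.ndarray:
    if np.isinf(kappa):
        return np.full(size, mean, dtype=float)
    return rng.vonmises(mean, kappa, size=size)


def _sample_dihedrals(spec: EnsembleSpec, rng: np.random.Generator):
    """Per-frame (phi, psi, chi1) arrays of shape (n_frames, n_residues) in radians."""
    n, r = spec.n_frames, spec.n_residues
    labels = rng.choice(spec.n_clusters, size=n, p=np.asarray(spec.cluster_weights))
    angles = {}
    for name in DIHEDRAL_NAMES:
        base = np.deg2rad(_BASE_DIHEDRAL_DEG[name])
        if spec.noise_level > 0:
            kappa = 1.0 / spec.noise_level**2
            angles[name] = rng.vonmises(base, kappa, size=(n, r))
        else:
            angles[name] = np.full((n, r), base)
    means = np.asarray(spec.cluster_means, dtype=float)
    kappas = np.asarray(spec.concentrations, dtype=float)
    for j, (res_id, name) in enumerate(spec.planted_features):
        col = np.empty(n)
        for c in range(spec.n_clusters):
            members = np.flatnonzero(labels == c)
            col[members] = _draw_circular(rng, means[c, j], kappas[c, j], members.size)
        angles[name][:, res_id - 1] = col
    return labels, angles


def _build_scaffold(phi: np.ndarray, psi: np.ndarray, chi1: np.ndarray) -> np.ndarray:
    """Build coordinates (frames, residues*6, 3) from per-frame dihedrals.

    NeRF construction: the backbone is grown residue by residue (vectorized
    over frames), then carbonyl O and the CB-CG sidechain are attached.
    """
    n_frames, n_res = phi.shape
    rad = np.deg2rad
    coords = np.empty((n_frames, n_res, len(RESIDUE_ATOMS), 3))
    i_n, i_ca, i_c, i_o, i_cb, i_cg = range(6)

    # seed residue 0 backbone in the xy-plane, identical in all frames
    n0 = np.zeros(3)
    ca0 = np.array([_BOND["N-CA"], 0.0, 0.0])
    th = rad(_ANGLE["N-CA-C"])
    c0 = ca0 + _BOND["CA-C"] * np.array([-np.cos(th), np.sin(th), 0.0])
    coords[:, 0, i_n] = n0
    coords[:, 0, i_ca] = ca0
    coords[:, 0, i_c] = c0

    for i in range(n_res - 1):
        n_i = coords[:, i, i_n]
        ca_i = coords[:, i, i_ca]
        c_i = coords[:, i, i_c]
        n_next = nerf_place(n_i, ca_i, c_i, _BOND["C-N"], rad(_ANGLE["CA-C-N"]), psi[:, i])
        ca_next = nerf_place(ca_i, c_i, n_next, _BOND["N-CA"], rad(_ANGLE["C-N-CA"]),
                             np.full(n_frames, rad(_OMEGA_DEG)))
        c_next = nerf_place(c_i, n_next, ca_next, _BOND["CA-C"], rad(_ANGLE["N-CA-C"]),
                            phi[:, i + 1])
        coords[:, i + 1, i_n] = n_next
        coords[:, i + 1, i_ca] = ca_next
        coords[:, i + 1, i_c] = c_next

    for i in range(n_res):
        n_i = coords[:, i, i_n]
        ca_i = coords[:, i, i_ca]
        c_i = coords[:, i, i_c]
        coords[:, i, i_o] = nerf_place(
            n_i, ca_i, c_i, _BOND["C-O"], rad(_ANGLE["CA-C-O"]),
            psi[:, i] + np.pi)
        cb = nerf_place(c_i, n_i, ca_i, _BOND["CA-CB"], rad(_ANGLE["N-CA-CB"]),
                        np.full(n_frames, rad(_CB_PLACEMENT_TORSION_DEG)))
        coords[:, i, i_cb] = cb
        coords[:, i, i_cg] = nerf_place(n_i, ca_i, cb, _BOND["CB-CG"],
                                        rad(_ANGLE["CA-CB-CG"]), chi1[:, i])
    return coords.reshape(n_frames, n_res * len(RESIDUE_ATOMS), 3)


def _scaffold_topology(n_residues: int) -> pd.DataFrame:
    rows = []
    for r in range(1, n_residues + 1):
        for name in RESIDUE_ATOMS:
            rows.append(("A", r, "ABU", name, _ATOM_ELEMENTS[name]))
    return pd.DataFrame(rows, columns=["chain_id", "res_id", "res_name", "atom_name", "element"])


def generate_ensemble(spec: EnsembleSpec) -> tuple[ConformationalEnsemble, PlantedTruth]:
    """Sample a planted multi-basin ensemble; returns (ensemble, truth)."""
    rng = np.random.default_rng(spec.seed)
    labels, angles = _sample_dihedrals(spec, rng)
    coords = _build_scaffold(angles["phi"], angles["psi"], angles["chi1"])
    ensemble = ConformationalEnsemble(
        coordinates=coords,
        topology=_scaffold_topology(spec.n_residues),
        metadata={
            "generator": "generate_ensemble",
            "seed": spec.seed,
            "n_clusters": spec.n_clusters,
            "planted_features": list(spec.planted_features),
        },
    )
    return ensemble, PlantedTruth(labels=labels, metadata={"seed": spec.seed})


def make_basin_spec(
    n_clusters: int = 2,
    separation: float = np.pi,
    concentration: float = 50.0,
    n_frames: int = 500,
    n_residues: int = 20,
    planted_residues: tuple[int, ...] = (5, 10, 15),
    planted_dihedral: str = "chi1",
    seed: int = 0,
    noise_level: float = 0.08,
) -> EnsembleSpec:
    """Convenience spec: k basins whose planted dihedrals sit `separation`
    radians apart around the circle, equal weights."""
    features = tuple((r, planted_dihedral) for r in planted_residues)
    base = np.deg2rad(_BASE_DIHEDRAL_DEG[planted_dihedral])
    means = tuple(
        tuple(base + c * separation for _ in features) for c in range(n_clusters)
    )
    kappas = tuple(tuple(concentration for _ in features) for _ in range(n_clusters))
    weights = tuple(1.0 / n_clusters for _ in range(n_clusters))
    # renormalize exactly
    weights = tuple(np.asarray(weights) / np.sum(weights))
    return EnsembleSpec(
        n_frames=n_frames,
        n_residues=n_residues,
        cluster_weights=weights,
        planted_features=features,
        cluster_means=means,
        concentrations=kappas,
        seed=seed,
        noise_level=noise_level,
    )


def generate_conjugated_chain_series(
    n_frames: int,
    s_cis_fraction: float,
    seed: int,
    n_atoms: int = 10,
    cis_spread_deg: float = 10.0,
    backbone_spread_deg: float = 5.0,
) -> ConformationalEnsemble:
    """Toy conjugated chain whose first torsion pedals between s-cis and s-trans.

    The first dihedral d1 is drawn near 0 deg with probability
    ``s_cis_fraction`` and near 180 deg otherwise (von Mises with circular
    spread ``cis_spread_deg``); remaining torsions stay near 180 deg.  The
    planted fraction and per-frame draw are stored in ``metadata``.
    """
    if not 0.0 <= s_cis_fraction <= 1.0:
        raise ValueError("s_cis_fraction must be in [0, 1]")
    if n_atoms < 4:
        raise ValueError("a chain needs at least 4 atoms")
    rng = np.random.default_rng(seed)
    is_cis = rng.random(n_frames) < s_cis_fraction
    kappa_d1 = 1.0 / np.deg2rad(cis_spread_deg) ** 2
    kappa_bb = 1.0 / np.deg2rad(backbone_spread_deg) ** 2
    n_torsions = n_atoms - 3
    torsions = rng.vonmises(np.pi, kappa_bb, size=(n_frames, n_torsions))
    d1 = np.where(
        is_cis,
        rng.vonmises(0.0, kappa_d1, size=n_frames),
        rng.vonmises(np.pi, kappa_d1, size=n_frames),
    )
    torsions[:, 0] = d1

    bond, angle = 1.45, np.deg2rad(120.0)
    coords = np.empty((n_frames, n_atoms, 3))
    coords[:, 0] = [0.0, 0.0, 0.0]
    coords[:, 1] = [bond, 0.0, 0.0]
    coords[:, 2] = coords[:, 1] + bond * np.array([-np.cos(angle), np.sin(angle), 0.0])
    for i in range(3, n_atoms):
        coords[:, i] = nerf_place(
            coords[:, i - 3], coords[:, i - 2], coords[:, i - 1],
            bond, angle, torsions[:, i - 3])

    topology = pd.DataFrame(
        {
            "chain_id": ["X"] * n_atoms,
            "res_id": [1] * n_atoms,
            "res_name": ["CAR"] * n_atoms,
            "atom_name": [f"C{i+1}" for i in range(n_atoms)],
            "element": ["C"] * n_atoms,
        }
    )
    return ConformationalEnsemble(
        coordinates=coords,
        topology=topology,
        metadata={
            "generator": "generate_conjugated_chain_series",
            "seed": seed,
            "planted_s_cis_fraction": float(s_cis_fraction),
            "planted_is_cis": is_cis,
        },
    )


# rectangle chromophore: one charged edge positive, the other negative ->
# net charge 0, dipole 2*q*1.4 e*A along +y
_PIGMENT_TEMPLATE = np.array(
    [
        [-0.6, -0.7, 0.0],
        [0.6, -0.7, 0.0],
        [-0.6, 0.7, 0.0],
        [0.6, 0.7, 0.0],
    ]
)


def generate_pigment_pair(
    separation: float,
    rotation: float = 0.0,
    charge_magnitude: float = 0.1,
) -> PigmentPair:
    """Two planar 4-atom toy pigments at exact separation (Angstrom, along z)
    and relative in-plane rotation (degrees, about z)."""
    if separation <= 0:
        raise ValueError("separation must be > 0")
    q = float(charge_magnitude)
    charges = (-q, -q, q, q)
    names = ("C1", "C2", "C3", "C4")
    coords_a = _PIGMENT_TEMPLATE.copy()
    rot = rotation_about_axis(np.array([0.0, 0.0, 1.0]), np.deg2rad(rotation))
    coords_b = _PIGMENT_TEMPLATE @ rot.T + np.array([0.0, 0.0, separation])
    mk = lambda pid: PigmentChargeSet(
        pigment_id=pid, transition="toy S1", atom_names=names, charges_e=charges
    )
    truth = PlantedTruth(pair_separation_A=float(separation), pair_rotation_deg=float(rotation))
    return PigmentPair(
        coords_a=coords_a, charges_a=mk("toyA"),
        coords_b=coords_b, charges_b=mk("toyB"),
        elements_a=("C",) * 4, elements_b=("C",) * 4,
        truth=truth,
    )


def write_truth_labels(truth: PlantedTruth, path: str | Path) -> None:
    """Write frame -> planted cluster label as TSV."""
    if truth.labels is None:
        raise ValueError("truth carries no cluster labels")
    df = pd.DataFrame(
        {"frame_index": np.arange(len(truth.labels)), "cluster_label": truth.labels}
    )
    write_table(df, path)
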