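"""Dihedral PCA: featurize an ensemble into torsions, embed circularly,
fit a (weighted) PCA, project, and build free-energy surfaces.

The circular embedding maps each angle theta to (cos theta, sin theta),
which removes the branch cut at +-pi before the linear PCA — the standard
dPCA construction for protein ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import torsion, superpose
from .io import ConformationalEnsemble, AtomSelection, resolve_selection

__all__ = [
    "DihedralFeatureMatrix",
    "PCAModel",
    "Projection",
    "FreeEnergySurface",
    "standard_dihedral_quadruples",
    "compute_dihedrals",
    "circular_embed",
    "fit_pca",
    "project",
    "free_energy_surface",
    "residue_fluctuations",
]


@dataclass
class DihedralFeatureMatrix:
    """frames x dihedrals angles (radians, (-pi, pi]) with per-column labels."""

    angles: np.ndarray
    labels: tuple[tuple[int, str], ...]  # (residue number, dihedral name)

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2:
            raise ValueError("angles must be 2D (frames x dihedrals)")
        if len(self.labels) != self.angles.shape[1]:
            raise ValueError("one label per dihedral column required")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def residues(self) -> np.ndarray:
        return np.array([r for r, _ in self.labels])


@dataclass
class PCAModel:
    mean: np.ndarray
    components: np.ndarray  # (n_components, n_features), orthonormal rows
    eigenvalues: np.ndarray  # non-increasing, >= 0
    n_input_features: int


@dataclass
class Projection:
    scores: np.ndarray  # frames x n_components


@dataclass
class FreeEnergySurface:
    """2D free-energy surface in kT units; empty bins are +inf, min is 0."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray  # (nx, ny)


# atom-name quadruples per dihedral, offsets are residue offsets
_DIHEDRAL_DEFS = {
    "phi": (("C", -1), ("N", 0), ("CA", 0), ("C", 0)),
    "psi": (("N", 0), ("CA", 0), ("C", 0), ("N", 1)),
    "chi1": (("N", 0), ("CA", 0), ("CB", 0), ("CG", 0)),
}


def standard_dihedral_quadruples(
    ensemble: ConformationalEnsemble,
    include: Sequence[str] = ("phi", "psi", "chi1"),
    residue_range: tuple[int, int] | None = None,
    chain_id: str | None = None,
) -> list[tuple[tuple[int, str], tuple[int, int, int, int]]]:
    """Resolve backbone phi/psi and sidechain chi1 atom quadruples.

    Returns [(label, (i, j, k, l)), ...] with atom indices into the
    topology.  Dihedrals whose atoms do not all exist (chain termini,
    residues lacking a CG) are silently omitted; an explicitly requested
    unknown dihedral name is a hard error.
    """
    for name in include:
        if name not in _DIHEDRAL_DEFS:
            raise ValueError(f"unknown dihedral {name!r}; known: {sorted(_DIHEDRAL_DEFS)}")
    top = ensemble.topology
    index = {}
    for i, row in enumerate(top.itertuples(index=False)):
        index[(row.chain_id, int(row.res_id), row.atom_name)] = i
    res_ids = sorted(
        set(
            (row.chain_id, int(row.res_id))
            for row in top.itertuples(index=False)
            if chain_id is None or row.chain_id == chain_id
        )
    )
    quadruples = []
    for ch, rid in res_ids:
        if residue_range is not None and not (residue_range[0] <= rid <= residue_range[1]):
            continue
        for name in include:
            atoms = []
            ok = True
            for atom_name, off in _DIHEDRAL_DEFS[name]:
                key = (ch, rid + off, atom_name)
                if key not in index:
                    ok = False
                    break
                atoms.append(index[key])
            if ok:
                quadruples.append(((rid, name), tuple(atoms)))
    return quadruples


def compute_dihedrals(
    ensemble: ConformationalEnsemble,
    quadruples: Sequence[tuple[tuple[int, str], tuple[int, int, int, int]]],
) -> DihedralFeatureMatrix:
    """Torsions for every labeled quadruple, all frames at once.

    Undefined torsions (collinear central atoms) come back as NaN in the
    affected frame; an out-of-range atom index is a hard error.
    """
    if len(quadruples) == 0:
        raise ValueError("no dihedrals requested")
    coords = ensemble.coordinates
    idx = np.array([q for _, q in quadruples])  # (D, 4)
    if idx.min() < 0 or idx.max() >= ensemble.n_atoms:
        raise IndexError("dihedral quadruple refers to a nonexistent atom")
    a = coords[:, idx[:, 0]]
    b = coords[:, idx[:, 1]]
    c = coords[:, idx[:, 2]]
    d = coords[:, idx[:, 3]]
    angles = torsion(a, b, c, d)  # (frames, D)
    labels = tuple(lab for lab, _ in quadruples)
    return DihedralFeatureMatrix(angles=angles, labels=labels)


def circular_embed(features: DihedralFeatureMatrix | np.ndarray) -> np.ndarray:
    """Map angles to interleaved (cos, sin) columns: theta_j -> columns 2j, 2j+1."""
    angles = features.angles if isinstance(features, DihedralFeatureMatrix) else np.asarray(features)
    n, d = angles.shape
    out = np.empty((n, 2 * d))
    out[:, 0::2] = np.cos(angles)
    out[:, 1::2] = np.sin(angles)
    return out


def fit_pca(embedded: np.ndarray, frame_weights: np.ndarray | None = None) -> PCAModel:
    """Weighted-mean-centered PCA of the embedded matrix.

    Eigenvalues are those of the weighted covariance (normalized by total
    weight, i.e. the ddof=0 convention), sorted descending.  Component sign
    is fixed so the largest-magnitude loading of each component is
    positive (ties broken by lowest feature index).
    """
    x = np.asarray(embedded, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least 2 frames")
    n, d = x.shape
    if frame_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(frame_weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("total frame weight must be positive")
    w = w / w.sum()
    mean = w @ x
    xc = x - mean
    cov = (xc * w[:, None]).T @ xc
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    comps = evecs[:, order].T  # rows are components
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return PCAModel(mean=mean, components=comps, eigenvalues=evals, n_input_features=d)


def project(model: PCAModel, embedded: np.ndarray, n_components: int | None = None) -> Projection:
    """Scores of (centered) data on the leading components."""
    x = np.asarray(embedded, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != model.n_input_features:
        raise ValueError(
            f"feature count {x.shape[1]} != model features {model.n_input_features}"
        )
    k = model.components.shape[0] if n_components is None else int(n_components)
    return Projection(scores=(x - model.mean) @ model.components[:k].T)


def free_energy_surface(
    xy: np.ndarray,
    frame_weights: np.ndarray | None = None,
    bins: int | Sequence = 40,
    temperature_kT: float = 1.0,
    range_: Sequence | None = None,
) -> FreeEnergySurface:
    """Boltzmann inversion of the weighted 2D density.

    F(bin) = -kT ln( w(bin) / w(best bin) ), so the global minimum is 0 by
    construction and empty bins are +inf.  Scaling all weights by a
    constant leaves F unchanged.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("xy must be (n, 2)")
    if frame_weights is None:
        frame_weights = np.ones(len(xy))
    w = np.asarray(frame_weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("all weights zero")
    hist, x_edges, y_edges = np.histogram2d(
        xy[:, 0], xy[:, 1], bins=bins, weights=w, range=range_
    )
    wmax = hist.max()
    if wmax <= 0:
        raise ValueError("no occupied bins")
    with np.errstate(divide="ignore"):
        fes = -temperature_kT * np.log(hist / wmax)
    return FreeEnergySurface(x_edges=x_edges, y_edges=y_edges, free_energy=fes)


def residue_fluctuations(
    ensemble: ConformationalEnsemble,
    selection: AtomSelection | None = None,
    n_iterations: int = 2,
) -> pd.DataFrame:
    """Per-residue RMSF (Angstrom) after iterative mean-structure superposition.

    Each frame is Kabsch-aligned (weighted by frame weights implicitly
    uniform per atom) to the running mean structure; the mean is
    recomputed and the alignment repeated ``n_iterations`` times.  RMSF of
    a residue is the root mean square deviation of its atoms from the mean
    structure, over frames and atoms.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if selection is not None:
        idx = resolve_selection(ensemble, selection)
        ens = ensemble.subset_atoms(idx)
    else:
        ens = ensemble
    coords = ens.coordinates.copy()
    mean = coords.mean(axis=0)
    for _ in range(n_iterations):
        coords = np.stack([superpose(frame, mean) for frame in coords])
        mean = coords.mean(axis=0)
    sq_dev = ((coords - mean) ** 2).sum(axis=2)  # (frames, atoms)
    per_atom_msf = sq_dev.mean(axis=0)
    top = ens.topology
    df = pd.DataFrame({
        "chain_id": top["chain_id"],
        "res_id": top["res_id"],
        "msf": per_atom_msf,
    })
    out = (
        df.groupby(["chain_id", "res_id"], sort=True)["msf"]
        .mean()
        .pow(0.5)
        .rename("rmsf_A")
        .reset_index()
    )
    return out
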