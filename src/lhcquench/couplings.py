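"""Chlorophyll-carotenoid interaction descriptors.

Two per-frame quantities are computed for a pigment pair:

* the Coulomb coupling between the transition densities of the two
  pigments, projected onto atomic transition charges (TrEsp form):
  V = K * sum_ij q_i q_j / r_ij, with q in elementary charges, r in
  Angstrom and K the CODATA conversion to cm^-1;
* the overlap parameter, a geometric proxy for inter-pigment
  electron-density overlap: the summed pairwise intersection volume of
  rigid van der Waals spheres centered on the atoms of the pair (cubic
  Angstrom).  It tracks the short-range (exchange/CT-mediated) part of
  the coupling that the Coulomb term misses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .constants import (
    COULOMB_E2_ANGSTROM_TO_WAVENUMBER,
    BONDI_VDW_RADII_A,
    DEFAULT_VDW_RADIUS_A,
)
from .io import (
    ConformationalEnsemble,
    PigmentChargeSet,
    AtomSelection,
    resolve_selection,
)

__all__ = [
    "SphereModel",
    "PairSpec",
    "coulomb_coupling",
    "overlap_parameter",
    "sphere_intersection_volume",
    "pair_couplings_over_ensemble",
]


@dataclass(frozen=True)
class SphereModel:
    """Per-element rigid-sphere radii: Bondi vdW radii times one global
    scale factor (the acknowledged free parameter of the overlap proxy)."""

    scale: float = 1.0
    radii_A: dict = field(default_factory=lambda: dict(BONDI_VDW_RADII_A))
    include_hydrogens: bool = False

    def __post_init__(self):
        if self.scale <= 0 or any(r <= 0 for r in self.radii_A.values()):
            raise ValueError("sphere radii and scale must be positive")

    def radius(self, element: str) -> float:
        return self.scale * self.radii_A.get(element.upper(), DEFAULT_VDW_RADIUS_A)

    def radii_for(self, elements: Sequence[str]) -> np.ndarray:
        return np.array([self.radius(e) for e in elements])


def coulomb_coupling(
    coords_a: np.ndarray,
    charges_a: Sequence[float],
    coords_b: np.ndarray,
    charges_b: Sequence[float],
) -> float:
    """TrEsp Coulomb coupling in cm^-1.

    V = K * sum_{i in A} sum_{j in B} q_i q_j / r_ij with K assembled from
    CODATA constants (about 1.1614e5 cm^-1 Angstrom / e^2).  Raises on
    coincident atoms across the two sets.
    """
    qa = np.asarray(charges_a, dtype=float)
    qb = np.asarray(charges_b, dtype=float)
    r = cdist(np.asarray(coords_a, dtype=float), np.asarray(coords_b, dtype=float))
    if np.any(r == 0.0):
        raise ValueError("coincident atoms across pigments (r = 0)")
    return float(COULOMB_E2_ANGSTROM_TO_WAVENUMBER * (qa @ (1.0 / r) @ qb))


def sphere_intersection_volume(r: np.ndarray, r1, r2) -> np.ndarray:
    """Analytic intersection volume of two spheres at center distance r.

    Zero beyond contact, full containment of the smaller sphere when
    r <= |r1 - r2|, spherical-lens formula in between.  Vectorized.
    """
    r = np.asarray(r, dtype=float)
    r1 = np.broadcast_to(np.asarray(r1, dtype=float), r.shape)
    r2 = np.broadcast_to(np.asarray(r2, dtype=float), r.shape)
    out = np.zeros_like(r)
    rmin = np.minimum(r1, r2)
    contained = r <= np.abs(r1 - r2)
    out[contained] = (4.0 / 3.0) * np.pi * rmin[contained] ** 3
    lens = (~contained) & (r < r1 + r2)
    if np.any(lens):
        d, a, b = r[lens], r1[lens], r2[lens]
        out[lens] = (
            np.pi
            * (a + b - d) ** 2
            * (d**2 + 2 * d * (a + b) - 3 * (a - b) ** 2)
            / (12.0 * d)
        )
    return out


def overlap_parameter(
    coords_a: np.ndarray,
    elements_a: Sequence[str],
    coords_b: np.ndarray,
    elements_b: Sequence[str],
    spheres: SphereModel | None = None,
) -> float:
    """Rigid-sphere overlap parameter, cubic Angstrom.

    Sum over all cross pairs of the analytic sphere-sphere intersection
    volume; hydrogens are excluded by default (heavy-atom convention).
    """
    spheres = spheres or SphereModel()
    ca = np.asarray(coords_a, dtype=float)
    cb = np.asarray(coords_b, dtype=float)
    ea = np.asarray([e.upper() for e in elements_a])
    eb = np.asarray([e.upper() for e in elements_b])
    if not spheres.include_hydrogens:
        keep_a, keep_b = ea != "H", eb != "H"
        ca, ea = ca[keep_a], ea[keep_a]
        cb, eb = cb[keep_b], eb[keep_b]
    if len(ca) == 0 or len(cb) == 0:
        return 0.0
    ra = spheres.radii_for(ea)
    rb = spheres.radii_for(eb)
    r = cdist(ca, cb)
    vol = sphere_intersection_volume(r, ra[:, None], rb[None, :])
    return float(vol.sum())


@dataclass(frozen=True)
class PairSpec:
    """One Car-Chl (or any pigment) pair: selections plus charge sets."""

    name: str
    selection_a: AtomSelection
    charges_a: PigmentChargeSet
    selection_b: AtomSelection
    charges_b: PigmentChargeSet


def _charge_atom_indices(
    ensemble: ConformationalEnsemble,
    selection: AtomSelection,
    charge_set: PigmentChargeSet,
) -> np.ndarray:
    """Indices of the charge-set atoms, in charge-table order, within a selection."""
    sel_idx = resolve_selection(ensemble, selection)
    names = ensemble.topology["atom_name"].to_numpy()
    out = []
    for nm in charge_set.atom_names:
        hits = sel_idx[names[sel_idx] == nm]
        if hits.size == 0:
            raise ValueError(f"charge-table atom {nm!r} not found in selection")
        if hits.size > 1:
            raise ValueError(f"charge-table atom {nm!r} ambiguous in selection")
        out.append(int(hits[0]))
    return np.array(out, dtype=int)


def pair_couplings_over_ensemble(
    ensemble: ConformationalEnsemble,
    pair_specs: Sequence[PairSpec],
    spheres: SphereModel | None = None,
) -> pd.DataFrame:
    """Per-frame Coulomb coupling (cm^-1) and overlap (A^3) for every pair.

    Returns a tidy table (frame_index, pair, V_coulomb_cm1, overlap_A3),
    joinable with cluster labels for per-state distributions.  Both
    quantities are symmetric under swapping the pair order.
    """
    spheres = spheres or SphereModel()
    rows = []
    for spec in pair_specs:
        idx_a = _charge_atom_indices(ensemble, spec.selection_a, spec.charges_a)
        idx_b = _charge_atom_indices(ensemble, spec.selection_b, spec.charges_b)
        if np.intersect1d(idx_a, idx_b).size:
            raise ValueError(f"pair {spec.name!r}: pigments share atoms")
        sel_a = resolve_selection(ensemble, spec.selection_a)
        sel_b = resolve_selection(ensemble, spec.selection_b)
        el_a = ensemble.topology["element"].to_numpy()[sel_a]
        el_b = ensemble.topology["element"].to_numpy()[sel_b]
        for f in range(ensemble.n_frames):
            coords = ensemble.coordinates[f]
            v = coulomb_coupling(
                coords[idx_a], spec.charges_a.charges_e,
                coords[idx_b], spec.charges_b.charges_e,
            )
            o = overlap_parameter(coords[sel_a], el_a, coords[sel_b], el_b, spheres)
            rows.append((f, spec.name, v, o))
    return pd.DataFrame(rows, columns=["frame_index", "pair", "V_coulomb_cm1", "overlap_A3"])
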