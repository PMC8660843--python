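"""Bespoke collective variables of the pigment-protein analysis.

* Inter-helical torsions P1 (lumenal/stromal variants): the torsion of the
  centers of geometry of four atom groups (nodes A2-A1-B1-B2) placed on
  two helices.  Widening of the lumenal torsion is the signature of the
  "open" conformation of the complex.
* Conjugated-chain dihedrals of a carotenoid, named d1..dN from the
  declared chain end, and their s-cis / s-trans classification: a torsion
  within 90 deg of planar-cis (|angle| < 90 deg) is s-cis, otherwise
  s-trans (the 90 deg boundary goes to trans).
* Box-plot style distribution summaries, optionally circular-aware for
  angular data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import torsion
from .io import ConformationalEnsemble, AtomSelection, resolve_selection

__all__ = [
    "HelixNodeSpec",
    "CarDihedralRecord",
    "compute_p1",
    "compute_car_dihedrals",
    "classify_conformer",
    "distribution_summary",
]

S_CIS = "s-cis"
S_TRANS = "s-trans"


@dataclass(frozen=True)
class HelixNodeSpec:
    """Four node selections (A2, A1, B1, B2) whose centers of geometry
    define the inter-helical torsion; variant labels the protein side."""

    a2: AtomSelection
    a1: AtomSelection
    b1: AtomSelection
    b2: AtomSelection
    variant: str = "lumenal"

    def selections(self) -> tuple[AtomSelection, ...]:
        return (self.a2, self.a1, self.b1, self.b2)


def compute_p1(ensemble: ConformationalEnsemble, node_spec: HelixNodeSpec) -> np.ndarray:
    """Per-frame inter-helical torsion (degrees, (-180, 180]).

    Nodes are the unweighted centers of geometry of the resolved
    selections; the sign convention matches :func:`lhcquench.geometry.torsion`.
    Collinear nodes yield NaN for the affected frame.
    """
    idx = [resolve_selection(ensemble, sel) for sel in node_spec.selections()]
    flat = np.concatenate(idx)
    if len(np.unique(flat)) != len(flat):
        raise ValueError("node selections must be mutually disjoint")
    centers = [ensemble.coordinates[:, i].mean(axis=1) for i in idx]
    ang = torsion(*centers)
    return np.degrees(ang)


@dataclass
class CarDihedralRecord:
    """Per-frame conjugated-chain torsions (degrees) and conformer labels."""

    dihedral_names: tuple[str, ...]
    values_deg: np.ndarray  # (frames, n_dihedrals)
    conformer: np.ndarray  # (frames, n_dihedrals) of S_CIS / S_TRANS

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values_deg, columns=list(self.dihedral_names))
        for j, name in enumerate(self.dihedral_names):
            df[f"{name}_conformer"] = self.conformer[:, j]
        df.insert(0, "frame_index", np.arange(len(df)))
        return df


def compute_car_dihedrals(
    ensemble: ConformationalEnsemble,
    chain_atom_names: Sequence[str],
    selection: AtomSelection | None = None,
) -> CarDihedralRecord:
    """All consecutive 4-atom torsions along an ordered conjugated chain.

    ``chain_atom_names`` is the atom order from the declared (lumenal)
    end; torsions are named d1..dN in that order.  Atom names are resolved
    within ``selection`` (default: whole topology) and must be unique.
    """
    names = list(chain_atom_names)
    if len(names) < 4:
        raise ValueError("need at least 4 ordered atoms")
    top = ensemble.topology
    base = np.flatnonzero(selection.mask(top)) if selection is not None else np.arange(len(top))
    atom_names = top["atom_name"].to_numpy()
    idx = []
    for nm in names:
        hits = base[atom_names[base] == nm]
        if hits.size == 0:
            raise ValueError(f"chain atom {nm!r} not found")
        if hits.size > 1:
            raise ValueError(f"chain atom {nm!r} is ambiguous in the selection")
        idx.append(int(hits[0]))
    coords = ensemble.coordinates[:, idx]  # (frames, n, 3)
    a, b, c, d = coords[:, :-3], coords[:, 1:-2], coords[:, 2:-1], coords[:, 3:]
    ang = np.degrees(torsion(a, b, c, d))  # (frames, n-3)
    labels = classify_conformer(ang)
    dihedral_names = tuple(f"d{j+1}" for j in range(ang.shape[1]))
    return CarDihedralRecord(dihedral_names=dihedral_names, values_deg=ang, conformer=labels)


def classify_conformer(angle_deg):
    """s-cis when |angle| < 90 deg, s-trans otherwise (boundary -> trans).

    Accepts scalars or arrays; scalars return a string.
    """
    arr = np.asarray(angle_deg, dtype=float)
    out = np.where(np.abs(arr) < 90.0, S_CIS, S_TRANS)
    if arr.ndim == 0:
        return str(out)
    return out


def _linear_summary(vals: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
    whisker_lo = float(inside.min()) if inside.size else float(q1)
    whisker_hi = float(inside.max()) if inside.size else float(q3)
    outliers = vals[(vals < lo_fence) | (vals > hi_fence)]
    return {
        "n": int(vals.size),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(iqr),
        "whisker_lo": whisker_lo,
        "whisker_hi": whisker_hi,
        "n_outliers": int(outliers.size),
        "outliers": outliers.tolist(),
    }


def _circular_summary(vals_deg: np.ndarray) -> dict:
    """Quartiles computed after recentering on the circular mean, then
    mapped back; robust against the +-180 wrap for tight angular data."""
    rad = np.deg2rad(vals_deg)
    mean = np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())
    shifted = np.degrees(np.angle(np.exp(1j * (rad - mean))))
    summ = _linear_summary(shifted)
    offset = np.degrees(mean)

    def back(x):
        return float(np.angle(np.exp(1j * np.deg2rad(x + offset)), deg=True))

    for key in ("median", "q1", "q3", "whisker_lo", "whisker_hi"):
        summ[key] = back(summ[key])
    summ["outliers"] = [back(v) for v in summ["outliers"]]
    return summ


def distribution_summary(
    values,
    groups=None,
    circular: bool | str = False,
) -> pd.DataFrame:
    """Box-plot statistics (median, quartiles, 1.5-IQR whiskers, outliers)
    per group.

    Whiskers extend to the most extreme data point within 1.5 IQR of the
    box; points beyond are listed as outliers.  ``circular="auto"``
    switches to circular statistics (values in degrees) for groups whose
    linear spread exceeds 90 deg — the regime where the +-180 wrap would
    bias linear quartiles.
    """
    values = np.asarray(values, dtype=float)
    if groups is None:
        groups = np.zeros(len(values), dtype=int)
    groups = np.asarray(groups)
    rows = []
    for g in pd.unique(groups):
        vals = values[groups == g]
        if vals.size == 0:
            raise ValueError(f"group {g} is empty")
        use_circ = circular is True or (
            circular == "auto" and (vals.max() - vals.min()) > 90.0
        )
        summ = _circular_summary(vals) if use_circ else _linear_summary(vals)
        summ["group"] = g
        summ["circular"] = bool(use_circ)
        rows.append(summ)
    cols = ["group", "n", "median", "q1", "q3", "iqr",
            "whisker_lo", "whisker_hi", "n_outliers", "outliers", "circular"]
    return pd.DataFrame(rows)[cols]
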