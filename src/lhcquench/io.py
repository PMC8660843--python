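"""Reading and writing the formats the pipeline touches.

Core containers:

* :class:`ConformationalEnsemble` — a stack of frames sharing one topology,
  the in-memory form of a multi-model PDB (one MODEL per frame).
* :class:`PigmentChargeSet` — ordered atom names with transition charges
  (elementary-charge units) for one electronic transition, read from a
  small TSV dialect (``atom_name<TAB>charge_e``, ``#`` comments).
* :class:`AtomSelection` — a declarative predicate over topology fields.

Coordinates are Angstrom throughout (PDB native); residue numbering is kept
exactly as in the file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

__all__ = [
    "ConformationalEnsemble",
    "PigmentChargeSet",
    "AtomSelection",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_charge_table",
    "write_charge_table",
    "resolve_selection",
    "write_table",
]

TOPOLOGY_COLUMNS = ["chain_id", "res_id", "res_name", "atom_name", "element"]


@dataclass
class ConformationalEnsemble:
    """frames x atoms x 3 coordinates (Angstrom) plus a shared topology.

    ``topology`` is a DataFrame with columns chain_id, res_id, res_name,
    atom_name, element, one row per atom.  ``frame_weights`` default to
    uniform and must have positive sum.
    """

    coordinates: np.ndarray
    topology: pd.DataFrame
    frame_weights: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")
        if len(self.topology) != self.coordinates.shape[1]:
            raise ValueError(
                f"topology has {len(self.topology)} atoms but coordinates "
                f"have {self.coordinates.shape[1]}"
            )
        missing = [c for c in TOPOLOGY_COLUMNS if c not in self.topology.columns]
        if missing:
            raise ValueError(f"topology missing columns: {missing}")
        if self.frame_weights is None:
            self.frame_weights = np.ones(self.n_frames)
        self.frame_weights = np.asarray(self.frame_weights, dtype=float)
        if self.frame_weights.shape != (self.n_frames,):
            raise ValueError("frame_weights length must equal number of frames")
        if np.any(self.frame_weights < 0) or self.frame_weights.sum() <= 0:
            raise ValueError("frame weights must be non-negative with positive sum")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def subset_atoms(self, indices: Sequence[int]) -> "ConformationalEnsemble":
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            coordinates=self.coordinates[:, idx],
            topology=self.topology.iloc[idx].reset_index(drop=True),
        )


@dataclass(frozen=True)
class PigmentChargeSet:
    """Ordered per-atom transition charges of one pigment/transition."""

    pigment_id: str
    transition: str
    atom_names: tuple[str, ...]
    charges_e: tuple[float, ...]

    def __post_init__(self):
        if len(self.atom_names) != len(self.charges_e):
            raise ValueError("atom_names and charges_e must align")
        if len(set(self.atom_names)) != len(self.atom_names):
            raise ValueError("duplicate atom names in charge set")
        if not np.all(np.isfinite(self.charges_e)):
            raise ValueError("non-finite charge")

    @property
    def net_charge(self) -> float:
        return float(np.sum(self.charges_e))

    def __len__(self) -> int:
        return len(self.atom_names)


@dataclass(frozen=True)
class AtomSelection:
    """Predicate over topology fields; ``None`` means 'no constraint'."""

    chain_id: str | None = None
    res_ids: tuple[int, int] | Sequence[int] | None = None  # (lo, hi) inclusive, or list
    res_names: Sequence[str] | None = None
    atom_names: Sequence[str] | None = None
    elements: Sequence[str] | None = None

    def mask(self, topology: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(topology), dtype=bool)
        if self.chain_id is not None:
            m &= (topology["chain_id"] == self.chain_id).to_numpy()
        if self.res_ids is not None:
            rid = topology["res_id"].to_numpy()
            r = self.res_ids
            if len(r) == 2 and all(isinstance(v, (int, np.integer)) for v in r):
                m &= (rid >= r[0]) & (rid <= r[1])
            else:
                m &= np.isin(rid, np.asarray(list(r)))
        if self.res_names is not None:
            m &= topology["res_name"].isin(list(self.res_names)).to_numpy()
        if self.atom_names is not None:
            m &= topology["atom_name"].isin(list(self.atom_names)).to_numpy()
        if self.elements is not None:
            m &= topology["element"].isin(list(self.elements)).to_numpy()
        return m


def resolve_selection(ensemble: ConformationalEnsemble, selection: AtomSelection) -> np.ndarray:
    """Topology-ordered atom indices matching a selection; error when empty."""
    idx = np.flatnonzero(selection.mask(ensemble.topology))
    if idx.size == 0:
        raise ValueError(f"selection matched no atoms: {selection}")
    return idx


def _stack_to_topology(stack: struc.AtomArrayStack) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chain_id": stack.chain_id,
            "res_id": stack.res_id.astype(int),
            "res_name": stack.res_name,
            "atom_name": stack.atom_name,
            "element": stack.element,
        }
    )


def read_multimodel_pdb(path: str | Path) -> ConformationalEnsemble:
    """Read a (multi-)MODEL PDB file into an ensemble, one frame per MODEL.

    The topology comes from the first model; biotite enforces that every
    model carries the same atom records, which implements the consistency
    contract.
    """
    pdb_file = pdbio.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])
    return ConformationalEnsemble(
        coordinates=np.asarray(stack.coord, dtype=float),
        topology=_stack_to_topology(stack),
        metadata={"source": str(path)},
    )


def write_multimodel_pdb(ensemble: ConformationalEnsemble, path: str | Path) -> None:
    """Write the ensemble as a multi-model PDB (MODEL/ENDMDL records)."""
    n_atoms = ensemble.n_atoms
    template = struc.AtomArray(n_atoms)
    top = ensemble.topology
    template.chain_id = top["chain_id"].to_numpy(dtype="U4")
    template.res_id = top["res_id"].to_numpy(dtype=int)
    template.res_name = top["res_name"].to_numpy(dtype="U5")
    template.atom_name = top["atom_name"].to_numpy(dtype="U6")
    template.element = top["element"].to_numpy(dtype="U2")
    template.hetero = np.asarray(
        ~top["res_name"].isin(_AMINO_ACIDS).to_numpy(), dtype=bool
    )
    stack = struc.stack([template] * ensemble.n_frames)
    stack.coord = np.asarray(ensemble.coordinates, dtype=np.float32)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "ABU",
}


def read_charge_table(path: str | Path, pigment_id: str = "",
                      transition: str = "") -> PigmentChargeSet:
    """Read a transition-charge table.

    Dialect: tab-separated, mandatory header with columns ``atom_name`` and
    ``charge_e``, ``#`` starts a comment.  Atom order in the file is the
    order of the returned set.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    for col in ("atom_name", "charge_e"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if len(df) == 0:
        raise ValueError(f"{path}: charge table has no data rows")
    charges = pd.to_numeric(df["charge_e"], errors="coerce")
    if charges.isna().any():
        bad = df.loc[charges.isna(), "atom_name"].tolist()
        raise ValueError(f"{path}: non-numeric charge for atoms {bad}")
    names = df["atom_name"].astype(str).tolist()
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate atom names")
    return PigmentChargeSet(
        pigment_id=pigment_id or path.stem,
        transition=transition,
        atom_names=tuple(names),
        charges_e=tuple(float(c) for c in charges),
    )


def write_charge_table(charge_set: PigmentChargeSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pigment: {charge_set.pigment_id}\ttransition: {charge_set.transition}\n")
        fh.write("atom_name\tcharge_e\n")
        for name, q in zip(charge_set.atom_names, charge_set.charges_e):
            fh.write(f"{name}\t{q:.10g}\n")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with a stable float format.

    One writer for every pipeline output keeps reruns byte-identical.
    """
    df.to_csv(path, sep="\t", index=False, float_format="%.8g", lineterminator="\n")
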