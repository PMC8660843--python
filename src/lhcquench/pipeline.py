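"""End-to-end orchestration: config parsing/validation, staged execution,
deterministic TSV outputs and a hashed run manifest.

The pipeline chains the analyses in their natural order:
featurize -> dPCA -> clustering -> collective variables -> couplings ->
summaries (-> Marcus rates when an energetics table is supplied).  Every
stage writes its table under the configured output directory; the manifest
lists each artifact with its SHA-256 so reruns can be checked for
byte-identity.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dpca, clustering, cvs as cvmod, couplings as cpl, marcus as marc
from .io import (
    AtomSelection,
    ConformationalEnsemble,
    read_multimodel_pdb,
    read_charge_table,
    write_table,
    write_multimodel_pdb,
    write_charge_table,
)
from .synthetic import (
    make_basin_spec,
    generate_ensemble,
    generate_conjugated_chain_series,
    generate_pigment_pair,
    write_truth_labels,
)

logger = logging.getLogger("lhcquench")

__all__ = ["RunConfig", "PipelineError", "load_config", "validate_config",
           "run_pipeline", "write_synthetic_fixture"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _selection_from_dict(d: dict) -> AtomSelection:
    allowed = {"chain_id", "res_ids", "res_names", "atom_names", "elements"}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown selection keys: {sorted(unknown)}")
    kw = dict(d)
    if "res_ids" in kw and kw["res_ids"] is not None:
        kw["res_ids"] = tuple(kw["res_ids"])
    return AtomSelection(**kw)


@dataclass
class RunConfig:
    """Validated run configuration (see docs/methods.md for the schema)."""

    ensemble_path: Path
    output_dir: Path
    seed: int = 0
    dihedral_include: tuple[str, ...] = ("phi", "psi", "chi1")
    residue_range: tuple[int, int] | None = None
    n_components: int = 3
    n_clusters: int = 2
    linkage: str = "ward"
    fes_bins: int = 40
    k_representatives: int = 3
    sphere_scale: float = 1.0
    node_specs: list = field(default_factory=list)      # list[HelixNodeSpec]
    car_chain: dict | None = None                       # {atom_names, selection}
    pair_specs: list = field(default_factory=list)      # list[PairSpec]
    marcus_energetics: Path | None = None
    marcus_competing_rate_s1: float | None = None
    raw: dict = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration; raises ValueError on schema errors."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    base = path.parent

    def respath(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    errors = []
    if "ensemble" not in raw:
        errors.append("missing required key 'ensemble'")
    if "output_dir" not in raw:
        errors.append("missing required key 'output_dir'")
    if errors:
        raise ValueError("; ".join(errors))

    di = raw.get("dihedrals", {}) or {}
    pca_cfg = raw.get("pca", {}) or {}
    cl = raw.get("clustering", {}) or {}
    fes_cfg = raw.get("fes", {}) or {}
    rep = raw.get("representatives", {}) or {}

    node_specs = []
    for nd in raw.get("nodes", []) or []:
        node_specs.append(
            cvmod.HelixNodeSpec(
                a2=_selection_from_dict(nd["a2"]),
                a1=_selection_from_dict(nd["a1"]),
                b1=_selection_from_dict(nd["b1"]),
                b2=_selection_from_dict(nd["b2"]),
                variant=nd.get("variant", "lumenal"),
            )
        )

    car = raw.get("car_chain")
    if car is not None:
        car = {
            "atom_names": list(car["atom_names"]),
            "selection": _selection_from_dict(car.get("selection", {}) or {}),
        }

    pair_specs = []
    for pr in raw.get("pairs", []) or []:
        for key in ("name", "selection_a", "charges_a", "selection_b", "charges_b"):
            if key not in pr:
                raise ValueError(f"pair spec missing key {key!r}")
        pair_specs.append(
            cpl.PairSpec(
                name=pr["name"],
                selection_a=_selection_from_dict(pr["selection_a"]),
                charges_a=read_charge_table(respath(pr["charges_a"])),
                selection_b=_selection_from_dict(pr["selection_b"]),
                charges_b=read_charge_table(respath(pr["charges_b"])),
            )
        )

    mc = raw.get("marcus", {}) or {}
    rr = di.get("residue_range")
    return RunConfig(
        ensemble_path=respath(raw["ensemble"]),
        output_dir=respath(raw["output_dir"]),
        seed=int(raw.get("seed", 0)),
        dihedral_include=tuple(di.get("include", ("phi", "psi", "chi1"))),
        residue_range=tuple(rr) if rr else None,
        n_components=int(pca_cfg.get("n_components", 3)),
        n_clusters=int(cl.get("n_clusters", 2)),
        linkage=str(cl.get("linkage", "ward")),
        fes_bins=int(fes_cfg.get("bins", 40)),
        k_representatives=int(rep.get("k_per_cluster", 3)),
        sphere_scale=float(raw.get("sphere_scale", 1.0)),
        node_specs=node_specs,
        car_chain=car,
        pair_specs=pair_specs,
        marcus_energetics=respath(mc["energetics"]) if "energetics" in mc else None,
        marcus_competing_rate_s1=(
            float(mc["competing_decay_rate_s1"])
            if "competing_decay_rate_s1" in mc else None
        ),
        raw=raw,
    )


def validate_config(path: str | Path) -> list[str]:
    """All schema and cross-reference problems at once; empty list means ok."""
    errors: list[str] = []
    try:
        cfg = load_config(path)
    except (ValueError, KeyError, OSError, yaml.YAMLError) as exc:
        return [str(exc)]
    if not cfg.ensemble_path.exists():
        errors.append(f"ensemble file not found: {cfg.ensemble_path}")
    if cfg.n_clusters < 1:
        errors.append("clustering.n_clusters must be >= 1")
    if cfg.n_components < 1:
        errors.append("pca.n_components must be >= 1")
    if cfg.fes_bins < 1:
        errors.append("fes.bins must be >= 1")
    if cfg.sphere_scale <= 0:
        errors.append("sphere_scale must be > 0")
    if cfg.marcus_energetics is not None and not cfg.marcus_energetics.exists():
        errors.append(f"marcus.energetics not found: {cfg.marcus_energetics}")
    if cfg.ensemble_path.exists():
        try:
            ensemble = read_multimodel_pdb(cfg.ensemble_path)
        except Exception as exc:  # malformed file is a validation failure
            errors.append(f"cannot read ensemble: {exc}")
            return errors
        for nd in cfg.node_specs:
            for label, sel in zip(("A2", "A1", "B1", "B2"), nd.selections()):
                if not sel.mask(ensemble.topology).any():
                    errors.append(f"node {label} ({nd.variant}): selection matches no atoms")
        for pr in cfg.pair_specs:
            for side, sel in (("A", pr.selection_a), ("B", pr.selection_b)):
                if not sel.mask(ensemble.topology).any():
                    errors.append(f"pair {pr.name} side {side}: selection matches no atoms")
        if cfg.car_chain is not None:
            sel = cfg.car_chain["selection"]
            if not sel.mask(ensemble.topology).any():
                errors.append("car_chain.selection matches no atoms")
    return errors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage; returns the run manifest (also
    written as manifest.json).  Outputs are pure functions of
    (inputs, config, seed)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def emit(name: str, df: pd.DataFrame):
        path = out / name
        write_table(df, path)
        artifacts[name] = _sha256(path)
        logger.info("wrote %s (%d rows)", path, len(df))

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("load")
        ensemble = read_multimodel_pdb(config.ensemble_path)
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc

    try:
        stage("featurize")
        quadruples = dpca.standard_dihedral_quadruples(
            ensemble, include=config.dihedral_include,
            residue_range=config.residue_range,
        )
        features = dpca.compute_dihedrals(ensemble, quadruples)
        feat_df = pd.DataFrame(
            features.angles, columns=[f"{name}_{rid}" for rid, name in features.labels]
        )
        feat_df.insert(0, "frame_index", np.arange(features.n_frames))
        emit("dihedrals.tsv", feat_df)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("featurize", str(exc)) from exc

    try:
        stage("pca")
        embedded = dpca.circular_embed(features)
        model = dpca.fit_pca(embedded, ensemble.frame_weights)
        projection = dpca.project(model, embedded, config.n_components)
        emit("pca_eigenvalues.tsv", pd.DataFrame({
            "component": np.arange(1, len(model.eigenvalues) + 1),
            "eigenvalue": model.eigenvalues,
            "explained_fraction": model.eigenvalues / max(model.eigenvalues.sum(), 1e-300),
        }))
        proj_df = pd.DataFrame(
            projection.scores,
            columns=[f"PC{i+1}" for i in range(projection.scores.shape[1])],
        )
        proj_df.insert(0, "frame_index", np.arange(len(proj_df)))
        emit("projection.tsv", proj_df)
    except Exception as exc:
        raise PipelineError("pca", str(exc)) from exc

    try:
        stage("cluster")
        cluster_model = clustering.hierarchical_cluster(
            projection, config.n_clusters, method=config.linkage
        )
        emit("clusters.tsv", pd.DataFrame({
            "frame_index": np.arange(len(cluster_model.labels)),
            "cluster": cluster_model.labels,
        }))
        if cluster_model.n_clusters >= 2 and np.all(cluster_model.counts >= 2):
            importance = clustering.residue_importance(features, cluster_model.labels)
            emit("residue_importance.tsv", importance.table)
        k_rep = min(config.k_representatives, int(cluster_model.counts.min()))
        reps = clustering.farthest_point_sample(projection, cluster_model.labels, k_rep)
        rep_rows = [
            (c, rank, fi) for c, frames in sorted(reps.items())
            for rank, fi in enumerate(frames)
        ]
        emit("representatives.tsv", pd.DataFrame(
            rep_rows, columns=["cluster", "rank", "frame_index"]))
    except Exception as exc:
        raise PipelineError("cluster", str(exc)) from exc

    try:
        stage("fes")
        fes = dpca.free_energy_surface(
            projection.scores[:, :2], ensemble.frame_weights, bins=config.fes_bins
        )
        nx, ny = fes.free_energy.shape
        xi, yi = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        emit("fes.tsv", pd.DataFrame({
            "x_bin": xi.ravel(),
            "y_bin": yi.ravel(),
            "x_center": ((fes.x_edges[:-1] + fes.x_edges[1:]) / 2)[xi.ravel()],
            "y_center": ((fes.y_edges[:-1] + fes.y_edges[1:]) / 2)[yi.ravel()],
            "free_energy_kT": fes.free_energy.ravel(),
        }))
    except Exception as exc:
        raise PipelineError("fes", str(exc)) from exc

    try:
        stage("cvs")
        cv_df = pd.DataFrame({"frame_index": np.arange(ensemble.n_frames)})
        for nd in config.node_specs:
            cv_df[f"P1_{nd.variant}"] = cvmod.compute_p1(ensemble, nd)
        if config.car_chain is not None:
            record = cvmod.compute_car_dihedrals(
                ensemble, config.car_chain["atom_names"], config.car_chain["selection"]
            )
            car_df = record.as_frame().drop(columns="frame_index")
            cv_df = pd.concat([cv_df, car_df], axis=1)
            summary = cvmod.distribution_summary(
                record.values_deg[:, 0], cluster_model.labels, circular="auto"
            ).drop(columns="outliers")
            emit("d1_summary_by_cluster.tsv", summary)
        if cv_df.shape[1] > 1:
            emit("cvs.tsv", cv_df)
    except Exception as exc:
        raise PipelineError("cvs", str(exc)) from exc

    try:
        stage("couplings")
        if config.pair_specs:
            spheres = cpl.SphereModel(scale=config.sphere_scale)
            table = cpl.pair_couplings_over_ensemble(ensemble, config.pair_specs, spheres)
            table = table.merge(
                pd.DataFrame({
                    "frame_index": np.arange(len(cluster_model.labels)),
                    "cluster": cluster_model.labels,
                }),
                on="frame_index",
            )
            emit("couplings.tsv", table)
            summaries = []
            for pair_name, sub in table.groupby("pair", sort=True):
                s = cvmod.distribution_summary(
                    sub["V_coulomb_cm1"].abs().to_numpy(), sub["cluster"].to_numpy()
                ).drop(columns="outliers")
                s.insert(0, "pair", pair_name)
                summaries.append(s)
            emit("coupling_summary_by_cluster.tsv", pd.concat(summaries, ignore_index=True))
    except Exception as exc:
        raise PipelineError("couplings", str(exc)) from exc

    try:
        stage("marcus")
        if config.marcus_energetics is not None:
            energetics = pd.read_csv(config.marcus_energetics, sep="\t", comment="#")
            rates = marc.marcus_table(
                energetics,
                competing_decay_rate_s1=config.marcus_competing_rate_s1,
            )
            emit("marcus_rates.tsv", rates)
    except Exception as exc:
        raise PipelineError("marcus", str(exc)) from exc

    manifest = {
        "seed": config.seed,
        "config": config.raw,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


def write_synthetic_fixture(
    out_dir: str | Path,
    n_frames: int = 200,
    n_residues: int = 80,
    n_clusters: int = 2,
    seed: int = 0,
) -> Path:
    """Write a complete synthetic run (PDB + charge tables + energetics +
    truth labels + config.yaml) and return the config path.

    The ensemble combines a planted multi-basin protein scaffold (chain A),
    a pedaling conjugated chain (chain X, displaced along -z) and a toy
    pigment pair (chains P and Q, displaced along +x, with a slow linear
    drift of pigment Q so couplings vary across frames).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    planted = (max(2, n_residues // 8), n_residues // 2, (3 * n_residues) // 4)
    spec = make_basin_spec(
        n_clusters=n_clusters, n_frames=n_frames, n_residues=n_residues,
        planted_residues=planted, seed=seed,
    )
    protein, truth = generate_ensemble(spec)
    chain = generate_conjugated_chain_series(n_frames, s_cis_fraction=0.3, seed=seed + 1)
    chain_coords = chain.coordinates + np.array([0.0, 0.0, -60.0])

    pair = generate_pigment_pair(separation=4.0, rotation=20.0)
    offset = np.array([80.0, 0.0, 0.0])
    pig_a = np.broadcast_to(pair.coords_a + offset, (n_frames, 4, 3)).copy()
    drift = np.linspace(0.0, 2.0, n_frames)[:, None, None] * np.array([0.0, 0.0, 1.0])
    pig_b = pair.coords_b + offset + drift

    def pigment_topology(chain_id, names):
        return pd.DataFrame({
            "chain_id": [chain_id] * len(names),
            "res_id": [1] * len(names),
            "res_name": ["PIG"] * len(names),
            "atom_name": list(names),
            "element": ["C"] * len(names),
        })

    topology = pd.concat(
        [
            protein.topology,
            chain.topology,
            pigment_topology("P", pair.charges_a.atom_names),
            pigment_topology("Q", pair.charges_b.atom_names),
        ],
        ignore_index=True,
    )
    coords = np.concatenate(
        [protein.coordinates, chain_coords, pig_a, pig_b], axis=1
    )
    ensemble = ConformationalEnsemble(coordinates=coords, topology=topology)
    pdb_path = out_dir / "ensemble.pdb"
    write_multimodel_pdb(ensemble, pdb_path)
    write_truth_labels(truth, out_dir / "truth_labels.tsv")
    write_charge_table(pair.charges_a, out_dir / "charges_P.tsv")
    write_charge_table(pair.charges_b, out_dir / "charges_Q.tsv")
    energetics = pd.DataFrame({
        "pair": ["LutChl_L1", "VioChl_L2"],
        "V_cm1": [30.0, 10.0],
        "dG_eV": [0.30, 0.35],
        "lambda_eV": [0.70, 0.70],
        "T_K": [300.0, 300.0],
    })
    write_table(energetics, out_dir / "ct_energetics.tsv")

    n_atoms_chain = chain.n_atoms
    config = {
        "ensemble": "ensemble.pdb",
        "output_dir": "results",
        "seed": seed,
        "dihedrals": {"include": ["phi", "psi", "chi1"]},
        "pca": {"n_components": 3},
        "clustering": {"n_clusters": n_clusters, "linkage": "ward"},
        "fes": {"bins": 30},
        "representatives": {"k_per_cluster": 3},
        "sphere_scale": 1.0,
        "nodes": [
            {
                "variant": "lumenal",
                # four disjoint two-residue CA nodes along the chain
                "a2": {"chain_id": "A", "res_ids": [1, 2], "atom_names": ["CA"]},
                "a1": {"chain_id": "A",
                       "res_ids": [n_residues // 4 + 1, n_residues // 4 + 2],
                       "atom_names": ["CA"]},
                "b1": {"chain_id": "A",
                       "res_ids": [n_residues // 2 + 1, n_residues // 2 + 2],
                       "atom_names": ["CA"]},
                "b2": {"chain_id": "A",
                       "res_ids": [(3 * n_residues) // 4 + 1, (3 * n_residues) // 4 + 2],
                       "atom_names": ["CA"]},
            }
        ],
        "car_chain": {
            "atom_names": [f"C{i+1}" for i in range(n_atoms_chain)],
            "selection": {"chain_id": "X"},
        },
        "pairs": [
            {
                "name": "toy_pair",
                "selection_a": {"chain_id": "P"},
                "charges_a": "charges_P.tsv",
                "selection_b": {"chain_id": "Q"},
                "charges_b": "charges_Q.tsv",
            }
        ],
        "marcus": {"energetics": "ct_energetics.tsv", "competing_decay_rate_s1": 2.5e9},
    }
    cfg_path = out_dir / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return cfg_path
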