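"""Readers and writers: multi-model PDB trajectories (via biotite), the
per-atom parameter table, affinity tables, per-frame energy tables, and the
ranking results table.

Trajectories travel as multi-model PDB files (one MODEL per frame; replicas
as separate files listed in a manifest); everything tabular is plain
comma-delimited text. Writers are deterministic byte-for-byte for identical
inputs.
"""

from __future__ import annotations

from pathlib import Path

import biotite.structure as struc
import numpy as np
import pandas as pd
from biotite.structure.io.pdb import PDBFile

from .ensemble_stats import RankingMetrics, RankingReport
from .model_core import AtomParam, Ensemble, Frame, FrameSchedule, Topology


class FormatError(ValueError):
    """Malformed or internally inconsistent input file."""


PARAMETER_COLUMNS = [
    "serial",
    "name",
    "element",
    "residue_name",
    "residue_index",
    "charge",
    "lj_rmin_half",
    "lj_epsilon",
    "born_radius",
    "mass",
    "role",
]


def write_parameter_table(topology: Topology, path: str | Path) -> None:
    """One row per atom; ``role`` encodes the receptor/ligand/water masks."""
    roles = np.empty(topology.n_atoms, dtype=object)
    roles[topology.receptor_mask] = "receptor"
    roles[topology.ligand_mask] = "ligand"
    roles[topology.water_mask] = "water"
    df = pd.DataFrame(
        {
            "serial": np.arange(1, topology.n_atoms + 1),
            "name": [a.name for a in topology.atoms],
            "element": [a.element for a in topology.atoms],
            "residue_name": [a.residue_name for a in topology.atoms],
            "residue_index": [a.residue_index for a in topology.atoms],
            "charge": [repr(a.charge) for a in topology.atoms],
            "lj_rmin_half": [repr(a.lj_rmin_half) for a in topology.atoms],
            "lj_epsilon": [repr(a.lj_epsilon) for a in topology.atoms],
            "born_radius": [repr(a.born_radius) for a in topology.atoms],
            "mass": [repr(a.mass) for a in topology.atoms],
            "role": roles,
        }
    )
    df.to_csv(path, index=False)


def read_parameter_table(path: str | Path) -> Topology:
    df = pd.read_csv(path)
    missing = set(PARAMETER_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"parameter table missing columns: {sorted(missing)}")
    bad_roles = set(df["role"]) - {"receptor", "ligand", "water"}
    if bad_roles:
        raise FormatError(f"unknown roles: {sorted(bad_roles)}")
    atoms = [
        AtomParam(
            name=row["name"],
            element=row["element"],
            charge=float(row["charge"]),
            lj_rmin_half=float(row["lj_rmin_half"]),
            lj_epsilon=float(row["lj_epsilon"]),
            born_radius=float(row["born_radius"]),
            mass=float(row["mass"]),
            residue_index=int(row["residue_index"]),
            residue_name=row["residue_name"],
            is_water=row["role"] == "water",
        )
        for _, row in df.iterrows()
    ]
    masks = {
        role: df.index[df["role"] == role].to_numpy()
        for role in ("receptor", "ligand", "water")
    }
    return Topology(atoms, masks["receptor"], masks["ligand"], masks["water"])


def _atom_array(topology: Topology, coordinates: np.ndarray) -> struc.AtomArray:
    n = topology.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coordinates, dtype=np.float32)
    chain = np.empty(n, dtype="U1")
    chain[topology.receptor_mask] = "R"
    chain[topology.ligand_mask] = "L"
    chain[topology.water_mask] = "W"
    arr.chain_id = chain
    arr.res_id = topology.residue_indices + 1  # PDB is 1-based
    arr.res_name = np.array([a.residue_name for a in topology.atoms])
    arr.atom_name = np.array([a.name for a in topology.atoms])
    arr.element = np.array([a.element for a in topology.atoms])
    arr.hetero = np.array([a.is_water for a in topology.atoms])
    return arr


def write_multimodel_pdb(
    frames: list[Frame], topology: Topology, path: str | Path
) -> None:
    """One MODEL record per frame, atom order fixed by the topology."""
    if not frames:
        raise ValueError("no frames to write")
    arrays = [_atom_array(topology, f.coordinates) for f in frames]
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_multimodel_pdb(
    path: str | Path,
    topology: Topology,
    replica_id: int = 0,
) -> list[Frame]:
    """Parse MODEL-delimited frames and validate against the topology."""
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises on inconsistent models
        raise FormatError(f"cannot parse multi-model PDB {path}: {exc}") from exc
    if stack.array_length() != topology.n_atoms:
        raise FormatError(
            f"{path}: {stack.array_length()} atoms per model, parameter "
            f"table has {topology.n_atoms}"
        )
    coords = np.asarray(stack.coord, dtype=np.float64)
    return [
        Frame(coordinates=coords[i], replica_id=replica_id, frame_index=i)
        for i in range(coords.shape[0])
    ]


def write_replica_manifest(paths: list[str | Path], manifest: str | Path) -> None:
    """One replica PDB path per line, in replica order."""
    Path(manifest).write_text("".join(f"{p}\n" for p in paths))


def read_replica_manifest(
    manifest: str | Path,
    topology: Topology,
    schedule: FrameSchedule | None = None,
) -> Ensemble:
    """Assemble an ensemble from a manifest of per-replica PDB files.

    Relative paths resolve against the manifest's directory.
    """
    manifest = Path(manifest)
    base = manifest.parent
    lines = [ln.strip() for ln in manifest.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty replica manifest")
    replicas: dict[int, list[Frame]] = {}
    for rid, line in enumerate(lines):
        p = Path(line)
        if not p.is_absolute():
            p = base / p
        replicas[rid] = read_multimodel_pdb(p, topology, replica_id=rid)
    n_frames = len(replicas[0])
    if schedule is None:
        schedule = FrameSchedule(4.0, 1.0, 3000.0 / n_frames)
    return Ensemble(topology=topology, replicas=replicas, schedule=schedule)


def read_affinity_table(path: str | Path) -> pd.DataFrame:
    """variant_id, ddg_exp (kcal/mol), optional mutation counts."""
    df = pd.read_csv(path)
    for col in ("variant_id", "ddg_exp"):
        if col not in df.columns:
            raise FormatError(f"affinity table missing column {col!r}")
    if df["variant_id"].duplicated().any():
        raise FormatError("duplicate variant ids in affinity table")
    return df


def write_affinity_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


ENERGY_COLUMNS = ["replica", "frame", "E_ele", "E_vdW", "G_pol", "G_npol", "total"]


def write_energy_table(
    rows: list[dict], path: str | Path
) -> None:
    """Per-frame energy decomposition as delimited text."""
    pd.DataFrame(rows, columns=ENERGY_COLUMNS).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_energy_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(ENERGY_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"energy table missing columns: {sorted(missing)}")
    return df


def write_results_table(report: RankingReport, path: str | Path) -> None:
    """Ranking report as delimited text.

    Metric lines (``# key,value``) precede the per-variant table so the file
    re-reads loss-free; floats are written at full repr precision.
    """
    lines = []
    m = report.metrics
    for key, val in (
        ("r_pearson", m.r_pearson),
        ("r_spearman", m.r_spearman),
        ("mad", m.mad),
        ("slope", m.slope),
        ("intercept", m.intercept),
    ):
        lines.append(f"# {key},{val!r}")
    if report.metrics_without_outliers is not None:
        mw = report.metrics_without_outliers
        for key, val in (
            ("r_pearson_no_outliers", mw.r_pearson),
            ("r_spearman_no_outliers", mw.r_spearman),
            ("mad_no_outliers", mw.mad),
        ):
            lines.append(f"# {key},{val!r}")
    table = report.table.copy()
    for col in ("ddg_calc", "sd", "ddg_exp", "z_residual"):
        table[col] = table[col].map(repr)
    lines.append(table.to_csv(index=False).rstrip("\n"))
    Path(path).write_text("\n".join(lines) + "\n")


def read_results_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, float]]:
    text = Path(path).read_text().splitlines()
    metrics: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(text):
        if line.startswith("# "):
            key, val = line[2:].split(",", 1)
            metrics[key] = float(val)
            body_start = i + 1
        else:
            break
    from io import StringIO

    body = "\n".join(text[body_start:])
    df = pd.read_csv(StringIO(body)) if body.strip() else pd.DataFrame()
    return df, metrics
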