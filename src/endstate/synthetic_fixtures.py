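"""Deterministic generators for toy complexes, multi-replica ensembles,
interaction-energy series, and variant affinity datasets.

These stand in for MD trajectories of real protein–protein complexes: bead
"residues" arranged on two facing chains with interface contacts near the
Lennard-Jones minimum, optional interfacial waters, Gaussian coordinate
jitter emulating thermal sampling across replicas, and charge-perturbed
"variants" whose true ΔΔG ordering is known by construction.

A single global seed fans out to named substreams (structure, jitter,
noise) so each stage is independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .entropy import InteractionEnergySeries, TruncatedSystem
from .model_core import AtomParam, Ensemble, Frame, FrameSchedule, Topology


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named, order-independent child stream of the global seed."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(key,))
    )


@dataclass(frozen=True)
class ToySpec:
    """Recipe for a toy bead complex."""

    n_receptor_residues: int = 3
    n_ligand_residues: int = 2
    atoms_per_residue: int = 2
    charge_scheme: str = "alternating"  # or "zero"
    charge_magnitude: float = 0.3  # e
    n_waters: int = 0
    interface_gap: float = 3.8  # Å; ≈ cross rmin at the defaults
    residue_spacing: float = 4.0  # Å along the chain
    atom_spacing: float = 2.0  # Å within a residue
    lj_rmin_half: float = 1.9  # Å
    lj_epsilon: float = 0.12  # kcal/mol
    born_radius: float = 1.7  # Å
    mass: float = 14.0  # amu
    seed: int = 0


def make_toy_complex(spec: ToySpec | None = None) -> tuple[Topology, Frame]:
    """Build a two-chain bead complex with a contact interface.

    Receptor residues lie along x at y = 0, ligand residues along x at
    y = ``interface_gap``; waters (O,H,H) sit above the interface. Charges
    alternate ±``charge_magnitude`` along the sequence (or are all zero).
    """
    spec = spec or ToySpec()
    atoms: list[AtomParam] = []
    coords: list[list[float]] = []
    rec_idx: list[int] = []
    lig_idx: list[int] = []
    wat_idx: list[int] = []
    res_counter = 0
    atom_counter = 0

    def add_chain(n_res: int, y: float, name: str, out: list[int]) -> None:
        nonlocal res_counter, atom_counter
        for r in range(n_res):
            for a in range(spec.atoms_per_residue):
                q = 0.0
                if spec.charge_scheme == "alternating":
                    q = spec.charge_magnitude * (-1) ** atom_counter
                elif spec.charge_scheme != "zero":
                    raise ValueError(f"unknown charge scheme {spec.charge_scheme!r}")
                # first atom of each residue is a polar (backbone-N-like)
                # site anchor; the rest are carbon beads
                atoms.append(
                    AtomParam(
                        name="N1" if a == 0 else f"C{a}",
                        element="N" if a == 0 else "C",
                        charge=q,
                        lj_rmin_half=spec.lj_rmin_half,
                        lj_epsilon=spec.lj_epsilon,
                        born_radius=spec.born_radius,
                        mass=spec.mass,
                        residue_index=res_counter,
                        residue_name=name,
                    )
                )
                coords.append(
                    [r * spec.residue_spacing + a * spec.atom_spacing, y, 0.0]
                )
                out.append(atom_counter)
                atom_counter += 1
            res_counter += 1

    add_chain(spec.n_receptor_residues, 0.0, "RES", rec_idx)
    add_chain(spec.n_ligand_residues, spec.interface_gap, "LIG", lig_idx)

    if spec.n_waters:
        extent = max(spec.n_receptor_residues, spec.n_ligand_residues)
        for w in range(spec.n_waters):
            ox = (w % extent) * spec.residue_spacing + 1.0
            oz = 3.5 + 3.0 * (w // extent)
            oy = spec.interface_gap / 2.0
            water_params = [
                ("O", "O", -0.834, 1.7682, 0.1521, 1.6, 16.0),
                ("H1", "H", 0.417, 0.6, 0.0157, 1.2, 1.008),
                ("H2", "H", 0.417, 0.6, 0.0157, 1.2, 1.008),
            ]
            water_xyz = [
                [ox, oy, oz],
                [ox + 0.76, oy + 0.59, oz],
                [ox - 0.76, oy + 0.59, oz],
            ]
            for (nm, el, q, rm, ep, br, m), xyz in zip(water_params, water_xyz):
                atoms.append(
                    AtomParam(
                        name=nm,
                        element=el,
                        charge=q,
                        lj_rmin_half=rm,
                        lj_epsilon=ep,
                        born_radius=br,
                        mass=m,
                        residue_index=res_counter,
                        residue_name="HOH",
                        is_water=True,
                    )
                )
                coords.append(xyz)
                wat_idx.append(atom_counter)
                atom_counter += 1
            res_counter += 1

    xyz = np.asarray(coords)
    # sanity: no overlapping atoms at the generated density
    from scipy.spatial.distance import pdist

    if len(xyz) > 1 and pdist(xyz).min() < 0.5:
        raise RuntimeError("toy generator produced overlapping atoms")
    topology = Topology(atoms, rec_idx, lig_idx, wat_idx)
    frame = Frame(coordinates=xyz, time=0.0, replica_id=0, frame_index=0)
    return topology, frame


def make_ensemble(
    topology: Topology,
    reference_frame: Frame,
    n_replicas: int = 25,
    n_frames: int = 300,
    jitter_sd: float = 0.05,
    seed: int = 0,
    schedule: FrameSchedule | None = None,
) -> Ensemble:
    """Gaussian-jittered replica ensemble around a reference structure.

    Each frame is the reference plus i.i.d. N(0, jitter_sd²) displacements;
    each replica draws from its own substream so replicas are independent
    but jointly reproducible. The schedule metadata defaults to the
    4 ns / discard 1 ns convention with the stride implied by ``n_frames``.
    """
    if schedule is None:
        schedule = FrameSchedule(4.0, 1.0, 3000.0 / n_frames)
    if schedule.frames_per_replica != n_frames:
        raise ValueError("schedule implies a different frame count")
    times = schedule.discard_ns * 1000.0 + schedule.stride_ps * np.arange(
        1, n_frames + 1
    )
    replicas: dict[int, list[Frame]] = {}
    for rid in range(n_replicas):
        rng = _substream(seed, f"jitter-{rid}")
        frames = []
        for fi in range(n_frames):
            disp = rng.normal(0.0, jitter_sd, size=reference_frame.coordinates.shape)
            frames.append(
                Frame(
                    coordinates=reference_frame.coordinates + disp,
                    time=float(times[fi]),
                    replica_id=rid,
                    frame_index=fi,
                )
            )
        replicas[rid] = frames
    return Ensemble(topology=topology, replicas=replicas, schedule=schedule)


def make_energy_series(
    mean: float, sd: float, n: int, seed: int = 0, temperature: float = 298.0
) -> InteractionEnergySeries:
    """Gaussian per-frame interaction-energy series (kcal/mol)."""
    rng = _substream(seed, "energy-series")
    return InteractionEnergySeries(
        values=rng.normal(mean, sd, size=n), temperature=temperature
    )


def make_affinity_dataset(
    n_variants: int = 18,
    true_slope: float = 1.0,
    noise_sd: float = 0.3,
    n_outliers: int = 0,
    outlier_shift: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired calculated/experimental ΔΔG table with optional planted
    outliers, shaped like the 18- and 29-variant test sets the ranking
    pipeline targets.

    ``ddg_calc = true_slope·ddg_exp + N(0, noise_sd²)``; the first
    ``n_outliers`` variants (after shuffling) get an extra ±``outlier_shift``
    displacement and are marked in ``is_outlier``.
    """
    rng = _substream(seed, "affinity")
    ddg_exp = np.sort(rng.uniform(-1.0, 4.0, size=n_variants))
    calc = true_slope * ddg_exp + rng.normal(0.0, noise_sd, size=n_variants)
    is_outlier = np.zeros(n_variants, dtype=bool)
    if n_outliers:
        idx = rng.choice(n_variants, size=n_outliers, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_outliers)
        calc[idx] += signs * outlier_shift
        is_outlier[idx] = True
    return pd.DataFrame(
        {
            "variant_id": [f"v{i:02d}" for i in range(n_variants)],
            "ddg_exp": ddg_exp,
            "ddg_calc": calc,
            "is_outlier": is_outlier,
        }
    )


PRESETS = {
    "small": {"n_variants": 8},
    "1g4-shaped": {"n_variants": 18},
    "a6-shaped": {"n_variants": 29},
}


def make_variant_set(
    spec: ToySpec | None = None,
    n_variants: int = 8,
    charge_scale_range: tuple[float, float] = (0.6, 1.4),
    seed: int = 0,
) -> tuple[dict[str, Topology], Frame, str]:
    """Charge-perturbed variants of a reference toy complex.

    Each variant scales the ligand charges by a factor drawn from
    ``charge_scale_range``, giving a family of complexes whose relative
    binding energies differ in a construction-known way (computable exactly
    on the unjittered reference frame). Returns (variants, reference frame,
    reference id); the reference variant "WT" has scale 1.
    """
    spec = spec or ToySpec()
    topology, frame = make_toy_complex(spec)
    rng = _substream(seed, "variants")
    scales = rng.uniform(*charge_scale_range, size=n_variants)
    variants: dict[str, Topology] = {"WT": topology}
    lig_set = set(topology.ligand_mask.tolist())
    for i, s in enumerate(scales):
        atoms = [
            AtomParam(
                name=a.name,
                element=a.element,
                charge=a.charge * s if j in lig_set else a.charge,
                lj_rmin_half=a.lj_rmin_half,
                lj_epsilon=a.lj_epsilon,
                born_radius=a.born_radius,
                mass=a.mass,
                residue_index=a.residue_index,
                residue_name=a.residue_name,
                is_water=a.is_water,
            )
            for j, a in enumerate(topology.atoms)
        ]
        variants[f"v{i:02d}"] = Topology(
            atoms,
            topology.receptor_mask,
            topology.ligand_mask,
            topology.water_mask,
        )
    return variants, frame, "WT"


# ---------------------------------------------------------------------------
# harmonic toy potentials for the NMA machinery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HarmonicBond:
    i: int
    j: int
    k: float  # kcal/mol/Å²
    r0: float  # Å


@dataclass
class HarmonicNetworkEnergy:
    """Pair-spring potential E = Σ k·(r_ij − r0)²; analytic gradient.

    Serves as the bonded toy potential for minimization / Hessian tests;
    real force-field bonded terms are out of scope by the single-trajectory
    cancellation.
    """

    bonds: list[HarmonicBond]
    n_atoms: int

    def value_and_grad(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        e = 0.0
        g = np.zeros((self.n_atoms, 3))
        for b in self.bonds:
            d = coords[b.i] - coords[b.j]
            r = float(np.linalg.norm(d))
            e += b.k * (r - b.r0) ** 2
            if r > 1e-12:
                f = 2.0 * b.k * (r - b.r0) * d / r
                g[b.i] += f
                g[b.j] -= f
        return e, g


def harmonic_bonds_for(
    topology: Topology, frame: Frame, k: float = 100.0
) -> list[HarmonicBond]:
    """Chain springs at the reference geometry: consecutive atoms within a
    residue and consecutive residues within each molecule, with r0 set to
    the reference distance (the reference frame is thus a minimum)."""
    bonds: list[HarmonicBond] = []

    def chain(mask: np.ndarray) -> None:
        idx = sorted(mask.tolist())
        for a, b in zip(idx[:-1], idx[1:]):
            r0 = float(np.linalg.norm(frame.coordinates[a] - frame.coordinates[b]))
            bonds.append(HarmonicBond(a, b, k, r0))

    chain(topology.receptor_mask)
    chain(topology.ligand_mask)
    for wr in sorted({int(r) for r in topology.residue_indices[topology.water_mask]}):
        atoms = topology.residue_atoms(wr)
        for a, b in zip(atoms[:-1], atoms[1:]):
            r0 = float(np.linalg.norm(frame.coordinates[a] - frame.coordinates[b]))
            bonds.append(HarmonicBond(int(a), int(b), k, r0))
    return bonds


def truncated_energy_factory(bonds: list[HarmonicBond]):
    """Restrict a parent-indexed bond list to a truncated system.

    Bonds with both endpoints among the kept atoms are remapped to local
    indices; bonds to deleted atoms are dropped (the frozen caps stand in
    for the removed chain continuation).
    """

    def factory(system: TruncatedSystem) -> HarmonicNetworkEnergy:
        local = {int(p): i for i, p in enumerate(system.kept_indices)}
        kept_bonds = [
            HarmonicBond(local[b.i], local[b.j], b.k, b.r0)
            for b in bonds
            if b.i in local and b.j in local
        ]
        return HarmonicNetworkEnergy(bonds=kept_bonds, n_atoms=system.n_atoms)

    return factory
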