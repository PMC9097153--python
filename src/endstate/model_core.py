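"""Core domain types: atoms, topologies, frames, ensembles, physical constants.

Unit conventions used throughout the package:

* lengths in Å (PDB convention), times in ps,
* energies in kcal/mol, charges in elementary charge units, masses in amu,
* temperatures in K.

Atom indices are 0-based internally; PDB serial numbers exist only at the
I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np


class InvalidTopologyError(ValueError):
    """Masks or residue structure violate the topology contract."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants in the package's kcal/mol-Å-e unit system."""

    coulomb_constant: float = 332.0637  # kcal·Å·mol⁻¹·e⁻²
    k_boltzmann: float = 0.0019872041  # kcal·mol⁻¹·K⁻¹
    default_temperature: float = 298.0  # K
    water_dielectric: float = 78.5
    default_ionic_strength: float = 0.150  # mol/L
    avogadro: float = 6.02214076e23

    def beta(self, temperature: float | None = None) -> float:
        """1/(k_B·T) in mol/kcal."""
        T = self.default_temperature if temperature is None else temperature
        return 1.0 / (self.k_boltzmann * T)

    def debye_kappa(
        self,
        ionic_strength: float | None = None,
        eps_solvent: float | None = None,
        temperature: float | None = None,
    ) -> float:
        """Inverse Debye screening length in Å⁻¹ for a 1:1 electrolyte.

        κ² = 8π·k_coul·N_A·I / (ε_w·k_B·T·10²⁷); at 150 mM, 298 K and
        ε_w = 78.5 this gives a Debye length of ~7.85 Å.
        """
        I = self.default_ionic_strength if ionic_strength is None else ionic_strength
        eps = self.water_dielectric if eps_solvent is None else eps_solvent
        T = self.default_temperature if temperature is None else temperature
        if I <= 0:
            return 0.0
        # ion number density in Å⁻³ for both species of a 1:1 salt
        n_density = 2.0 * I * self.avogadro / 1e27
        kappa_sq = 4.0 * np.pi * self.coulomb_constant * n_density / (
            eps * self.k_boltzmann * T
        )
        return float(np.sqrt(kappa_sq))


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class AtomParam:
    """Per-atom force-field parameters.

    ``lj_rmin_half`` is half the pair-minimum distance (Å) of the
    Lennard-Jones potential; ``lj_epsilon`` the well depth (kcal/mol);
    ``born_radius`` the intrinsic (unscreened) Born radius (Å).
    """

    name: str
    element: str
    charge: float
    lj_rmin_half: float
    lj_epsilon: float
    born_radius: float
    mass: float
    residue_index: int
    residue_name: str
    is_water: bool = False

    def __post_init__(self) -> None:
        if self.lj_epsilon < 0:
            raise ValueError(f"lj_epsilon must be >= 0, got {self.lj_epsilon}")
        if self.born_radius <= 0:
            raise ValueError(f"born_radius must be > 0, got {self.born_radius}")
        if self.mass <= 0:
            raise ValueError(f"mass must be > 0, got {self.mass}")


class Topology:
    """Ordered atoms plus a disjoint receptor/ligand/water partition.

    The three masks must be disjoint and together cover every atom.
    Residues must occupy contiguous, non-overlapping index ranges.
    """

    def __init__(
        self,
        atoms: Sequence[AtomParam],
        receptor_mask: Sequence[int],
        ligand_mask: Sequence[int],
        water_mask: Sequence[int] = (),
    ):
        self.atoms = tuple(atoms)
        self.receptor_mask = np.asarray(sorted(receptor_mask), dtype=np.intp)
        self.ligand_mask = np.asarray(sorted(ligand_mask), dtype=np.intp)
        self.water_mask = np.asarray(sorted(water_mask), dtype=np.intp)
        self._validate()
        # cached parameter arrays, used by every energy kernel
        self.charges = np.array([a.charge for a in self.atoms])
        self.lj_rmin_half = np.array([a.lj_rmin_half for a in self.atoms])
        self.lj_epsilon = np.array([a.lj_epsilon for a in self.atoms])
        self.born_radii = np.array([a.born_radius for a in self.atoms])
        self.masses = np.array([a.mass for a in self.atoms])
        self.residue_indices = np.array([a.residue_index for a in self.atoms])
        self.residue_table = self._build_residue_table()

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def solute_mask(self) -> np.ndarray:
        """Receptor + ligand atoms (no water), in index order."""
        return np.sort(np.concatenate([self.receptor_mask, self.ligand_mask]))

    def _validate(self) -> None:
        n = len(self.atoms)
        all_idx = np.concatenate(
            [self.receptor_mask, self.ligand_mask, self.water_mask]
        )
        if all_idx.size and (all_idx.min() < 0 or all_idx.max() >= n):
            raise InvalidTopologyError("mask references out-of-range atom index")
        if len(np.unique(all_idx)) != all_idx.size:
            raise InvalidTopologyError("receptor/ligand/water masks overlap")
        if all_idx.size != n:
            raise InvalidTopologyError(
                f"masks cover {all_idx.size} of {n} atoms; partition must be total"
            )
        water_set = set(self.water_mask.tolist())
        for i, a in enumerate(self.atoms):
            if a.is_water != (i in water_set):
                raise InvalidTopologyError(
                    f"atom {i} is_water flag disagrees with water mask"
                )

    def _build_residue_table(self) -> dict[int, tuple[int, int]]:
        """residue_index -> half-open atom index range (start, stop)."""
        table: dict[int, tuple[int, int]] = {}
        for i, a in enumerate(self.atoms):
            r = a.residue_index
            if r in table:
                start, stop = table[r]
                if i != stop:
                    raise InvalidTopologyError(
                        f"residue {r} occupies non-contiguous atom indices"
                    )
                table[r] = (start, i + 1)
            else:
                table[r] = (i, i + 1)
        return table

    def residue_atoms(self, residue_index: int) -> np.ndarray:
        start, stop = self.residue_table[residue_index]
        return np.arange(start, stop, dtype=np.intp)


@dataclass
class Frame:
    """One snapshot of coordinates (N×3, Å) with provenance metadata."""

    coordinates: np.ndarray
    time: float | None = None  # ps
    replica_id: int = 0
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an N×3 array")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass(frozen=True)
class FrameSchedule:
    """Replica length, equilibration discard, and snapshot stride (ns/ps)."""

    replica_length_ns: float = 4.0
    discard_ns: float = 1.0
    stride_ps: float = 10.0

    @property
    def frames_per_replica(self) -> int:
        span_ps = (self.replica_length_ns - self.discard_ns) * 1000.0
        return int(round(span_ps / self.stride_ps))


@dataclass
class Ensemble:
    """Replica-indexed frame collections sharing one topology."""

    topology: Topology
    replicas: dict[int, list[Frame]]
    schedule: FrameSchedule = field(default_factory=FrameSchedule)

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        for rid, frames in self.replicas.items():
            for f in frames:
                if f.n_atoms != n:
                    raise ValueError(
                        f"replica {rid} frame has {f.n_atoms} atoms, topology has {n}"
                    )

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    @property
    def n_frames(self) -> int:
        return sum(len(v) for v in self.replicas.values())

    def iter_frames(self) -> Iterator[Frame]:
        for rid in sorted(self.replicas):
            yield from self.replicas[rid]


@dataclass(frozen=True)
class SubsetView:
    """Coordinate view of a subset of a frame's atoms (no re-simulation)."""

    indices: np.ndarray
    coordinates: np.ndarray

    @property
    def n_atoms(self) -> int:
        return self.indices.size


def split_single_trajectory(
    frame: Frame, topology: Topology
) -> tuple[SubsetView, SubsetView, SubsetView]:
    """Split a complex frame into complex / receptor / ligand coordinate views.

    This is the single-trajectory bookkeeping: receptor and ligand views are
    literal coordinate subsets of the same snapshot, so intramolecular
    (bonded) energy terms are identical in all three states and cancel in
    any end-state difference; they are never computed.

    Waters are excluded from all three views (explicit-water augmentation is
    a separate, opt-in step).
    """
    if frame.n_atoms != topology.n_atoms:
        raise InvalidTopologyError(
            f"frame has {frame.n_atoms} atoms, topology has {topology.n_atoms}"
        )
    if topology.receptor_mask.size == 0:
        raise InvalidTopologyError("empty receptor mask")
    if topology.ligand_mask.size == 0:
        raise InvalidTopologyError("empty ligand mask")
    cpx_idx = topology.solute_mask
    views = tuple(
        SubsetView(indices=idx, coordinates=frame.coordinates[idx])
        for idx in (cpx_idx, topology.receptor_mask, topology.ligand_mask)
    )
    return views  # type: ignore[return-value]
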