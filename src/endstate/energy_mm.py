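"""Gas-phase receptor–ligand interaction energy and per-residue decomposition.

In the single-trajectory approach only the receptor↔ligand cross terms of
the nonbonded energy survive the end-state difference, so the kernels here
evaluate cross pairs only, with no cutoff (end-state post-processing
convention; systems are small).

The internal dielectric ``eps_int`` divides the Coulomb cross term (the
"indi" convention of scaling solute–solute electrostatics); van der Waals
terms are dielectric-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .model_core import CONSTANTS, Frame, Topology, split_single_trajectory

MIN_DISTANCE = 1e-6  # Å; below this two atoms are considered coincident


class GeometryError(ValueError):
    """Raised when coincident atoms make a pair energy singular."""


@dataclass
class EnergyComponents:
    """Per-frame binding energy terms in kcal/mol.

    Unfilled components are ``None`` (explicitly absent), never zero.
    """

    E_ele: float | None = None
    E_vdW: float | None = None
    G_pol: float | None = None
    G_npol: float | None = None
    frame_id: int = 0
    replica_id: int = 0

    def total(self) -> float:
        parts = [self.E_ele, self.E_vdW, self.G_pol, self.G_npol]
        filled = [p for p in parts if p is not None]
        if not filled:
            raise ValueError("no energy components filled")
        return float(sum(filled))


def _cross_distances(coords_a: np.ndarray, coords_b: np.ndarray) -> np.ndarray:
    r = cdist(coords_a, coords_b)
    if np.any(r < MIN_DISTANCE):
        raise GeometryError("coincident atoms across the interface (r < 1e-6 Å)")
    return r


def coulomb_energy(
    coords_a: np.ndarray,
    charges_a: np.ndarray,
    coords_b: np.ndarray,
    charges_b: np.ndarray,
    eps_int: float = 1.0,
) -> float:
    """Cross-group Coulomb energy: Σ k·q_i·q_j/(ε_int·r_ij), kcal/mol."""
    if eps_int < 1.0:
        raise ValueError(f"eps_int must be >= 1, got {eps_int}")
    r = _cross_distances(coords_a, coords_b)
    qq = np.outer(charges_a, charges_b)
    return float(CONSTANTS.coulomb_constant * np.sum(qq / r) / eps_int)


def lj_energy(
    coords_a: np.ndarray,
    rmin_half_a: np.ndarray,
    epsilon_a: np.ndarray,
    coords_b: np.ndarray,
    rmin_half_b: np.ndarray,
    epsilon_b: np.ndarray,
) -> float:
    """Cross-group Lennard-Jones energy with Lorentz–Berthelot combination.

    rmin_ij = rmin_half_i + rmin_half_j (arithmetic), ε_ij = √(ε_i·ε_j)
    (geometric); E = Σ ε_ij[(rmin_ij/r)¹² − 2(rmin_ij/r)⁶].
    """
    r = _cross_distances(coords_a, coords_b)
    rmin = np.add.outer(rmin_half_a, rmin_half_b)
    eps = np.sqrt(np.outer(epsilon_a, epsilon_b))
    x6 = (rmin / r) ** 6
    return float(np.sum(eps * (x6 * x6 - 2.0 * x6)))


def interaction_energy(
    frame: Frame, topology: Topology, eps_int: float = 1.0
) -> EnergyComponents:
    """ΔE_ele and ΔE_vdW of binding from receptor↔ligand cross terms only."""
    _, rec, lig = split_single_trajectory(frame, topology)
    e_ele = coulomb_energy(
        rec.coordinates,
        topology.charges[rec.indices],
        lig.coordinates,
        topology.charges[lig.indices],
        eps_int,
    )
    e_vdw = lj_energy(
        rec.coordinates,
        topology.lj_rmin_half[rec.indices],
        topology.lj_epsilon[rec.indices],
        lig.coordinates,
        topology.lj_rmin_half[lig.indices],
        topology.lj_epsilon[lig.indices],
    )
    return EnergyComponents(
        E_ele=e_ele,
        E_vdW=e_vdw,
        frame_id=frame.frame_index,
        replica_id=frame.replica_id,
    )


def per_residue_decomposition(
    frame: Frame, topology: Topology, eps_int: float = 1.0
) -> dict[int, tuple[float, float]]:
    """Per-residue (E_ele, E_vdW) contributions to the interaction energy.

    Each cross pair's energy is split half-and-half between the two partner
    residues, so the residue sums reproduce the totals exactly.
    """
    _, rec, lig = split_single_trajectory(frame, topology)
    r = _cross_distances(rec.coordinates, lig.coordinates)
    q_rec = topology.charges[rec.indices]
    q_lig = topology.charges[lig.indices]
    e_ele_pairs = CONSTANTS.coulomb_constant * np.outer(q_rec, q_lig) / (r * eps_int)
    rmin = np.add.outer(
        topology.lj_rmin_half[rec.indices], topology.lj_rmin_half[lig.indices]
    )
    eps = np.sqrt(
        np.outer(topology.lj_epsilon[rec.indices], topology.lj_epsilon[lig.indices])
    )
    x6 = (rmin / r) ** 6
    e_vdw_pairs = eps * (x6 * x6 - 2.0 * x6)

    res_rec = topology.residue_indices[rec.indices]
    res_lig = topology.residue_indices[lig.indices]
    out: dict[int, list[float]] = {
        int(ri): [0.0, 0.0] for ri in np.unique(topology.residue_indices)
    }
    for pairs, slot in ((e_ele_pairs, 0), (e_vdw_pairs, 1)):
        half_rec = 0.5 * pairs.sum(axis=1)
        half_lig = 0.5 * pairs.sum(axis=0)
        for ri, v in zip(res_rec, half_rec):
            out[int(ri)][slot] += float(v)
        for ri, v in zip(res_lig, half_lig):
            out[int(ri)][slot] += float(v)
    return {k: (v[0], v[1]) for k, v in out.items()}
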