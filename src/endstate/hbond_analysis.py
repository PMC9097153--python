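"""Hydrogen-bond detection (solute–solute and water-bridged) and ensemble
summaries.

A bond is counted when the donor–acceptor distance is below ``d_max``
(default 3 Å, strict) and the donor–hydrogen–acceptor angle lies within
``angle_center ± angle_tol`` (default 180 ± 45°, inclusive). Donor chemistry
is supplied explicitly as a donor→hydrogen map — nothing is inferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import Ensemble, Frame, Topology


@dataclass(frozen=True)
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    distance: float  # donor–acceptor, Å
    angle: float  # donor–hydrogen–acceptor, degrees
    category: str  # "solute-solute" | "water-bridged"


def _dha_angle(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    v1 = d - h
    v2 = a - h
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(
    frame: Frame,
    donors: list[int],
    acceptors: list[int],
    donor_hydrogens: dict[int, list[int]],
    d_max: float = 3.0,
    angle_center: float = 180.0,
    angle_tol: float = 45.0,
    category: str = "solute-solute",
) -> list[HBond]:
    """All donor–acceptor pairs satisfying both geometric criteria.

    Output is deterministically ordered by (donor, acceptor) index.
    """
    xyz = frame.coordinates
    lo, hi = angle_center - angle_tol, angle_center + angle_tol
    bonds = []
    for don in sorted(donors):
        if don not in donor_hydrogens or not donor_hydrogens[don]:
            raise ValueError(f"donor atom {don} has no mapped hydrogen")
        for acc in sorted(acceptors):
            if acc == don:
                continue
            dist = float(np.linalg.norm(xyz[don] - xyz[acc]))
            if dist >= d_max:
                continue
            for h in donor_hydrogens[don]:
                ang = _dha_angle(xyz[don], xyz[h], xyz[acc])
                if lo <= ang <= hi:
                    bonds.append(HBond(don, h, acc, dist, ang, category))
                    break
    return bonds


def _group_hbonds_with_water(
    frame: Frame,
    water_donors: list[int],
    water_acceptors: list[int],
    group_donors: list[int],
    group_acceptors: list[int],
    donor_hydrogens: dict[int, list[int]],
    d_max: float,
    angle_center: float,
    angle_tol: float,
) -> bool:
    """Either-polarity H-bond between one water and one solute group."""
    kw = dict(
        d_max=d_max, angle_center=angle_center, angle_tol=angle_tol,
        category="water-bridged",
    )
    if water_donors and group_acceptors:
        if detect_hbonds(frame, water_donors, group_acceptors, donor_hydrogens, **kw):
            return True
    if group_donors and water_acceptors:
        if detect_hbonds(frame, group_donors, water_acceptors, donor_hydrogens, **kw):
            return True
    return False


def water_bridges(
    frame: Frame,
    topology: Topology,
    group_a: list[int],
    group_b: list[int],
    donors: list[int],
    acceptors: list[int],
    donor_hydrogens: dict[int, list[int]],
    d_max: float = 3.0,
    angle_center: float = 180.0,
    angle_tol: float = 45.0,
) -> list[int]:
    """Water residues simultaneously H-bonded (either polarity) to both groups.

    Only single-water bridges count; chains of two or more waters do not.
    Returns the bridging water residue indices in ascending order.
    """
    don_set, acc_set = set(donors), set(acceptors)
    a_set, b_set = set(group_a), set(group_b)
    water_res = sorted({int(r) for r in topology.residue_indices[topology.water_mask]})
    bridges = []
    for wr in water_res:
        watoms = set(topology.residue_atoms(wr).tolist())
        wd = sorted(watoms & don_set)
        wa = sorted(watoms & acc_set)
        linked = []
        for grp in (a_set, b_set):
            gd = sorted(grp & don_set)
            ga = sorted(grp & acc_set)
            linked.append(
                _group_hbonds_with_water(
                    frame, wd, wa, gd, ga, donor_hydrogens,
                    d_max, angle_center, angle_tol,
                )
            )
        if all(linked):
            bridges.append(wr)
    return bridges


def ensemble_hbond_summary(
    ensemble: Ensemble,
    donors: list[int],
    acceptors: list[int],
    donor_hydrogens: dict[int, list[int]],
    d_max: float = 3.0,
    angle_center: float = 180.0,
    angle_tol: float = 45.0,
) -> dict[str, float]:
    """Mean receptor–ligand solute–solute and water-bridged H-bond counts,
    averaged over frames within replicas then over replicas, with the SD
    over replica means."""
    topo = ensemble.topology
    rec = set(topo.receptor_mask.tolist())
    lig = set(topo.ligand_mask.tolist())
    ss_means, br_means = [], []
    for rid in sorted(ensemble.replicas):
        ss_counts, br_counts = [], []
        for frame in ensemble.replicas[rid]:
            rec_d = sorted(rec & set(donors))
            lig_a = sorted(lig & set(acceptors))
            lig_d = sorted(lig & set(donors))
            rec_a = sorted(rec & set(acceptors))
            n = 0
            if rec_d and lig_a:
                n += len(
                    detect_hbonds(
                        frame, rec_d, lig_a, donor_hydrogens,
                        d_max, angle_center, angle_tol,
                    )
                )
            if lig_d and rec_a:
                n += len(
                    detect_hbonds(
                        frame, lig_d, rec_a, donor_hydrogens,
                        d_max, angle_center, angle_tol,
                    )
                )
            ss_counts.append(n)
            br_counts.append(
                len(
                    water_bridges(
                        frame, topo, sorted(rec), sorted(lig),
                        donors, acceptors, donor_hydrogens,
                        d_max, angle_center, angle_tol,
                    )
                )
            )
        ss_means.append(np.mean(ss_counts))
        br_means.append(np.mean(br_counts))
    ss = np.array(ss_means)
    br = np.array(br_means)
    return {
        "solute_solute_mean": float(ss.mean()),
        "solute_solute_sd": float(ss.std(ddof=1)) if ss.size > 1 else float("nan"),
        "bridged_mean": float(br.mean()),
        "bridged_sd": float(br.std(ddof=1)) if br.size > 1 else float("nan"),
    }
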