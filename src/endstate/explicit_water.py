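"""Selection of the X closest interfacial waters and their attachment to the
receptor and complex sides of the end-state calculation.

Selected waters join the receptor and the complex (never the ligand) for
every energy term, so a water's internal terms cancel in the binding
difference while its interactions with the ligand survive. Selection is
re-evaluated per frame so retained waters stay near the site throughout the
ensemble; distance is measured from each water's oxygen to the O/N atoms of
the designated binding-site residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .model_core import Frame, SubsetView, Topology


@dataclass(frozen=True)
class WaterSelection:
    frame_id: int
    water_residues: tuple[int, ...]  # ordered by distance, ties by index
    water_atoms: np.ndarray  # all atoms of the selected waters
    n_requested: int
    site_residues: tuple[int, ...]


def select_waters(
    frame: Frame,
    topology: Topology,
    site_residues: list[int],
    n_waters: int,
) -> WaterSelection:
    """The ``n_waters`` waters closest to any O/N atom of the site residues.

    Ranking is by the minimum distance from the water's oxygen; exact ties
    break toward the lower water residue index. Requesting more waters than
    exist selects all with a warning.
    """
    if not site_residues:
        raise ValueError("site_residues must be non-empty")
    if n_waters < 0:
        raise ValueError("n_waters must be >= 0")
    site_atoms = np.concatenate(
        [topology.residue_atoms(r) for r in site_residues]
    ).astype(np.intp)
    site_on = np.array(
        [i for i in site_atoms if topology.atoms[i].element in ("O", "N")],
        dtype=np.intp,
    )
    if site_on.size == 0:
        raise ValueError("site residues contain no O/N atoms")
    water_res = sorted({int(r) for r in topology.residue_indices[topology.water_mask]})
    if n_waters > len(water_res):
        warnings.warn(
            f"requested {n_waters} waters, only {len(water_res)} present; "
            "selecting all"
        )
        n_waters = len(water_res)
    oxygens = []
    for wr in water_res:
        atoms = topology.residue_atoms(wr)
        ox = [i for i in atoms if topology.atoms[i].element == "O"]
        oxygens.append(ox[0] if ox else atoms[0])
    if water_res:
        d = cdist(
            frame.coordinates[oxygens], frame.coordinates[site_on]
        ).min(axis=1)
        order = np.argsort(d, kind="stable")  # stable: ties by water index
        chosen = [water_res[i] for i in order[:n_waters]]
    else:
        chosen = []
    atoms = (
        np.concatenate([topology.residue_atoms(r) for r in chosen]).astype(np.intp)
        if chosen
        else np.array([], dtype=np.intp)
    )
    return WaterSelection(
        frame_id=frame.frame_index,
        water_residues=tuple(chosen),
        water_atoms=atoms,
        n_requested=n_waters,
        site_residues=tuple(site_residues),
    )


def augment_for_energy(
    frame: Frame,
    complex_view: SubsetView,
    receptor_view: SubsetView,
    ligand_view: SubsetView,
    selection: WaterSelection,
) -> tuple[SubsetView, SubsetView, SubsetView]:
    """Append the selected water atoms to the complex and receptor views.

    The ligand view is returned unchanged. With an empty selection all three
    views are identical to the input, so X = 0 reproduces the water-free
    pipeline exactly.
    """
    if selection.frame_id != frame.frame_index:
        raise ValueError(
            f"selection from frame {selection.frame_id}, "
            f"energy frame is {frame.frame_index}"
        )
    if selection.water_atoms.size == 0:
        return complex_view, receptor_view, ligand_view

    def extend(view: SubsetView) -> SubsetView:
        idx = np.concatenate([view.indices, selection.water_atoms])
        return SubsetView(indices=idx, coordinates=frame.coordinates[idx])

    return extend(complex_view), extend(receptor_view), ligand_view
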