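"""Solute-entropy corrections to the end-state binding free energy.

Two estimators are provided:

* **Interaction entropy** — the exponential average of per-frame
  interaction-energy fluctuations pooled over all replicas,
  −TΔS = (1/β)·ln⟨exp(β·(ΔE_int − ⟨ΔE_int⟩))⟩, evaluated with a
  log-sum-exp stabilization. By Jensen's inequality the estimate is a
  non-negative penalty.

* **Truncated normal-mode analysis** — vibrational entropies of a
  binding-site region carved out of each species: residues with any atom
  within ``r_keep`` of the partner are retained, those in the
  [``r_freeze_inner``, ``r_keep``] shell are frozen ("belly") through both
  minimization and the frequency calculation, chain breaks are capped with
  frozen pseudo-atoms placed at the first deleted residue, and a frozen
  water shell is kept around the site. Frozen atoms contribute no modes,
  so they have no direct impact on the entropy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
from scipy.optimize import minimize as scipy_minimize
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

from .model_core import CONSTANTS, Ensemble, Frame, Topology

logger = logging.getLogger(__name__)

# conversion: mass-weighted Hessian eigenvalue (kcal·mol⁻¹·Å⁻²·amu⁻¹) →
# squared angular frequency (s⁻²)
EIGENVALUE_TO_OMEGA_SQ = 4.184e26
HBAR = 1.054571817e-34  # J·s
KB_SI = 1.380649e-23  # J/K


class NotAMinimumError(RuntimeError):
    """Hessian has significantly negative eigenvalues."""


class EntropyOverflowError(RuntimeError):
    """Interaction-entropy series too wide for a meaningful estimate."""


@dataclass
class InteractionEnergySeries:
    """Per-frame ΔE_int values (kcal/mol) pooled over replicas."""

    values: np.ndarray
    temperature: float = 298.0
    eps_int: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("interaction-energy series contains non-finite values")


@dataclass
class EntropyEstimate:
    """−TΔS (kcal/mol) with method metadata and diagnostics."""

    minus_T_delta_S: float
    method: str
    n_frames_used: int
    diagnostics: dict = field(default_factory=dict)


def interaction_entropy(series: InteractionEnergySeries) -> EntropyEstimate:
    """Interaction-entropy estimate of −TΔS from ΔE_int fluctuations.

    For i.i.d. Gaussian fluctuations of standard deviation σ the large-n
    limit is βσ²/2.
    """
    x = series.values
    if x.size < 2:
        raise ValueError("need at least 2 frames for interaction entropy")
    beta = CONSTANTS.beta(series.temperature)
    dev = beta * (x - x.mean())
    # exact up to fp rounding: (1/β)·[logsumexp(β·dev) − ln n]
    log_mean_exp = logsumexp(dev) - np.log(x.size)
    value = float(log_mean_exp / beta)
    if not np.isfinite(value) or log_mean_exp > 700.0:
        raise EntropyOverflowError(
            "interaction-energy fluctuations too large for a stable estimate; "
            "consider a higher internal dielectric (eps_int), which narrows "
            "the ΔE_int distribution"
        )
    return EntropyEstimate(
        minus_T_delta_S=max(0.0, value),
        method="interaction_entropy",
        n_frames_used=int(x.size),
        diagnostics={"series_sd": float(x.std(ddof=1)), "beta": beta},
    )


# ---------------------------------------------------------------------------
# truncated normal-mode analysis
# ---------------------------------------------------------------------------


class EnergyFunction(Protocol):
    """Potential over a truncated system's full coordinate array."""

    def value_and_grad(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        """Energy (kcal/mol) and gradient (kcal/mol/Å), both over all atoms."""
        ...


@dataclass(frozen=True)
class CapRecord:
    """Frozen pseudo-atom closing a chain break.

    The cap takes its per-frame coordinates from ``source_atom`` — the first
    atom of the first deleted residue — standing in for an acetyl (break on
    the N-terminal side) or amide (C-terminal side) capping group.
    """

    source_atom: int
    kind: str  # "acetyl" | "amide"


@dataclass
class TruncatedSystem:
    """Kept-atom map plus flexible/frozen partition for one species."""

    species: str  # "complex" | "receptor" | "ligand"
    kept_indices: np.ndarray  # parent topology atom indices, ordered
    flexible_mask: np.ndarray  # bool over kept + cap atoms
    caps: list[CapRecord]
    masses: np.ndarray  # over kept + cap atoms

    def __post_init__(self) -> None:
        n = self.kept_indices.size + len(self.caps)
        if self.flexible_mask.size != n or self.masses.size != n:
            raise ValueError("mask/mass lengths disagree with kept+caps count")
        if np.any(self.flexible_mask[self.kept_indices.size:]):
            raise ValueError("cap atoms must be frozen")

    @property
    def n_atoms(self) -> int:
        return self.kept_indices.size + len(self.caps)

    @property
    def flexible_indices(self) -> np.ndarray:
        return np.where(self.flexible_mask)[0]

    def coordinates_from_frame(self, frame: Frame) -> np.ndarray:
        cap_src = [c.source_atom for c in self.caps]
        parts = [frame.coordinates[self.kept_indices]]
        if cap_src:
            parts.append(frame.coordinates[cap_src])
        return np.vstack(parts)


@dataclass(frozen=True)
class NMAConfig:
    r_keep: float = 16.0  # Å
    r_freeze_inner: float = 12.0  # Å
    n_waters_complex: int = 1000
    n_waters_free: int = 500
    fd_step: float = 1e-4  # Å
    low_freq_cutoff: float = 1e-6  # mass-weighted eigenvalue units
    rms_grad_tol: float = 1e-6  # kcal·mol⁻¹·Å⁻¹
    max_minimize_steps: int = 5000
    frame_stride_ps: float = 100.0
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if self.r_freeze_inner >= self.r_keep:
            raise ValueError("r_freeze_inner must be < r_keep")


def _residue_partner_distances(
    frame: Frame, topology: Topology
) -> dict[int, float]:
    """Minimum any-atom distance from each solute residue to the partner."""
    rec, lig = topology.receptor_mask, topology.ligand_mask
    d = cdist(frame.coordinates[rec], frame.coordinates[lig])
    out: dict[int, float] = {}
    rec_res = topology.residue_indices[rec]
    lig_res = topology.residue_indices[lig]
    for r in np.unique(rec_res):
        out[int(r)] = float(d[rec_res == r].min())
    for r in np.unique(lig_res):
        out[int(r)] = float(d[:, lig_res == r].min())
    return out


def _molecule_residues(topology: Topology, mask: np.ndarray) -> list[int]:
    return sorted({int(r) for r in topology.residue_indices[mask]})


def _cap_breaks(
    topology: Topology, molecule_residues: list[int], kept: set[int]
) -> list[CapRecord]:
    """One frozen cap per kept/deleted boundary along a molecule's chain."""
    caps = []
    for pos, r in enumerate(molecule_residues):
        if r not in kept:
            continue
        if pos + 1 < len(molecule_residues):
            nxt = molecule_residues[pos + 1]
            if nxt not in kept:
                caps.append(
                    CapRecord(int(topology.residue_atoms(nxt)[0]), "amide")
                )
        if pos - 1 >= 0:
            prev = molecule_residues[pos - 1]
            if prev not in kept:
                caps.append(
                    CapRecord(int(topology.residue_atoms(prev)[0]), "acetyl")
                )
    return caps


def _select_waters(
    frame: Frame,
    topology: Topology,
    flexible_atoms: np.ndarray,
    n_waters: int,
) -> list[int]:
    """Whole water residues closest to the flexible region, by min distance."""
    if topology.water_mask.size == 0 or n_waters == 0:
        return []
    water_res = sorted(
        {int(r) for r in topology.residue_indices[topology.water_mask]}
    )
    dmin = []
    flex_xyz = frame.coordinates[flexible_atoms]
    for r in water_res:
        atoms = topology.residue_atoms(r)
        dmin.append(cdist(frame.coordinates[atoms], flex_xyz).min())
    order = np.argsort(dmin, kind="stable")
    if n_waters > len(water_res):
        warnings.warn(
            f"requested {n_waters} shell waters but only {len(water_res)} "
            "available; keeping all"
        )
        n_waters = len(water_res)
    return [water_res[i] for i in order[:n_waters]]


def build_truncated_system(
    reference_frame: Frame,
    topology: Topology,
    config: NMAConfig | None = None,
) -> dict[str, TruncatedSystem]:
    """Carve truncated, partially frozen systems for complex/receptor/ligand.

    Distances are measured on the designated reference structure with the
    any-atom convention: a residue is kept if any of its atoms lies within
    ``r_keep`` of any partner atom, and frozen when its minimum distance
    falls in [``r_freeze_inner``, ``r_keep``].
    """
    config = config or NMAConfig()
    dists = _residue_partner_distances(reference_frame, topology)
    kept = {r for r, d in dists.items() if d <= config.r_keep}
    frozen_res = {r for r in kept if dists[r] >= config.r_freeze_inner}
    if not frozen_res:
        warnings.warn("no residues fall in the frozen buffer shell")

    rec_res = _molecule_residues(topology, topology.receptor_mask)
    lig_res = _molecule_residues(topology, topology.ligand_mask)

    def assemble(species: str, molecules: list[list[int]], n_waters: int):
        kept_res = [r for mol in molecules for r in mol if r in kept]
        atom_idx = np.concatenate(
            [topology.residue_atoms(r) for r in kept_res]
        ).astype(np.intp)
        flex_res = {r for r in kept_res if r not in frozen_res}
        flex_atoms = atom_idx[
            np.isin(topology.residue_indices[atom_idx], sorted(flex_res))
        ]
        water_res = _select_waters(reference_frame, topology, flex_atoms, n_waters)
        water_idx = (
            np.concatenate([topology.residue_atoms(r) for r in water_res]).astype(
                np.intp
            )
            if water_res
            else np.array([], dtype=np.intp)
        )
        caps: list[CapRecord] = []
        for mol in molecules:
            caps.extend(_cap_breaks(topology, mol, kept))
        all_kept = np.concatenate([atom_idx, water_idx])
        flex_mask = np.zeros(all_kept.size + len(caps), dtype=bool)
        flex_mask[: atom_idx.size] = np.isin(atom_idx, flex_atoms)
        masses = np.concatenate(
            [
                topology.masses[all_kept],
                topology.masses[[c.source_atom for c in caps]],
            ]
        )
        return TruncatedSystem(
            species=species,
            kept_indices=all_kept,
            flexible_mask=flex_mask,
            caps=caps,
            masses=masses,
        )

    return {
        "complex": assemble("complex", [rec_res, lig_res], config.n_waters_complex),
        "receptor": assemble("receptor", [rec_res], config.n_waters_free),
        "ligand": assemble("ligand", [lig_res], config.n_waters_free),
    }


def minimize_flexible(
    coords: np.ndarray,
    flexible_indices: np.ndarray,
    energy_fn: EnergyFunction,
    rms_grad_tol: float = 1e-6,
    max_steps: int = 5000,
) -> np.ndarray:
    """Belly minimization: frozen atoms held bit-identical to the input.

    Converged when the RMS gradient over flexible degrees of freedom is at
    most ``rms_grad_tol`` (kcal·mol⁻¹·Å⁻¹); otherwise stops at ``max_steps``
    with a warning.
    """
    coords = np.asarray(coords, dtype=np.float64).copy()
    flex = np.asarray(flexible_indices, dtype=np.intp)
    if flex.size == 0:
        return coords

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        c = coords.copy()
        c[flex] = x.reshape(-1, 3)
        e, g = energy_fn.value_and_grad(c)
        return e, g[flex].ravel()

    def rms(g: np.ndarray) -> float:
        return float(np.sqrt(np.mean(g**2)))

    x0 = coords[flex].ravel()
    e0, g0 = objective(x0)
    if rms(g0) <= rms_grad_tol:
        return coords
    result = scipy_minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": max_steps,
            "ftol": 1e-16,
            "gtol": rms_grad_tol * 1e-2,
            "maxcor": 20,
        },
    )
    _, g = objective(result.x)
    if rms(g) > rms_grad_tol:
        warnings.warn(
            f"minimizer stopped with RMS gradient {rms(g):.3e} > "
            f"{rms_grad_tol:.1e} after {result.nit} iterations"
        )
    out = coords
    out[flex] = result.x.reshape(-1, 3)
    return out


def flexible_hessian(
    coords: np.ndarray,
    flexible_indices: np.ndarray,
    energy_fn: EnergyFunction,
    masses: np.ndarray,
    fd_step: float = 1e-4,
) -> np.ndarray:
    """Mass-weighted Hessian (3F×3F) over flexible atoms only.

    Central finite differences of the analytic gradient; symmetrized by
    averaging, with frozen atoms entering only through the potential.
    """
    coords = np.asarray(coords, dtype=np.float64)
    flex = np.asarray(flexible_indices, dtype=np.intp)
    nf = flex.size
    H = np.empty((3 * nf, 3 * nf))
    for a in range(nf):
        for d in range(3):
            cp = coords.copy()
            cp[flex[a], d] += fd_step
            _, gp = energy_fn.value_and_grad(cp)
            cm = coords.copy()
            cm[flex[a], d] -= fd_step
            _, gm = energy_fn.value_and_grad(cm)
            H[3 * a + d] = ((gp - gm)[flex] / (2.0 * fd_step)).ravel()
    if not np.all(np.isfinite(H)):
        raise FloatingPointError("non-finite second derivatives")
    H = 0.5 * (H + H.T)
    w = 1.0 / np.sqrt(np.repeat(masses[flex], 3))
    return H * np.outer(w, w)


@dataclass
class VibrationalEntropy:
    """Harmonic-oscillator entropy of one species (kcal·mol⁻¹·K⁻¹)."""

    S: float
    n_modes_used: int
    n_discarded: int


def harmonic_entropy(
    eigenvalues: np.ndarray,
    temperature: float = 298.0,
    low_freq_cutoff: float = 1e-6,
) -> VibrationalEntropy:
    """Quantum harmonic-oscillator vibrational entropy from mass-weighted
    Hessian eigenvalues.

    Per mode, with x = ħω/k_BT: S/R = x/(eˣ−1) − ln(1−e⁻ˣ). Modes with
    |eigenvalue| below ``low_freq_cutoff`` are discarded (belly systems do
    not carry exactly six rigid-body modes, so the near-zero count is
    logged, not assumed).
    """
    lam = np.asarray(eigenvalues, dtype=np.float64)
    negative = lam < -low_freq_cutoff
    if np.any(negative):
        raise NotAMinimumError(
            f"{int(negative.sum())} negative Hessian eigenvalue(s): "
            "structure is not at a minimum"
        )
    keep = np.abs(lam) >= low_freq_cutoff
    n_disc = int((~keep).sum())
    if n_disc:
        logger.info("discarded %d near-zero mode(s)", n_disc)
    lam = lam[keep]
    omega = np.sqrt(lam * EIGENVALUE_TO_OMEGA_SQ)  # rad/s
    x = HBAR * omega / (KB_SI * temperature)
    s_over_r = x / np.expm1(x) - np.log1p(-np.exp(-x))
    S = float(CONSTANTS.k_boltzmann * np.sum(s_over_r))
    return VibrationalEntropy(S=S, n_modes_used=int(lam.size), n_discarded=n_disc)


def species_entropy(
    system: TruncatedSystem,
    frame: Frame,
    energy_fn: EnergyFunction,
    config: NMAConfig,
) -> VibrationalEntropy:
    """Minimize → Hessian → harmonic entropy for one species in one frame."""
    coords = system.coordinates_from_frame(frame)
    flex = system.flexible_indices
    if flex.size == 0:
        return VibrationalEntropy(S=0.0, n_modes_used=0, n_discarded=0)
    minimized = minimize_flexible(
        coords, flex, energy_fn, config.rms_grad_tol, config.max_minimize_steps
    )
    H = flexible_hessian(minimized, flex, energy_fn, system.masses, config.fd_step)
    lam = np.linalg.eigvalsh(H)
    return harmonic_entropy(lam, config.temperature, config.low_freq_cutoff)


def trunc_nma_correction(
    ensemble: Ensemble,
    energy_for: Callable[[TruncatedSystem], EnergyFunction],
    config: NMAConfig | None = None,
    reference_frame: Frame | None = None,
) -> EntropyEstimate:
    """−TΔS from truncated NMA averaged over a strided frame subset.

    Frames are taken every ``frame_stride_ps`` from each replica's retained
    span (the default 100 ps stride over 25 × 3 ns gives 750 frames).
    Per-frame failures are logged and skipped; more than 20% skipped is a
    hard error.
    """
    config = config or NMAConfig()
    topo = ensemble.topology
    if reference_frame is None:
        first = sorted(ensemble.replicas)[0]
        reference_frame = ensemble.replicas[first][0]
    systems = build_truncated_system(reference_frame, topo, config)
    energies = {sp: energy_for(systems[sp]) for sp in systems}

    ratio = max(1, int(round(config.frame_stride_ps / ensemble.schedule.stride_ps)))
    per_frame: list[float] = []
    n_failed = 0
    n_total = 0
    for rid in sorted(ensemble.replicas):
        for frame in ensemble.replicas[rid][ratio - 1 :: ratio]:
            n_total += 1
            try:
                s = {
                    sp: species_entropy(systems[sp], frame, energies[sp], config).S
                    for sp in ("complex", "receptor", "ligand")
                }
                delta_s = s["complex"] - s["receptor"] - s["ligand"]
                per_frame.append(-config.temperature * delta_s)
            except (NotAMinimumError, FloatingPointError) as exc:
                n_failed += 1
                logger.warning(
                    "frame %d/replica %d skipped: %s",
                    frame.frame_index,
                    rid,
                    exc,
                )
    if n_total and n_failed / n_total > 0.20:
        raise RuntimeError(
            f"{n_failed}/{n_total} frames failed truncated NMA (> 20%)"
        )
    values = np.array(per_frame)
    return EntropyEstimate(
        minus_T_delta_S=float(values.mean()) if values.size else 0.0,
        method="trunc_nma",
        n_frames_used=int(values.size),
        diagnostics={
            "per_frame": values,
            "sd": float(values.std(ddof=1)) if values.size > 1 else float("nan"),
            "n_failed": n_failed,
        },
    )
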