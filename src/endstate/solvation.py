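"""Implicit-solvation terms: polar (GB, optional finite-difference linearized
PB) and nonpolar (linear SASA model) contributions, and their binding
differences.

The GB flavor is the Still pairwise form fed by a configurable radii scheme
(intrinsic radii, or HCT-style pairwise descreening). It deliberately does
NOT reproduce any specific Amber GB parameterization (e.g. GB-Neck2): the
aim is a transparent, testable scheme whose single-atom limit is the exact
Born formula. GB exposes no interior-dielectric knob — only the PB solver
and the gas-phase Coulomb term do.

Salt enters GB through exponential Debye screening of the solvent term and
PB through κ² outside the solute plus a 2 Å ion-exclusion layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .model_core import CONSTANTS, SubsetView, Topology

# ---------------------------------------------------------------------------
# nonpolar term
# ---------------------------------------------------------------------------

SURFACE_TENSION = 0.00542  # kcal·mol⁻¹·Å⁻² (γ)
NONPOLAR_OFFSET = 0.92  # kcal·mol⁻¹ (b)


def nonpolar_solvation(
    total_sasa: float,
    surface_tension: float = SURFACE_TENSION,
    offset: float = NONPOLAR_OFFSET,
) -> float:
    """Nonpolar solvation free energy γ·SASA + b in kcal/mol."""
    if total_sasa < 0:
        raise ValueError(f"SASA must be >= 0, got {total_sasa}")
    return surface_tension * total_sasa + offset


# ---------------------------------------------------------------------------
# solvent-accessible surface area (Shrake–Rupley)
# ---------------------------------------------------------------------------


def unit_sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral point set on the unit sphere."""
    k = np.arange(n, dtype=np.float64) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley_sasa(
    coordinates: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (Å²).

    Test points are placed on each atom's expanded sphere (radius + probe)
    and counted accessible when outside every other atom's expanded sphere.
    The point set is a fixed golden-section spiral, so results are
    deterministic for a given ``n_sphere_points``.
    """
    coords = np.asarray(coordinates, dtype=np.float64)
    radii = np.asarray(radii, dtype=np.float64)
    if np.any(radii <= 0):
        raise ValueError("all radii must be positive")
    n = coords.shape[0]
    expanded = radii + probe_radius
    sphere = unit_sphere_points(n_sphere_points)
    areas = np.empty(n)
    # neighbor prefilter: only atoms whose expanded spheres can overlap
    d = squareform(pdist(coords)) if n > 1 else np.zeros((1, 1))
    for i in range(n):
        pts = coords[i] + expanded[i] * sphere
        nbrs = np.where((d[i] < expanded[i] + expanded) & (np.arange(n) != i))[0]
        if nbrs.size:
            buried = np.zeros(n_sphere_points, dtype=bool)
            for j in nbrs:
                buried |= (
                    np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
                    < expanded[j] ** 2
                )
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * frac
    return areas


# ---------------------------------------------------------------------------
# generalized Born
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GBConfig:
    """Generalized-Born settings.

    ``radii_scheme``: "intrinsic" uses each atom's intrinsic Born radius
    unchanged; "pairwise-descreening" integrates HCT-style descreening by
    neighbor spheres scaled by ``descreening_scale``. The scale's default
    (0.8) is in the range used by pairwise-descreening GB variants; the
    radius offset is zero so an isolated atom's effective radius equals its
    intrinsic radius exactly.
    """

    eps_solvent: float = 78.5
    ionic_strength: float = 0.150  # mol/L
    radii_scheme: str = "pairwise-descreening"
    descreening_scale: float = 0.8
    max_effective_radius: float = 100.0
    temperature: float = 298.0

    def kappa(self) -> float:
        return CONSTANTS.debye_kappa(
            self.ionic_strength, self.eps_solvent, self.temperature
        )


def _hct_integral(r: np.ndarray, rho_i: np.ndarray, s_j: np.ndarray) -> np.ndarray:
    """HCT pairwise-descreening integral I_ij ≥ 0.

    ``r``: separations; ``rho_i``: intrinsic radius of the descreened atom;
    ``s_j``: scaled radius of the descreening neighbor. Vectorized over
    arrays of identical shape.
    """
    U = r + s_j
    I = np.zeros_like(r)
    active = rho_i < U  # neighbor not fully engulfed by atom i
    if not np.any(active):
        return I
    rA, rhoA, sA, UA = r[active], rho_i[active], s_j[active], U[active]
    L = np.maximum(np.abs(rA - sA), rhoA)
    term = (
        1.0 / L
        - 1.0 / UA
        + (rA / 4.0) * (1.0 / UA**2 - 1.0 / L**2)
        + (1.0 / (2.0 * rA)) * np.log(L / UA)
        + (sA**2 / (4.0 * rA)) * (1.0 / L**2 - 1.0 / UA**2)
    )
    # atom i's center inside neighbor sphere: add the engulfed-cap term
    inside = rhoA < (sA - rA)
    term = np.where(inside, term + 2.0 * (1.0 / rhoA - 1.0 / L), term)
    I[active] = 0.5 * term
    return I


def effective_born_radii(
    coordinates: np.ndarray,
    intrinsic_radii: np.ndarray,
    config: GBConfig | None = None,
) -> np.ndarray:
    """Per-atom effective Born radii (Å) under the configured scheme.

    An isolated atom's effective radius is its intrinsic radius under any
    scheme; descreening by neighbors can only increase it.
    """
    config = config or GBConfig()
    coords = np.asarray(coordinates, dtype=np.float64)
    rho = np.asarray(intrinsic_radii, dtype=np.float64)
    if np.any(rho <= 0):
        raise ValueError("intrinsic radii must be positive")
    if config.radii_scheme == "intrinsic":
        return rho.copy()
    if config.radii_scheme != "pairwise-descreening":
        raise ValueError(f"unknown radii scheme: {config.radii_scheme!r}")
    n = coords.shape[0]
    inv = 1.0 / rho
    if n > 1:
        r = squareform(pdist(coords))
        rho_i = np.broadcast_to(rho[:, None], (n, n))
        s_j = np.broadcast_to((config.descreening_scale * rho)[None, :], (n, n))
        I = _hct_integral(r, rho_i, s_j)
        np.fill_diagonal(I, 0.0)
        inv = inv - I.sum(axis=1)
    inv = np.maximum(inv, 1.0 / config.max_effective_radius)
    return 1.0 / inv


def gb_polar_energy(
    coordinates: np.ndarray,
    charges: np.ndarray,
    effective_radii: np.ndarray,
    config: GBConfig | None = None,
) -> float:
    """Still-form GB polar solvation energy (kcal/mol).

    G = −(k/2)·Σ_{ij} q_i q_j (1 − e^{−κ f_ij}/ε_w) / f_ij with
    f_ij = sqrt(r² + R_i R_j exp(−r²/(4 R_i R_j))); the i=j term gives the
    Born self-energy, so a single ion reproduces the Born formula exactly.
    """
    config = config or GBConfig()
    coords = np.asarray(coordinates, dtype=np.float64)
    q = np.asarray(charges, dtype=np.float64)
    R = np.asarray(effective_radii, dtype=np.float64)
    if np.any(R <= 0):
        raise ValueError("effective radii must be positive")
    r2 = squareform(pdist(coords)) ** 2 if len(q) > 1 else np.zeros((1, 1))
    RR = np.outer(R, R)
    f = np.sqrt(r2 + RR * np.exp(-r2 / (4.0 * RR)))
    kappa = config.kappa()
    screen = 1.0 - np.exp(-kappa * f) / config.eps_solvent
    qq = np.outer(q, q)
    return float(-0.5 * CONSTANTS.coulomb_constant * np.sum(qq * screen / f))


# ---------------------------------------------------------------------------
# finite-difference linearized Poisson–Boltzmann
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PBGrid:
    """Finite-difference grid and dielectric settings for the LPB solver."""

    spacing: float = 0.5  # Å
    padding: float = 8.0  # Å beyond atom spheres on every side
    eps_int: float = 1.0
    eps_solvent: float = 78.5
    ionic_strength: float = 0.0  # mol/L
    ion_exclusion: float = 2.0  # Å Stern layer around atom spheres
    boundary: str = "debye-huckel"  # or "zero"
    tol: float = 1e-6
    max_iterations: int = 20000
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")


class PBConvergenceError(RuntimeError):
    pass


def _sor_solve(
    phi: np.ndarray,
    eps_faces: tuple[np.ndarray, ...],
    kappa_sq_h2: np.ndarray,
    rhs: np.ndarray,
    tol: float,
    max_iterations: int,
) -> np.ndarray:
    """Red-black SOR on the interior nodes; boundary values held fixed."""
    ex, ey, ez = eps_faces
    nx, ny, nz = phi.shape
    # face arrays sliced to the 6 neighbors of interior nodes
    exm = ex[:-1, 1:-1, 1:-1]  # face to (i-1)
    exp_ = ex[1:, 1:-1, 1:-1]  # face to (i+1)
    eym = ey[1:-1, :-1, 1:-1]
    eyp = ey[1:-1, 1:, 1:-1]
    ezm = ez[1:-1, 1:-1, :-1]
    ezp = ez[1:-1, 1:-1, 1:]
    diag = exm + exp_ + eym + eyp + ezm + ezp + kappa_sq_h2
    ii, jj, kk = np.meshgrid(
        np.arange(1, nx - 1), np.arange(1, ny - 1), np.arange(1, nz - 1),
        indexing="ij",
    )
    parity = (ii + jj + kk) % 2
    masks = (parity == 0, parity == 1)
    n_max = max(nx, ny, nz)
    omega = 2.0 / (1.0 + np.sin(np.pi / n_max))
    rhs_norm = np.linalg.norm(rhs)
    scale = rhs_norm if rhs_norm > 0 else 1.0
    for _ in range(max_iterations):
        for m in masks:
            nb = (
                exm * phi[:-2, 1:-1, 1:-1]
                + exp_ * phi[2:, 1:-1, 1:-1]
                + eym * phi[1:-1, :-2, 1:-1]
                + eyp * phi[1:-1, 2:, 1:-1]
                + ezm * phi[1:-1, 1:-1, :-2]
                + ezp * phi[1:-1, 1:-1, 2:]
            )
            new = (nb + rhs) / diag
            interior = phi[1:-1, 1:-1, 1:-1]
            interior[m] += omega * (new[m] - interior[m])
        nb = (
            exm * phi[:-2, 1:-1, 1:-1]
            + exp_ * phi[2:, 1:-1, 1:-1]
            + eym * phi[1:-1, :-2, 1:-1]
            + eyp * phi[1:-1, 2:, 1:-1]
            + ezm * phi[1:-1, 1:-1, :-2]
            + ezp * phi[1:-1, 1:-1, 2:]
        )
        residual = nb + rhs - diag * phi[1:-1, 1:-1, 1:-1]
        if np.linalg.norm(residual) / scale < tol:
            return phi
    raise PBConvergenceError(
        f"SOR did not reach tol={tol} in {max_iterations} iterations "
        f"(residual {np.linalg.norm(residual) / scale:.3e})"
    )


def _grid_solve(
    coords: np.ndarray,
    charges: np.ndarray,
    radii: np.ndarray,
    grid: PBGrid,
    homogeneous: bool,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Solve ∇·ε∇φ − ε_w κ² φ = −4π k ρ on a uniform grid.

    Returns (phi, origin, spacing). ``homogeneous=True`` solves the
    all-ε_int, no-salt reference used to cancel grid self-energy.
    """
    h = grid.spacing
    lo = (coords - radii[:, None]).min(axis=0) - grid.padding
    hi = (coords + radii[:, None]).max(axis=0) + grid.padding
    shape = np.ceil((hi - lo) / h).astype(int) + 1
    origin = lo
    axes = [origin[d] + h * np.arange(shape[d]) for d in range(3)]

    def inside_solute(points: np.ndarray, extra: float = 0.0) -> np.ndarray:
        d = cdist(points, coords)
        return np.any(d < (radii + extra)[None, :], axis=1)

    if homogeneous:
        eps_faces = []
        for d in range(3):
            fshape = shape.copy()
            fshape[d] -= 1
            eps_faces.append(np.full(fshape, grid.eps_int))
        kappa_sq_h2 = np.zeros(tuple(shape - 2))
    else:
        eps_faces = []
        for d in range(3):
            face_axes = [a.copy() for a in axes]
            face_axes[d] = face_axes[d][:-1] + 0.5 * h
            gx, gy, gz = np.meshgrid(*face_axes, indexing="ij")
            pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
            eps = np.where(inside_solute(pts), grid.eps_int, grid.eps_solvent)
            eps_faces.append(eps.reshape(gx.shape))
        kappa = CONSTANTS.debye_kappa(
            grid.ionic_strength, grid.eps_solvent, grid.temperature
        )
        if kappa > 0:
            in_axes = [a[1:-1] for a in axes]
            gx, gy, gz = np.meshgrid(*in_axes, indexing="ij")
            pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
            salty = ~inside_solute(pts, extra=grid.ion_exclusion)
            kappa_sq_h2 = (
                salty.reshape(gx.shape) * grid.eps_solvent * kappa**2 * h**2
            )
        else:
            kappa_sq_h2 = np.zeros(tuple(shape - 2))

    # trilinear charge spreading to grid nodes
    q_grid = np.zeros(tuple(shape))
    frac = (coords - origin) / h
    base = np.floor(frac).astype(int)
    t = frac - base
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (t[:, 0] if dx else 1 - t[:, 0])
                    * (t[:, 1] if dy else 1 - t[:, 1])
                    * (t[:, 2] if dz else 1 - t[:, 2])
                )
                np.add.at(
                    q_grid, (base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz),
                    w * charges,
                )
    rhs = 4.0 * np.pi * CONSTANTS.coulomb_constant * q_grid[1:-1, 1:-1, 1:-1] / h

    phi = np.zeros(tuple(shape))
    if grid.boundary == "debye-huckel":
        Q = charges.sum()
        center = (
            np.average(coords, axis=0, weights=np.abs(charges) + 1e-12)
            if len(charges)
            else origin
        )
        eps_bc = grid.eps_int if homogeneous else grid.eps_solvent
        kap_bc = 0.0 if homogeneous else CONSTANTS.debye_kappa(
            grid.ionic_strength, grid.eps_solvent, grid.temperature
        )
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        boundary = np.zeros(tuple(shape), dtype=bool)
        boundary[0], boundary[-1] = True, True
        boundary[:, 0], boundary[:, -1] = True, True
        boundary[:, :, 0], boundary[:, :, -1] = True, True
        rb = np.sqrt(
            (gx[boundary] - center[0]) ** 2
            + (gy[boundary] - center[1]) ** 2
            + (gz[boundary] - center[2]) ** 2
        )
        phi[boundary] = (
            CONSTANTS.coulomb_constant * Q * np.exp(-kap_bc * rb) / (eps_bc * rb)
        )
    elif grid.boundary != "zero":
        raise ValueError(f"unknown boundary condition: {grid.boundary!r}")

    phi = _sor_solve(
        phi, tuple(eps_faces), kappa_sq_h2, rhs, grid.tol, grid.max_iterations
    )
    return phi, origin, h


def _trilinear_sample(
    phi: np.ndarray, origin: np.ndarray, h: float, points: np.ndarray
) -> np.ndarray:
    frac = (points - origin) / h
    base = np.floor(frac).astype(int)
    t = frac - base
    out = np.zeros(len(points))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (t[:, 0] if dx else 1 - t[:, 0])
                    * (t[:, 1] if dy else 1 - t[:, 1])
                    * (t[:, 2] if dz else 1 - t[:, 2])
                )
                out += w * phi[base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz]
    return out


def pb_polar_energy(
    coordinates: np.ndarray,
    charges: np.ndarray,
    radii: np.ndarray,
    grid: PBGrid | None = None,
) -> float:
    """Polar solvation (reaction-field) energy from the FD linearized PB
    equation, kcal/mol.

    Two solves on the same grid — the two-dielectric system and an all-ε_int
    homogeneous reference — are subtracted, so the grid Coulomb self-energy
    cancels: G = ½ Σ q_i (φ_het − φ_hom)(x_i).
    """
    grid = grid or PBGrid()
    coords = np.asarray(coordinates, dtype=np.float64)
    q = np.asarray(charges, dtype=np.float64)
    radii = np.asarray(radii, dtype=np.float64)
    if not np.any(q):
        return 0.0
    phi_het, origin, h = _grid_solve(coords, q, radii, grid, homogeneous=False)
    phi_hom, _, _ = _grid_solve(coords, q, radii, grid, homogeneous=True)
    dphi = _trilinear_sample(phi_het - phi_hom, origin, h, coords)
    return float(0.5 * np.sum(q * dphi))


# ---------------------------------------------------------------------------
# binding differences
# ---------------------------------------------------------------------------


@dataclass
class SolvationConfig:
    """Bundles the polar and nonpolar settings for binding calculations."""

    gb: GBConfig = field(default_factory=GBConfig)
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    surface_tension: float = SURFACE_TENSION
    nonpolar_offset: float = NONPOLAR_OFFSET
    polar_model: str = "gb"  # or "pb"
    pb_grid: PBGrid | None = None


def _species_solvation(
    view: SubsetView, topology: Topology, config: SolvationConfig
) -> tuple[float, float]:
    radii = topology.born_radii[view.indices]
    charges = topology.charges[view.indices]
    sasa = shrake_rupley_sasa(
        view.coordinates, radii, config.probe_radius, config.n_sphere_points
    ).sum()
    g_np = nonpolar_solvation(sasa, config.surface_tension, config.nonpolar_offset)
    if config.polar_model == "gb":
        eff = effective_born_radii(view.coordinates, radii, config.gb)
        g_pol = gb_polar_energy(view.coordinates, charges, eff, config.gb)
    elif config.polar_model == "pb":
        g_pol = pb_polar_energy(
            view.coordinates, charges, radii, config.pb_grid or PBGrid()
        )
    else:
        raise ValueError(f"unknown polar model: {config.polar_model!r}")
    return g_pol, g_np


def binding_solvation(
    complex_view: SubsetView,
    receptor_view: SubsetView,
    ligand_view: SubsetView,
    topology: Topology,
    config: SolvationConfig | None = None,
) -> tuple[float, float]:
    """ΔG_pol, ΔG_npol of binding = G(complex) − G(receptor) − G(ligand)."""
    config = config or SolvationConfig()
    gp_c, gn_c = _species_solvation(complex_view, topology, config)
    gp_r, gn_r = _species_solvation(receptor_view, topology, config)
    gp_l, gn_l = _species_solvation(ligand_view, topology, config)
    return gp_c - gp_r - gp_l, gn_c - gn_r - gn_l
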