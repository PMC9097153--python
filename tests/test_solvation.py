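import numpy as np
import pytest
from scipy.integrate import quad

from endstate import (
    CONSTANTS,
    GBConfig,
    PBGrid,
    Topology,
    binding_solvation,
    effective_born_radii,
    gb_polar_energy,
    nonpolar_solvation,
    pb_polar_energy,
    shrake_rupley_sasa,
    split_single_trajectory,
)
from endstate.model_core import AtomParam, Frame
from endstate.solvation import NONPOLAR_OFFSET, SolvationConfig, _hct_integral


def born_energy(q, radius, eps_solvent=78.5):
    return -0.5 * CONSTANTS.coulomb_constant * q**2 * (1 - 1 / eps_solvent) / radius


class TestNonpolar:
    def test_offset_at_zero_sasa(self):
        assert nonpolar_solvation(0.0) == pytest.approx(0.92, abs=1e-15)

    def test_linear_slope(self):
        assert nonpolar_solvation(1000.0) == pytest.approx(6.34, abs=1e-12)

    def test_negative_sasa_rejected(self):
        with pytest.raises(ValueError):
            nonpolar_solvation(-1.0)


class TestSASA:
    def test_isolated_sphere_closed_form(self):
        # atom radius 1.7 + probe 1.4: area 4*pi*3.1^2 within 1%
        area = shrake_rupley_sasa(np.zeros((1, 3)), np.array([1.7]))
        exact = 4 * np.pi * 3.1**2
        assert abs(area.sum() - exact) / exact < 0.01

    def test_distant_atoms_additive(self):
        coords = np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
        areas = shrake_rupley_sasa(coords, np.array([1.7, 2.0]))
        singles = [
            shrake_rupley_sasa(np.zeros((1, 3)), np.array([r])).sum()
            for r in (1.7, 2.0)
        ]
        assert areas.sum() == pytest.approx(sum(singles), abs=1e-9)

    def test_engulfed_atom_has_zero_area(self):
        coords = np.zeros((2, 3))
        coords[1, 0] = 0.1
        areas = shrake_rupley_sasa(coords, np.array([1.0, 8.0]))
        assert areas[0] == 0.0

    def test_cross_check_against_mdtraj(self):
        md = pytest.importorskip("mdtraj")
        # two carbons 4 Å apart; mdtraj uses 1.7 Å carbon radius internally
        coords = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        ours = shrake_rupley_sasa(coords, np.array([1.7, 1.7])).sum()
        top = md.Topology()
        chain = top.add_chain()
        res = top.add_residue("RES", chain)
        for i in range(2):
            top.add_atom(f"C{i}", md.element.carbon, res)
        traj = md.Trajectory(xyz=coords[None] / 10.0, topology=top)
        ref = md.shrake_rupley(traj, probe_radius=0.14, n_sphere_points=960)
        ref_total = ref.sum() * 100.0  # nm² -> Å²
        assert ours == pytest.approx(ref_total, rel=0.02)


class TestEffectiveBornRadii:
    def test_isolated_atom_keeps_intrinsic_radius(self):
        r = effective_born_radii(np.zeros((1, 3)), np.array([1.7]))
        assert r[0] == 1.7

    def test_intrinsic_scheme_is_identity(self, rng):
        coords = rng.normal(scale=3.0, size=(5, 3))
        rho = np.full(5, 1.6)
        r = effective_born_radii(coords, rho, GBConfig(radii_scheme="intrinsic"))
        np.testing.assert_array_equal(r, rho)

    def test_hct_integral_matches_numeric_quadrature(self):
        # oracle: I = ∫ f(x)/x² dx with f the shell fraction inside the
        # descreening sphere
        def numeric(r, rho_i, s):
            def frac(x):
                if x <= s - r:
                    return 1.0
                if x >= s + r:
                    return 0.0
                c = (x**2 + r**2 - s**2) / (2 * x * r)
                return (1 - np.clip(c, -1, 1)) / 2

            val, _ = quad(lambda x: frac(x) / x**2, rho_i, r + s, limit=200)
            return val

        for r, rho_i, s in [(4.0, 1.7, 1.4), (2.5, 1.5, 1.4), (1.0, 1.2, 1.8)]:
            ours = _hct_integral(
                np.array([r]), np.array([rho_i]), np.array([s])
            )[0]
            assert ours == pytest.approx(numeric(r, rho_i, s), abs=1e-7)

    def test_approach_monotonically_grows_radius(self):
        rho = np.array([1.7, 1.7])
        prev = 1.7
        for sep in (50.0, 20.0, 10.0, 5.0, 3.5, 2.5):
            coords = np.array([[0.0, 0.0, 0.0], [sep, 0.0, 0.0]])
            r = effective_born_radii(coords, rho)[0]
            assert r >= prev - 1e-12
            prev = r

    def test_buried_atom_exceeds_intrinsic(self):
        # central atom caged by 6 octahedral neighbors
        cage = 3.0 * np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=float,
        )
        coords = np.vstack([[0.0, 0.0, 0.0], cage])
        r = effective_born_radii(coords, np.full(7, 1.7))
        assert r[0] > 1.7


class TestGBPolar:
    def test_single_ion_equals_born_formula(self):
        a = 3.320637
        e = gb_polar_energy(
            np.zeros((1, 3)), np.array([1.0]), np.array([a]),
            GBConfig(ionic_strength=0.0),
        )
        assert e == pytest.approx(born_energy(1.0, a), abs=1e-9)

    def test_zero_charges(self, rng):
        coords = rng.normal(scale=3.0, size=(4, 3))
        e = gb_polar_energy(coords, np.zeros(4), np.full(4, 1.7))
        assert e == 0.0

    def test_salt_free_limit_continuous(self, rng):
        coords = rng.normal(scale=3.0, size=(4, 3))
        q = rng.uniform(-0.5, 0.5, size=4)
        R = np.full(4, 1.7)
        e0 = gb_polar_energy(coords, q, R, GBConfig(ionic_strength=0.0))
        e_tiny = gb_polar_energy(coords, q, R, GBConfig(ionic_strength=1e-12))
        assert e_tiny == pytest.approx(e0, abs=1e-8)

    def test_salt_screens_solvation(self):
        a = 2.0
        e0 = gb_polar_energy(
            np.zeros((1, 3)), np.array([1.0]), np.array([a]),
            GBConfig(ionic_strength=0.0),
        )
        e_salt = gb_polar_energy(
            np.zeros((1, 3)), np.array([1.0]), np.array([a]),
            GBConfig(ionic_strength=0.150),
        )
        assert e_salt < e0  # more negative: ions stabilize the ion


class TestPBPolar:
    def test_born_ion_error_decreases_with_refinement(self):
        coords = np.zeros((1, 3))
        q = np.array([1.0])
        radii = np.array([2.0])
        exact = born_energy(1.0, 2.0)
        errs = []
        for h in (0.8, 0.5):
            e = pb_polar_energy(coords, q, radii, PBGrid(spacing=h, padding=8.0))
            errs.append(abs(e - exact) / abs(exact))
        assert errs[1] < errs[0]
        assert errs[1] < 0.10

    def test_zero_charges_short_circuit(self):
        e = pb_polar_energy(np.zeros((1, 3)), np.array([0.0]), np.array([2.0]))
        assert e == 0.0

    def test_homogeneous_dielectric_gives_zero_reaction_field(self):
        grid = PBGrid(spacing=0.8, padding=6.0, eps_int=78.5, eps_solvent=78.5,
                      ionic_strength=0.0)
        e = pb_polar_energy(np.zeros((1, 3)), np.array([1.0]), np.array([2.0]), grid)
        assert e == pytest.approx(0.0, abs=1e-9)


def _two_group_topology(rec_xyz, lig_xyz, rec_q, lig_q):
    atoms = []
    coords = []
    for i, (xyz, q) in enumerate(
        [(x, q) for x, q in zip(rec_xyz, rec_q)]
        + [(x, q) for x, q in zip(lig_xyz, lig_q)]
    ):
        atoms.append(
            AtomParam(
                name="C1", element="C", charge=float(q), lj_rmin_half=1.9,
                lj_epsilon=0.12, born_radius=1.7, mass=12.0,
                residue_index=i, residue_name="RES",
            )
        )
        coords.append(xyz)
    n_rec = len(rec_xyz)
    topo = Topology(
        atoms, list(range(n_rec)), list(range(n_rec, len(atoms))), []
    )
    return topo, Frame(coordinates=np.array(coords, dtype=float))


class TestBindingSolvation:
    def test_disjoint_union_offsets(self):
        # parts 500 Å apart: ΔG_pol ~ 0 and ΔG_npol = b - 2b = -b
        rec = [[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]]
        lig = [[500.0, 0.0, 0.0], [503.0, 0.0, 0.0]]
        topo, frame = _two_group_topology(rec, lig, [0.3, -0.3], [0.3, -0.3])
        views = split_single_trajectory(frame, topo)
        cfg = SolvationConfig(gb=GBConfig(ionic_strength=0.0))
        dg_pol, dg_npol = binding_solvation(*views, topo, cfg)
        assert dg_pol == pytest.approx(0.0, abs=1e-2)
        assert dg_npol == pytest.approx(-NONPOLAR_OFFSET, abs=1e-9)

    def test_desolvation_penalty_for_buried_charge(self):
        # neutral ligand cage buries the receptor ion -> ΔG_pol > 0
        cage = (3.0 * np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1],
             [0, 0, -1]], dtype=float,
        )).tolist()
        topo, frame = _two_group_topology(
            [[0.0, 0.0, 0.0]], cage, [1.0], [0.0] * 6
        )
        views = split_single_trajectory(frame, topo)
        dg_pol, _ = binding_solvation(*views, topo, SolvationConfig())
        assert dg_pol > 0.0

    def test_bound_pose_buries_surface(self, toy):
        topo, frame = toy
        cpx, rec, lig = split_single_trajectory(frame, topo)
        radii = topo.born_radii
        sasa_c = shrake_rupley_sasa(cpx.coordinates, radii[cpx.indices]).sum()
        sasa_r = shrake_rupley_sasa(rec.coordinates, radii[rec.indices]).sum()
        sasa_l = shrake_rupley_sasa(lig.coordinates, radii[lig.indices]).sum()
        assert sasa_c <= sasa_r + sasa_l + 1e-9
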