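import numpy as np
import pytest

from endstate import (
    CONSTANTS,
    InteractionEnergySeries,
    NMAConfig,
    ToySpec,
    build_truncated_system,
    flexible_hessian,
    harmonic_entropy,
    interaction_entropy,
    make_energy_series,
    make_ensemble,
    make_toy_complex,
    minimize_flexible,
    trunc_nma_correction,
)
from endstate.entropy import (
    EIGENVALUE_TO_OMEGA_SQ,
    HBAR,
    KB_SI,
    NotAMinimumError,
    species_entropy,
)
from endstate.synthetic_fixtures import (
    HarmonicBond,
    HarmonicNetworkEnergy,
    harmonic_bonds_for,
    truncated_energy_factory,
)


class TestInteractionEntropy:
    def test_constant_series_gives_zero(self):
        est = interaction_entropy(
            InteractionEnergySeries(values=np.full(100, -35.0))
        )
        assert est.minus_T_delta_S == 0.0

    def test_gaussian_limit(self):
        # i.i.d. Gaussian sd σ: -TΔS -> βσ²/2 = 3.377 kcal/mol for σ=2, 298 K
        sigma, n = 2.0, 100_000
        series = make_energy_series(-40.0, sigma, n, seed=11)
        est = interaction_entropy(series)
        beta = CONSTANTS.beta(298.0)
        expected = beta * sigma**2 / 2
        # rough MC standard error of the exponential-average estimator
        se = expected * np.sqrt(2.0 / n) * 3
        assert abs(est.minus_T_delta_S - expected) < max(3 * se, 0.35)

    def test_non_negative_on_random_series(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            vals = rng.normal(rng.uniform(-50, 0), rng.uniform(0.01, 3.0), 50)
            est = interaction_entropy(InteractionEnergySeries(values=vals))
            assert est.minus_T_delta_S >= 0.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            interaction_entropy(InteractionEnergySeries(values=np.array([1.0])))

    def test_nonfinite_series_rejected(self):
        with pytest.raises(ValueError):
            InteractionEnergySeries(values=np.array([1.0, np.inf]))


class TestTruncation:
    def test_distant_residue_dropped_and_capped(self):
        # receptor chain long enough that its far end leaves the keep shell
        topo, frame = make_toy_complex(
            ToySpec(n_receptor_residues=8, n_ligand_residues=1,
                    atoms_per_residue=1, residue_spacing=4.0)
        )
        cfg = NMAConfig(r_keep=10.0, r_freeze_inner=5.0)
        systems = build_truncated_system(frame, topo, cfg)
        rec_sys = systems["receptor"]
        # ligand sits at x=0..; far receptor residues beyond 10 Å dropped
        assert rec_sys.kept_indices.size < topo.receptor_mask.size
        assert len(rec_sys.caps) == 1
        assert rec_sys.caps[0].kind == "amide"

    def test_no_buffer_warns(self):
        topo, frame = make_toy_complex(ToySpec())
        with pytest.warns(UserWarning, match="frozen buffer"):
            build_truncated_system(frame, topo, NMAConfig(r_keep=50.0,
                                                          r_freeze_inner=40.0))

    def test_water_shortage_warns_and_keeps_all(self):
        topo, frame = make_toy_complex(ToySpec(n_waters=3))
        with pytest.warns(UserWarning, match="shell waters"):
            systems = build_truncated_system(
                frame, topo,
                NMAConfig(r_keep=50.0, r_freeze_inner=40.0,
                          n_waters_complex=1000, n_waters_free=500),
            )
        n_water_atoms = topo.water_mask.size
        kept_waters = np.intersect1d(
            systems["complex"].kept_indices, topo.water_mask
        )
        assert kept_waters.size == n_water_atoms

    def test_invalid_shells_rejected(self):
        with pytest.raises(ValueError):
            NMAConfig(r_keep=12.0, r_freeze_inner=16.0)

    def test_caps_are_frozen(self):
        topo, frame = make_toy_complex(
            ToySpec(n_receptor_residues=8, n_ligand_residues=1,
                    atoms_per_residue=1)
        )
        systems = build_truncated_system(
            frame, topo, NMAConfig(r_keep=10.0, r_freeze_inner=5.0)
        )
        for sys in systems.values():
            n_kept = sys.kept_indices.size
            assert not sys.flexible_mask[n_kept:].any()


class TestMinimizer:
    def test_single_atom_converges_to_well_center(self):
        center = np.array([[1.0, -2.0, 3.0]])
        # three orthogonal anchor springs pull the atom to the center
        bonds = [HarmonicBond(0, 1, 50.0, 1.0), HarmonicBond(0, 2, 50.0, 1.0),
                 HarmonicBond(0, 3, 50.0, 1.0)]
        coords = np.vstack([
            center[0] + np.array([0.4, 0.1, -0.2]),
            center[0] + [1.0, 0.0, 0.0],
            center[0] + [0.0, 1.0, 0.0],
            center[0] + [0.0, 0.0, 1.0],
        ])
        energy = HarmonicNetworkEnergy(bonds=bonds, n_atoms=4)
        out = minimize_flexible(coords, np.array([0]), energy, 1e-8)
        _, g = energy.value_and_grad(out)
        assert np.sqrt((g[0] ** 2).mean()) <= 1e-8

    def test_frozen_atoms_bit_identical(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(5, 3)) * 2.0
        bonds = [HarmonicBond(i, j, 10.0, 1.5)
                 for i in range(5) for j in range(i + 1, 5)]
        energy = HarmonicNetworkEnergy(bonds=bonds, n_atoms=5)
        frozen_before = coords[2:].copy()
        out = minimize_flexible(coords, np.array([0, 1]), energy, 1e-6)
        assert np.array_equal(out[2:], frozen_before)

    def test_already_minimal_returns_input(self):
        coords = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]])
        energy = HarmonicNetworkEnergy(
            bonds=[HarmonicBond(0, 1, 10.0, 1.5)], n_atoms=2
        )
        out = minimize_flexible(coords, np.array([0]), energy, 1e-6)
        np.testing.assert_array_equal(out, coords)


class TestHessian:
    def _isotropic_system(self, k=37.0, mass=14.0):
        # flexible atom tethered along x,y,z to frozen anchors at r0
        bonds = [HarmonicBond(0, 1, k / 2, 1.0), HarmonicBond(0, 2, k / 2, 1.0),
                 HarmonicBond(0, 3, k / 2, 1.0)]
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                           [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        energy = HarmonicNetworkEnergy(bonds=bonds, n_atoms=4)
        masses = np.array([mass, 1.0, 1.0, 1.0])
        return coords, energy, masses

    def test_isotropic_well_closed_form(self):
        # E = Σ (k/2)(r_i - r0)²: at the minimum the longitudinal stiffness
        # per bond is k, so the x,y,z eigenvalues are k/m each... plus the
        # transverse terms vanish at r=r0, leaving (k/m)·I₃
        k, m = 37.0, 14.0
        coords, energy, masses = self._isotropic_system(k, m)
        H = flexible_hessian(coords, np.array([0]), energy, masses)
        lam = np.linalg.eigvalsh(H)
        np.testing.assert_allclose(lam, k / m, rtol=1e-4)

    def test_symmetrization_residual_small(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(4, 3)) * 2.0
        bonds = [HarmonicBond(i, j, 10.0, 1.0)
                 for i in range(4) for j in range(i + 1, 4)]
        energy = HarmonicNetworkEnergy(bonds=bonds, n_atoms=4)
        flex = np.array([0, 1])
        masses = np.ones(4)
        # raw asymmetry of the finite-difference Hessian
        nf = 2
        H = np.empty((3 * nf, 3 * nf))
        for a in range(nf):
            for d in range(3):
                cp = coords.copy(); cp[flex[a], d] += 1e-4
                cm = coords.copy(); cm[flex[a], d] -= 1e-4
                gp = energy.value_and_grad(cp)[1]
                gm = energy.value_and_grad(cm)[1]
                H[3 * a + d] = ((gp - gm)[flex] / 2e-4).ravel()
        asym = np.linalg.norm(H - H.T) / np.linalg.norm(H)
        assert asym < 1e-4

    def test_mass_doubling_halves_eigenvalues(self):
        coords, energy, masses = self._isotropic_system()
        H1 = flexible_hessian(coords, np.array([0]), energy, masses)
        H2 = flexible_hessian(coords, np.array([0]), energy, masses * 2)
        np.testing.assert_allclose(
            np.linalg.eigvalsh(H2), np.linalg.eigvalsh(H1) / 2, rtol=1e-10
        )


class TestHarmonicEntropy:
    @staticmethod
    def eigenvalue_for_x(x, temperature=298.0):
        """Mass-weighted eigenvalue whose mode has ħω/kT = x."""
        omega = x * KB_SI * temperature / HBAR
        return omega**2 / EIGENVALUE_TO_OMEGA_SQ

    def test_single_mode_closed_form(self):
        # at ħω/kT = 1: S/R = 1/(e−1) − ln(1−e⁻¹) ≈ 1.04066
        lam = self.eigenvalue_for_x(1.0)
        out = harmonic_entropy(np.array([lam]), 298.0)
        s_over_r = out.S / CONSTANTS.k_boltzmann
        expected = 1 / (np.e - 1) - np.log(1 - np.exp(-1))
        assert s_over_r == pytest.approx(expected, abs=1e-4)
        assert s_over_r == pytest.approx(1.04066, abs=1e-4)

    def test_stiff_mode_entropy_vanishes(self):
        lam = self.eigenvalue_for_x(60.0)
        assert harmonic_entropy(np.array([lam])).S == pytest.approx(0.0, abs=1e-12)

    def test_entropy_monotone_in_frequency(self):
        xs = np.array([0.2, 0.5, 1.0, 3.0, 8.0])
        s = [harmonic_entropy(np.array([self.eigenvalue_for_x(x)])).S for x in xs]
        assert all(a > b for a, b in zip(s, s[1:]))

    def test_negative_eigenvalue_rejected(self):
        with pytest.raises(NotAMinimumError):
            harmonic_entropy(np.array([-1.0]))

    def test_near_zero_modes_discarded(self):
        lam = self.eigenvalue_for_x(1.0)
        out = harmonic_entropy(np.array([0.0, lam]))
        assert out.n_discarded == 1
        assert out.n_modes_used == 1


class TestTruncNMA:
    def test_fully_frozen_complex_gives_zero(self):
        topo, frame = make_toy_complex(ToySpec())
        ens = make_ensemble(topo, frame, n_replicas=1, n_frames=3,
                            jitter_sd=0.0, seed=0)
        bonds = harmonic_bonds_for(topo, frame)
        # r_freeze_inner=0: every kept residue lands in the frozen shell
        cfg = NMAConfig(r_keep=100.0, r_freeze_inner=0.0,
                        frame_stride_ps=1000.0)
        est = trunc_nma_correction(ens, truncated_energy_factory(bonds), cfg)
        assert est.minus_T_delta_S == 0.0

    def test_paper_frame_schedule_count(self):
        # 25 replicas × last 3 ns at 100 ps -> 750 frames
        topo, frame = make_toy_complex(
            ToySpec(n_receptor_residues=1, n_ligand_residues=1,
                    atoms_per_residue=1)
        )
        ens = make_ensemble(topo, frame, n_replicas=25, n_frames=300,
                            jitter_sd=0.0, seed=0)
        bonds = harmonic_bonds_for(topo, frame)
        cfg = NMAConfig(r_keep=100.0, r_freeze_inner=0.0,
                        frame_stride_ps=100.0)
        est = trunc_nma_correction(ens, truncated_energy_factory(bonds), cfg)
        assert est.n_frames_used == 750

    def test_interface_stiffening_costs_entropy(self):
        # complex carries an extra interface spring -> fewer soft modes ->
        # -TΔS > 0
        topo, frame = make_toy_complex(
            ToySpec(n_receptor_residues=2, n_ligand_residues=2,
                    atoms_per_residue=1, charge_scheme="zero")
        )
        ens = make_ensemble(topo, frame, n_replicas=1, n_frames=2,
                            jitter_sd=0.0, seed=0)
        chain_bonds = harmonic_bonds_for(topo, frame, k=30.0)
        rec0 = int(topo.receptor_mask[0])
        lig0 = int(topo.ligand_mask[0])
        r0 = float(np.linalg.norm(frame.coordinates[rec0]
                                  - frame.coordinates[lig0]))
        interface = HarmonicBond(rec0, lig0, 60.0, r0)
        # anchors so each species has a positive-definite flexible Hessian
        def factory(system):
            local = {int(p): i for i, p in enumerate(system.kept_indices)}
            bonds = [HarmonicBond(local[b.i], local[b.j], b.k, b.r0)
                     for b in chain_bonds if b.i in local and b.j in local]
            if system.species == "complex" and rec0 in local and lig0 in local:
                bonds.append(HarmonicBond(local[rec0], local[lig0],
                                          interface.k, interface.r0))
            # isotropic tethers keep every flexible atom bound
            n = system.n_atoms
            energy = HarmonicNetworkEnergy(bonds=bonds, n_atoms=n)
            tether_k = 5.0
            ref = system.coordinates_from_frame(frame)

            class Tethered:
                def value_and_grad(self, coords):
                    e, g = energy.value_and_grad(coords)
                    d = coords - ref
                    e += tether_k * np.sum(d * d)
                    g = g + 2 * tether_k * d
                    return e, g

            return Tethered()

        with pytest.warns(UserWarning, match="frozen buffer"):
            cfg = NMAConfig(r_keep=100.0, r_freeze_inner=99.0,
                            frame_stride_ps=1500.0)
            est = trunc_nma_correction(ens, factory, cfg)
        assert est.minus_T_delta_S > 0.0
        assert est.method == "trunc_nma"

    def test_frozen_atoms_have_no_direct_entropy_impact(self):
        # adding extra fully-frozen atoms must not change species entropy
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                           [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        bonds = [HarmonicBond(0, 1, 25.0, 1.0), HarmonicBond(0, 2, 25.0, 1.0),
                 HarmonicBond(0, 3, 25.0, 1.0)]
        energy = HarmonicNetworkEnergy(bonds=bonds, n_atoms=4)
        masses = np.full(4, 12.0)
        H = flexible_hessian(coords, np.array([0]), energy, masses)
        s_small = harmonic_entropy(np.linalg.eigvalsh(H)).S
        # same system plus two inert frozen atoms
        coords2 = np.vstack([coords, [[5.0, 5.0, 5.0], [6.0, 5.0, 5.0]]])
        energy2 = HarmonicNetworkEnergy(bonds=bonds, n_atoms=6)
        H2 = flexible_hessian(coords2, np.array([0]), energy2,
                              np.full(6, 12.0))
        s_big = harmonic_entropy(np.linalg.eigvalsh(H2)).S
        assert s_big == pytest.approx(s_small, abs=1e-12)
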