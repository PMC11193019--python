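"""Unit tests of the region maps, LPB solve, energies and valences.

Fast checks run here; the full-resolution analytic benchmark suite
(screened Coulomb at 97^3, capacitor profile, translocation valence)
lives in the acceptance tests.
"""

import numpy as np
import pytest

from presteady.constants import COULOMB_KCAL_A
from presteady.membrane_pb import (
    Grid3D,
    MembraneSlab,
    SolverSettings,
    build_region_maps,
    compute_valence,
    electrostatic_energy,
    membrane_voltage_profile,
    solve_lpb,
    write_dx,
)
from presteady.model_io import AtomicModel, AtomRecord, StatePair


def single_atom(z=0.0, charge=1.0, radius=2.0):
    return AtomicModel(atoms=(
        AtomRecord(name="Q", residue="ION", chain="A",
                   position=(0.0, 0.0, z), charge=charge, radius=radius),
    ))


EMPTY = AtomicModel(atoms=())


class TestRegionMaps:
    def test_no_protein_limit(self):
        grid = Grid3D.centered((0, 0, 0), 2.0, (17, 17, 33))
        slab = MembraneSlab(-15.0, 15.0)
        st = SolverSettings()
        maps = build_region_maps(EMPTY, slab, grid, st)
        z = grid.axes()[2]
        in_slab = (z >= -15) & (z <= 15)
        assert np.all(maps.epsilon[:, :, in_slab] == st.eps_membrane)
        assert np.all(maps.epsilon[:, :, ~in_slab] == st.eps_solvent)
        # ions excluded from the membrane, present in both baths
        assert np.all(maps.kappa2[:, :, in_slab] == 0.0)
        assert np.all(maps.kappa2[:, :, ~in_slab] > 0.0)
        # f = 1 exactly in the lower (intracellular) bath
        assert np.all(maps.f_intracellular[:, :, z < -15] == 1.0)
        assert np.all(maps.f_intracellular[:, :, z > -15] == 0.0)

    def test_single_atom_dielectric(self):
        grid = Grid3D.centered((0, 0, 0), 1.0, (41, 41, 65))
        st = SolverSettings(solvent_probe_A=0.0, enforce_padding=False)
        maps = build_region_maps(single_atom(radius=2.0), MembraneSlab(-15, 15),
                                 grid, st)
        assert maps.epsilon[20, 20, 32] == st.eps_protein  # at the atom centre
        assert maps.epsilon[20, 20, 2] == st.eps_solvent

    def test_f_respects_connectivity(self):
        grid = Grid3D.centered((0, 0, 0), 2.0, (17, 17, 33))
        maps = build_region_maps(EMPTY, MembraneSlab(-10, 10), grid, SolverSettings())
        assert np.any(maps.f_intracellular > 0)
        assert np.all((maps.f_intracellular == 0) | (maps.kappa2 > 0))

    def test_padding_precondition(self):
        grid = Grid3D.centered((0, 0, 0), 1.0, (15, 15, 15))
        with pytest.raises(ValueError, match="padding"):
            build_region_maps(single_atom(), MembraneSlab(-5, 5), grid,
                              SolverSettings())

    def test_slab_outside_grid(self):
        grid = Grid3D.centered((0, 0, 0), 1.0, (15, 15, 15))
        with pytest.raises(ValueError, match="slab"):
            build_region_maps(EMPTY, MembraneSlab(-50, 50), grid, SolverSettings())


class TestSolve:
    def test_zero_charge_zero_voltage_gives_zero_field(self):
        grid = Grid3D.centered((0, 0, 0), 2.0, (17, 17, 17))
        st = SolverSettings()
        maps = build_region_maps(EMPTY, None, grid, st)
        sol = solve_lpb(maps, EMPTY, st)
        assert sol.converged
        assert np.max(np.abs(sol.phi)) < 1e-10

    def test_voltage_requires_slab(self):
        grid = Grid3D.centered((0, 0, 0), 2.0, (17, 17, 17))
        st = SolverSettings(membrane_potential_mV=-100.0)
        maps = build_region_maps(EMPTY, None, grid, st)
        with pytest.raises(ValueError, match="slab"):
            solve_lpb(maps, EMPTY, st)

    def test_superposition_of_charge_and_voltage_sources(self):
        """phi(rho, V) = phi(rho, 0) + phi(0, V): the PDE is linear."""
        grid = Grid3D.centered((0, 0, 0), 2.0, (25, 25, 33))
        slab = MembraneSlab(-12, 12)
        model = single_atom(z=-22.0, charge=1.0)
        kw = dict(enforce_padding=False)
        maps = build_region_maps(model, slab, grid, SolverSettings(**kw))
        sol_both = solve_lpb(maps, model, SolverSettings(membrane_potential_mV=-80.0, **kw))
        sol_rho = solve_lpb(maps, model, SolverSettings(**kw))
        sol_v = solve_lpb(maps, EMPTY, SolverSettings(membrane_potential_mV=-80.0, **kw))
        scale = np.abs(sol_both.phi).max()
        assert np.allclose(sol_both.phi, sol_rho.phi + sol_v.phi,
                           atol=1e-4 * scale)

    def test_energy_linear_in_voltage(self):
        grid = Grid3D.centered((0, 0, 0), 2.0, (25, 25, 33))
        slab = MembraneSlab(-12, 12)
        model = single_atom(z=-22.0)
        energies = []
        for v in (-100.0, -50.0, 50.0, 100.0):
            st = SolverSettings(membrane_potential_mV=v, enforce_padding=False)
            maps = build_region_maps(EMPTY, slab, grid, st)
            sol = solve_lpb(maps, EMPTY, st)
            energies.append(electrostatic_energy(sol, model))
        e = np.asarray(energies)
        assert e[0] == pytest.approx(2 * e[1], rel=1e-3)
        assert e[3] == pytest.approx(2 * e[2], rel=1e-3)
        assert e[0] == pytest.approx(-e[3], rel=1e-3)


class TestEnergy:
    def test_zero_charge_model_zero_energy(self):
        grid = Grid3D.centered((0, 0, 0), 2.0, (17, 17, 17))
        st = SolverSettings()
        maps = build_region_maps(EMPTY, None, grid, st)
        sol = solve_lpb(maps, EMPTY, st)
        assert electrostatic_energy(sol, single_atom(charge=0.0)) == 0.0

    def test_two_charge_coulomb_difference(self):
        """Charge-potential sum reproduces Coulomb's law in energy differences.

        +1/-1 e at 10 A in uniform eps 80 without salt, versus the same
        pair far apart: the double-counted interaction energy
        2 * (-332.0636 / (80 d)) changes by the analytic amount; grid
        self-energies cancel because every charge sits on a node.
        """
        st = SolverSettings(eps_protein=80.0, eps_membrane=80.0,
                            ionic_strength_M=0.0, stern_layer_A=0.0,
                            solvent_probe_A=0.0, enforce_padding=False)
        grid = Grid3D.centered((0, 0, 0), 1.0, (61, 61, 61))

        def pair_model(z1, z2):
            return AtomicModel(atoms=(
                AtomRecord("P", "ION", "A", (0.0, 0.0, z1), 1.0, 0.0),
                AtomRecord("M", "ION", "A", (0.0, 0.0, z2), -1.0, 0.0),
            ))

        def energy(model):
            maps = build_region_maps(model, None, grid, st)
            return electrostatic_energy(solve_lpb(maps, model, st), model)

        d_near, d_far = 10.0, 40.0
        delta = energy(pair_model(-5.0, 5.0)) - energy(pair_model(-20.0, 20.0))
        expected = 2 * (-COULOMB_KCAL_A / (80.0 * d_near)) - 2 * (
            -COULOMB_KCAL_A / (80.0 * d_far))
        assert delta == pytest.approx(expected, rel=0.05)

    def test_atom_outside_grid_interior_errors(self):
        grid = Grid3D.centered((0, 0, 0), 2.0, (17, 17, 17))
        st = SolverSettings()
        maps = build_region_maps(EMPTY, None, grid, st)
        sol = solve_lpb(maps, EMPTY, st)
        with pytest.raises(ValueError, match="grid"):
            electrostatic_energy(sol, single_atom(z=100.0))


class TestValence:
    def test_identical_states_zero_valence(self):
        model = single_atom(z=-25.0)
        pair = StatePair(state_bound=model, state_free=model)
        grid = Grid3D.centered((0, 0, 0), 2.0, (25, 25, 41))
        res = compute_valence(pair, MembraneSlab(-12, 12), grid,
                              SolverSettings(enforce_padding=False),
                              [-100, 0, 100])
        assert res.valence == pytest.approx(0.0, abs=1e-12)

    def test_voltages_must_span_zero(self):
        model = single_atom(z=-25.0)
        pair = StatePair(state_bound=model, state_free=model)
        grid = Grid3D.centered((0, 0, 0), 2.0, (25, 25, 41))
        with pytest.raises(ValueError, match="span zero"):
            compute_valence(pair, MembraneSlab(-12, 12), grid,
                            SolverSettings(enforce_padding=False), [10, 50, 100])

    def test_zwitterion_sign_ordering_and_additivity(self):
        """Buried carboxylate vs shallow amino: component valences.

        A net-neutral two-charge ligand whose negative charge sits deeper
        in the membrane field than its positive charge must show
        z(carboxy-only) < z(full) < 0 < z(amino-only),
        |z(amino)| < |z(carboxy)|, and (by superposition)
        z(full) = z(carboxy) + z(amino) up to discretization error.
        """
        st = SolverSettings(enforce_padding=False)
        grid = Grid3D.centered((0, 0, 0), 2.0, (25, 25, 49))
        slab = MembraneSlab(-15.0, 15.0)
        volts = [-100.0, 0.0, 100.0]

        def lig(q_carboxy, q_amino):
            return AtomicModel(atoms=(
                AtomRecord("OXT", "LIG", "B", (0.0, 0.0, -6.0), q_carboxy, 1.4),
                AtomRecord("N", "LIG", "B", (0.0, 0.0, 2.0), q_amino, 1.5),
            ))

        def valence(q_c, q_a):
            pair = StatePair(state_bound=lig(q_c, q_a),
                             state_free=AtomicModel(atoms=()))
            return compute_valence(pair, slab, grid, st, volts).valence

        z_full = valence(-1.0, 1.0)
        z_carboxy = valence(-1.0, 0.0)
        z_amino = valence(0.0, 1.0)
        assert z_carboxy < z_full < 0.0 < z_amino
        assert abs(z_amino) < abs(z_carboxy)
        assert z_full == pytest.approx(z_carboxy + z_amino, abs=0.01)


def test_membrane_voltage_profile_limits():
    st = SolverSettings()
    slab = MembraneSlab(-15.0, 15.0)
    z = np.array([-80.0, -15.0, 0.0, 15.0, 80.0])
    g = membrane_voltage_profile(z, slab, st)
    assert g[0] == pytest.approx(1.0, abs=1e-4)   # deep intracellular
    assert g[-1] == pytest.approx(0.0, abs=1e-4)  # deep extracellular
    assert g[1] > g[2] > g[3]                     # monotone across the slab
    mid = 0.5 * (g[1] + g[3])
    assert g[2] == pytest.approx(mid, rel=1e-9)   # linear inside the slab


def test_write_dx_roundtrippable_header(tmp_path):
    grid = Grid3D.centered((0, 0, 0), 1.0, (9, 9, 9))
    field = np.arange(9**3, dtype=float).reshape(9, 9, 9)
    path = tmp_path / "phi.dx"
    write_dx(field, grid, path, comment="potential")
    text = path.read_text()
    assert "gridpositions counts 9 9 9" in text
    assert "items 729" in text
    vals = []
    for line in text.splitlines():
        parts = line.split()
        if parts and all(p.replace("e", "").replace("-", "").replace("+", "")
                         .replace(".", "").isdigit() for p in parts):
            vals.extend(float(p) for p in parts)
    assert vals[:4] == [0.0, 1.0, 2.0, 3.0]
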