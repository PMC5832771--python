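"""Constraint networks, body-bar pebble game, dilution, ligand ΔG."""

import math
import random

import numpy as np
import pytest

import peptisite as ps
from peptisite.rigidity import (BodyBarPebbleGame, Constraint,
                                ConstraintNetwork, NetworkParams,
                                dilution_stability, hbond_energy,
                                perturb_remove_ligand)
from peptisite.structures import Atom, Topology

from oracles import random_body_bar_network, rigidity_matrix_analysis


class TestHbondEnergy:
    def test_minimum_at_ideal_linear_geometry(self):
        d, h, a = np.zeros(3), np.array([1.0, 0, 0]), np.array([2.8, 0, 0])
        assert np.isclose(hbond_energy(d, h, a), -8.0, atol=1e-12)

    def test_perpendicular_geometry_scores_zero(self):
        d, h = np.zeros(3), np.array([1.0, 0, 0])
        a = h + np.array([0.0, 2.0, 0.0])   # 90° at the hydrogen
        assert np.isclose(hbond_energy(d, h, a), 0.0, atol=1e-12)

    def test_sub_perpendicular_geometry_is_excluded(self):
        d, h = np.zeros(3), np.array([1.0, 0, 0])
        a = h + np.array([-0.5, 1.0, 0.0])  # acceptor on the donor side: < 90°
        assert hbond_energy(d, h, a) == float("inf")

    def test_oblique_geometry_matches_formula_evaluation(self):
        # D at origin, H on x, A placed so that |D-A| = 3.2 and the
        # D-H...A angle is exactly 160°
        d = np.zeros(3)
        h = np.array([1.0, 0.0, 0.0])
        w = np.array([-math.cos(math.radians(160.0)),
                      math.sin(math.radians(160.0)), 0.0])
        t = (-1.8794 + math.sqrt(1.8794 ** 2 + 4 * 9.24)) / 2.0
        a = h + t * w
        assert np.isclose(np.linalg.norm(a - d), 3.2, atol=1e-3)
        x = 2.8 / np.linalg.norm(a - d)
        expected = 8.0 * (5 * x ** 12 - 6 * x ** 10) * \
            math.cos(math.radians(160.0)) ** 2
        assert np.isclose(hbond_energy(d, h, a), expected, atol=1e-6)

    def test_coincident_atoms_rejected(self):
        with pytest.raises(ValueError):
            hbond_energy(np.zeros(3), np.zeros(3), np.ones(3))


def _carbon_pair_topology(elements, names, distance):
    atoms = [
        Atom(1, names[0], elements[0], "A", "LEU", 1, np.zeros(3),
             12.0, False),
        Atom(2, names[1], elements[1], "A", "LEU", 2,
             np.array([distance, 0.0, 0.0]), 12.0, False),
    ]
    return Topology(atoms, [], ligand_chain="P")


class TestBuildNetwork:
    def test_carbon_pair_inside_vdw_plus_dcut_gets_tether(self):
        # 1.7 + 1.7 + 0.25 = 3.65 >= 3.55: tether present
        topo = _carbon_pair_topology(("C", "C"), ("CG", "CG"), 3.55)
        net = ps.build_network(np.array([a.coords for a in topo.atoms]), topo)
        assert net.count("hydrophobic") == 1

    def test_carbon_sulfur_pair_beyond_cutoff_gets_no_tether(self):
        # 1.7 + 1.8 + 0.25 = 3.75 < 3.80: no tether
        topo = _carbon_pair_topology(("C", "S"), ("CG", "SD"), 3.80)
        net = ps.build_network(np.array([a.coords for a in topo.atoms]), topo)
        assert net.count("hydrophobic") == 0

    def test_exclude_ligand_leaves_no_ligand_constraints(self, dimer, peptide,
                                                         small_runs):
        runs, truth, _ = small_runs
        t = int(truth[(truth.run == 0) & (truth.state == "site_III")]
                .frame.iloc[0])
        topo = runs[0].topology
        lig = {topo.atoms[i].serial for i in topo.ligand_indices()}
        net = ps.build_network(runs[0].frames[t], topo, include_ligand=False)
        assert all(not (set(c.atoms) & lig) for c in net.constraints)
        assert not (set(net.bodies) & lig)
        with_lig = ps.build_network(runs[0].frames[t], topo,
                                    include_ligand=True)
        assert any(c.interface for c in with_lig.constraints)

    def test_peptide_and_carbonyl_bonds_are_six_bar(self, dimer):
        net = ps.build_network(dimer.frames[0], dimer.topology)
        kinds = {}
        topo = dimer.topology
        for c in net.constraints:
            a = topo.atoms[topo.index_of(c.atoms[0])]
            b = topo.atoms[topo.index_of(c.atoms[1])]
            key = (frozenset((a.name, b.name)), a.res_seq == b.res_seq)
            kinds[key] = (c.kind, c.bars)
        # backbone carbonyl
        assert kinds[(frozenset(("C", "O")), True)] == ("double_or_peptide", 6)
        # inter-residue peptide bond
        assert kinds[(frozenset(("C", "N")), False)] == ("double_or_peptide", 6)
        # N-CA single bond
        assert kinds[(frozenset(("N", "CA")), True)] == ("covalent", 5)


class TestPebbleGame:
    def test_six_bars_lock_two_bodies(self):
        game = BodyBarPebbleGame(2)
        game.add_constraint(0, 1, 6)
        assert game.dof == 6
        assert game.components() == [frozenset({0, 1})]

    def test_five_bars_leave_a_hinge(self):
        game = BodyBarPebbleGame(2)
        game.add_constraint(0, 1, 5)
        assert game.dof == 7
        assert set(game.components()) == {frozenset({0}), frozenset({1})}

    def test_redundant_bars_counted_not_placed(self):
        game = BodyBarPebbleGame(2)
        game.add_constraint(0, 1, 6)
        game.add_constraint(0, 1, 3)
        assert game.independent_bars == 6
        assert game.redundant_bars == 3
        assert game.dof == 6

    def test_decomposition_independent_of_insertion_order(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n, edges = random_body_bar_network(rng)
            games = []
            for shuffle_seed in range(3):
                order = list(edges)
                random.Random(shuffle_seed).shuffle(order)
                game = BodyBarPebbleGame(n)
                for u, v, bars in order:
                    game.add_constraint(u, v, bars)
                games.append(game)
            ref = set(games[0].components())
            assert all(set(g.components()) == ref for g in games)
            assert len({g.dof for g in games}) == 1

    def test_connected_network_keeps_at_least_six_dof(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 8))
            game = BodyBarPebbleGame(n)
            for i in range(n - 1):       # spanning tree keeps it connected
                game.add_constraint(i, i + 1, int(rng.integers(1, 7)))
            for _ in range(rng.integers(0, 10)):
                u, v = rng.integers(0, n, 2)
                if u != v:
                    game.add_constraint(int(u), int(v),
                                        int(rng.integers(1, 7)))
            assert game.dof >= 6

    def test_adding_bars_never_increases_dof(self, rng):
        game = BodyBarPebbleGame(5)
        last = game.dof
        for _ in range(30):
            u, v = rng.integers(0, 5, 2)
            if u == v:
                continue
            game.add_constraint(int(u), int(v), 1)
            assert game.dof <= last
            last = game.dof

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_rigidity_matrix_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            n, edges = random_body_bar_network(rng)
            dof_o, comps_o = rigidity_matrix_analysis(n, edges, rng)
            game = BodyBarPebbleGame(n)
            for u, v, bars in edges:
                game.add_constraint(u, v, bars)
            assert game.dof == dof_o
            assert set(game.components()) == comps_o


def _ladder_toy(with_ligand=False, bond_energy=-3.0):
    """Hand-traceable network: a rigid 2-body core (the giant cluster),
    residue 3 held to it by one extra bond, residue 4 isolated."""
    atoms = [
        Atom(1, "CA", "C", "A", "ALA", 1, np.zeros(3), 12.0, False),
        Atom(2, "CA", "C", "A", "ALA", 2, np.array([1.0, 0, 0]), 12.0, False),
        Atom(3, "CA", "C", "A", "ALA", 3, np.array([2.0, 0, 0]), 12.0, False),
        Atom(4, "CA", "C", "A", "ALA", 4, np.array([9.0, 0, 0]), 12.0, False),
    ]
    constraints = [
        Constraint((1, 2), "double_or_peptide", 6),
        Constraint((1, 3), "covalent", 5),
    ]
    if with_ligand:
        atoms.append(Atom(5, "NZ", "N", "P", "LYS", 1,
                          np.array([2.0, 2.0, 0]), 14.0, False))
        # ligand rigidly held to the core by two strong hydrogen bonds,
        # and the helix (residue 3) held via one interface bond
        constraints += [
            Constraint((1, 5), "hbond", 5, e_hb=-8.0),
            Constraint((2, 5), "hbond", 5, e_hb=-8.0),
            Constraint((3, 5), "hbond", 5, e_hb=bond_energy),
        ]
    else:
        constraints.append(Constraint((2, 3), "hbond", 5, e_hb=bond_energy))
    topo = Topology(atoms, [], ligand_chain="P")
    bodies = [a.serial for a in atoms]
    return ConstraintNetwork(bodies=bodies, constraints=constraints,
                             topology=topo)


class TestDilution:
    def test_full_persistence_accumulates_whole_ladder_mass(self):
        net = _ladder_toy()
        g = dilution_stability([net])[0]
        assert np.isclose(g[("A", 1)], 8.0, atol=1e-9)
        assert np.isclose(g[("A", 2)], 8.0, atol=1e-9)

    def test_isolated_residue_scores_zero(self):
        g = dilution_stability([_ladder_toy()])[0]
        assert g[("A", 4)] == 0.0

    def test_detachment_at_bond_energy_is_exact(self):
        # residue 3 is rigid with the core only while the E = -3 bond is
        # retained (sigma >= -3): ladder mass 3.0 of the total 8.0
        g = dilution_stability([_ladder_toy(bond_energy=-3.0)])[0]
        assert np.isclose(g[("A", 1)] - g[("A", 3)], 5.0, atol=1e-9)
        assert np.isclose(g[("A", 3)], 3.0, atol=1e-9)

    def test_g_non_increasing_as_ladder_shortens(self):
        net = _ladder_toy(bond_energy=-3.0)
        g_values = []
        for stop in (-8.0, -4.0, -2.0):
            params = NetworkParams(dilution_stop=stop)
            g_values.append(dilution_stability([net], params)[0][("A", 3)])
        assert g_values[0] >= g_values[1] >= g_values[2]


class TestPerturbation:
    def test_ligand_free_network_is_a_noop_with_warning(self):
        net = _ladder_toy(with_ligand=False)
        with pytest.warns(UserWarning):
            perturbed, tally = perturb_remove_ligand(net)
        assert tally["total_removed"] == 0
        assert perturbed.constraints == net.constraints

    def test_tally_counts_constructed_constraints(self, dimer, peptide):
        topo = ps.merge_topologies(dimer.topology, peptide.topology)
        lig_serial = topo.atoms[topo.ligand_indices()[0]].serial
        rec = [topo.atoms[i].serial for i in topo.receptor_indices()[:6]]
        constraints = [Constraint((min(r, lig_serial), max(r, lig_serial)),
                                  "hbond", 5, e_hb=-2.0) for r in rec[:3]]
        constraints += [Constraint((min(r, lig_serial), max(r, lig_serial)),
                                   "hydrophobic", 2) for r in rec[3:5]]
        constraints += [Constraint((rec[0], rec[1]), "covalent", 5)]
        net = ConstraintNetwork(bodies=[a.serial for a in topo.atoms],
                                constraints=constraints, topology=topo)
        perturbed, tally = perturb_remove_ligand(net)
        assert (tally["hbond_removed"], tally["hydrophobic_removed"]) == (3, 2)
        assert tally["hbond_removed_pct"] == 100.0

    def test_receptor_internal_constraints_untouched(self, small_runs):
        runs, truth, _ = small_runs
        t = int(truth[(truth.run == 0) & (truth.state == "site_III")]
                .frame.iloc[0])
        topo = runs[0].topology
        net = ps.build_network(runs[0].frames[t], topo)
        lig = {topo.atoms[i].serial for i in topo.ligand_indices()}
        perturbed, _ = perturb_remove_ligand(net)
        internal = [c for c in net.constraints if not set(c.atoms) & lig]
        assert perturbed.constraints == internal


class TestDeltaG:
    def test_distant_ligand_gives_identically_zero_profile(self, dimer,
                                                           peptide):
        topo = ps.merge_topologies(dimer.topology, peptide.topology)
        frame = np.vstack([dimer.frames[0],
                           peptide.frames[0] + np.array([150.0, 0.0, 0.0])])
        net = ps.build_network(frame, topo)
        assert not any(c.interface for c in net.constraints)
        profile, tally = ps.delta_g_profile([net])
        assert np.all(profile.entries.delta_g.to_numpy() == 0.0)
        assert tally["hbond_removed_pct"] < 100.0

    def test_hand_traceable_interface_bond_gives_exact_ladder_mass(self):
        net = _ladder_toy(with_ligand=True, bond_energy=-3.0)
        profile, tally = ps.delta_g_profile([net])
        # the helix residue is held in the giant cluster over exactly the
        # ladder mass above the interface bond energy
        assert np.isclose(profile.get("A", 3), 3.0, atol=1e-9)
        assert profile.get("A", 1) == 0.0
        assert profile.get("A", 2) == 0.0
        assert tally["hbond_removed"] == 3

    def test_bridge_bound_ensemble_localises_stabilisation(self, dimer,
                                                           small_runs):
        runs, truth, spec = small_runs
        bound, _ = ps.extract_bound_frames(runs, [("A", 152)], stride_ns=2.0)
        nets = [ps.build_network(bound.frames[t], bound.topology)
                for t in range(3)]
        profile, _ = ps.delta_g_profile(nets)
        e = profile.entries
        peak = e.loc[e.delta_g.idxmax()]
        # stabilisation concentrated on the two bridged chain-A helices
        assert peak.chain_id == "A"
        assert 145 <= peak.res_seq <= 154 or 165 <= peak.res_seq <= 174
        assert peak.delta_g > 1.0
        # giant-cluster identity flips may produce small negative artifacts,
        # but they stay an order of magnitude below the planted signal
        assert e.delta_g.min() > -0.2 * peak.delta_g
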