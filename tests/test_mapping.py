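"""Occupancy grids, contact propensities, bound-frame extraction, RMSF."""

import numpy as np
import pandas as pd
import pytest

import peptisite as ps
from peptisite.hbonds import ContactDetector, HBondCriterion
from peptisite.mapping import OccupancyGrid


def _engineered_complex(dimer, peptide, da_distance, n_frames=4,
                        angle_linear=True):
    """Complex frames with the peptide's Lys5 NZ at a controlled distance
    from the (A, 152) carboxylate OE1, linear D-H...A geometry."""
    topo = ps.merge_topologies(dimer.topology, peptide.topology)
    oe1 = next(i for i, a in enumerate(topo.atoms)
               if (a.chain_id, a.res_seq, a.name) == ("A", 152, "OE1"))
    rframe = dimer.frames[0]
    acceptor = rframe[oe1]
    u = acceptor - rframe.mean(axis=0)
    u /= np.linalg.norm(u)
    pep = peptide.frames[0] + (acceptor + (da_distance + 12.0) * u)
    nz = next(i for i, a in enumerate(peptide.topology.atoms)
              if (a.res_seq, a.name) == (5, "NZ"))
    hz = next(i for i, a in enumerate(peptide.topology.atoms)
              if (a.res_seq, a.name) == (5, "HZ1"))
    shift = (acceptor + da_distance * u) - pep[nz]
    pep[nz] += shift
    pep[hz] = acceptor + (da_distance - 1.0) * u if angle_linear \
        else pep[nz] + np.array([0.0, 0.0, 1.0])
    frames = np.repeat(np.vstack([rframe, pep])[None], n_frames, axis=0)
    times = 0.1 * np.arange(1, n_frames + 1)
    return ps.StructuralEnsemble(topo, frames, times)


class TestOccupancyGrid:
    def test_single_com_lands_in_expected_bin(self):
        grid = OccupancyGrid(origin=np.zeros(3), bin_edge=3.0,
                             counts=np.zeros((2, 2, 2), dtype=int),
                             window_end_ns=1.0)
        assert np.allclose(grid.bin_center((0, 0, 0)), 1.5)

    def test_count_conservation_across_windows(self, small_runs):
        runs, truth, _ = small_runs
        for window in (5.0, 15.0, 30.0):
            grid = ps.occupancy_grid(runs, window_end_ns=window)
            expected = int((truth.time_ns <= window).sum())
            assert grid.total == expected
            assert np.all(grid.counts >= 0)

    def test_two_site_max_bins_match_truth_ratio(self, dimer, peptide):
        from peptisite.synthetic import PlantedSite
        sites = (PlantedSite("a", contact_residue=("A", 152)),
                 PlantedSite("b", contact_residue=("B", 152)))
        spec = ps.DiffusionSpec(
            sites=sites, dwell_fractions={"a": 0.6, "b": 0.4, "free": 0.0},
            n_runs=2, frames_per_run=500, positional_noise_sd=0.0,
            receptor_jitter_sd=0.0, seed=13)
        runs, truth = ps.simulate_diffusion_runs(dimer, peptide, spec)
        grid = ps.occupancy_grid(runs, window_end_ns=1e6)
        counts = np.sort(grid.counts.ravel())[::-1]
        na = int((truth.state == "a").sum())
        nb = int((truth.state == "b").sum())
        assert {counts[0], counts[1]} == {na, nb}

    def test_empty_window_warns_and_returns_empty_grid(self, small_runs):
        runs, _, _ = small_runs
        with pytest.warns(UserWarning):
            grid = ps.occupancy_grid(runs, window_end_ns=1e-6)
        assert grid.total == 0


class TestTopSites:
    def test_single_occupied_bin_yields_one_site(self):
        counts = np.zeros((3, 3, 3), dtype=int)
        counts[1, 1, 1] = 7
        grid = OccupancyGrid(np.zeros(3), 3.0, counts, 1.0)
        sites = ps.top_sites(grid, k=3, min_separation=6.0)
        assert len(sites) == 1
        assert sites[0][1] == 7

    def test_nearby_bins_are_suppressed(self):
        counts = np.zeros((4, 1, 1), dtype=int)
        counts[0, 0, 0] = 10
        counts[1, 0, 0] = 8       # 3 Å away: suppressed at min_separation 6
        counts[3, 0, 0] = 5       # 9 Å away: kept
        grid = OccupancyGrid(np.zeros(3), 3.0, counts, 1.0)
        sites = ps.top_sites(grid, k=3, min_separation=6.0)
        assert [n for _, n in sites] == [10, 5]

    @pytest.mark.parametrize("seed", range(20))
    def test_site_recovery_for_any_seed(self, dimer, peptide, seed):
        # 1000 frames per seed: enough sampling that even the 12% site's
        # dwell count dominates any free-diffusion bin despite the sticky
        # Markov chain's autocorrelation
        from peptisite.synthetic import _SitePlacement
        spec = ps.default_diffusion_spec(n_runs=2, frames_per_run=500,
                                         seed=seed)
        runs, _ = ps.simulate_diffusion_runs(dimer, peptide, spec)
        grid = ps.occupancy_grid(runs, window_end_ns=1e6)
        found = ps.top_sites(grid, k=3, min_separation=8.0)
        tol = grid.bin_edge * np.sqrt(3) / 2.0
        for site in spec.sites:
            center = _SitePlacement(site, dimer, peptide).center
            assert min(np.linalg.norm(center - c) for c, _ in found) <= tol

    def test_recovers_planted_site_centers(self, dimer, peptide, small_runs):
        from peptisite.synthetic import _SitePlacement
        runs, _, spec = small_runs
        grid = ps.occupancy_grid(runs, window_end_ns=1e6)
        found = ps.top_sites(grid, k=3, min_separation=8.0)
        tol = grid.bin_edge * np.sqrt(3) / 2.0
        planted = [_SitePlacement(s, dimer, peptide).center
                   for s in spec.sites]
        for center in planted:
            assert min(np.linalg.norm(center - c) for c, _ in found) <= tol


class TestPropensity:
    def test_permanent_linear_contact_scores_one(self, dimer, peptide):
        ens = _engineered_complex(dimer, peptide, da_distance=2.8)
        table = ps.hbond_saltbridge_propensity([ens])
        assert table.get("A", 152) == 1.0

    def test_half_occupied_contact_scores_half(self, dimer, peptide):
        near = _engineered_complex(dimer, peptide, 2.8, n_frames=2)
        far = _engineered_complex(dimer, peptide, 9.0, n_frames=2)
        frames = np.concatenate([near.frames, far.frames])
        ens = ps.StructuralEnsemble(near.topology, frames,
                                    0.1 * np.arange(1, 5))
        table = ps.hbond_saltbridge_propensity([ens])
        assert table.get("A", 152) == 0.5

    def test_distant_pair_scores_zero(self, dimer, peptide):
        ens = _engineered_complex(dimer, peptide, da_distance=5.0)
        # 5 Å exceeds both the H-bond (3.5) and salt-bridge (4.0) cutoffs
        table = ps.hbond_saltbridge_propensity([ens])
        assert table.get("A", 152) == 0.0

    def test_matches_truth_table_dwell_fractions(self, small_runs):
        runs, truth, spec = small_runs
        table = ps.hbond_saltbridge_propensity(runs)
        fractions = truth.state.value_counts(normalize=True)
        for site in spec.sites:
            chain, res = site.contact_residue
            assert np.isclose(table.get(chain, res),
                              fractions.get(site.name, 0.0), atol=1e-12)

    def test_chain_averaging_merges_homologous_residues(self, small_runs):
        runs, truth, _ = small_runs
        plain = ps.hbond_saltbridge_propensity(runs)
        avg = ps.hbond_saltbridge_propensity(runs, average_chains=True)
        row = avg.entries[avg.entries.res_seq == 152]
        assert len(row) == 1
        expected = 0.5 * (plain.get("A", 152) + plain.get("B", 152))
        assert np.isclose(float(row.propensity.iloc[0]), expected)

    def test_invariant_under_run_reordering(self, small_runs):
        runs, _, _ = small_runs
        fwd = ps.hbond_saltbridge_propensity(runs)
        rev = ps.hbond_saltbridge_propensity(runs[::-1])
        assert fwd.entries.propensity.equals(rev.entries.propensity)

    def test_wider_cutoff_never_decreases_propensity(self, small_runs):
        runs, _, _ = small_runs
        tight = ps.hbond_saltbridge_propensity(
            runs[:1], HBondCriterion(da_cutoff=3.0))
        loose = ps.hbond_saltbridge_propensity(
            runs[:1], HBondCriterion(da_cutoff=3.8))
        assert np.all(loose.entries.propensity.to_numpy() >=
                      tight.entries.propensity.to_numpy() - 1e-12)

    def test_no_hydrogens_without_fallback_is_an_error(self, dimer, peptide):
        ens = _engineered_complex(dimer, peptide, 2.8)
        topo = ens.topology
        heavy = [i for i, a in enumerate(topo.atoms) if not a.is_hydrogen]
        from peptisite.structures import Topology
        atoms = [topo.atoms[i] for i in heavy]
        serial_set = {a.serial for a in atoms}
        bonds = [tuple(b) for b in topo.covalent_bonds
                 if set(b) <= serial_set]
        stripped = Topology(atoms, bonds, ligand_chain="P")
        bare = ps.StructuralEnsemble(stripped, ens.frames[:, heavy, :],
                                     ens.times)
        with pytest.raises(Exception, match="hydrogens"):
            ps.hbond_saltbridge_propensity([bare])
        table = ps.hbond_saltbridge_propensity(
            [bare], HBondCriterion(heavy_only_fallback=True))
        assert table.get("A", 152) == 1.0


class TestExtraction:
    def test_counts_match_truth_table_for_every_anchor_set(self, small_runs):
        runs, truth, spec = small_runs
        for site in spec.sites:
            bound, prov = ps.extract_bound_frames(
                runs, [site.contact_residue], stride_ns=0.1)
            expected = int((truth.state == site.name).sum())
            got = 0 if bound is None else bound.n_frames
            assert got == expected
            assert len(prov) == got

    def test_stride_subsamples_on_the_time_axis(self, small_runs):
        runs, truth, spec = small_runs
        site = spec.sites[2]
        bound, _ = ps.extract_bound_frames(runs, [site.contact_residue],
                                           stride_ns=2.0)
        strided = truth[np.isclose((truth.time_ns / 2.0) % 1.0, 0.0)]
        assert bound.n_frames == int((strided.state == site.name).sum())

    def test_no_anchors_satisfied_returns_empty_with_warning(self, small_runs):
        runs, _, _ = small_runs
        with pytest.warns(UserWarning):
            bound, prov = ps.extract_bound_frames(runs, [("A", 160)],
                                                  stride_ns=0.1)
        assert bound is None and prov == []

    def test_stride_below_frame_spacing_is_an_error(self, small_runs):
        runs, _, _ = small_runs
        with pytest.raises(ValueError):
            ps.extract_bound_frames(runs, [("A", 152)], stride_ns=0.01)

    def test_all_bound_run_with_matching_stride_keeps_all_frames(self, dimer,
                                                                 peptide):
        from peptisite.synthetic import PlantedSite
        site = PlantedSite("s", contact_residue=("A", 152))
        spec = ps.DiffusionSpec(sites=(site,),
                                dwell_fractions={"s": 1.0, "free": 0.0},
                                n_runs=1, frames_per_run=100, seed=2)
        runs, _ = ps.simulate_diffusion_runs(dimer, peptide, spec)
        bound, _ = ps.extract_bound_frames(runs, [("A", 152)], stride_ns=0.1)
        assert bound.n_frames == 100


class TestRmsfCompare:
    def test_identical_ensembles_give_zero_delta(self, dimer):
        runs = ps.simulate_apo_runs(dimer, n_runs=2, frames_per_run=30, seed=1)
        table = ps.rmsf_compare(runs, runs)
        assert np.allclose(table.delta, 0.0, atol=1e-12)

    def test_planted_extra_noise_shows_up_in_delta(self, dimer):
        noisy_res = {("A", r): 4.0 for r in range(158, 163)}
        noisy_res.update({("B", r): 4.0 for r in range(158, 163)})
        bound = ps.simulate_apo_runs(dimer, 3, 60, seed=5)
        apo = ps.simulate_apo_runs(dimer, 3, 60, seed=6,
                                   residue_noise_scale=noisy_res)
        table = ps.rmsf_compare(bound, apo)
        flagged = table[(table.res_seq >= 158) & (table.res_seq <= 162)]
        others = table[(table.res_seq < 157) | (table.res_seq > 163)]
        assert flagged.delta.min() > 0.2
        assert others.delta.abs().max() < flagged.delta.min()

    def test_single_frame_runs_propagate_rmsf_error(self, dimer):
        one = [ps.StructuralEnsemble(dimer.topology, dimer.frames,
                                     np.array([0.0]))]
        with pytest.raises(ValueError):
            ps.rmsf_compare(one, one)
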