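# peptisite

Where does an inhibitory peptide bind a receptor dimer, and what does the
binding do to the receptor's mechanics? `peptisite` is an analysis pipeline
for that question, built around the ethylene-receptor case: a short basic
peptide (the EIN2-derived octapeptide NOP-1, LKRYKRRL) binds the GAF-domain
dimer of the receptor ETR1 at the dimerisation interface and rigidifies it,
which plausibly throttles signal transmission across the receptor. The
package implements the full computational chain on top of trajectory
ensembles:

1. **Site mapping** — superpose all frames onto the receptor, bin the
   peptide's centre of mass on a 3 Å cubic occupancy grid over growing time
   windows, rank the maxima, and compute per-residue hydrogen-bond /
   salt-bridge propensities (peptide donor → receptor acceptor, chains of
   the homodimer averaged).
2. **Bound-state extraction and pose clustering** — collect frames (every
   2 ns) whose peptide hydrogen-bonds an anchor residue, compare bound
   poses by all-atom ligand RMSD in the receptor frame, and cluster with
   Ward's method on the δ(c1, c2) = √ΔSS scale (two singleton poses at
   distance D merge at δ = D/√2).
3. **Rigidity perturbation** — turn each bound snapshot into a body-bar
   constraint network (covalent bonds 5 or 6 bars, H-bonds scored by the
   12-10 potential E_HB = V0·[5(d0/d)¹² − 6(d0/d)¹⁰]·cos²θ, hydrophobic
   tethers within vdW + 0.25 Å), decompose it with a (6,6) pebble game,
   and integrate per-residue stability over a constraint-dilution ladder.
   The per-residue perturbation free energy
   ΔG_i = ⟨g_i(ground)⟩ − ⟨g_i(peptide constraints removed)⟩
   is positive where the peptide rigidifies the receptor.
4. **Fluctuations** — pooled bound-vs-apo Cα RMSF differences as the
   independent mobility check.
5. **Binding isotherms** — microscale-thermophoresis window arithmetic
   (temperature-jump ratio minus the ligand-free baseline) and one-site
   fits with ligand depletion, fb(c) = [(P+c+K_d) − √((P+c+K_d)² − 4Pc)]/(2P),
   appropriate because the labelled protein (25 nM) is comparable to the
   measured K_d (~100 nM).

Because no trajectories or raw fluorescence traces are publicly deposited
for this system, the package ships a first-class synthetic-data module:
a C2-symmetric helix-bundle dimer, a diffusing peptide with planted dwell
sites (including a bridging site that genuinely rigidifies two receptor
helices), and seeded isotherm generators — each returning exact ground
truth so every stage is testable against it. See `docs/methods.md` for the
model details and their limits.

## Worked example

```python
import peptisite as ps

receptor = ps.build_toy_dimer()
peptide = ps.build_peptide()                     # LKRYKRRL, chain P
spec = ps.default_diffusion_spec(n_runs=15, frames_per_run=400, seed=1)
runs, truth = ps.simulate_diffusion_runs(receptor, peptide, spec)

grid = ps.occupancy_grid(runs, window_end_ns=40.0)
for center, count in ps.top_sites(grid, k=3, min_separation=8.0):
    print(center, count)

bound, _ = ps.extract_bound_frames(runs, [("A", 152)], stride_ns=2.0)
nets = [ps.build_network(bound.frames[t], bound.topology) for t in range(8)]
profile, tally = ps.delta_g_profile(nets)
peak = profile.entries.loc[profile.entries.delta_g.idxmax()]
print(peak.chain_id, peak.res_seq, round(peak.delta_g, 2))
```

prints (seed 1):

```
[ 13.5  -4.5  10.5] 697
[-25.5  10.5   7.5] 674
[ -1.5  16.5   1.5] 396
A 154 7.5
```

The three occupancy maxima are the three planted sites (the first is the
bridging site III analogue next to residue E152 of chain A; the counts
reflect the 30/18/12% dwell fractions spread over neighbouring bins), and
the rigidity profile peaks at 7.5 kcal/mol on the helix the bound peptide
bridges — residues adjacent to the planted anchors — while chain B is
essentially unperturbed.

The same flow, step by step with written outputs, lives in `analysis/`:

```
python analysis/01_build_system.py      # receptor + peptide PDBs
python analysis/02_simulate_runs.py     # 15 runs + truth table
python analysis/03_map_sites.py         # occupancy windows, propensities
python analysis/04_cluster_poses.py     # bound poses, Ward dendrogram
python analysis/05_rigidity.py          # per-residue ΔG profile
python analysis/06_rmsf_compare.py      # bound vs apo fluctuations
python analysis/07_fit_isotherms.py     # K_d recovery at 88/104/128 nM
```

Each script prints what it found and writes tables under `results/`.

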