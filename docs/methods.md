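# Methods

This package reconstructs, as a tested pipeline on synthetic ensembles, the
computational workflow by which an inhibitory peptide's binding site on a
receptor GAF-domain dimer is located from free-diffusion trajectories and
its rigidifying effect on the receptor is quantified: occupancy-grid site
mapping, contact-propensity analysis, bound-pose Ward clustering,
constraint-network rigidity perturbation (per-residue ΔG), RMSF comparison,
and one-site binding-isotherm fitting. No molecular-dynamics trajectories
or raw thermophoresis traces are publicly available for this system, so
every stage runs on seeded surrogate data whose ground truth is known
exactly; what each passing test demonstrates about real data is discussed
at the end.

## Structural model and conventions

Coordinates are in Å, times in ns, masses in Da; residues are numbered
1-based as in the PDB. The receptor dimer uses chains "A"/"B", the peptide
chain "P". Ensembles are a fixed topology plus `T × N × 3` coordinate
frames with strictly increasing times; multi-model PDB files carry one
frame per MODEL, with frame times in `REMARK 250 TIME_NS` lines and a
0.1 ns default spacing (snapshots every 100 ps). Superposition is
least-squares Kabsch (proper rotations only) over receptor Cα atoms by
default — the ligand diffuses, so it never takes part in the fit. Cα-only
fitting is an assumption; heavy-atom fitting is available through the
selection argument.

## Synthetic study system

`build_toy_dimer` constructs two identical three-helix bundles related by
an exact C2 rotation: ideal α-helices (rise 1.5 Å, 100°/residue, Cα radius
2.3 Å) with backbone amide hydrogens, Ala side chains, a Leu stripe (every
helix's residues j ∈ {2, 5, 9}) supplying hydrophobic-tether substrate, and
Glu at configurable positions so planted binding sites have carboxylate
acceptors. There are no loops between helices and no force field; the
geometry exists to make every downstream criterion (H-bond geometry,
tether distances, helix rigidity through backbone hydrogen bonds)
well-defined and controllable.

`simulate_diffusion_runs` draws a per-frame dwell state from a sticky
Markov chain (stay probability 0.8, otherwise an independent draw from the
stationary distribution), so the marginal occupancy of every frame equals
the configured dwell fractions exactly, while runs still show dwell
episodes. Receptor atoms get Gaussian jitter (default sd 0.15 Å,
per-residue scalable for planted-mobility experiments). Dwell placements
come in two modes:

* **anchor** — the peptide sits outside the receptor, rigidly oriented
  along the outward direction (spin chosen to maximise clearance), with
  one planted hydrogen bond from a designated donor (Lys5 NZ) to the
  contact residue's carboxylate. The donor and its hydrogens are snapped
  onto exact linear D–H···A geometry (2.9 Å) against the current, jittered
  acceptor position, so geometric detection downstream is guaranteed and
  the truth table is exact. Mechanically a single bond through a
  side-chain hinge chain cannot rigidify anything — which is itself a
  statement the rigidity stage verifies.
* **bridge** — the peptide lies in the groove between the two helices
  named by the site and plants seven hydrogen bonds: five peptide amide
  N–H donors onto backbone carbonyls, two receptor amide donors onto
  peptide carbonyls. The doubly tied peptide amide units (10 bars to one
  rigid body) merge rigidly into each helix and the single ties lock the
  intervening backbone torsions, so the bound peptide bridges the two
  helices into one rigid cluster. This is a planted analogue of an
  interface-bridging binding site, and the merge cascade runs entirely through
  topology-defined covalent constraints, making it robust to the small
  coordinate adjustments the snapping introduces.

Free frames place the peptide uniformly in a shell whose inner boundary is
the receptor's support distance plus the peptide radius plus 8 Å, so every
peptide atom is at least 8 Å from every receptor atom and can never
register a contact. Snapping moves a handful of atoms of an otherwise
rigid conformer; this deliberately relaxes "one rigid conformer" so that
oracle tests can rely on exact truth-table counts.

`generate_isotherm` produces 2-fold serial dilutions (default 16 points
from 10 µM) of the one-site depletion model at 25 nM labelled protein,
with Gaussian noise scaled to the amplitude. Defaults (amplitude 0.02
ΔF_norm, offset 0, 3 replicates, 5% noise) represent a clean
thermophoresis experiment at the assay conditions this emulates.

## Site mapping

The ligand centre of mass of every frame inside a time window, after
superposition onto a common reference, is binned on a cubic grid of 3 Å
bins spanning the bounding box of the observed centres plus one bin of
margin, with half-open bin intervals — fine enough to separate
neighbouring surface sites, coarse enough that a dwelling peptide's COM
noise stays mostly within one bin. Site ranking is a greedy
pick of the highest-count bins with a minimum mutual separation (default
6 Å; the analysis scripts use 8 Å, comparable to the planted-site spacing),
ties broken by lexicographic bin index.

Hydrogen-bond/salt-bridge propensity counts, per receptor residue, the
fraction of frames with at least one contact in which the peptide is the
donor and the receptor the acceptor — a deliberate directional convention:
the basic peptide supplies the donors, the acidic receptor surface the
acceptors. Geometric criteria (donor–acceptor ≤ 3.5 Å with D–H···A ≥ 135°;
charged side-chain N to carboxylate O ≤ 4.0 Å; heavy-only fallback
≤ 3.5 Å) are standard values and fully configuration-exposed, since the
values are interoperable with common trajectory-analysis tools. "Fraction
of frames with ≥ 1 bond" was chosen over "mean bond count": an occupancy
fraction compares directly across residues regardless of how many
simultaneous bonds a carboxylate can accept. Bound frames are extracted on a 2 ns
stride (the network-ensemble stride) as those hydrogen-bonding at least
one anchor residue.

## Pose clustering

Bound poses are compared by all-atom ligand RMSD in the receptor frame
with **no** re-superposition: location and orientation differences are the
signal a binding-mode clustering must separate, and positional RMSDs of
tens of Å between sites are exactly what the dendrogram should spread out. Ward linkage is
delegated to SciPy; merge heights are reported as δ(c1, c2) =
√(increase in total within-cluster sum of squares), converted from
SciPy's scale via δ = h/√2 (SciPy's Ward height squared equals twice the
variance increase; two singletons at distance D merge at δ = D/√2).
Cluster ids after cutting are ordered by decreasing size, and each
cluster's representative is its medoid — an actual conformation, not an
average. Exact agreement with a naive O(n³) Lance–Williams implementation
is enforced in the tests; because the agreement is floating-point, it is
asserted to 1e-8 Å.

## Rigidity analysis

Each strided bound conformation becomes a body-bar network: atoms are
rigid bodies (6 degrees of freedom), constraints are bars — 5 for covalent
single bonds (the torsion remains), 6 for peptide and carbonyl/carboxylate
bonds (locked), 5 for hydrogen bonds and salt bridges, 2 for hydrophobic
tethers; the counts follow first-generation rigidity-software conventions
and are configurable. Hydrogen bonds are scored with a Mayo-style 12-10
potential with a cos² angular weight (V0 = 8 kcal/mol, d0 = 2.8 Å, bonds
with D–H···A below 90° excluded; candidate search radius 3.6 Å, inclusion
cutoff −0.1 kcal/mol) — the standard functional form of the rigidity
literature, with every parameter configuration-exposed. Hydrophobic tethers connect side-chain C/S atoms of
different residues closer than the sum of their van der Waals radii
(C 1.7 Å, S 1.8 Å) plus D_cut = 0.25 Å. Ligand-interface constraints use
the same hydrogen-bond and tether rules across the interface rather than
knowledge-based pair potentials, preserving the constraint-topology class
if not the energies.

Rigid clusters and the global degree-of-freedom count come from a (6,6)
body-bar pebble game. Each body carries 6 pebbles; an independent bar
requires 7 pebbles gathered on its endpoints and consumes one. After every
edge insertion a component-detection step in the Lee–Streinu style runs: if
a 7-pebble gather fails, every body that cannot reach a free pebble outside
the failed search closure is mutually rigid with the endpoints, and the
set is merged in a union-find. Bars are processed in ascending
atom-serial-pair order for determinism; the decomposition itself is
order-independent (checked over shuffles), and on random networks of up to
8 bodies the decomposition and DOF equal a generic rigidity-matrix
null-space oracle exactly.

Per-residue stability uses constraint dilution: hydrogen-bond constraints
with E_HB ≤ σ are retained while σ steps from 0 down to −8 kcal/mol in
0.1 steps (σ ∈ {−0.1, …, −8.0}, total ladder mass exactly 8.0 kcal/mol).
Because removing weak bonds first is equivalent to adding strong bonds
first, the ladder runs bottom-up on a single incrementally grown pebble
game. A residue is stable at σ when its Cα lies in the giant rigid
cluster; g_i is the stable ladder mass, and the ligand-perturbation free
energy is ΔG_i = ⟨g_i(ground)⟩ − ⟨g_i(ligand constraints removed)⟩ over
the network ensemble, with a 0.1 kcal/mol reporting threshold. This
dilution-integral ΔG is one concrete realisation of the
ensemble-perturbation idea; alternative per-residue decompositions share
the contract — per-residue, kcal/mol, positive means ligand-stabilised —
but not necessarily the magnitudes.

The giant cluster is the cluster containing the most *receptor* atoms
(ties broken by lowest receptor serial). Counting ligand bodies would let
a large rigid ligand displace the receptor cluster the profile is about
and flip signs spuriously. Even so, ΔG_i is not guaranteed non-negative:
when ligand binding moves the giant cluster from one chain to the other,
residues of the demoted chain score small negative values. On the bridge
scenario these artifacts stay an order of magnitude below the planted
signal (≈ −0.5 vs +7.5 kcal/mol) and are asserted as such rather than
hidden.

## Binding isotherms

The temperature-jump readout of a trace is the mean fluorescence over
(laser-on + 0.5 s, laser-on + 1.5 s] divided by the mean over the last
second before the laser; ΔF_norm subtracts the ligand-free baseline's
ratio. The binding model is the one-binding-site isotherm with ligand
depletion — the quadratic mass-balance root

    fb(c) = [(P + c + K_d) − √((P + c + K_d)² − 4 P c)] / (2 P)

because the labelled protein (25 nM) is not negligible against dissociation
constants near 100 nM; the pure hyperbola c/(c + K_d) is available behind a
flag for comparison; depletion is the default at these concentrations. Fits are nonlinear least squares in
(log K_d, amplitude, offset) with a decade-spaced multistart on K_d,
standard errors from the residual-covariance Jacobian approximation
(delta method for K_d), and a no-binding flag when |amplitude| < 2 SE —
the behaviour of the denatured negative control.

## Problem sizes and numerical choices

The analysis scripts use 15 runs × 400 frames (40 ns per run at 0.1 ns
spacing) and 8-network dilution ensembles; the full-scale validation test
uses 15 × 2000 frames. Monte-Carlo K_d recovery uses 100 isotherms per
constant; the acceptance script derives all its seeds from a single
command-line seed. Ties in site ranking break lexicographically, in
cluster ordering by smallest leaf index, in giant-cluster selection by
lowest serial. Degenerate inputs (empty selections, windows without
frames, anchorless extractions, flat isotherms) warn or flag rather than
crash, except where the contract demands an error (fewer than 3 or
collinear fit atoms, stride below the frame spacing, coordinates outside
the PDB field range, inconsistent model sizes).

## What the synthetic results do and do not show

The generators emulate the *structure* of such experiments' data —
dwell/diffuse trajectories with planted contact geometry, dilution-series isotherms with
realistic noise — not its physics: there is no force field, no water, no
thermostat, no thermophoresis model, and the dwell kinetics are a Markov
chain. Passing tests therefore demonstrate that the analysis operators are
correct (against oracles and exact truth tables) and that the pipeline
recovers planted effects at realistic noise levels; they do not reproduce
any real system's absolute occupancies, cluster counts, constraint tallies
or ΔG magnitudes, which would require the actual microsecond-scale
trajectories. The K_d recovery checks are the exception: they exercise the
fitting protocol at the experimentally reported constants for this
receptor (88, 104 and 128 nM) under the real assay conditions, where the
planted value is the experimental number itself.

## Known limitations

* No binary trajectory formats (DCD/XTC) and no periodic-boundary imaging;
  ensembles are expected unwrapped, one PDB MODEL per frame.
* The pebble game is pure Python; networks beyond a few thousand atoms per
  frame become slow (seconds per dilution ladder at ~550 atoms).
* Chain averaging of propensities matches residues by number, which is
  exact for the homomeric toy dimer but not for hetero-oligomers.
* The E_HB form, bar counts, and the dilution-integral ΔG are
  conventional choices within the rigidity literature, not canonical
  ones; conclusions should be drawn from relative, not absolute,
  ΔG values.
* Negative ΔG artifacts from giant-cluster identity changes are possible
  in strongly multi-domain networks (see above).
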