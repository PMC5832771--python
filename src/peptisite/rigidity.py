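"""Constraint-network rigidity analysis and ligand-perturbation ΔG profiles.

A conformation is turned into a body-bar network: every atom is a rigid
body with 6 degrees of freedom, and interactions are bars that each remove
one degree of freedom when independent — 5 bars for a covalent single bond
(leaving the torsion), 6 for peptide/double bonds (locked), 5 for hydrogen
bonds and salt bridges, 2 for hydrophobic tethers. Rigid clusters and the
global degree-of-freedom count are computed with a (6, 6) body-bar pebble
game; rigid components are detected after every edge insertion in the
Lee–Streinu fashion (a failed 7-pebble gather marks a rigid vertex set).

Hydrogen-bond strengths use the 12-10 potential with an angular weight,

    E_HB = V0 * [5 (d0/d)^12 - 6 (d0/d)^10] * cos^2(theta),  theta >= 90 deg

with V0 = 8 kcal/mol, d0 = 2.8 Å, d the donor-acceptor distance and theta
the D-H...A angle (bonds with theta < 90 deg are excluded). Hydrophobic
tethers connect side-chain C/S atom pairs closer than the sum of their van
der Waals radii (C 1.7 Å, S 1.8 Å) plus D_cut = 0.25 Å.

Per-residue stability uses a constraint-dilution ladder: H-bond constraints
with E_HB <= sigma are retained while sigma steps from ``dilution_start``
down to ``dilution_stop``; residue i is stable at sigma when its Cα body
belongs to the giant rigid cluster, and g_i is the ladder mass (kcal/mol)
over which it stays stable. The ligand-perturbation free energy per residue
is ΔG_i = <g_i(ground)> - <g_i(ligand constraints removed)>, averaged over
the network ensemble; positive values mean the ligand stabilises residue i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import BACKBONE_ATOM_NAMES, StructuralEnsemble, Topology

_DOUBLE_BOND_OXYGENS = frozenset({"O", "OE1", "OE2", "OD1", "OD2", "OXT"})


@dataclass(frozen=True)
class NetworkParams:
    """Constraint rules and the dilution ladder."""

    hbond_include_cutoff: float = -0.1       # kcal/mol, E_HB <= cutoff enters
    hbond_candidate_cutoff: float = 3.6      # Å, donor-acceptor search radius
    d_cut_hydrophobic: float = 0.25          # Å beyond vdW contact
    vdw_radii: tuple[tuple[str, float], ...] = (("C", 1.7), ("S", 1.8))
    bars: tuple[tuple[str, int], ...] = (
        ("covalent", 5), ("double_or_peptide", 6), ("hbond", 5),
        ("hydrophobic", 2))
    v0: float = 8.0                          # kcal/mol, well depth at d0
    d0: float = 2.8                          # Å, optimal donor-acceptor
    dilution_start: float = 0.0              # kcal/mol
    dilution_stop: float = -8.0
    dilution_step: float = 0.1

    def __post_init__(self):
        if self.d_cut_hydrophobic < 0:
            raise ValueError("d_cut_hydrophobic must be >= 0")
        for kind, b in self.bars:
            if not 1 <= b <= 6:
                raise ValueError(f"bar count for {kind} must be in [1, 6]")
        if self.dilution_step <= 0:
            raise ValueError("dilution_step must be > 0")
        if self.dilution_stop >= self.dilution_start:
            raise ValueError("dilution_stop must lie below dilution_start")

    @property
    def bar_map(self) -> dict[str, int]:
        return dict(self.bars)

    @property
    def vdw_map(self) -> dict[str, float]:
        return dict(self.vdw_radii)

    def ladder(self) -> np.ndarray:
        """Dilution cutoffs, descending from start-step to stop inclusive."""
        n = int(round((self.dilution_start - self.dilution_stop)
                      / self.dilution_step))
        return self.dilution_start - self.dilution_step * np.arange(1, n + 1)


def hbond_energy(donor: np.ndarray, hydrogen: np.ndarray, acceptor: np.ndarray,
                 acceptor_base: np.ndarray | None = None,
                 v0: float = 8.0, d0: float = 2.8) -> float:
    """12-10 hydrogen-bond energy with a cos^2 angular weight (kcal/mol).

    ``acceptor_base`` is accepted for interface compatibility; this
    functional form weights only the D-H...A angle at the hydrogen.
    Returns +inf (excluded) for angles below 90 degrees.
    """
    donor = np.asarray(donor, float)
    hydrogen = np.asarray(hydrogen, float)
    acceptor = np.asarray(acceptor, float)
    d = float(np.linalg.norm(acceptor - donor))
    if d <= 0 or np.linalg.norm(hydrogen - donor) <= 0:
        raise ValueError("coincident atoms in hydrogen-bond geometry")
    v1 = donor - hydrogen
    v2 = acceptor - hydrogen
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    cosang = max(-1.0, min(1.0, cosang))
    theta = np.degrees(np.arccos(cosang))
    if theta < 90.0:
        return float("inf")
    x = d0 / d
    return v0 * (5.0 * x ** 12 - 6.0 * x ** 10) * cosang ** 2


@dataclass(frozen=True)
class Constraint:
    atoms: tuple[int, int]       # serial pair, sorted ascending
    kind: str                    # covalent | double_or_peptide | hbond | hydrophobic
    bars: int
    e_hb: float | None = None    # kcal/mol, hbond only
    interface: bool = False      # True when exactly one atom is ligand


@dataclass
class ConstraintNetwork:
    bodies: list[int]            # atom serials acting as rigid bodies
    constraints: list[Constraint]
    topology: Topology
    frame_provenance: tuple[int, int] | None = None

    def __post_init__(self):
        pairs = [c.atoms for c in self.constraints]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate constraint on an atom pair")

    def count(self, kind: str) -> int:
        return sum(1 for c in self.constraints if c.kind == kind)


def build_network(frame: np.ndarray, topology: Topology,
                  params: NetworkParams = NetworkParams(),
                  include_ligand: bool = True,
                  frame_provenance: tuple[int, int] | None = None
                  ) -> ConstraintNetwork:
    """Construct the body-bar constraint network of one conformation.

    Covalent constraints come from the topology (peptide and carbonyl /
    carboxylate C-O bonds are typed ``double_or_peptide``); hydrogen bonds
    and salt bridges enter when their E_HB lies at or below the inclusion
    cutoff; hydrophobic tethers follow the vdW + D_cut rule between
    side-chain C/S atoms of different residues. With ``include_ligand``
    False the ligand chain is excluded entirely, so no constraint touches it.
    """
    frame = np.asarray(frame, float)
    bars = params.bar_map
    vdw = params.vdw_map
    ligand = topology.ligand_chain
    atoms = topology.atoms

    if include_ligand:
        active = list(range(len(atoms)))
    else:
        active = [i for i, a in enumerate(atoms) if a.chain_id != ligand]
    active_set = set(active)
    bodies = [atoms[i].serial for i in active]
    is_ligand = [atoms[i].chain_id == ligand for i in range(len(atoms))]

    constraints: dict[tuple[int, int], Constraint] = {}

    def add(i: int, j: int, kind: str, e: float | None = None):
        key = (min(atoms[i].serial, atoms[j].serial),
               max(atoms[i].serial, atoms[j].serial))
        if key in constraints:
            return
        constraints[key] = Constraint(
            atoms=key, kind=kind, bars=bars[kind], e_hb=e,
            interface=is_ligand[i] != is_ligand[j])

    # --- covalent ---------------------------------------------------------
    for bond in topology.covalent_bonds:
        s1, s2 = tuple(bond)
        i, j = topology.index_of(s1), topology.index_of(s2)
        if i not in active_set or j not in active_set:
            continue
        a, b = atoms[i], atoms[j]
        kind = "covalent"
        names = {a.name, b.name}
        if names == {"C", "N"} and (a.chain_id, a.res_seq) != (b.chain_id, b.res_seq):
            kind = "double_or_peptide"                      # peptide bond
        elif {a.element, b.element} == {"C", "O"} and (
                (a.element == "O" and a.name in _DOUBLE_BOND_OXYGENS) or
                (b.element == "O" and b.name in _DOUBLE_BOND_OXYGENS)):
            kind = "double_or_peptide"                      # C=O / carboxylate
        add(i, j, kind)

    bonded_pairs = {tuple(sorted((topology.index_of(x), topology.index_of(y))))
                    for x, y in (tuple(b) for b in topology.covalent_bonds)}

    def excluded(i, j):
        if (atoms[i].chain_id, atoms[i].res_seq) == (atoms[j].chain_id,
                                                     atoms[j].res_seq):
            return True
        return tuple(sorted((i, j))) in bonded_pairs

    # --- hydrogen bonds / salt bridges ------------------------------------
    nb = topology.bond_neighbours()
    donors = []
    for i in active:
        a = atoms[i]
        if a.element in ("N", "O"):
            hyds = [topology.index_of(s) for s in nb[a.serial]
                    if atoms[topology.index_of(s)].is_hydrogen]
            if hyds:
                donors.append((i, hyds))
    acceptor_idx = np.array([i for i in active
                             if atoms[i].element in ("N", "O", "S")], dtype=int)
    if acceptor_idx.size:
        acc_coords = frame[acceptor_idx]
        for di, hyds in donors:
            dist = np.linalg.norm(acc_coords - frame[di], axis=1)
            for k in np.where(dist <= params.hbond_candidate_cutoff)[0]:
                ai = int(acceptor_idx[k])
                if ai == di or excluded(di, ai):
                    continue
                e_best = float("inf")
                for hi in hyds:
                    e = hbond_energy(frame[di], frame[hi], frame[ai],
                                     v0=params.v0, d0=params.d0)
                    e_best = min(e_best, e)
                if e_best <= params.hbond_include_cutoff:
                    add(di, ai, "hbond", e_best)

    # --- hydrophobic tethers ----------------------------------------------
    hydrophobic = [i for i in active
                   if atoms[i].element in vdw
                   and atoms[i].name not in BACKBONE_ATOM_NAMES]
    if hydrophobic:
        hp = np.array(hydrophobic, dtype=int)
        coords = frame[hp]
        radii = np.array([vdw[atoms[i].element] for i in hydrophobic])
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        limit = radii[:, None] + radii[None, :] + params.d_cut_hydrophobic
        for a_k, b_k in zip(*np.where(np.triu(d < limit, k=1))):
            i, j = int(hp[a_k]), int(hp[b_k])
            if excluded(i, j):
                continue
            add(i, j, "hydrophobic")

    ordered = [constraints[k] for k in sorted(constraints)]
    return ConstraintNetwork(bodies=bodies, constraints=ordered,
                             topology=topology,
                             frame_provenance=frame_provenance)


def networks_from_ensemble(ensemble: StructuralEnsemble,
                           params: NetworkParams = NetworkParams(),
                           stride_ns: float = 2.0,
                           include_ligand: bool = True
                           ) -> list[ConstraintNetwork]:
    """One network per strided frame of a (bound) ensemble."""
    networks = []
    for t in range(ensemble.n_frames):
        phase = ensemble.times[t] / stride_ns
        if abs(phase - round(phase)) > 1e-6:
            continue
        networks.append(build_network(
            ensemble.frames[t], ensemble.topology, params,
            include_ligand=include_ligand,
            frame_provenance=(ensemble.source_run, t)))
    return networks


# ---------------------------------------------------------------------------
# (6, 6) body-bar pebble game
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


class BodyBarPebbleGame:
    """Incremental (6, 6) pebble game on bodies 0..n-1.

    Each body starts with 6 pebbles; placing an independent bar from u to v
    requires 7 pebbles gathered on {u, v} and consumes one from u. Rigid
    components are maintained in a union-find: whenever a 7-pebble gather
    on an inserted edge fails, the set of bodies that cannot reach a free
    pebble outside the failed search closure is mutually rigid and is
    merged. Adding bars never destroys rigidity, so the game supports
    incremental constraint dilution.
    """

    K = 6

    def __init__(self, n_bodies: int):
        self.n = n_bodies
        self.pebbles = [self.K] * n_bodies
        self.out: list[dict[int, int]] = [dict() for _ in range(n_bodies)]
        self.rin: list[dict[int, int]] = [dict() for _ in range(n_bodies)]
        self.uf = _UnionFind(n_bodies)
        self.independent_bars = 0
        self.redundant_bars = 0

    # -- pebble searches ---------------------------------------------------

    def _reverse(self, a: int, b: int):
        """Reverse one unit of the directed edge a -> b."""
        out_a = self.out[a]
        out_a[b] -= 1
        if out_a[b] == 0:
            del out_a[b]
        rin_b = self.rin[b]
        rin_b[a] -= 1
        if rin_b[a] == 0:
            del rin_b[a]
        self.out[b][a] = self.out[b].get(a, 0) + 1
        self.rin[a][b] = self.rin[a].get(b, 0) + 1

    def _find_pebble(self, root: int, other: int):
        """DFS from root (never through ``other``); move one free pebble to
        root. Returns (True, None) or (False, visited set)."""
        visited = {root, other}
        parent: dict[int, int] = {}
        stack = [root]
        while stack:
            x = stack.pop()
            for y in self.out[x]:
                if y in visited:
                    continue
                visited.add(y)
                parent[y] = x
                if self.pebbles[y] > 0:
                    self.pebbles[y] -= 1
                    node = y
                    while node != root:
                        p = parent[node]
                        self._reverse(p, node)
                        node = p
                    self.pebbles[root] += 1
                    return True, None
                stack.append(y)
        return False, visited

    def _gather(self, u: int, v: int, need: int = 7):
        """Collect ``need`` pebbles on {u, v}; on failure return the search
        closure (Reach of both endpoints)."""
        while self.pebbles[u] + self.pebbles[v] < need:
            ok, vis_u = self._find_pebble(u, v)
            if ok:
                continue
            ok, vis_v = self._find_pebble(v, u)
            if ok:
                continue
            return False, vis_u | vis_v
        return True, None

    # -- component detection ----------------------------------------------

    def _union_rigid(self, reach: set[int]):
        """After a failed gather, merge the rigid component implied by the
        search closure ``reach``: every body whose reachable free pebbles
        all lie inside the closure is mutually rigid with the endpoints."""
        escape = set()
        stack = [w for w in range(self.n)
                 if w not in reach and self.pebbles[w] > 0]
        escape.update(stack)
        while stack:
            x = stack.pop()
            for y in self.rin[x]:
                if y not in escape:
                    escape.add(y)
                    stack.append(y)
        component = [w for w in range(self.n) if w not in escape]
        base = component[0]
        for w in component[1:]:
            self.uf.union(base, w)

    # -- public API --------------------------------------------------------

    def add_constraint(self, u: int, v: int, n_bars: int):
        if u == v:
            raise ValueError("self-constraint")
        if self.uf.find(u) == self.uf.find(v):
            self.redundant_bars += n_bars
            return
        for b in range(n_bars):
            ok, reach = self._gather(u, v)
            if not ok:
                self.redundant_bars += n_bars - b
                self._union_rigid(reach)
                return
            self.pebbles[u] -= 1
            self.out[u][v] = self.out[u].get(v, 0) + 1
            self.rin[v][u] = self.rin[v].get(u, 0) + 1
            self.independent_bars += 1
        ok, reach = self._gather(u, v)
        if not ok:
            self._union_rigid(reach)

    @property
    def dof(self) -> int:
        """Global degrees of freedom (includes the 6 trivial rigid-body
        motions of each connected component)."""
        return sum(self.pebbles)

    def components(self) -> list[frozenset[int]]:
        groups: dict[int, set[int]] = {}
        for x in range(self.n):
            groups.setdefault(self.uf.find(x), set()).add(x)
        return [frozenset(g) for g in groups.values()]


def pebble_game_rigid_clusters(network: ConstraintNetwork
                               ) -> tuple[dict[int, int], int]:
    """Rigid-cluster labelling (atom serial -> cluster id) and global DOF.

    Constraints are processed in ascending atom-serial-pair order, making
    the run deterministic; the resulting decomposition itself is
    order-independent (a matroid property, checked by the test suite).
    Cluster ids are 1-based, ordered by decreasing size with ties broken by
    the smallest member serial.
    """
    serial_to_id = {s: i for i, s in enumerate(network.bodies)}
    game = BodyBarPebbleGame(len(network.bodies))
    for c in sorted(network.constraints, key=lambda c: c.atoms):
        game.add_constraint(serial_to_id[c.atoms[0]], serial_to_id[c.atoms[1]],
                            c.bars)
    id_to_serial = {i: s for s, i in serial_to_id.items()}
    comps = sorted(game.components(),
                   key=lambda g: (-len(g), min(id_to_serial[x] for x in g)))
    labels: dict[int, int] = {}
    for cid, comp in enumerate(comps, start=1):
        for x in comp:
            labels[id_to_serial[x]] = cid
    return labels, game.dof


# ---------------------------------------------------------------------------
# dilution ladder and ligand perturbation
# ---------------------------------------------------------------------------

def dilution_stability(networks: list[ConstraintNetwork],
                       params: NetworkParams = NetworkParams()
                       ) -> list[dict[tuple[str, int], float]]:
    """Per-network, per-residue stability scores g_i (kcal/mol).

    For every dilution cutoff sigma, only H-bond constraints with
    E_HB <= sigma are retained; a residue is stable at sigma when its Cα
    body lies in the giant rigid cluster. The giant cluster is the cluster
    containing the most *receptor* atoms (ties by lowest receptor serial):
    counting receptor bodies keeps the measure comparable between ground
    and ligand-removed networks — a large rigid ligand must not displace
    the receptor cluster the profile is about. g_i is the summed ladder
    mass of the stable steps. The ladder is traversed bottom-up (strongest
    network first) so the pebble game runs incrementally.
    """
    ladder = params.ladder()
    if ladder.size == 0:
        raise ValueError("empty dilution ladder")
    ascending = ladder[::-1]          # from stop (harshest) up to start-step
    results = []
    for network in networks:
        serial_to_id = {s: i for i, s in enumerate(network.bodies)}
        topo = network.topology
        body_set = set(network.bodies)
        ligand_serials = {topo.atoms[i].serial for i in topo.ligand_indices()}
        receptor_body = np.array(
            [s not in ligand_serials for s in network.bodies])
        ca_bodies: dict[tuple[str, int], int] = {}
        for a in topo.atoms:
            if a.name == "CA" and a.serial in body_set:
                ca_bodies[(a.chain_id, a.res_seq)] = serial_to_id[a.serial]

        fixed = [c for c in network.constraints if c.kind != "hbond"]
        hbonds = sorted((c for c in network.constraints if c.kind == "hbond"),
                        key=lambda c: (c.e_hb, c.atoms))
        game = BodyBarPebbleGame(len(network.bodies))
        for c in sorted(fixed, key=lambda c: c.atoms):
            game.add_constraint(serial_to_id[c.atoms[0]],
                                serial_to_id[c.atoms[1]], c.bars)
        g = {res: 0.0 for res in ca_bodies}
        pointer = 0
        id_to_serial = {i: s for s, i in serial_to_id.items()}
        for sigma in ascending:
            while pointer < len(hbonds) and hbonds[pointer].e_hb <= sigma + 1e-12:
                c = hbonds[pointer]
                game.add_constraint(serial_to_id[c.atoms[0]],
                                    serial_to_id[c.atoms[1]], c.bars)
                pointer += 1
            # giant rigid cluster at this cutoff (receptor atom count)
            roots: dict[int, tuple[int, float]] = {}
            for x in range(game.n):
                if not receptor_body[x]:
                    continue
                r = game.uf.find(x)
                size, mn = roots.get(r, (0, np.inf))
                roots[r] = (size + 1, min(mn, id_to_serial[x]))
            giant = max(roots, key=lambda r: (roots[r][0], -roots[r][1]))
            for res, body in ca_bodies.items():
                if game.uf.find(body) == giant:
                    g[res] += params.dilution_step
        results.append({res: round(val, 10) for res, val in g.items()})
    return results


def perturb_remove_ligand(network: ConstraintNetwork
                          ) -> tuple[ConstraintNetwork, dict]:
    """Remove every constraint touching the ligand, and the ligand bodies.

    Returns the perturbed network and a tally of removed H-bond and
    hydrophobic constraints (counts and percentages of all constraints of
    that kind), the bookkeeping used to judge how small the perturbation is.
    """
    topo = network.topology
    ligand_serials = {topo.atoms[i].serial for i in topo.ligand_indices()}
    if not ligand_serials & set(network.bodies):
        warnings.warn("network has no ligand bodies; perturbation is a no-op")
        tally = {"hbond_removed": 0, "hydrophobic_removed": 0,
                 "hbond_removed_pct": 0.0, "hydrophobic_removed_pct": 0.0,
                 "total_removed": 0}
        return network, tally
    kept, removed = [], []
    for c in network.constraints:
        if ligand_serials & set(c.atoms):
            removed.append(c)
        else:
            kept.append(c)
    bodies = [s for s in network.bodies if s not in ligand_serials]
    n_hb = sum(1 for c in network.constraints if c.kind == "hbond")
    n_tether = sum(1 for c in network.constraints if c.kind == "hydrophobic")
    hb_removed = sum(1 for c in removed if c.kind == "hbond")
    tether_removed = sum(1 for c in removed if c.kind == "hydrophobic")
    tally = {
        "hbond_removed": hb_removed,
        "hydrophobic_removed": tether_removed,
        "hbond_removed_pct": 100.0 * hb_removed / n_hb if n_hb else 0.0,
        "hydrophobic_removed_pct":
            100.0 * tether_removed / n_tether if n_tether else 0.0,
        "total_removed": len(removed),
    }
    perturbed = ConstraintNetwork(bodies=bodies, constraints=kept,
                                  topology=topo,
                                  frame_provenance=network.frame_provenance)
    return perturbed, tally


@dataclass
class StabilityProfile:
    """Per-residue ligand-perturbation free energies ΔG_i (kcal/mol)."""

    entries: pd.DataFrame        # chain_id, res_seq, delta_g, flagged
    threshold: float = 0.1

    def get(self, chain: str, res_seq: int) -> float:
        df = self.entries
        row = df[(df.chain_id == chain) & (df.res_seq == res_seq)]
        return float(row.delta_g.iloc[0]) if len(row) else 0.0

    @property
    def fraction_flagged(self) -> float:
        return float(self.entries.flagged.mean())


def delta_g_profile(ground_networks: list[ConstraintNetwork],
                    params: NetworkParams = NetworkParams(),
                    threshold: float = 0.1
                    ) -> tuple[StabilityProfile, dict]:
    """ΔG_i = <g_i(ground)> - <g_i(perturbed)> over the network ensemble.

    The perturbed ensemble is produced by removing all ligand-associated
    constraints from each ground network. Residues with ΔG above
    ``threshold`` (default 0.1 kcal/mol) are flagged perturbed-responsive.
    Also returns the averaged constraint-removal tally.
    """
    if not ground_networks:
        raise ValueError("need at least one ground network")
    perturbed, tallies = [], []
    for net in ground_networks:
        p, tally = perturb_remove_ligand(net)
        perturbed.append(p)
        tallies.append(tally)
    g_ground = dilution_stability(ground_networks, params)
    g_pert = dilution_stability(perturbed, params)

    ligand = ground_networks[0].topology.ligand_chain
    residues = sorted({res for g in g_pert for res in g})
    rows = []
    for chain, res_seq in residues:
        if chain == ligand:
            continue
        vals = [gg.get((chain, res_seq), 0.0) - gp.get((chain, res_seq), 0.0)
                for gg, gp in zip(g_ground, g_pert)]
        dg = float(np.mean(vals))
        rows.append((chain, res_seq, dg, dg > threshold))
    entries = pd.DataFrame(rows, columns=["chain_id", "res_seq", "delta_g",
                                          "flagged"])
    mean_tally = {k: float(np.mean([t[k] for t in tallies]))
                  for k in tallies[0]}
    return StabilityProfile(entries=entries, threshold=threshold), mean_tally
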