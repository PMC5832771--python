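"""Synthetic study systems: a C2-symmetric helix-bundle receptor dimer, a
short basic peptide ligand, seeded diffusion/dwell trajectories with planted
binding sites, and one-site binding isotherms.

No trajectory or thermophoresis raw data are publicly deposited for this
system, so every downstream stage is exercised on ensembles generated here. The
generators are pure functions of their seed, and each diffusion run returns
a truth table of the per-frame dwell state, which downstream oracle tests
use to compute exact expected values (occupancy fractions, contact
propensities, bound-frame counts).

Geometry is idealised: α-helices with 1.5 Å rise, 100°/residue and 2.3 Å Cα
radius; two receptor chains related by an exact C2 rotation; side chains
extended radially from the helix axis. There is no force field — dwell-state
dynamics are a sticky Markov chain, not Langevin dynamics, because the
downstream analyses consume only positions and contacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PlacementError
from .structures import (Atom, Selection, StructuralEnsemble, Topology,
                         center_of_mass, mass_of)

# ---------------------------------------------------------------------------
# residue templates (local residue frame: u = radial-out, w = lateral, z = axis)
# ---------------------------------------------------------------------------

_ONE_TO_THREE = {
    "A": "ALA", "G": "GLY", "E": "GLU", "D": "ASP", "K": "LYS",
    "R": "ARG", "Y": "TYR", "L": "LEU",
}

# (atom_name, element, du, dw, dz) offsets from CA
_SIDECHAINS: dict[str, list[tuple[str, str, float, float, float]]] = {
    "ALA": [("CB", "C", 1.53, 0.0, -0.5)],
    "GLY": [],
    "GLU": [("CB", "C", 1.53, 0.0, -0.5), ("CG", "C", 2.55, 0.4, -0.3),
            ("CD", "C", 3.8, 0.6, 0.0), ("OE1", "O", 4.55, 0.7, 0.95),
            ("OE2", "O", 4.55, 0.7, -0.95)],
    "ASP": [("CB", "C", 1.53, 0.0, -0.5), ("CG", "C", 2.55, 0.4, -0.3),
            ("OD1", "O", 3.3, 0.5, 0.65), ("OD2", "O", 3.3, 0.5, -1.25)],
    "LYS": [("CB", "C", 1.53, 0.0, -0.5), ("CG", "C", 2.8, 0.3, -0.2),
            ("CD", "C", 4.05, 0.45, 0.0), ("CE", "C", 5.3, 0.6, 0.2),
            ("NZ", "N", 6.4, 0.7, 0.4), ("HZ1", "H", 7.39, 0.7, 0.5),
            ("HZ2", "H", 6.07, 0.7, 1.34), ("HZ3", "H", 6.07, 0.7, -0.54)],
    "ARG": [("CB", "C", 1.53, 0.0, -0.5), ("CG", "C", 2.8, 0.3, -0.2),
            ("CD", "C", 4.0, 0.4, 0.0), ("NE", "N", 5.2, 0.5, 0.2),
            ("HE", "H", 5.75, 0.5, 1.03), ("CZ", "C", 6.5, 0.6, 0.2),
            ("NH1", "N", 7.2, 0.6, 1.2), ("HH11", "H", 8.0, 0.6, 1.8),
            ("NH2", "N", 7.2, 0.6, -0.8), ("HH21", "H", 8.0, 0.6, -1.4)],
    "TYR": [("CB", "C", 1.53, 0.0, -0.5), ("CG", "C", 2.9, 0.0, -0.3),
            ("CD1", "C", 3.6, 1.2, -0.2), ("CD2", "C", 3.6, -1.2, -0.2),
            ("CE1", "C", 5.0, 1.2, 0.0), ("CE2", "C", 5.0, -1.2, 0.0),
            ("CZ", "C", 5.7, 0.0, 0.1), ("OH", "O", 7.0, 0.0, 0.2),
            ("HH", "H", 7.97, 0.0, 0.45)],
    "LEU": [("CB", "C", 1.53, 0.0, -0.5), ("CG", "C", 2.9, 0.0, -0.3),
            ("CD1", "C", 3.7, 1.1, 0.0), ("CD2", "C", 3.7, -1.1, 0.0)],
}

_HELIX_RISE = 1.5          # Å per residue
_HELIX_TWIST = 100.0       # degrees per residue
_CA_RADIUS = 2.3           # Å

#: planted hydrogen-bond geometry during dwells: donor-acceptor distance and
#: donor-hydrogen distance along the linear D-H...A axis
_HBOND_DA = 2.9
_HBOND_DH = 1.0


def _helix_residue(j: int, res_name: str) -> list[tuple[str, str, np.ndarray]]:
    """Atoms of residue ``j`` of an ideal α-helix whose axis is local +z."""
    phi = math.radians(_HELIX_TWIST * j)
    z0 = _HELIX_RISE * j

    def cyl(r, dphi_deg, z):
        a = phi + math.radians(dphi_deg)
        return np.array([r * math.cos(a), r * math.sin(a), z])

    ca = cyl(_CA_RADIUS, 0.0, z0)
    n = cyl(1.56, -28.0, z0 - 0.93)
    c = cyl(1.64, 26.4, z0 + 1.05)
    # carbonyl O points along the helix axis (toward the C-terminus), amide H
    # back along it, which is what places the i -> i-4 hydrogen bonds
    o = c + np.array([0.30 * math.cos(phi + math.radians(26.4)),
                      0.30 * math.sin(phi + math.radians(26.4)), 1.19])
    h = n + np.array([-0.29 * math.cos(phi - math.radians(28.0)),
                      -0.29 * math.sin(phi - math.radians(28.0)), -0.97])
    atoms = [("N", "N", n), ("H", "H", h), ("CA", "C", ca), ("C", "C", c),
             ("O", "O", o)]
    u = np.array([math.cos(phi), math.sin(phi), 0.0])
    w = np.array([-math.sin(phi), math.cos(phi), 0.0])
    for name, element, du, dw, dz in _SIDECHAINS[res_name]:
        atoms.append((name, element, ca + du * u + dw * w + dz * np.array([0, 0, 1.0])))
    return atoms


def _bond_by_distance(atoms: list[Atom]) -> set[tuple[int, int]]:
    """Covalent bonds from the controlled generator geometry.

    Heavy-heavy pairs bond in the 0.8-1.8 Å window; each hydrogen bonds to
    its nearest heavy atom within 1.25 Å. Only intra-chain pairs are
    considered (the two receptor chains are not covalently linked).
    """
    coords = np.array([a.coords for a in atoms])
    chains = np.array([a.chain_id for a in atoms])
    heavy = np.array([not a.is_hydrogen for a in atoms])
    bonds: set[tuple[int, int]] = set()
    n = len(atoms)
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=2)
    for i in range(n):
        if not heavy[i]:
            # hydrogen: nearest heavy neighbour within 1.25 Å
            cand = np.where(heavy & (chains == chains[i]))[0]
            j = cand[np.argmin(d2[i, cand])]
            if d2[i, j] <= 1.25 ** 2:
                bonds.add((atoms[min(i, j)].serial, atoms[max(i, j)].serial))
            continue
        for j in range(i + 1, n):
            if not heavy[j] or chains[i] != chains[j]:
                continue
            if 0.8 ** 2 < d2[i, j] < 1.8 ** 2:
                bonds.add((atoms[i].serial, atoms[j].serial))
    return bonds


def _make_atoms(chain_id: str, res_specs: list[tuple[int, str]],
                positions: list[list[tuple[str, str, np.ndarray]]],
                serial_start: int) -> list[Atom]:
    atoms = []
    serial = serial_start
    for (res_seq, res_name), res_atoms in zip(res_specs, positions):
        for name, element, xyz in res_atoms:
            atoms.append(Atom(serial=serial, name=name, element=element,
                              chain_id=chain_id, res_name=res_name,
                              res_seq=res_seq, coords=xyz,
                              mass=mass_of(element), is_hydrogen=element == "H"))
            serial += 1
    return atoms


# ---------------------------------------------------------------------------
# receptor dimer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyDimerSpec:
    """Geometry of the synthetic receptor dimer.

    Two identical chains ("A"/"B") of parallel α-helix bundles, related by an
    exact C2 rotation about the z axis — a stand-in for a six-helix-bundle
    dimer interface. ``acidic_site_residues`` are built as Glu (carboxylate
    oxygens present) so that planted binding sites have salt-bridge/H-bond
    acceptors; every other residue is Ala.
    """

    helices_per_chain: int = 3
    residues_per_helix: int = 10
    start_res: int = 145
    acidic_site_residues: tuple[tuple[str, int], ...] = (
        ("A", 152), ("A", 169), ("A", 171),
        ("B", 152), ("B", 169), ("B", 171),
    )
    chain_offset: float = 10.0     # Å, chain centre to dimer axis
    bundle_radius: float = 6.0     # Å, helix axis to chain centre
    seed: int = 0

    def __post_init__(self):
        if self.helices_per_chain < 1:
            raise ValueError("need >= 1 helix per chain")
        if self.residues_per_helix < 4:
            raise ValueError("need >= 4 residues per helix")


def build_toy_dimer(spec: ToyDimerSpec = ToyDimerSpec()) -> StructuralEnsemble:
    """Build the C2-symmetric receptor dimer as a single-frame ensemble."""
    n_res = spec.helices_per_chain * spec.residues_per_helix
    acidic = set(spec.acidic_site_residues)
    for chain, res in acidic:
        if chain not in ("A", "B"):
            raise ValueError(f"acidic residue chain {chain!r} not in dimer")
        if not (spec.start_res <= res < spec.start_res + n_res):
            raise ValueError(f"acidic residue {res} outside built range")

    def residue_name(chain: str, res_seq: int, j: int) -> str:
        if (chain, res_seq) in acidic:
            return "GLU"
        # hydrophobic stripe: longer Leu side chains supply the tether
        # substrate between helices; everything else is Ala
        return "LEU" if j % spec.residues_per_helix in (2, 5, 9) else "ALA"

    res_specs_a, pos_a = [], []
    for k in range(spec.helices_per_chain):
        ang = 2.0 * math.pi * k / spec.helices_per_chain
        base = np.array([spec.chain_offset + spec.bundle_radius * math.cos(ang),
                         spec.bundle_radius * math.sin(ang), 0.0])
        for j in range(spec.residues_per_helix):
            res_seq = spec.start_res + k * spec.residues_per_helix + j
            res_name = residue_name("A", res_seq, j)
            res_specs_a.append((res_seq, res_name))
            pos_a.append([(nm, el, xyz + base)
                          for nm, el, xyz in _helix_residue(j, res_name)])

    atoms_a = _make_atoms("A", res_specs_a, pos_a, serial_start=1)

    # chain B: exact C2 rotation about z, i.e. (x, y, z) -> (-x, -y, z)
    c2 = np.diag([-1.0, -1.0, 1.0])
    res_specs_b, pos_b = [], []
    for k in range(spec.helices_per_chain):
        ang = 2.0 * math.pi * k / spec.helices_per_chain
        base = np.array([spec.chain_offset + spec.bundle_radius * math.cos(ang),
                         spec.bundle_radius * math.sin(ang), 0.0])
        for j in range(spec.residues_per_helix):
            res_seq = spec.start_res + k * spec.residues_per_helix + j
            res_name = residue_name("B", res_seq, j)
            res_specs_b.append((res_seq, res_name))
            pos_b.append([(nm, el, c2 @ (xyz + base))
                          for nm, el, xyz in _helix_residue(j, res_name)])
    atoms_b = _make_atoms("B", res_specs_b, pos_b,
                          serial_start=atoms_a[-1].serial + 1)

    atoms = atoms_a + atoms_b
    bonds = _bond_by_distance(atoms)
    topology = Topology(atoms, bonds, ligand_chain="P")
    frames = np.array([[a.coords for a in atoms]])
    return StructuralEnsemble(topology, frames, np.array([0.0]))


def build_peptide(sequence: str = "LKRYKRRL", chain_id: str = "P"
                  ) -> StructuralEnsemble:
    """Build the peptide ligand (default: the inhibitory octapeptide
    NOP-1, LKRYKRRL) as a single rigid conformer at the origin.

    The peptide is built on the same ideal-helix backbone generator; the
    internal conformation is a single rigid template (the real peptide is
    predominantly random-coil, and no folding model is attempted).
    """
    res_specs, positions = [], []
    for j, letter in enumerate(sequence):
        res_name = _ONE_TO_THREE[letter.upper()]
        res_specs.append((j + 1, res_name))
        positions.append(_helix_residue(j, res_name))
    atoms = _make_atoms(chain_id, res_specs, positions, serial_start=1)
    bonds = _bond_by_distance(atoms)
    topology = Topology(atoms, bonds, ligand_chain=chain_id)
    frames = np.array([[a.coords for a in atoms]])
    # centre at the origin for clean placement arithmetic
    frames -= frames[0].mean(axis=0)
    atoms = [Atom(a.serial, a.name, a.element, a.chain_id, a.res_name,
                  a.res_seq, frames[0, i], a.mass, a.is_hydrogen)
             for i, a in enumerate(atoms)]
    topology = Topology(atoms, bonds, ligand_chain=chain_id)
    return StructuralEnsemble(topology, frames, np.array([0.0]))


def merge_topologies(receptor: Topology, peptide: Topology) -> Topology:
    """Receptor + ligand topology with contiguous serials (ligand last)."""
    offset = max(a.serial for a in receptor.atoms)
    atoms = list(receptor.atoms)
    for a in peptide.atoms:
        atoms.append(Atom(a.serial + offset, a.name, a.element, a.chain_id,
                          a.res_name, a.res_seq, a.coords, a.mass, a.is_hydrogen))
    bonds = [tuple(b) for b in receptor.covalent_bonds]
    bonds += [tuple(x + offset for x in b) for b in peptide.covalent_bonds]
    return Topology(atoms, bonds, ligand_chain=peptide.ligand_chain)


# ---------------------------------------------------------------------------
# diffusion runs with planted dwell sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSite:
    """One planted binding site.

    ``mode="anchor"``: the peptide dwells outside the receptor with one
    planted hydrogen bond from its ``donor`` atom to the carboxylate of
    ``contact_residue`` — enough for occupancy/propensity/extraction truth
    but mechanically a hinge, so it does not rigidify the receptor.

    ``mode="bridge"``: the peptide lies in the groove between the two
    helices carrying ``contact_residue`` and ``second_contact`` and plants
    seven hydrogen bonds (five peptide-amide donors to backbone carbonyls,
    two receptor amide donors to peptide carbonyls). The double-tied amide
    units merge rigidly into each helix and the single ties lock the
    intervening backbone torsions, so the bound peptide bridges the two
    helices into one rigid cluster — the planted rigidifying effect that
    the perturbation ΔG profile is meant to recover.
    """

    name: str
    contact_residue: tuple[str, int]       # (chain, res_seq)
    donor: tuple[int, str] = (5, "NZ")     # peptide (res_seq, atom_name), anchor mode
    mode: str = "anchor"
    second_contact: tuple[str, int] | None = None   # bridge mode only

    def __post_init__(self):
        if self.mode not in ("anchor", "bridge"):
            raise ValueError(f"unknown site mode {self.mode!r}")
        if self.mode == "bridge" and self.second_contact is None:
            raise ValueError("bridge sites need a second_contact residue")

    def __hash__(self):
        return hash(self.name)


@dataclass(frozen=True)
class DiffusionSpec:
    """Conditions of the synthetic peptide-diffusion trajectories.

    Defaults: 15 independent runs, frames every 0.1 ns. ``dwell_fractions`` maps each site name plus ``"free"`` to its
    stationary occupancy; the per-run state sequence is a sticky Markov
    chain (stay probability ``persistence``, otherwise an independent draw
    from the stationary distribution), so the marginal distribution of every
    frame equals ``dwell_fractions`` exactly.
    """

    sites: tuple[PlantedSite, ...]
    dwell_fractions: dict[str, float]
    n_runs: int = 15
    frames_per_run: int = 2000
    frame_spacing_ns: float = 0.1
    positional_noise_sd: float = 0.75      # Å on the dwelling peptide COM
    receptor_jitter_sd: float = 0.15       # Å per receptor atom per frame
    residue_noise_scale: tuple[tuple[tuple[str, int], float], ...] = ()
    persistence: float = 0.8
    free_shell: tuple[float, float] = (8.0, 40.0)   # Å beyond the surface
    seed: int = 0

    def __post_init__(self):
        names = [s.name for s in self.sites] + ["free"]
        if set(self.dwell_fractions) != set(names):
            raise ValueError("dwell_fractions must cover every site plus 'free'")
        vals = np.array([self.dwell_fractions[n] for n in names])
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("dwell fractions must lie in [0, 1]")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"dwell fractions sum to {vals.sum()}, expected 1")
        if self.positional_noise_sd < 0 or self.receptor_jitter_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0 <= self.persistence < 1:
            raise ValueError("persistence must be in [0, 1)")


def default_diffusion_spec(n_runs: int = 15, frames_per_run: int = 2000,
                           seed: int = 0) -> DiffusionSpec:
    """Three planted sites on the default dimer: two peripheral anchor
    sites on chain B and a dominant bridging site III analogue spanning
    residue 152's helix and the neighbouring helix of chain A."""
    sites = (
        PlantedSite("site_I", contact_residue=("B", 171)),
        PlantedSite("site_II", contact_residue=("B", 152)),
        PlantedSite("site_III", contact_residue=("A", 152), mode="bridge",
                    second_contact=("A", 172)),
    )
    fractions = {"site_I": 0.12, "site_II": 0.18, "site_III": 0.30, "free": 0.40}
    return DiffusionSpec(sites=sites, dwell_fractions=fractions, n_runs=n_runs,
                         frames_per_run=frames_per_run, seed=seed)


def _rotation_from_z(u: np.ndarray) -> np.ndarray:
    """Proper rotation taking the +z axis onto unit vector ``u``."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, u)
    c = float(np.dot(z, u))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _peptide_atom(ptopo: Topology, res_seq: int, name: str) -> int:
    for s in ptopo.residue_index.get((ptopo.ligand_chain, res_seq), []):
        if ptopo.atoms[ptopo.index_of(s)].name == name:
            return ptopo.index_of(s)
    raise PlacementError(f"peptide atom {res_seq}:{name} not found")


def _receptor_atom(rtopo: Topology, chain: str, res_seq: int, name: str) -> int:
    for s in rtopo.residue_index.get((chain, res_seq), []):
        if rtopo.atoms[rtopo.index_of(s)].name == name:
            return rtopo.index_of(s)
    raise PlacementError(f"receptor atom {chain}:{res_seq}:{name} not found")


class _SitePlacement:
    """Pre-computed rigid placement of the peptide at one planted site.

    Each planted hydrogen bond is stored as a snap rule; per frame the
    peptide is rigidly translated (COM noise) and the few bond-forming
    atoms are snapped onto exact linear D-H...A geometry against the
    current (jittered) receptor coordinates, so detection downstream is
    guaranteed and the truth table stays exact.
    """

    def __init__(self, site: PlantedSite, receptor: StructuralEnsemble,
                 peptide: StructuralEnsemble):
        rtopo, rframe = receptor.topology, receptor.frames[0]
        ptopo, pframe = peptide.topology, peptide.frames[0]
        self.site = site
        receptor_com = center_of_mass(rframe, rtopo)

        # snap rules:
        #   ("donor", pep_heavy, [pep_H...], rec_acceptor, u)
        #       pep donor D -> rec acceptor A: D at A + 2.9 u, H1 at A + 1.9 u
        #   ("acceptor", pep_O, rec_N, rec_H)
        #       rec amide donates: pep O at N + 2.9 * unit(H - N)
        self.rules: list[tuple] = []
        nb = ptopo.bond_neighbours()

        def donor_rule(pidx: int, rec_idx: int):
            serial = ptopo.atoms[pidx].serial
            hyds = [ptopo.index_of(s) for s in nb[serial]
                    if ptopo.atoms[ptopo.index_of(s)].is_hydrogen]
            if not hyds:
                raise PlacementError(
                    f"peptide donor {ptopo.atoms[pidx].res_seq}:"
                    f"{ptopo.atoms[pidx].name} carries no hydrogen")
            acc = rframe[rec_idx]
            u = acc - receptor_com
            u = u / np.linalg.norm(u)
            self.rules.append(("donor", pidx, hyds, rec_idx, u))

        if site.mode == "anchor":
            chain, res_seq = site.contact_residue
            acc_idx = None
            for name in ("OE1", "OD1"):
                try:
                    acc_idx = _receptor_atom(rtopo, chain, res_seq, name)
                    break
                except PlacementError:
                    continue
            if acc_idx is None:
                raise PlacementError(
                    f"contact residue {chain}:{res_seq} has no carboxylate "
                    "acceptor")
            donor_rule(_peptide_atom(ptopo, *site.donor), acc_idx)
            # rigid placement: peptide axis along the outward direction with
            # the donor at the ideal H-bond distance; the spin about that
            # axis is chosen to maximise clearance from the receptor, which
            # keeps the dangling peptide body away from every other residue
            u = self.rules[0][4]
            base_rot = _rotation_from_z(u)
            target = rframe[acc_idx] + _HBOND_DA * u
            didx = self.rules[0][1]
            best, best_score = None, -np.inf
            for spin_deg in range(0, 360, 15):
                spin = math.radians(spin_deg)
                cs, sn = math.cos(spin), math.sin(spin)
                spin_z = np.array([[cs, -sn, 0], [sn, cs, 0], [0, 0, 1.0]])
                rotated = pframe @ (base_rot @ spin_z).T
                cand = rotated + (target - rotated[didx])
                score = np.min(np.linalg.norm(
                    cand[:, None, :] - rframe[None, :, :], axis=2))
                if score > best_score:
                    best, best_score = cand, score
            self.placed = best
        else:                                       # bridge
            c1, r1 = site.contact_residue
            c2, r2 = site.second_contact
            # five peptide-amide donors onto backbone carbonyls of the two
            # helices; the end amide units are double-tied through the two
            # receptor-donated bonds below
            for pep_res, (chain, res) in [(2, (c1, r1)), (3, (c1, r1 - 2)),
                                          (4, (c2, r2 - 4)), (5, (c2, r2 - 2)),
                                          (6, (c2, r2))]:
                donor_rule(_peptide_atom(ptopo, pep_res, "N"),
                           _receptor_atom(rtopo, chain, res, "O"))
            for pep_res, (chain, res) in [(1, (c1, r1 + 1)), (5, (c2, r2 + 1))]:
                self.rules.append((
                    "acceptor", _peptide_atom(ptopo, pep_res, "O"),
                    _receptor_atom(rtopo, chain, res, "N"),
                    _receptor_atom(rtopo, chain, res, "H")))
            # rough placement: translate so the bond-forming peptide atoms
            # straddle their targets; snapping does the rest
            pep_pts, targets = [], []
            for rule in self.rules:
                if rule[0] == "donor":
                    _, pidx, _, rec_idx, u = rule
                    pep_pts.append(pframe[pidx])
                    targets.append(rframe[rec_idx] + _HBOND_DA * u)
                else:
                    _, pidx, rec_n, rec_h = rule
                    v = rframe[rec_h] - rframe[rec_n]
                    pep_pts.append(pframe[pidx])
                    targets.append(rframe[rec_n] + _HBOND_DA * v
                                   / np.linalg.norm(v))
            shift = np.mean(targets, axis=0) - np.mean(pep_pts, axis=0)
            self.placed = pframe + shift

        self.placed = self._snap(self.placed, rframe)
        self.center = self.placed.T @ ptopo.masses / ptopo.masses.sum()
        # the contact atom index mapping feeds per-frame re-snapping
        dmin = np.min(np.linalg.norm(rframe - self.center, axis=1))
        if dmin < 1.7:
            raise PlacementError(
                f"site {site.name}: centre lies inside the receptor vdW "
                f"volume (min atom distance {dmin:.2f} Å)")

    def _snap(self, coords: np.ndarray, receptor_frame: np.ndarray
              ) -> np.ndarray:
        coords = coords.copy()
        for rule in self.rules:
            if rule[0] == "donor":
                _, pidx, hyds, rec_idx, u = rule
                acc = receptor_frame[rec_idx]
                shift = acc + _HBOND_DA * u - coords[pidx]
                coords[pidx] += shift
                for hi in hyds:
                    coords[hi] += shift
                coords[hyds[0]] = acc + (_HBOND_DA - _HBOND_DH) * u
            else:
                _, pidx, rec_n, rec_h = rule
                v = receptor_frame[rec_h] - receptor_frame[rec_n]
                coords[pidx] = receptor_frame[rec_n] + \
                    _HBOND_DA * v / np.linalg.norm(v)
        return coords

    def frame_coords(self, rng: np.random.Generator, noise_sd: float,
                     receptor_frame: np.ndarray) -> np.ndarray:
        coords = self.placed.copy()
        if noise_sd > 0:
            coords += rng.normal(0.0, noise_sd, size=3)
        return self._snap(coords, receptor_frame)


def simulate_diffusion_runs(receptor: StructuralEnsemble,
                            peptide: StructuralEnsemble,
                            spec: DiffusionSpec
                            ) -> tuple[list[StructuralEnsemble], pd.DataFrame]:
    """Generate ``spec.n_runs`` complex trajectories plus the truth table.

    In every frame the peptide either dwells at a planted site (rigid
    placement with Gaussian COM noise and an exact planted hydrogen bond to
    the site's contact carboxylate) or diffuses freely in a shell at least
    8 Å away from the receptor surface. Returns the ensembles and a
    DataFrame with columns run, frame, time_ns, state.
    """
    rtopo, rframe0 = receptor.topology, receptor.frames[0]
    ptopo = peptide.topology
    complex_topo = merge_topologies(rtopo, ptopo)
    placements = {s.name: _SitePlacement(s, receptor, peptide) for s in spec.sites}

    state_names = [s.name for s in spec.sites] + ["free"]
    probs = np.array([spec.dwell_fractions[n] for n in state_names])

    receptor_com = center_of_mass(rframe0, rtopo)
    rel = rframe0 - receptor_com
    peptide_radius = float(np.max(np.linalg.norm(peptide.frames[0], axis=1)))

    jitter_scale = np.ones(rtopo.n_atoms)
    for (chain, res_seq), factor in dict(spec.residue_noise_scale).items():
        for s in rtopo.residue_index.get((chain, res_seq), []):
            jitter_scale[rtopo.index_of(s)] = factor

    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_runs)
    runs: list[StructuralEnsemble] = []
    records: list[tuple[int, int, float, str]] = []
    n_rec, n_pep = rtopo.n_atoms, ptopo.n_atoms
    times = spec.frame_spacing_ns * (np.arange(spec.frames_per_run) + 1)

    for run_id, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        # sticky Markov chain over dwell states, stationary == dwell_fractions
        states = np.empty(spec.frames_per_run, dtype=int)
        states[0] = rng.choice(len(state_names), p=probs)
        stay = rng.random(spec.frames_per_run)
        redraw = rng.choice(len(state_names), p=probs, size=spec.frames_per_run)
        for t in range(1, spec.frames_per_run):
            states[t] = states[t - 1] if stay[t] < spec.persistence else redraw[t]

        frames = np.empty((spec.frames_per_run, n_rec + n_pep, 3))
        for t in range(spec.frames_per_run):
            rec = rframe0 + (rng.normal(0.0, spec.receptor_jitter_sd,
                                        size=(n_rec, 3)) * jitter_scale[:, None]
                             if spec.receptor_jitter_sd > 0 else 0.0)
            name = state_names[states[t]]
            if name == "free":
                omega = rng.normal(size=3)
                omega /= np.linalg.norm(omega)
                support = float(np.max(rel @ omega))
                lo, hi = spec.free_shell
                r = support + peptide_radius + lo + rng.uniform(0.0, hi - lo)
                rot = _random_rotation(rng)
                pep = peptide.frames[0] @ rot.T + receptor_com + r * omega
            else:
                pep = placements[name].frame_coords(
                    rng, spec.positional_noise_sd, rec)
            frames[t, :n_rec] = rec
            frames[t, n_rec:] = pep
            records.append((run_id, t, float(times[t]), name))
        runs.append(StructuralEnsemble(complex_topo, frames, times,
                                       source_run=run_id))

    truth = pd.DataFrame(records, columns=["run", "frame", "time_ns", "state"])
    return runs, truth


def simulate_apo_runs(receptor: StructuralEnsemble, n_runs: int,
                      frames_per_run: int, receptor_jitter_sd: float = 0.15,
                      residue_noise_scale: dict[tuple[str, int], float] | None = None,
                      frame_spacing_ns: float = 0.1,
                      seed: int = 0) -> list[StructuralEnsemble]:
    """Receptor-only trajectories (Gaussian positional jitter, no ligand)."""
    rtopo, rframe0 = receptor.topology, receptor.frames[0]
    scale = np.ones(rtopo.n_atoms)
    for (chain, res_seq), factor in (residue_noise_scale or {}).items():
        for s in rtopo.residue_index.get((chain, res_seq), []):
            scale[rtopo.index_of(s)] = factor
    seeds = np.random.SeedSequence(seed).spawn(n_runs)
    times = frame_spacing_ns * (np.arange(frames_per_run) + 1)
    runs = []
    for run_id, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        jitter = rng.normal(0.0, receptor_jitter_sd,
                            size=(frames_per_run, rtopo.n_atoms, 3))
        frames = rframe0[None] + jitter * scale[None, :, None]
        runs.append(StructuralEnsemble(rtopo, frames, times, source_run=run_id))
    return runs


# ---------------------------------------------------------------------------
# synthetic binding isotherms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsothermDesign:
    """A serial-dilution thermophoresis titration with a one-site ground
    truth. Concentrations in nM; the labelled-protein concentration default
    (25 nM) matches the thermophoresis assay this emulates, where depletion of the free ligand is
    not negligible against the measured dissociation constants."""

    protein_conc: float = 25.0
    kd_true: float = 88.0
    amplitude_true: float = 0.02
    offset_true: float = 0.0
    dilution_points: int = 16
    top_conc: float = 10000.0
    replicates: int = 3
    noise_sd: float = 0.05          # fraction of |amplitude_true|
    noise_sd_absolute: float | None = None   # overrides the fractional sd
    seed: int = 0

    def __post_init__(self):
        if self.protein_conc <= 0 or self.kd_true <= 0:
            raise ValueError("protein_conc and kd_true must be > 0")
        if self.dilution_points < 2 or self.top_conc <= 0:
            raise ValueError("need a strictly decreasing dilution series")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_isotherm(design: IsothermDesign):
    """Synthesise an :class:`~peptisite.mst.Isotherm` from the one-site
    depletion model plus Gaussian noise; returns (isotherm, truth dict)."""
    from .mst import Isotherm, fraction_bound

    rng = np.random.default_rng(design.seed)
    conc = design.top_conc * 2.0 ** (-np.arange(design.dilution_points))
    fb = fraction_bound(conc, design.kd_true, design.protein_conc)
    clean = design.offset_true + design.amplitude_true * fb
    sd = (design.noise_sd_absolute if design.noise_sd_absolute is not None
          else design.noise_sd * abs(design.amplitude_true))
    rows = []
    for rep in range(design.replicates):
        noisy = clean + (rng.normal(0.0, sd, size=conc.size) if sd > 0 else 0.0)
        for c, y in zip(conc, noisy):
            rows.append((float(c), float(y), rep))
    points = pd.DataFrame(rows, columns=["conc_nM", "delta_fnorm", "replicate"])
    truth = {"kd": design.kd_true, "amplitude": design.amplitude_true,
             "offset": design.offset_true, "protein_conc": design.protein_conc}
    return Isotherm(points=points, protein_conc=design.protein_conc), truth
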