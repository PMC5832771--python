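"""Geometric hydrogen-bond / salt-bridge detection between the peptide
ligand (donor side) and the receptor (acceptor side).

The direction of the criterion is fixed by the analysis design: the peptide
is the donor molecule and the receptor the acceptor molecule. Defaults are
the standard geometric criteria (donor-acceptor <= 3.5 Å with a D-H...A
angle >= 135°; charged side-chain N to carboxylate O <= 4.0 Å for salt
bridges); all values are configuration-exposed. Topologies without
hydrogens can opt into a heavy-atom-only fallback (distance criterion
alone).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import TopologyError
from .structures import (BASIC_NITROGENS, CARBOXYLATE_OXYGENS,
                         StructuralEnsemble, Topology)


@dataclass(frozen=True)
class HBondCriterion:
    da_cutoff: float = 3.5            # Å, donor-acceptor distance
    dha_min_angle: float = 135.0      # degrees, D-H...A at the hydrogen
    saltbridge_cutoff: float = 4.0    # Å, charged N ... carboxylate O
    heavy_only_fallback: bool = False

    def __post_init__(self):
        if self.da_cutoff <= 0 or self.saltbridge_cutoff <= 0:
            raise ValueError("distance cutoffs must be > 0")
        if not 0 < self.dha_min_angle <= 180:
            raise ValueError("dha_min_angle must be in (0, 180]")


class ContactDetector:
    """Pre-indexed ligand-donor / receptor-acceptor contact detection.

    Built once per topology; :meth:`contact_residues` then maps a coordinate
    frame to the set of receptor residues contacted in that frame.
    """

    def __init__(self, topology: Topology, criterion: HBondCriterion):
        self.topology = topology
        self.criterion = criterion
        ligand = topology.ligand_chain
        nb = topology.bond_neighbours()

        donors = []          # (donor_index, [hydrogen indices])
        basic_n = []         # charged side-chain N indices (salt bridges)
        for i, a in enumerate(topology.atoms):
            if a.chain_id != ligand:
                continue
            if a.element in ("N", "O"):
                hyds = [topology.index_of(s) for s in nb[a.serial]
                        if topology.atoms[topology.index_of(s)].is_hydrogen]
                if hyds:
                    donors.append((i, hyds))
                elif criterion.heavy_only_fallback:
                    donors.append((i, []))
            if a.element == "N" and a.name in BASIC_NITROGENS:
                basic_n.append(i)

        has_ligand_h = any(a.is_hydrogen for a in topology.atoms
                           if a.chain_id == ligand)
        if not has_ligand_h and not criterion.heavy_only_fallback:
            raise TopologyError(
                "ligand topology has no hydrogens; enable heavy_only_fallback "
                "to use the distance-only criterion")

        acceptors = []       # receptor O (and S) acceptor indices
        carboxylate = []
        for i, a in enumerate(topology.atoms):
            if a.chain_id == ligand:
                continue
            if a.element in ("O", "S"):
                acceptors.append(i)
                if a.name in CARBOXYLATE_OXYGENS:
                    carboxylate.append(i)

        self.donors = donors
        self.basic_nitrogens = np.array(basic_n, dtype=int)
        self.acceptors = np.array(acceptors, dtype=int)
        self.carboxylate = np.array(carboxylate, dtype=int)
        self._acceptor_residue = [
            (topology.atoms[i].chain_id, topology.atoms[i].res_seq)
            for i in acceptors]
        self._carboxylate_residue = [
            (topology.atoms[i].chain_id, topology.atoms[i].res_seq)
            for i in carboxylate]

    def contact_residues(self, frame: np.ndarray) -> set[tuple[str, int]]:
        """Receptor residues with >= 1 H-bond or salt bridge in ``frame``."""
        crit = self.criterion
        found: set[tuple[str, int]] = set()
        if self.acceptors.size:
            acc = frame[self.acceptors]
            for di, hyds in self.donors:
                d = frame[di]
                dist = np.linalg.norm(acc - d, axis=1)
                close = np.where(dist <= crit.da_cutoff)[0]
                if close.size == 0:
                    continue
                if not hyds:          # heavy-only fallback donor
                    found.update(self._acceptor_residue[k] for k in close)
                    continue
                for k in close:
                    a = acc[k]
                    for hi in hyds:
                        h = frame[hi]
                        v1, v2 = d - h, a - h
                        cosang = np.dot(v1, v2) / (
                            np.linalg.norm(v1) * np.linalg.norm(v2))
                        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                        if angle >= crit.dha_min_angle:
                            found.add(self._acceptor_residue[k])
                            break
        if self.basic_nitrogens.size and self.carboxylate.size:
            nz = frame[self.basic_nitrogens]
            ox = frame[self.carboxylate]
            dist = np.linalg.norm(nz[:, None, :] - ox[None, :, :], axis=2)
            for k in np.unique(np.where(dist <= crit.saltbridge_cutoff)[1]):
                found.add(self._carboxylate_residue[k])
        return found
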