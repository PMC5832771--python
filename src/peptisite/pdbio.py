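"""Multi-model PDB reading and writing.

Parsing and formatting of ATOM/CONECT records is delegated to biotite; this
module adds the ensemble-level contract on top: one frame per MODEL, shared
atom ordering across models (violations are reported naming the model),
frame times carried in per-model ``REMARK 250 TIME_NS`` lines (0.1 ns
spacing is assumed when absent, matching trajectory snapshots saved every
100 ps), and covalent bonds reconstructed from CONECT records plus
standard-residue templates.
"""

from __future__ import annotations

import re

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import PDBFormatError, TopologyError
from .structures import Atom, StructuralEnsemble, Topology, mass_of

DEFAULT_FRAME_SPACING_NS = 0.1

_TIME_REMARK = re.compile(r"^REMARK 250 TIME_NS\s+([-0-9.eE+]+)")

#: largest coordinate representable in the fixed-width %8.3f PDB field
_COORD_LIMIT = 9999.999


def _prescan(lines: list[str]) -> tuple[list[int], list[float]]:
    """Per-model atom counts and REMARK-carried times from raw PDB lines."""
    counts: list[int] = []
    times: list[float] = []
    current = 0
    in_model = False
    saw_model = False
    for line in lines:
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            in_model = True
            current = 0
        elif rec == "ENDMDL":
            counts.append(current)
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            current += 1
        m = _TIME_REMARK.match(line)
        if m:
            times.append(float(m.group(1)))
    if not saw_model:
        # single implicit model
        counts = [current]
    elif in_model:
        counts.append(current)
    return counts, times


def read_multimodel_pdb(path, ligand_chain: str = "P") -> StructuralEnsemble:
    """Read a multi-model PDB file into a :class:`StructuralEnsemble`.

    Every MODEL becomes one frame; all models must share the atom ordering.
    Times default to 0.1 ns spacing unless ``REMARK 250 TIME_NS`` lines
    (one per model) provide them.
    """
    pdb_file = PDBFile.read(str(path))
    counts, remark_times = _prescan(pdb_file.lines)
    if not counts or counts[0] == 0:
        raise PDBFormatError(f"{path}: no atoms found")
    for k, n in enumerate(counts, start=1):
        if n != counts[0]:
            raise PDBFormatError(f"model {k}: atom count {n} ≠ {counts[0]}")

    structure = pdb_file.get_structure(model=None, include_bonds=True)
    frames = np.asarray(structure.coord, dtype=float)

    atoms = []
    for i in range(structure.array_length()):
        element = str(structure.element[i]).upper()
        atoms.append(Atom(
            serial=i + 1,
            name=str(structure.atom_name[i]),
            element=element,
            chain_id=str(structure.chain_id[i]),
            res_name=str(structure.res_name[i]),
            res_seq=int(structure.res_id[i]),
            coords=frames[0, i],
            mass=mass_of(element),
            is_hydrogen=element == "H",
        ))

    bonds = []
    if structure.bonds is not None:
        for i, j, _ in structure.bonds.as_array():
            bonds.append((int(i) + 1, int(j) + 1))
    topology = Topology(atoms, bonds, ligand_chain=ligand_chain)

    # A residue with several atoms but no bond at all means biotite knew no
    # template for it and the file carried no CONECT records.
    bonded = set()
    for b in topology.covalent_bonds:
        bonded.update(b)
    for (chain, res_seq), serials in topology.residue_index.items():
        if len(serials) > 1 and not any(s in bonded for s in serials):
            res_name = topology.atoms[topology.index_of(serials[0])].res_name
            raise TopologyError(
                f"unknown residue {res_name} {chain}:{res_seq} without CONECT records")

    n_frames = frames.shape[0]
    if len(remark_times) == n_frames:
        times = np.asarray(remark_times, dtype=float)
    else:
        times = DEFAULT_FRAME_SPACING_NS * np.arange(n_frames)
    return StructuralEnsemble(topology, frames, times)


def write_multimodel_pdb(ensemble: StructuralEnsemble, path) -> None:
    """Write a standard multi-model PDB (MODEL/ENDMDL per frame).

    Frame times are stored as ``REMARK 250 TIME_NS`` lines after each MODEL
    record so that a round trip preserves them.
    """
    if np.any(np.abs(ensemble.frames) > _COORD_LIMIT):
        raise PDBFormatError("coordinate out of PDB field range (|x| > 9999.999 Å)")
    topo = ensemble.topology
    n = topo.n_atoms
    t = ensemble.n_frames

    array = struc.AtomArrayStack(t, n)
    array.coord = np.asarray(ensemble.frames, dtype=np.float32)
    array.chain_id = np.array([a.chain_id for a in topo.atoms], dtype="U4")
    array.res_id = np.array([a.res_seq for a in topo.atoms], dtype=int)
    array.res_name = np.array([a.res_name for a in topo.atoms], dtype="U5")
    array.atom_name = np.array([a.name for a in topo.atoms], dtype="U6")
    array.element = np.array([a.element for a in topo.atoms], dtype="U2")
    array.hetero = np.zeros(n, dtype=bool)
    if topo.covalent_bonds:
        bond_array = np.array(
            [[topo.index_of(x) for x in sorted(b)] + [struc.BondType.SINGLE]
             for b in sorted(topo.covalent_bonds, key=sorted)], dtype=np.uint32)
        array.bonds = struc.BondList(n, bond_array)

    pdb_file = PDBFile()
    pdb_file.set_structure(array)
    lines = list(pdb_file.lines)
    out_lines: list[str] = []
    frame = 0
    for line in lines:
        out_lines.append(line)
        if line[:6].strip() == "MODEL":
            out_lines.append(f"REMARK 250 TIME_NS {ensemble.times[frame]:.6f}")
            frame += 1
    if frame == 0 and t == 1:
        # biotite writes single-model stacks with MODEL records as well, but
        # guard the implicit-model case anyway
        out_lines.insert(0, f"REMARK 250 TIME_NS {ensemble.times[0]:.6f}")
    pdb_file.lines = out_lines
    pdb_file.write(str(path))
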