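"""Atomic data model and geometric primitives.

The unit of analysis everywhere in this package is a :class:`StructuralEnsemble`:
a fixed atomic :class:`Topology` (receptor dimer plus, optionally, a peptide
ligand chain) together with ``T`` coordinate frames and their times in ns.
This module also provides the geometric primitives shared by every downstream
stage: Kabsch superposition, mass-weighted centres of mass, and per-residue
Cα root-mean-square fluctuations (RMSF).

Conventions: coordinates in Å, times in ns, residue numbering 1-based as in
the PDB, receptor chains "A"/"B", peptide chain "P", masses in Da.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import SelectionError, TopologyError

# Standard atomic masses (Da) for the elements that occur in protein models.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}

BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O", "H", "HA", "OXT", "H1", "H2", "H3"})

#: atom names of side-chain carboxylate oxygens (salt-bridge acceptors)
CARBOXYLATE_OXYGENS = frozenset({"OE1", "OE2", "OD1", "OD2"})

#: atom names of charged side-chain nitrogens (salt-bridge donors)
BASIC_NITROGENS = frozenset({"NZ", "NH1", "NH2", "NE"})


def mass_of(element: str) -> float:
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError as exc:
        raise TopologyError(f"no standard mass for element {element!r}") from exc


@dataclass(frozen=True)
class Atom:
    """A single atom of the fixed topology.

    ``coords`` holds the reference-frame (frame 0) position; per-frame
    positions live in :attr:`StructuralEnsemble.frames`.
    """

    serial: int
    name: str
    element: str
    chain_id: str
    res_name: str
    res_seq: int
    coords: np.ndarray
    mass: float
    is_hydrogen: bool

    def __post_init__(self):
        if self.serial <= 0:
            raise TopologyError(f"atom serial must be positive, got {self.serial}")
        if self.mass <= 0:
            raise TopologyError(f"atom {self.serial}: mass must be > 0")
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise TopologyError(f"atom {self.serial}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)


class Topology:
    """Ordered atom list, covalent bonds, and residue bookkeeping.

    Parameters
    ----------
    atoms:
        Ordered atoms; serials must be unique.
    covalent_bonds:
        Unordered pairs of atom serials.
    ligand_chain:
        Chain id designating the peptide ligand ("P" by convention).
    """

    def __init__(self, atoms: Sequence[Atom], covalent_bonds: Iterable[tuple[int, int]],
                 ligand_chain: str = "P"):
        self.atoms: list[Atom] = list(atoms)
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise TopologyError("atom serials are not unique")
        self._index_of_serial = {s: i for i, s in enumerate(serials)}
        bonds = set()
        for a, b in covalent_bonds:
            if a not in self._index_of_serial or b not in self._index_of_serial:
                raise TopologyError(f"bond ({a}, {b}) references unknown atom serial")
            if a == b:
                raise TopologyError(f"self-bond on atom {a}")
            bonds.add(frozenset((a, b)))
        self.covalent_bonds: set[frozenset[int]] = bonds
        self.ligand_chain = ligand_chain

        self.residue_index: dict[tuple[str, int], list[int]] = {}
        for a in self.atoms:
            self.residue_index.setdefault((a.chain_id, a.res_seq), []).append(a.serial)

    # -- basic queries -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def index_of(self, serial: int) -> int:
        return self._index_of_serial[serial]

    @property
    def serials(self) -> np.ndarray:
        return np.array([a.serial for a in self.atoms], dtype=int)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def has_hydrogens(self) -> bool:
        return any(a.is_hydrogen for a in self.atoms)

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def ligand_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms)
                         if a.chain_id == self.ligand_chain], dtype=int)

    def receptor_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms)
                         if a.chain_id != self.ligand_chain], dtype=int)

    def bonded_to(self, serial: int) -> list[int]:
        out = []
        for b in self.covalent_bonds:
            if serial in b:
                (x,) = set(b) - {serial}
                out.append(x)
        return sorted(out)

    def bond_neighbours(self) -> dict[int, list[int]]:
        """Serial -> sorted list of covalently bonded serials (precomputed)."""
        nb: dict[int, list[int]] = {a.serial: [] for a in self.atoms}
        for b in self.covalent_bonds:
            x, y = tuple(b)
            nb[x].append(y)
            nb[y].append(x)
        return {k: sorted(v) for k, v in nb.items()}

    def residues(self, chain_id: str | None = None) -> list[tuple[str, int, str]]:
        """(chain, res_seq, res_name) in order of first appearance."""
        out, seen = [], set()
        for a in self.atoms:
            key = (a.chain_id, a.res_seq)
            if key in seen:
                continue
            if chain_id is not None and a.chain_id != chain_id:
                continue
            seen.add(key)
            out.append((a.chain_id, a.res_seq, a.res_name))
        return out


@dataclass(frozen=True)
class Selection:
    """Declarative atom selection; ``None`` fields match everything.

    An empty resolution is reportable (returns a zero-length index array),
    not a crash; operations that cannot proceed on an empty selection raise
    :class:`~peptisite.errors.SelectionError` themselves.
    """

    chain_ids: frozenset[str] | None = None
    res_seq_ranges: tuple[tuple[int, int], ...] | None = None
    atom_names: frozenset[str] | None = None

    @classmethod
    def make(cls, chain_ids=None, res_seq_ranges=None, atom_names=None) -> "Selection":
        return cls(
            chain_ids=None if chain_ids is None else frozenset(chain_ids),
            res_seq_ranges=None if res_seq_ranges is None
            else tuple((int(a), int(b)) for a, b in res_seq_ranges),
            atom_names=None if atom_names is None else frozenset(atom_names),
        )

    def resolve(self, topology: Topology) -> np.ndarray:
        idx = []
        for i, a in enumerate(topology.atoms):
            if self.chain_ids is not None and a.chain_id not in self.chain_ids:
                continue
            if self.res_seq_ranges is not None and not any(
                    lo <= a.res_seq <= hi for lo, hi in self.res_seq_ranges):
                continue
            if self.atom_names is not None and a.name not in self.atom_names:
                continue
            idx.append(i)
        return np.array(idx, dtype=int)


def receptor_calpha_selection(topology: Topology) -> Selection:
    """Default superposition fit selection: receptor Cα atoms only."""
    chains = [c for c in topology.chain_ids() if c != topology.ligand_chain]
    return Selection.make(chain_ids=chains, atom_names=["CA"])


@dataclass
class FluctuationProfile:
    """Per-residue Cα RMSF in Å."""

    entries: list[tuple[str, int, float]]

    def __post_init__(self):
        for chain, res, rmsf in self.entries:
            if rmsf < 0:
                raise ValueError(f"negative RMSF for {chain}:{res}")

    def as_dict(self) -> dict[tuple[str, int], float]:
        return {(c, r): v for c, r, v in self.entries}


class StructuralEnsemble:
    """Fixed topology + T coordinate frames with strictly increasing times."""

    def __init__(self, topology: Topology, frames: np.ndarray, times: np.ndarray,
                 source_run: int = 0):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        times = np.atleast_1d(np.asarray(times, dtype=float))
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise ValueError("frames must have shape (T, N, 3)")
        if frames.shape[1] != topology.n_atoms:
            raise ValueError(
                f"frame atom count {frames.shape[1]} != topology atom count "
                f"{topology.n_atoms}")
        if frames.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if times.shape[0] != frames.shape[0]:
            raise ValueError("times length must equal frame count")
        if times[0] < 0:
            raise ValueError("times must start at >= 0 ns")
        if times.shape[0] > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        self.topology = topology
        self.frames = frames
        self.times = times
        self.source_run = int(source_run)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame(self, t: int) -> np.ndarray:
        return self.frames[t]


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     fit_indices: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd_fit)`` such that
    ``mobile @ rotation.T + translation`` minimises the RMSD over the fit
    atoms. The rotation is proper (det = +1); reflections are excluded, as
    required for chiral molecules.

    Raises
    ------
    SelectionError
        If fewer than 3 fit atoms are given or the fit atoms are collinear.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit_indices is None:
        m, r = mobile, reference
    else:
        fit_indices = np.asarray(fit_indices, dtype=int)
        m, r = mobile[fit_indices], reference[fit_indices]
    if m.shape[0] < 3:
        raise SelectionError(
            f"superposition needs >= 3 fit atoms, got {m.shape[0]}")
    mc, rc = m.mean(axis=0), r.mean(axis=0)
    dm, dr = m - mc, r - rc
    # collinearity check: rank of the centred fit coordinates must be >= 2
    if np.linalg.matrix_rank(dm, tol=1e-8) < 2 or np.linalg.matrix_rank(dr, tol=1e-8) < 2:
        raise SelectionError("superposition fit atoms are collinear")
    h = dm.T @ dr
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rotation = vt.T @ flip @ u.T
    translation = rc - rotation @ mc
    fitted = dm @ rotation.T + rc
    rmsd_fit = float(np.sqrt(np.mean(np.sum((fitted - r) ** 2, axis=1))))
    return rotation, translation, rmsd_fit


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return coords @ rotation.T + translation


def superpose_frames(frames: np.ndarray, reference: np.ndarray,
                     fit_indices: np.ndarray) -> np.ndarray:
    """Superpose every frame onto ``reference`` over ``fit_indices``."""
    out = np.empty_like(frames)
    for t in range(frames.shape[0]):
        rot, trans, _ = kabsch_superpose(frames[t], reference, fit_indices)
        out[t] = apply_transform(frames[t], rot, trans)
    return out


def center_of_mass(frame: np.ndarray, topology: Topology,
                   selection: Selection | np.ndarray | None = None) -> np.ndarray:
    """Mass-weighted mean position of the selected atoms in one frame."""
    if selection is None:
        idx = np.arange(topology.n_atoms)
    elif isinstance(selection, Selection):
        idx = selection.resolve(topology)
    else:
        idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise SelectionError("center_of_mass: empty selection")
    masses = topology.masses[idx]
    return np.asarray(frame)[idx].T @ masses / masses.sum()


def rmsf_calpha(ensemble: StructuralEnsemble, reference_frame: int = 0,
                fit_selection: Selection | None = None) -> FluctuationProfile:
    """Per-residue Cα RMSF after superposing every frame onto the reference.

    RMSF_i = sqrt(mean_t |x_i(t) - <x_i>|^2) for each Cα atom i, computed
    after a rigid superposition of each frame onto ``frames[reference_frame]``
    over ``fit_selection`` (default: receptor Cα atoms).
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF is undefined for fewer than 2 frames")
    topo = ensemble.topology
    if fit_selection is None:
        fit_selection = receptor_calpha_selection(topo)
    fit_idx = fit_selection.resolve(topo)
    if fit_idx.size < 3:
        raise SelectionError("RMSF fit selection resolves to fewer than 3 atoms")
    ca_idx = Selection.make(atom_names=["CA"]).resolve(topo)
    if ca_idx.size == 0:
        raise SelectionError("ensemble has no CA atoms")
    fitted = superpose_frames(ensemble.frames, ensemble.frames[reference_frame], fit_idx)
    ca = fitted[:, ca_idx, :]
    mean = ca.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((ca - mean) ** 2, axis=2), axis=0))
    entries = []
    for k, i in enumerate(ca_idx):
        a = topo.atoms[i]
        entries.append((a.chain_id, a.res_seq, float(rmsf[k])))
    return FluctuationProfile(entries)
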