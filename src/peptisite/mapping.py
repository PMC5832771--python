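"""Binding-site mapping from trajectory ensembles.

Three views of where the peptide binds the receptor dimer:

* an occupancy grid of the ligand centre of mass over a time window (the
  convergence evidence: occupied bins concentrate at the binding sites as
  the window grows),
* per-residue hydrogen-bond/salt-bridge propensities (fraction of frames
  with at least one contact, optionally averaged over the two homologous
  chains of the dimer),
* the bound-state sub-ensemble: frames, sampled on a stride, in which the
  peptide hydrogen-bonds one of a set of anchor residues,
* a bound-versus-apo Cα RMSF comparison.

All frames are superposed onto a common reference over the receptor Cα
atoms before any spatial binning, so ligand positions live in the receptor
frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SelectionError
from .hbonds import ContactDetector, HBondCriterion
from .structures import (Selection, StructuralEnsemble, Topology,
                         center_of_mass, kabsch_superpose, apply_transform,
                         receptor_calpha_selection, rmsf_calpha)

DEFAULT_BIN_EDGE = 3.0   # Å, cubic occupancy bins
DEFAULT_STRIDE_NS = 2.0  # network/bound-frame sampling stride


@dataclass
class OccupancyGrid:
    """3-D histogram of ligand centre-of-mass positions (cubic bins,
    half-open intervals [origin + k*edge, origin + (k+1)*edge))."""

    origin: np.ndarray
    bin_edge: float
    counts: np.ndarray           # integer array, shape = grid shape
    window_end_ns: float

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def bin_center(self, index: tuple[int, int, int]) -> np.ndarray:
        return self.origin + (np.asarray(index) + 0.5) * self.bin_edge


def _superposed_ligand_coms(runs: list[StructuralEnsemble],
                            reference: np.ndarray,
                            window_end_ns: float | None = None) -> np.ndarray:
    """Ligand COM of every in-window frame, in the reference receptor frame."""
    coms = []
    for run in runs:
        topo = run.topology
        fit_idx = receptor_calpha_selection(topo).resolve(topo)
        lig_idx = topo.ligand_indices()
        if lig_idx.size == 0:
            raise SelectionError("run has no ligand chain")
        masses = topo.masses[lig_idx]
        for t in range(run.n_frames):
            if window_end_ns is not None and run.times[t] > window_end_ns:
                continue
            rot, trans, _ = kabsch_superpose(run.frames[t], reference, fit_idx)
            lig = apply_transform(run.frames[t][lig_idx], rot, trans)
            coms.append(lig.T @ masses / masses.sum())
    return np.array(coms).reshape(-1, 3)


def occupancy_grid(runs: list[StructuralEnsemble], window_end_ns: float,
                   bin_edge: float = DEFAULT_BIN_EDGE,
                   reference: np.ndarray | None = None) -> OccupancyGrid:
    """Bin the ligand COM of all frames with time <= ``window_end_ns``.

    The grid spans the bounding box of the contributing COMs plus one bin of
    margin. The count sum equals the number of contributing frames.
    """
    if window_end_ns <= 0:
        raise ValueError("window_end_ns must be > 0")
    if reference is None:
        reference = runs[0].frames[0]
    coms = _superposed_ligand_coms(runs, reference, window_end_ns)
    if coms.shape[0] == 0:
        warnings.warn("no frames fall inside the requested window; empty grid")
        return OccupancyGrid(origin=np.zeros(3), bin_edge=bin_edge,
                             counts=np.zeros((1, 1, 1), dtype=int),
                             window_end_ns=window_end_ns)
    origin = np.floor(coms.min(axis=0) / bin_edge) * bin_edge - bin_edge
    shape = np.floor((coms.max(axis=0) - origin) / bin_edge).astype(int) + 2
    counts = np.zeros(tuple(shape), dtype=int)
    idx = np.floor((coms - origin) / bin_edge).astype(int)
    np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1)
    return OccupancyGrid(origin=origin, bin_edge=bin_edge, counts=counts,
                         window_end_ns=window_end_ns)


def top_sites(grid: OccupancyGrid, k: int = 3, min_separation: float = 6.0
              ) -> list[tuple[np.ndarray, int]]:
    """Greedy selection of the ``k`` highest-count bins, suppressing bins
    closer than ``min_separation`` to an already selected site. Ties break
    by lexicographic bin index."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if grid.total == 0:
        raise ValueError("occupancy grid is empty")
    # descending count, ties by lexicographic bin index
    indices = [np.unravel_index(i, grid.shape) for i in range(grid.counts.size)]
    order = sorted(range(grid.counts.size),
                   key=lambda i: (-grid.counts[indices[i]], indices[i]))
    sites: list[tuple[np.ndarray, int]] = []
    for i in order:
        count = int(grid.counts[indices[i]])
        if count == 0 or len(sites) == k:
            break
        center = grid.bin_center(indices[i])
        if any(np.linalg.norm(center - c) < min_separation for c, _ in sites):
            continue
        sites.append((center, count))
    return sites


@dataclass
class PropensityTable:
    """Per-residue fraction of frames with >= 1 H-bond/salt bridge to the
    peptide."""

    entries: pd.DataFrame     # chain_id, res_seq, res_name, propensity
    averaged_over_chains: bool

    def get(self, chain: str, res_seq: int) -> float:
        df = self.entries
        row = df[(df.chain_id == chain) & (df.res_seq == res_seq)]
        return float(row.propensity.iloc[0]) if len(row) else 0.0


def hbond_saltbridge_propensity(runs: list[StructuralEnsemble],
                                criterion: HBondCriterion = HBondCriterion(),
                                average_chains: bool = False) -> PropensityTable:
    """Fraction of all frames (pooled over runs) in which each receptor
    residue accepts >= 1 hydrogen bond or salt bridge from the peptide.

    With ``average_chains`` the homologous residues of chains A and B
    (matched by residue number) are averaged and reported once.
    """
    topo = runs[0].topology
    detector = ContactDetector(topo, criterion)
    residues = topo.residues()
    receptor_residues = [(c, r, n) for c, r, n in residues
                         if c != topo.ligand_chain]
    hits = {(c, r): 0 for c, r, _ in receptor_residues}
    total = 0
    for run in runs:
        for t in range(run.n_frames):
            total += 1
            for key in detector.contact_residues(run.frames[t]):
                hits[key] += 1
    if total == 0:
        raise ValueError("no frames supplied")

    rows = []
    if average_chains:
        chains = sorted({c for c, _, _ in receptor_residues})
        by_res: dict[int, list[tuple[str, str]]] = {}
        for c, r, n in receptor_residues:
            by_res.setdefault(r, []).append((c, n))
        for r in sorted(by_res):
            members = by_res[r]
            prop = float(np.mean([hits[(c, r)] / total for c, _ in members]))
            rows.append(("+".join(sorted(c for c, _ in members)), r,
                         members[0][1], prop))
    else:
        for c, r, n in receptor_residues:
            rows.append((c, r, n, hits[(c, r)] / total))
    entries = pd.DataFrame(rows, columns=["chain_id", "res_seq", "res_name",
                                          "propensity"])
    return PropensityTable(entries=entries, averaged_over_chains=average_chains)


def extract_bound_frames(runs: list[StructuralEnsemble],
                         anchor_residues: list[tuple[str, int]],
                         criterion: HBondCriterion = HBondCriterion(),
                         stride_ns: float = DEFAULT_STRIDE_NS
                         ) -> tuple[StructuralEnsemble | None,
                                    list[tuple[int, int]]]:
    """Bound-state sub-ensemble: frames sampled every ``stride_ns`` whose
    ligand hydrogen-bonds at least one anchor residue (OR over anchors).

    Returns the concatenated ensemble (None if no frame qualifies) and the
    (run, frame) provenance list.
    """
    topo = runs[0].topology
    for chain, res in anchor_residues:
        if (chain, res) not in topo.residue_index:
            raise SelectionError(f"anchor residue {chain}:{res} not in topology")
    spacing = float(runs[0].times[1] - runs[0].times[0]) \
        if runs[0].n_frames > 1 else stride_ns
    if stride_ns < spacing - 1e-9:
        raise ValueError(
            f"stride {stride_ns} ns is smaller than the frame spacing "
            f"{spacing} ns")
    anchors = set(anchor_residues)
    detector = ContactDetector(topo, criterion)
    frames, times, provenance = [], [], []
    for run in runs:
        for t in range(run.n_frames):
            # strided sampling on the time axis
            phase = run.times[t] / stride_ns
            if abs(phase - round(phase)) > 1e-6:
                continue
            if detector.contact_residues(run.frames[t]) & anchors:
                frames.append(run.frames[t])
                times.append(run.times[t])
                provenance.append((run.source_run, t))
    if not frames:
        warnings.warn("no bound frames matched the anchor criterion")
        return None, []
    # concatenated sub-ensemble: synthetic uniform time axis, provenance kept
    spacing_out = stride_ns
    out_times = spacing_out * np.arange(len(frames))
    ensemble = StructuralEnsemble(topo, np.array(frames), out_times)
    return ensemble, provenance


def rmsf_compare(bound_runs: list[StructuralEnsemble],
                 apo_runs: list[StructuralEnsemble],
                 reference: np.ndarray | None = None,
                 fit_selection: Selection | None = None) -> pd.DataFrame:
    """Per-residue pooled Cα RMSF of bound vs apo ensembles.

    Pools all frames of each condition (after per-frame superposition onto
    the shared reference) and reports rmsf_bound, rmsf_apo and
    delta = apo - bound, so positive delta means the ligand rigidifies the
    residue.
    """

    def pooled_rmsf(runs: list[StructuralEnsemble]) -> dict[tuple[str, int], float]:
        topo = runs[0].topology
        frames = np.concatenate([r.frames for r in runs], axis=0)
        times = np.arange(frames.shape[0], dtype=float)
        pooled = StructuralEnsemble(topo, frames, times)
        sel = fit_selection or receptor_calpha_selection(topo)
        return rmsf_calpha(pooled, reference_frame=0, fit_selection=sel).as_dict()

    bound = pooled_rmsf(bound_runs)
    apo = pooled_rmsf(apo_runs)
    receptor_keys = [k for k in apo if k in bound]
    if not receptor_keys:
        raise SelectionError("bound and apo ensembles share no receptor residues")
    rows = [(c, r, bound[(c, r)], apo[(c, r)], apo[(c, r)] - bound[(c, r)])
            for c, r in sorted(receptor_keys)]
    return pd.DataFrame(rows, columns=["chain_id", "res_seq", "rmsf_bound",
                                       "rmsf_apo", "delta"])
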