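#!/usr/bin/env python
"""Extract the site-III bound state and group the bound peptide poses.

Frames sampled every 2 ns whose peptide hydrogen-bonds the site-III anchor
residue (A:152) form the bound ensemble. Poses are compared by all-atom
ligand RMSD in the receptor frame (no re-superposition — position and
orientation differences ARE the signal) and clustered with Ward's method;
the dendrogram is cut on the δ = sqrt(ΔSS) scale and the large clusters
are merged into the ensemble used for the rigidity analysis.
"""

import importlib

import numpy as np
import pandas as pd

from pathlib import Path

import peptisite as ps

sim = importlib.import_module("02_simulate_runs")

OUT = "results"
ANCHORS = [("A", 152)]
STRIDE_NS = 2.0
CUT_DELTA = 4.0      # Å; separates distinct placements, keeps COM noise together
KEEP_FRACTION = 0.6  # merge the big clusters covering >= 60% of snapshots


def extract_and_cluster():
    dimer, peptide, spec, runs, truth = sim.simulate()
    bound, provenance = ps.extract_bound_frames(runs, ANCHORS,
                                                stride_ns=STRIDE_NS)
    distances = ps.pairwise_ligand_rmsd(bound)
    tree = ps.ward_linkage(distances)
    cut = ps.cut_tree(tree, threshold=CUT_DELTA)
    sizes = [int(np.sum(cut.labels == cid))
             for cid in range(1, cut.n_clusters + 1)]
    keep, covered = [], 0
    for cid, size in enumerate(sizes, start=1):
        keep.append(cid)
        covered += size
        if covered >= KEEP_FRACTION * bound.n_frames:
            break
    merged = ps.merge_clusters(cut, keep, bound)
    return bound, provenance, tree, cut, keep, merged


def main():
    Path(OUT).mkdir(exist_ok=True)
    bound, provenance, tree, cut, keep, merged = extract_and_cluster()
    print(f"bound ensemble: {bound.n_frames} snapshots "
          f"(anchors {ANCHORS}, stride {STRIDE_NS} ns)")
    print(f"Ward cut at delta = {CUT_DELTA} Å -> {cut.n_clusters} clusters, "
          f"sizes {[int(np.sum(cut.labels == c)) for c in range(1, cut.n_clusters + 1)]}")
    print(f"kept clusters {keep} -> merged ensemble of {merged.n_frames} "
          f"snapshots ({merged.n_frames / bound.n_frames:.0%})")

    pd.DataFrame(tree.merges, columns=["cluster_u", "cluster_v", "delta_A",
                                       "size"]) \
        .to_csv(f"{OUT}/dendrogram.tsv", sep="\t", index=False)
    pd.DataFrame({"frame": np.arange(bound.n_frames),
                  "run": [r for r, _ in provenance],
                  "source_frame": [t for _, t in provenance],
                  "cluster": cut.labels}) \
        .to_csv(f"{OUT}/cluster_assignment.tsv", sep="\t", index=False)
    # medoid conformation of each cluster (actual snapshots, not averages)
    centroid_frames = [cut.centroid_leaf[c]
                       for c in range(1, cut.n_clusters + 1)]
    centroids = ps.StructuralEnsemble(
        bound.topology, bound.frames[centroid_frames],
        STRIDE_NS * np.arange(len(centroid_frames)))
    ps.write_multimodel_pdb(centroids, f"{OUT}/cluster_centroids.pdb")
    print(f"wrote {OUT}/dendrogram.tsv, {OUT}/cluster_assignment.tsv, "
          f"{OUT}/cluster_centroids.pdb")


if __name__ == "__main__":
    main()
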