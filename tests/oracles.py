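"""Independent oracle implementations used only by the test suite.

These deliberately take different algorithmic routes than the library:
quaternion (Horn) superposition instead of SVD Kabsch, an O(n^3)
Lance-Williams Ward instead of SciPy linkage, and a generic rigidity-matrix
rank/null-space computation instead of the pebble game.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import null_space


def quaternion_superpose_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal superposition RMSD via Horn's quaternion eigenvalue method."""
    m = mobile - mobile.mean(axis=0)
    r = reference - reference.mean(axis=0)
    s = m.T @ r
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    n = m.shape[0]
    msd = (np.sum(m ** 2) + np.sum(r ** 2) - 2.0 * lam) / n
    return float(np.sqrt(max(msd, 0.0)))


def naive_ward_heights(distances: np.ndarray) -> np.ndarray:
    """Sorted Ward merge heights on the delta = sqrt(ΔSS) scale, computed
    by the O(n^3) Lance-Williams recursion on merge costs directly."""
    n = distances.shape[0]
    cost = {}
    for i in range(n):
        for j in range(i + 1, n):
            cost[(i, j)] = distances[i, j] ** 2 / 2.0
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    heights = []
    next_id = n
    while len(active) > 1:
        (i, j), c = min(cost.items(), key=lambda kv: kv[1])
        heights.append(np.sqrt(c))
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        for k in list(active):
            if k in (i, j):
                continue
            nk = sizes[k]
            cik = cost.pop((min(i, k), max(i, k)))
            cjk = cost.pop((min(j, k), max(j, k)))
            cost[(min(new, k), max(new, k))] = (
                (ni + nk) * cik + (nj + nk) * cjk - nk * c) / (ni + nj + nk)
        del cost[(i, j)]
        active -= {i, j}
        active.add(new)
        sizes[new] = ni + nj
    return np.sort(np.array(heights))


def rigidity_matrix_analysis(n_bodies: int,
                             edges: list[tuple[int, int, int]],
                             rng: np.random.Generator
                             ) -> tuple[int, set[frozenset[int]]]:
    """Generic body-bar rigidity: global DOF and rigid-body partition.

    Builds a generic rigidity matrix (random body centres, random bar
    attachment points), takes its null space (the infinitesimal motions),
    and declares a body pair mutually rigid when their combined motion
    space has dimension <= 6 (it always contains the 6 shared rigid
    motions). Mutual rigidity is transitive, so a union-find yields the
    partition.
    """
    centers = rng.normal(size=(n_bodies, 3))
    rows = []
    for u, v, bars in edges:
        for _ in range(bars):
            a = centers[u] + rng.normal(size=3)
            b = centers[v] + rng.normal(size=3)
            d = a - b
            row = np.zeros(6 * n_bodies)
            row[6 * u:6 * u + 3] = d
            row[6 * u + 3:6 * u + 6] = np.cross(a - centers[u], d)
            row[6 * v:6 * v + 3] = -d
            row[6 * v + 3:6 * v + 6] = -np.cross(b - centers[v], d)
            rows.append(row)
    if rows:
        motions = null_space(np.array(rows), rcond=1e-10)
    else:
        motions = np.eye(6 * n_bodies)
    dof = motions.shape[1]

    parent = list(range(n_bodies))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u in range(n_bodies):
        for v in range(u + 1, n_bodies):
            pair = np.vstack([motions[6 * u:6 * u + 6],
                              motions[6 * v:6 * v + 6]])
            if np.linalg.matrix_rank(pair, tol=1e-8) <= 6:
                ru, rv = find(u), find(v)
                if ru != rv:
                    parent[ru] = rv
    comps: dict[int, set[int]] = {}
    for x in range(n_bodies):
        comps.setdefault(find(x), set()).add(x)
    return dof, {frozenset(c) for c in comps.values()}


def random_body_bar_network(rng: np.random.Generator,
                            max_bodies: int = 8
                            ) -> tuple[int, list[tuple[int, int, int]]]:
    """A random multigraph body-bar instance (bars 1..6 per edge)."""
    n = int(rng.integers(2, max_bodies + 1))
    m = int(rng.integers(1, n * (n - 1) // 2 + 2))
    edges, seen = [], set()
    for _ in range(m):
        u, v = rng.integers(0, n, 2)
        key = (min(u, v), max(u, v))
        if u == v or key in seen:
            continue
        seen.add(key)
        edges.append((key[0], key[1], int(rng.integers(1, 7))))
    if not edges:
        edges = [(0, 1 % n if n > 1 else 0, 3)] if n > 1 else []
    return n, edges
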