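"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the RMSD oracle searches
rotation space numerically instead of using the closed-form fit, the
alignment oracle enumerates every global alignment of tiny strings, and the
buried-area oracle is the spherical-cap closed form.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def bruteforce_rmsd(a: np.ndarray, b: np.ndarray, n_starts: int = 12,
                    seed: int = 0) -> float:
    """Minimum RMSD over rotations by multi-start numerical optimization.

    Centers both sets (the optimal translation matches centroids for any
    rotation) and minimizes the mean squared deviation over the
    rotation-vector parametrization from several deterministic starting
    orientations.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)

    def msd(rotvec: np.ndarray) -> float:
        r = Rotation.from_rotvec(rotvec).as_matrix()
        return float(np.mean(np.sum((a0 @ r.T - b0) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    starts = [np.zeros(3)]
    for _ in range(n_starts - 1):
        q = rng.normal(size=4)
        starts.append(Rotation.from_quat(q / np.linalg.norm(q)).as_rotvec())
    best = np.inf
    for s in starts:
        res = minimize(msd, s, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
        best = min(best, res.fun)
    return float(np.sqrt(best))


def rmsd_under_random_rotations(a: np.ndarray, b: np.ndarray, n: int = 1000,
                                seed: int = 0) -> np.ndarray:
    """RMSD (with optimal translation) under n random proper rotations."""
    a0 = np.asarray(a, float) - np.asarray(a, float).mean(axis=0)
    b0 = np.asarray(b, float) - np.asarray(b, float).mean(axis=0)
    rng = np.random.default_rng(seed)
    out = np.empty(n)
    for i in range(n):
        q = rng.normal(size=4)
        r = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
        out[i] = np.sqrt(np.mean(np.sum((a0 @ r.T - b0) ** 2, axis=1)))
    return out


def enumerate_global_alignments_score(a: str, b: str, mat, gap_open: float,
                                      gap_extend: float) -> float:
    """Optimal global alignment score by exhaustive enumeration.

    Affine penalties follow the convention that a gap of length L costs
    gap_open + (L-1) * gap_extend.  Only viable for tiny strings.
    """
    best = -np.inf
    # state: (i, j, score, gap_state) where gap_state in {None, 'a', 'b'}
    stack = [(0, 0, 0.0, None)]
    while stack:
        i, j, score, gap = stack.pop()
        if i == len(a) and j == len(b):
            best = max(best, score)
            continue
        if i < len(a) and j < len(b):
            stack.append((i + 1, j + 1, score + mat[a[i], b[j]], None))
        if i < len(a):  # gap in b
            pen = gap_extend if gap == "b" else gap_open
            stack.append((i + 1, j, score - pen, "b"))
        if j < len(b):  # gap in a
            pen = gap_extend if gap == "a" else gap_open
            stack.append((i, j + 1, score - pen, "a"))
    return float(best)


def cap_buried_area(r1: float, r2: float, d: float) -> float:
    """Total buried area of two intersecting spheres (both caps), closed form."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return 4.0 * np.pi * min(r1, r2) ** 2
    x1 = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    return float(2.0 * np.pi * (r1 * (r1 - x1) + r2 * (r2 - (d - x1))))


def additive_tree_matrix_4taxa():
    """A 4-taxon additive distance matrix with its generating tree.

    Tree: ((A:1,B:2):3,(C:4,D:5));  internal edge 3 splits AB | CD.
    """
    ids = ["A", "B", "C", "D"]
    bl = {"A": 1.0, "B": 2.0, "C": 4.0, "D": 5.0}
    internal = 3.0
    d = np.zeros((4, 4))
    for i, x in enumerate(ids):
        for j, y in enumerate(ids):
            if i == j:
                continue
            same_side = {x, y} <= {"A", "B"} or {x, y} <= {"C", "D"}
            d[i, j] = bl[x] + bl[y] + (0.0 if same_side else internal)
    return d, ids, frozenset({"A", "B"})


def additive_tree_matrix_5taxa():
    """A 5-taxon additive matrix: (((A:1,B:1):1,C:3):1,(D:2,E:2));"""
    ids = ["A", "B", "C", "D", "E"]
    # path lengths computed by hand on the tree above
    d = np.array([
        [0, 2, 5, 5, 5],
        [2, 0, 5, 5, 5],
        [5, 5, 0, 6, 6],
        [5, 5, 6, 0, 4],
        [5, 5, 6, 4, 0],
    ], dtype=float)
    splits = {frozenset({"A", "B"}), frozenset({"D", "E"})}
    return d, ids, splits
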