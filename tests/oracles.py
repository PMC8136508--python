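"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's dynamic-programming and linear-
algebra shortcuts: alignments are scored by enumerating every monotone
alignment path, and superposition RMSD by searching a rotation grid.
"""

from __future__ import annotations

import numpy as np

from bridgethemes.alignment import SubstitutionMatrix


def brute_force_global(seq_a: str, seq_b: str, matrix: SubstitutionMatrix,
                       gap_open: float, gap_extend: float) -> float:
    """Best global affine-gap score by enumerating every alignment path.

    A gap of length k costs ``gap_open + (k-1)*gap_extend``, matching the
    package's convention.
    """
    best = [float("-inf")]

    def rec(i: int, j: int, prev: str, score: float) -> None:
        if i == len(seq_a) and j == len(seq_b):
            best[0] = max(best[0], score)
            return
        if i < len(seq_a) and j < len(seq_b):
            rec(i + 1, j + 1, "M", score + matrix.score(seq_a[i], seq_b[j]))
        if i < len(seq_a):
            rec(i + 1, j, "A", score - (gap_extend if prev == "A" else gap_open))
        if j < len(seq_b):
            rec(i, j + 1, "B", score - (gap_extend if prev == "B" else gap_open))

    rec(0, 0, "", 0.0)
    return best[0]


def brute_force_local(seq_a: str, seq_b: str, matrix: SubstitutionMatrix,
                      gap_open: float, gap_extend: float) -> float:
    """Best local score: global score maximised over all substring pairs
    (the empty alignment scores 0)."""
    best = 0.0
    for i0 in range(len(seq_a) + 1):
        for i1 in range(i0 + 1, len(seq_a) + 1):
            for j0 in range(len(seq_b) + 1):
                for j1 in range(j0 + 1, len(seq_b) + 1):
                    s = brute_force_global(seq_a[i0:i1], seq_b[j0:j1],
                                           matrix, gap_open, gap_extend)
                    best = max(best, s)
    return best


def grid_search_rmsd(coords_a: np.ndarray, coords_b: np.ndarray,
                     coarse: int = 24, refine_rounds: int = 3) -> float:
    """Minimum RMSD over rigid motions by searching Euler-angle space.

    Coarse grid over (alpha, beta, gamma), then iterative refinement
    around the best cell.  Translation is optimal at centroid matching
    for any rotation, so only rotations are searched.
    """
    a = coords_a - coords_a.mean(axis=0)
    b = coords_b - coords_b.mean(axis=0)

    def rmsd_for(angles: tuple[float, float, float]) -> float:
        al, be, ga = angles
        rz1 = _rot_z(al)
        ry = _rot_y(be)
        rz2 = _rot_z(ga)
        R = rz1 @ ry @ rz2
        diff = a - b @ R.T
        return float(np.sqrt((diff**2).sum() / len(a)))

    step = 2 * np.pi / coarse
    grid = np.arange(coarse) * step
    best_angles, best = None, np.inf
    for al in grid:
        for be in grid[: coarse // 2 + 1]:
            for ga in grid:
                r = rmsd_for((al, be, ga))
                if r < best:
                    best, best_angles = r, (al, be, ga)
    for _ in range(refine_rounds):
        step /= 6.0
        al0, be0, ga0 = best_angles
        offs = np.linspace(-3 * step, 3 * step, 7)
        for dal in offs:
            for dbe in offs:
                for dga in offs:
                    r = rmsd_for((al0 + dal, be0 + dbe, ga0 + dga))
                    if r < best:
                        best, best_angles = r, (al0 + dal, be0 + dbe, ga0 + dga)
    return best


def _rot_z(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _rot_y(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def contact_change_by_enumeration(coords_a: np.ndarray, coords_b: np.ndarray,
                                  threshold: float) -> float:
    """Percent differing contact-map entries by explicit pair enumeration."""
    l = len(coords_a)
    differing = 0
    for i in range(l):
        for j in range(l):
            da = np.linalg.norm(coords_a[i] - coords_a[j])
            db = np.linalg.norm(coords_b[i] - coords_b[j])
            if (da < threshold) != (db < threshold):
                differing += 1
    return 100.0 * differing / (l * l)
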