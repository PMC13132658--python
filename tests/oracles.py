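"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive — plain loops, explicit set algebra,
brute-force optimization — and shares no code path with the implementation
it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

# refinement constants mirrored from the method definition
_D_CUTS = (8.0, 7.0, 6.0, 5.0, 4.5)
_MAX_ITERS = 20


def svd_kabsch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Plain Kabsch: rotation/translation of a onto b (own SVD arithmetic)."""
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, _, vt = np.linalg.svd(h)
    d = np.diag([1.0, 1.0, np.sign(np.linalg.det(vt.T @ u.T))])
    rot = vt.T @ d @ u.T
    return rot, cb - rot @ ca


def brute_force_min_rmsd(a: np.ndarray, b: np.ndarray, n_starts: int = 60,
                         seed: int = 0) -> float:
    """Minimum RMSD over rigid transforms by multi-start numeric optimization.

    Parametrizes rotation by a rotation vector and optimizes rotation plus
    translation jointly from a quaternion grid of starting points.
    """
    rng = np.random.default_rng(seed)

    def cost(x):
        rot = Rotation.from_rotvec(x[:3]).as_matrix()
        diff = a @ rot.T + x[3:] - b
        return np.sqrt(np.mean(np.sum(diff * diff, axis=1)))

    best = np.inf
    starts = [np.zeros(3)] + [Rotation.random(random_state=rng).as_rotvec()
                              for _ in range(n_starts)]
    for rv in starts:
        x0 = np.concatenate([rv, b.mean(axis=0) - a.mean(axis=0)])
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000})
        best = min(best, res.fun)
    return float(best)


def exhaustive_tm(ca: np.ndarray, cb: np.ndarray, d0: float, L_norm: int) -> float:
    """TM-score by exhaustive seeding: every contiguous fragment of length
    >= 4 starts an iterative superposition refinement."""
    n = len(ca)
    best = 0.0
    for flen in range(4, n + 1):
        for start in range(0, n - flen + 1):
            idx = np.arange(start, start + flen)
            rot, tr = svd_kabsch(ca[idx], cb[idx])
            for d_cut in _D_CUTS:
                prev = None
                for _ in range(_MAX_ITERS):
                    d = np.sqrt(np.sum((ca @ rot.T + tr - cb) ** 2, axis=1))
                    best = max(best, float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L_norm))
                    cut = d_cut
                    sel = d < cut
                    while sel.sum() < 3 and cut < d.max() + 1.0:
                        cut += 0.5
                        sel = d < cut
                    if sel.sum() < 3:
                        sel = np.zeros(n, dtype=bool)
                        sel[np.argsort(d)[:3]] = True
                    if prev is not None and np.array_equal(sel, prev):
                        break
                    prev = sel
                    rot, tr = svd_kabsch(ca[sel], cb[sel])
    return best


def enumerate_inf(pairs_a: set, pairs_b: set) -> float:
    """INF by explicit TP/FP/FN set enumeration."""
    if not pairs_a and not pairs_b:
        return 1.0
    if not pairs_a or not pairs_b:
        return 0.0
    tp = pairs_a & pairs_b
    fp = pairs_a - pairs_b
    fn = pairs_b - pairs_a
    if not tp:
        return 0.0
    precision = len(tp) / (len(tp) + len(fp))
    recall = len(tp) / (len(tp) + len(fn))
    return math.sqrt(precision * recall)


def naive_quality(values: list[list[float]]) -> list[float]:
    """Per-decoy quality as the plain off-diagonal row mean (exact sums)."""
    n = len(values)
    out = []
    for i in range(n):
        out.append(math.fsum(values[i][j] for j in range(n) if j != i) / (n - 1))
    return out


def naive_top1_loss(predicted, truth, ids) -> float:
    """Top-1 loss applied literally: truth of the predicted-best decoy vs
    the truth of the actually-best decoy."""
    order = sorted(range(len(predicted)), key=lambda k: (-predicted[k], ids[k]))
    return abs(truth[order[0]] - max(truth))


def fisher_mean_direct(rs) -> float:
    zs = [math.atanh(max(min(r, 1 - 1e-12), -(1 - 1e-12))) for r in rs]
    return math.tanh(sum(zs) / len(zs))
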