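"""Pairwise TM-score between equal-length RNA decoys.

The TM-score of two structures in 1:1 residue correspondence is

    TM = max over superpositions of (1/L) * sum_k 1 / (1 + (d_k/d0)^2)

where d_k is the distance between corresponding representative atoms
(C1' by default), L is the normalization length, and d0 the length-dependent
distance scale.  The maximum is searched with the standard heuristic:
rigid-body fits seeded from contiguous chain fragments, each refined by
iterating superposition on the residue pairs closer than a shrinking
distance cutoff.  Scores are in (0, 1]; 1 means an identical fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import CorrespondenceError, DegenerateFitError
from .structures import REPRESENTATIVE_ATOMS, RnaStructure

#: Distance-cutoff schedule (Å) for iterative refinement of each seed.
D_CUT_SCHEDULE = (8.0, 7.0, 6.0, 5.0, 4.5)
MAX_REFINE_ITERS = 20


@dataclass
class Superposition:
    """A rigid transform x -> R x + t minimizing RMSD over the aligned set."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    aligned_indices: np.ndarray | None = None

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class TmParams:
    """Normalization constants for the TM-score.

    ``d0`` and ``L_norm`` default to None, meaning "derive from the common
    chain length": d0 from the nucleic-acid formula of :func:`default_d0`
    and L_norm from the (equal) decoy length, which makes the score
    symmetric across the ensemble.
    """

    d0: float | None = None
    L_norm: int | None = None
    representative_atom: Sequence[str] = REPRESENTATIVE_ATOMS
    d0_floor: float = 0.3
    #: below this chain length every contiguous fragment (>= 4 residues)
    #: seeds the search; above it a geometric fragment ladder is used
    dense_seed_limit: int = 64

    def resolve(self, length: int) -> tuple[float, int]:
        d0 = self.d0 if self.d0 is not None else default_d0(length, self.d0_floor)
        L = self.L_norm if self.L_norm is not None else length
        if d0 <= 0 or L < 1:
            raise ValueError("d0 must be > 0 and L_norm >= 1")
        return d0, L


def default_d0(L: int, floor: float = 0.3) -> float:
    """Nucleic-acid TM-score distance scale: 0.6*sqrt(L-0.5) - 2.5, floored.

    The raw formula goes negative for short chains, hence the floor
    (default 0.3 Å).  Monotonically non-decreasing in L.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    return max(floor, 0.6 * np.sqrt(L - 0.5) - 2.5)


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of ``coords_a`` onto ``coords_b``.

    Returns the proper rotation (det +1) and translation minimizing RMSD.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise DegenerateFitError("coordinate sets must both be (n, 3)")
    if len(a) < 3:
        raise DegenerateFitError(f"need >=3 points for a rigid fit, got {len(a)}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise DegenerateFitError("non-finite coordinates")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rotation = vt.T @ d @ u.T
    translation = cb - rotation @ ca
    diff = a @ rotation.T + translation - b
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return Superposition(rotation=rotation, translation=translation, rmsd=rmsd)


def tm_terms(coords_a: np.ndarray, coords_b: np.ndarray, sup: Superposition,
             d0: float) -> np.ndarray:
    """Per-residue terms 1/(1+(d/d0)^2) under a given superposition."""
    moved = sup.apply(np.asarray(coords_a, float))
    d2 = np.sum((moved - np.asarray(coords_b, float)) ** 2, axis=1)
    return 1.0 / (1.0 + d2 / (d0 * d0))


def tm_score_under(coords_a: np.ndarray, coords_b: np.ndarray,
                   sup: Superposition, d0: float, L_norm: int) -> float:
    """TM-score of a fixed (externally supplied) superposition."""
    return float(np.sum(tm_terms(coords_a, coords_b, sup, d0)) / L_norm)


def _fragment_seeds(n: int, dense: bool) -> list[np.ndarray]:
    """Seed index sets for the superposition search.

    Dense mode: every contiguous fragment of length >= 4 (plus the full
    chain).  Ladder mode: full chain plus fragments of n/2, n/4, ... down
    to 4 at stride n/10 — cheaper for long chains.
    """
    seeds: set[tuple[int, int]] = {(0, n)}
    if dense:
        for flen in range(4, n + 1):
            for start in range(0, n - flen + 1):
                seeds.add((start, flen))
    else:
        stride = max(1, n // 10)
        flen = n
        while flen >= 4:
            for start in range(0, n - flen + 1, stride):
                seeds.add((start, flen))
            if flen == 4:
                break
            flen = max(4, flen // 2)
    return [np.arange(s, s + l) for s, l in sorted(seeds)]


def _refine_and_score(coords_a: np.ndarray, coords_b: np.ndarray,
                      seed_idx: np.ndarray, d0: float, L_norm: int,
                      seen: set | None = None) -> float:
    """Refine one seed through the cutoff schedule; return the best score.

    ``seen`` memoizes (schedule stage, selected-residue set) states across
    seeds: once a refinement trajectory enters a state another seed already
    visited, its continuation is identical, so the seed can stop early.
    """
    n = len(coords_a)
    best = 0.0
    sup = kabsch_superpose(coords_a[seed_idx], coords_b[seed_idx])
    for stage, d_cut in enumerate(D_CUT_SCHEDULE):
        prev_sel: np.ndarray | None = None
        for _ in range(MAX_REFINE_ITERS):
            moved = sup.apply(coords_a)
            d = np.sqrt(np.sum((moved - coords_b) ** 2, axis=1))
            score = float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L_norm)
            if score > best:
                best = score
            cut = d_cut
            sel = d < cut
            while sel.sum() < 3 and cut < d.max() + 1.0:
                cut += 0.5
                sel = d < cut
            if sel.sum() < 3:
                idx3 = np.argsort(d)[:3]
                sel = np.zeros(n, dtype=bool)
                sel[idx3] = True
            if prev_sel is not None and np.array_equal(sel, prev_sel):
                break
            if seen is not None:
                state = (stage, sel.tobytes())
                if state in seen:
                    return best  # identical continuation already explored
                seen.add(state)
            prev_sel = sel
            sup = kabsch_superpose(coords_a[sel], coords_b[sel])
    return best


def _extract_common(a: RnaStructure, b: RnaStructure,
                    priority: Sequence[str]) -> tuple[np.ndarray, np.ndarray, int]:
    if a.length != b.length:
        raise CorrespondenceError(
            f"length mismatch: {a.id} has {a.length}, {b.id} has {b.length}"
        )
    mask_a, ca = a.representative_coords(priority)
    mask_b, cb = b.representative_coords(priority)
    common = mask_a & mask_b
    if common.sum() < 3:
        raise DegenerateFitError(
            f"<3 residues with a representative atom shared by {a.id} and {b.id}"
        )
    return ca[common], cb[common], a.length


def tm_score(a: RnaStructure | np.ndarray, b: RnaStructure | np.ndarray,
             params: TmParams | None = None) -> float:
    """TM-score between two decoys in positional residue correspondence.

    Residues missing the representative atom in either decoy are excluded
    from the sum while L_norm stays at the full chain length, so missing
    atoms penalize the score.  Accepts raw (n, 3) coordinate arrays for
    convenience in tests and oracles.
    """
    params = params or TmParams()
    if isinstance(a, RnaStructure):
        ca, cb, length = _extract_common(a, b, params.representative_atom)
    else:
        ca = np.asarray(a, dtype=float)
        cb = np.asarray(b, dtype=float)
        if ca.shape != cb.shape:
            raise CorrespondenceError("coordinate arrays differ in shape")
        if len(ca) < 3:
            raise DegenerateFitError("need >=3 residues")
        length = len(ca)
    d0, L_norm = params.resolve(length)
    best = 0.0
    seen: set = set()
    dense = len(ca) <= params.dense_seed_limit
    for seed in _fragment_seeds(len(ca), dense):
        if len(seed) < 3:
            continue
        s = _refine_and_score(ca, cb, seed, d0, L_norm, seen)
        if s > best:
            best = s
    return min(best, 1.0)
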