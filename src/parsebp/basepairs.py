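"""Base-pair extraction and Interaction Network Fidelity (INF).

Each decoy's 3D coordinates are reduced to a 2D base-pair map, either by
the built-in geometric annotator or by ingesting a pair-list file written
by an external annotator (MC-annotate, FR3D, RNAView style).  Two maps are
compared with INF, the geometric mean of precision and recall over the two
pair sets:

    INF = sqrt( |TP|/(|TP|+|FP|) * |TP|/(|TP|+|FN|) )

where TP are pairs found in both maps and FP/FN pairs found only in the
first/second map.  Matching is on residue-index pairs by default; a strict
mode additionally requires identical interaction labels.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import CorrespondenceError, PairAnnotationError
from .structures import RnaStructure

logger = logging.getLogger(__name__)

CANONICAL_WC = "canonical_wc"
WOBBLE = "wobble"
NONCANONICAL = "noncanonical"

#: Base ring atoms used to fit the base plane.
RING_ATOMS = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "U": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

#: Hydrogen-bond donor/acceptor heavy atoms on the base edges.
EDGE_ATOMS = {
    "A": ("N1", "N3", "N6", "N7"),
    "G": ("N1", "N2", "N3", "O6", "N7"),
    "C": ("O2", "N3", "N4"),
    "U": ("O2", "N3", "O4"),
}

_WC_COMBOS = frozenset({frozenset("AU"), frozenset("GC")})
_WOBBLE_COMBO = frozenset("GU")


@dataclass(frozen=True, order=True)
class BasePair:
    """One annotated base-base interaction between residues i < j (0-based)."""

    i: int
    j: int
    category: str = NONCANONICAL
    detail: str = ""

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise ValueError(f"require i < j, got ({self.i}, {self.j})")

    @property
    def key(self) -> tuple[int, int]:
        return (self.i, self.j)


@dataclass
class BasePairMap:
    """The 2D annotation of one decoy: a set of base pairs."""

    structure_id: str
    pairs: frozenset[BasePair]
    length: int

    def __post_init__(self) -> None:
        keys = [p.key for p in self.pairs]
        if len(keys) != len(set(keys)):
            # collapse duplicates that differ only in label: keep sorted-first
            by_key: dict[tuple[int, int], BasePair] = {}
            for p in sorted(self.pairs):
                by_key.setdefault(p.key, p)
            self.pairs = frozenset(by_key.values())
        for p in self.pairs:
            if p.j >= self.length:
                raise ValueError(f"pair {p.key} outside structure of length {self.length}")

    def keys(self) -> frozenset[tuple[int, int]]:
        return frozenset(p.key for p in self.pairs)


@dataclass
class AnnotationCriteria:
    """Geometric thresholds of the built-in annotator (Å and degrees)."""

    c1_min: float = 8.0
    c1_max: float = 12.0
    hbond_max: float = 3.5
    min_contacts: int = 2
    plane_angle_max: float = 65.0
    min_sequence_separation: int = 2


def _plane_normal(points: np.ndarray) -> np.ndarray | None:
    if len(points) < 3:
        return None
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2]


def _classify(base_i: str, base_j: str, res_i, res_j, hbond_max: float) -> str:
    combo = frozenset((base_i, base_j))
    if combo == _WOBBLE_COMBO:
        return WOBBLE
    if combo in _WC_COMBOS:
        # canonical WC requires the N1(purine)-N3(pyrimidine) contact
        if base_i in "AG":
            pur, pyr = res_i, res_j
        else:
            pur, pyr = res_j, res_i
        n1, n3 = pur.get("N1"), pyr.get("N3")
        if n1 is not None and n3 is not None and np.linalg.norm(n1 - n3) <= hbond_max:
            return CANONICAL_WC
    return NONCANONICAL


def annotate_base_pairs(
    s: RnaStructure, criteria: AnnotationCriteria | None = None
) -> BasePairMap:
    """Detect base-base pairs from geometry.

    A pair (i, j) is emitted when the C1'-C1' distance lies in
    [c1_min, c1_max], at least ``min_contacts`` donor-acceptor heavy-atom
    contacts exist between the two base edges at <= ``hbond_max`` Å, the
    base planes are within ``plane_angle_max`` degrees of parallel, and the
    residues are not sequence-adjacent (separation >= 2 within a chain;
    residues on different chains are never adjacent).  Residues with
    missing base atoms are left unpaired.
    """
    crit = criteria or AnnotationCriteria()
    n = s.length
    c1 = np.full((n, 3), np.nan)
    normals: list[np.ndarray | None] = []
    edges: list[np.ndarray | None] = []
    n_missing = 0
    for k, res in enumerate(s.residues):
        xyz = res.get("C1'")
        if xyz is not None:
            c1[k] = xyz
        ring = [res.get(a) for a in RING_ATOMS[res.base]]
        ring_pts = np.array([p for p in ring if p is not None])
        normals.append(_plane_normal(ring_pts) if len(ring_pts) >= 3 else None)
        edge = [res.get(a) for a in EDGE_ATOMS[res.base]]
        edge_pts = np.array([p for p in edge if p is not None])
        if len(edge_pts) == 0 or normals[-1] is None or xyz is None:
            n_missing += 1
            edges.append(None)
        else:
            edges.append(edge_pts)
    if n_missing:
        logger.warning("%s: %d residue(s) lack base atoms and stay unpaired",
                       s.id, n_missing)

    pairs: set[BasePair] = set()
    cos_max = math.cos(math.radians(crit.plane_angle_max))
    for i in range(n):
        if edges[i] is None:
            continue
        for j in range(i + 1, n):
            if edges[j] is None:
                continue
            ri, rj = s.residues[i], s.residues[j]
            if ri.chain == rj.chain and j - i < crit.min_sequence_separation:
                continue
            d_c1 = np.linalg.norm(c1[i] - c1[j])
            if not (crit.c1_min <= d_c1 <= crit.c1_max):
                continue
            dists = np.linalg.norm(edges[i][:, None, :] - edges[j][None, :, :], axis=2)
            if int((dists <= crit.hbond_max).sum()) < crit.min_contacts:
                continue
            cosang = abs(float(np.dot(normals[i], normals[j])))
            if cosang < cos_max:
                continue
            category = _classify(ri.base, rj.base, ri, rj, crit.hbond_max)
            pairs.add(BasePair(i, j, category))
    return BasePairMap(structure_id=s.id, pairs=frozenset(pairs), length=n)


_LABEL_CATEGORIES = {
    "WC": CANONICAL_WC,
    "WW": CANONICAL_WC,
    "CWW": CANONICAL_WC,
    "+/+": CANONICAL_WC,
    "-/-": CANONICAL_WC,
    "WOBBLE": WOBBLE,
    "GU": WOBBLE,
}


def read_pair_annotation(path: str | Path, length: int) -> BasePairMap:
    """Read a pair-list file: one "i j label" line per pair, 1-based indices.

    '#' starts a comment; the label is optional and free-form (FR3D/RNAView
    style labels such as cWW are mapped to categories best-effort).
    Duplicate index pairs collapse; out-of-range indices are an error.
    """
    path = Path(path)
    pairs: dict[tuple[int, int], BasePair] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = re.split(r"[,\s]+", line)
            if len(fields) < 2:
                raise PairAnnotationError(f"{path}:{lineno}: expected 'i j [label]'")
            try:
                i1, j1 = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise PairAnnotationError(
                    f"{path}:{lineno}: non-integer residue index"
                ) from exc
            if not (1 <= i1 <= length and 1 <= j1 <= length) or i1 == j1:
                raise PairAnnotationError(
                    f"{path}:{lineno}: pair ({i1}, {j1}) out of range for length {length}"
                )
            i, j = sorted((i1 - 1, j1 - 1))
            label = fields[2] if len(fields) > 2 else ""
            category = _LABEL_CATEGORIES.get(label.upper(), NONCANONICAL)
            pairs.setdefault((i, j), BasePair(i, j, category, detail=label))
    return BasePairMap(structure_id=path.stem, pairs=frozenset(pairs.values()),
                       length=length)


def inf_score(a: BasePairMap, b: BasePairMap, strict_labels: bool = False) -> float:
    """Interaction Network Fidelity between two base-pair maps.

    Geometric mean of precision and recall over the pair sets.  Both maps
    empty counts as perfect agreement (1.0); exactly one empty is 0.0.
    """
    if a.length != b.length:
        raise CorrespondenceError(
            f"maps refer to different lengths: {a.length} vs {b.length}"
        )
    if strict_labels:
        set_a = frozenset((p.i, p.j, p.category) for p in a.pairs)
        set_b = frozenset((p.i, p.j, p.category) for p in b.pairs)
    else:
        set_a, set_b = a.keys(), b.keys()
    if not set_a and not set_b:
        return 1.0
    if not set_a or not set_b:
        return 0.0
    tp = len(set_a & set_b)
    if tp == 0:
        return 0.0
    precision = tp / len(set_a)
    recall = tp / len(set_b)
    return float(math.sqrt(precision * recall))
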