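"""Consensus scoring of a decoy ensemble.

Given N equal-length decoys, two N x N similarity matrices are built over
all unordered pairs: T (pairwise TM-score, global 3D fold agreement) and
I (pairwise INF, 2D base-pairing agreement).  Their element-wise product

    M = T o I,   M_ij = T_ij * I_ij

is the consensus matrix, and each decoy's quality score is its mean
agreement with the rest of the pool:

    Q_i = (1 / (N - 1)) * sum_{j != i} M_ij

The "no_bp" baseline variant scores from T alone, dropping the emphasis on
base pairings.  Higher Q means a decoy is consistently supported by both
the 3D folds and the base-pairing patterns of the other decoys.

Pair evaluations are independent, so they are partitioned into batches and
optionally dispatched to worker processes; each matrix cell is written once,
which makes the result bit-identical regardless of worker count.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from joblib import Parallel, delayed

from .basepairs import AnnotationCriteria, BasePairMap, annotate_base_pairs, \
    inf_score, read_pair_annotation
from .errors import MatrixAlignmentError, PairEvaluationError
from .structures import Ensemble
from .tmscore import TmParams, tm_score

VARIANT_PARSEBP = "parsebp"
VARIANT_NO_BP = "no_bp"


@dataclass
class SimilarityMatrix:
    """Symmetric N x N pairwise similarity over the ensemble, values in [0,1]."""

    ids: tuple[str, ...]
    values: np.ndarray
    kind: str  # tm | inf | consensus

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("similarity values must lie in [0, 1]")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class QualityScores:
    """Per-decoy consensus quality scores for one scoring variant."""

    ids: tuple[str, ...]
    q: np.ndarray
    variant: str

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if len(self.q) != len(self.ids):
            raise ValueError("one score per decoy required")

    def ranking(self) -> list[str]:
        """Decoy ids sorted best-first; ties broken lexicographically by id."""
        order = sorted(range(len(self.ids)), key=lambda k: (-self.q[k], self.ids[k]))
        return [self.ids[k] for k in order]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.ids, self.q.tolist()))


def _eval_batch(items: Sequence, ids: Sequence[str], measure: Callable,
                batch: list[tuple[int, int]]):
    out = []
    for i, j in batch:
        # canonical argument order by decoy id: scoring a permuted ensemble
        # then evaluates every pair with bit-identical operand order
        if ids[i] <= ids[j]:
            out.append((i, j, measure(items[i], items[j])))
        else:
            out.append((i, j, measure(items[j], items[i])))
    return out


def pairwise_matrix(
    items: Sequence,
    ids: Sequence[str],
    measure: Callable,
    kind: str,
    jobs: int = 1,
    batch: int = 64,
) -> SimilarityMatrix:
    """Evaluate a symmetric pair measure over all unordered pairs.

    Each unordered pair is computed exactly once and mirrored; the diagonal
    is set to 1 by convention (never consumed by the quality scores).  Any
    pair failure is reported with both decoy ids — no silent NaN.
    """
    n = len(items)
    if n < 2:
        raise ValueError("need at least 2 items")
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    batches = [pairs[k:k + batch] for k in range(0, len(pairs), max(1, batch))]
    try:
        if jobs == 1:
            results = [_eval_batch(items, ids, measure, b) for b in batches]
        else:
            results = Parallel(n_jobs=jobs)(
                delayed(_eval_batch)(items, ids, measure, b) for b in batches
            )
    except PairEvaluationError:
        raise
    except Exception as exc:
        raise PairEvaluationError(f"pairwise {kind} evaluation failed: {exc}") from exc

    values = np.eye(n)
    for chunk in results:
        for i, j, v in chunk:
            if not np.isfinite(v):
                raise PairEvaluationError(
                    f"{kind} measure returned non-finite value for "
                    f"({ids[i]}, {ids[j]})"
                )
            values[i, j] = values[j, i] = v
    return SimilarityMatrix(ids=tuple(ids), values=values, kind=kind)


def combine(T: SimilarityMatrix, I: SimilarityMatrix) -> SimilarityMatrix:
    """Element-wise product M = T o I of the 3D and 2D agreement matrices."""
    if T.ids != I.ids:
        raise MatrixAlignmentError("T and I must carry identical decoy ids in order")
    if T.values.shape != I.values.shape:
        raise MatrixAlignmentError("T and I differ in shape")
    return SimilarityMatrix(ids=T.ids, values=T.values * I.values, kind="consensus")


def quality_scores(M: SimilarityMatrix, variant: str = VARIANT_PARSEBP) -> QualityScores:
    """Off-diagonal row means of the consensus matrix: Q_i = mean_{j != i} M_ij.

    Row sums use exactly-rounded summation (math.fsum), so the result does
    not depend on summation order.
    """
    n = M.n
    if n < 2:
        raise ValueError("need N >= 2 decoys")
    q = np.array([
        math.fsum(M.values[i, j] for j in range(n) if j != i) / (n - 1)
        for i in range(n)
    ])
    return QualityScores(ids=M.ids, q=q, variant=variant)


@dataclass
class ScoreConfig:
    """End-to-end scoring configuration."""

    tm_params: TmParams = field(default_factory=TmParams)
    criteria: AnnotationCriteria = field(default_factory=AnnotationCriteria)
    annotation_dir: str | Path | None = None  # external per-decoy pair lists
    tm_csv: str | Path | None = None  # precomputed pairwise TM-score table
    strict_labels: bool = False
    jobs: int = 1
    batch: int = 64


@dataclass
class ScoreResult:
    """Everything the scorer produces for one ensemble."""

    parsebp: QualityScores
    no_bp: QualityScores
    T: SimilarityMatrix
    I: SimilarityMatrix
    M: SimilarityMatrix


def tm_matrix_from_csv(path: str | Path, ids: Sequence[str]) -> SimilarityMatrix:
    """Load a precomputed pairwise TM-score table (columns i, j, score).

    ``i`` and ``j`` may be decoy ids or 0-based integer indices.  Used to
    cross-check the internal TM-score engine against an external program.
    """
    idx = {d: k for k, d in enumerate(ids)}
    n = len(ids)
    values = np.eye(n)
    seen = np.eye(n, dtype=bool)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for row in reader:
            if not row or row[0].strip().lower() in ("i", "id_i", "decoy_i"):
                continue
            a, b, s = row[0].strip(), row[1].strip(), float(row[2])
            i = idx[a] if a in idx else int(a)
            j = idx[b] if b in idx else int(b)
            values[i, j] = values[j, i] = s
            seen[i, j] = seen[j, i] = True
    if not seen.all():
        raise MatrixAlignmentError(f"{path}: missing pairwise entries")
    return SimilarityMatrix(ids=tuple(ids), values=values, kind="tm")


def _maps_for(e: Ensemble, config: ScoreConfig) -> list[BasePairMap]:
    if config.annotation_dir is not None:
        root = Path(config.annotation_dir)
        maps = []
        for s in e.structures:
            matches = sorted(root.glob(s.id + ".*")) + \
                ([root / s.id] if (root / s.id).exists() else [])
            if not matches:
                raise FileNotFoundError(
                    f"no annotation file for decoy {s.id!r} in {root}"
                )
            maps.append(read_pair_annotation(matches[0], s.length))
        return maps
    return [annotate_base_pairs(s, config.criteria) for s in e.structures]


def score_ensemble(e: Ensemble, config: ScoreConfig | None = None) -> ScoreResult:
    """Run the full consensus pipeline on one ensemble.

    Returns both scoring variants plus the T, I and M matrices for
    inspection.  Base-pair maps come from the built-in annotator unless an
    external annotation directory is configured; the TM-score matrix can be
    substituted with a precomputed table.
    """
    config = config or ScoreConfig()
    ids = e.ids
    if config.tm_csv is not None:
        T = tm_matrix_from_csv(config.tm_csv, ids)
    else:
        measure = _TmMeasure(config.tm_params)
        T = pairwise_matrix(e.structures, ids, measure, "tm",
                            jobs=config.jobs, batch=config.batch)
    maps = _maps_for(e, config)
    inf_measure = _InfMeasure(config.strict_labels)
    I = pairwise_matrix(maps, ids, inf_measure, "inf",
                        jobs=config.jobs, batch=config.batch)
    M = combine(T, I)
    return ScoreResult(
        parsebp=quality_scores(M, VARIANT_PARSEBP),
        no_bp=quality_scores(T, VARIANT_NO_BP),
        T=T, I=I, M=M,
    )


class _TmMeasure:
    """Picklable TM-score pair measure (worker processes need a top-level callable)."""

    def __init__(self, params: TmParams):
        self.params = params

    def __call__(self, a, b):
        return tm_score(a, b, self.params)


class _InfMeasure:
    def __init__(self, strict: bool):
        self.strict = strict

    def __call__(self, a, b):
        return inf_score(a, b, strict_labels=self.strict)


def write_scores_csv(result: ScoreResult, path: str | Path) -> None:
    """Write per-decoy scores: decoy_id, Q_parsebp, Q_no_bp, rank (6 decimals)."""
    rank_order = result.parsebp.ranking()
    rank = {d: k + 1 for k, d in enumerate(rank_order)}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["decoy_id", "Q_parsebp", "Q_no_bp", "rank"])
        for k, d in enumerate(result.parsebp.ids):
            w.writerow([d, f"{result.parsebp.q[k]:.6f}",
                        f"{result.no_bp.q[k]:.6f}", rank[d]])


def write_matrices_csv(result: ScoreResult, path: str | Path) -> None:
    """Write T, I and M in long format: i, j, kind, value (6 decimals)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["decoy_i", "decoy_j", "kind", "value"])
        for mat in (result.T, result.I, result.M):
            for i in range(mat.n):
                for j in range(mat.n):
                    w.writerow([mat.ids[i], mat.ids[j], mat.kind,
                                f"{mat.values[i, j]:.6f}"])
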