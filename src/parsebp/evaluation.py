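"""Assessment harness for decoy-scoring methods.

Predicted per-decoy scores are compared to ground-truth quality metrics
(composite score G, INF-All, TM-score, GDT_TS, lDDT, or negated RMSD).
Following standard multi-target assessment practice, raw scores and truths
are min-max normalized within each target before decoys are pooled for the
global Pearson r and Spearman rho; per-target correlations are additionally
averaged across targets, both arithmetically and through Fisher's
z-transformation, and the per-target top-1 loss reports how much quality is
lost by trusting each method's first-ranked decoy.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EvaluationInputError

#: Weights of the composite ground-truth score G.
G_WEIGHTS = {"tm": 0.3, "gdt_ts": 0.3, "lddt": 0.4}

TRUTH_METRICS = ("G", "inf_all", "tm", "gdt_ts", "lddt", "rmsd")


def composite_score(tm, gdt_ts, lddt):
    """Composite structural quality G = 0.3*TM + 0.3*GDT_TS + 0.4*lDDT.

    All three components must be present and within [0, 1]; no imputation.
    Accepts scalars or aligned arrays.
    """
    parts = {"tm": tm, "gdt_ts": gdt_ts, "lddt": lddt}
    arrs = {}
    for name, x in parts.items():
        if x is None:
            raise EvaluationInputError(f"composite score requires {name}")
        a = np.asarray(x, dtype=float)
        if np.any(~np.isfinite(a)):
            raise EvaluationInputError(f"composite score: missing/NaN {name} values")
        if np.any(a < 0) or np.any(a > 1):
            raise EvaluationInputError(f"composite score: {name} outside [0, 1]")
        arrs[name] = a
    g = sum(G_WEIGHTS[k] * arrs[k] for k in G_WEIGHTS)
    return float(g) if np.ndim(g) == 0 else g


def minmax_normalize(scores: Sequence[float]) -> np.ndarray:
    """Per-target min-max rescaling to [0, 1]; constant input maps to 0.5."""
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise EvaluationInputError("min-max normalization needs >= 2 values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def negate_if_energy(scores, convention: str = "higher_better"):
    """Flip sign of energy/RMSD-style scores so that higher always means better."""
    x = np.asarray(scores, dtype=float)
    if convention == "lower_better":
        return -x
    if convention == "higher_better":
        return x
    raise ValueError(f"unknown convention {convention!r}")


def top1_loss(
    predicted: Sequence[float],
    truth: Sequence[float],
    ids: Sequence[str] | None = None,
    normalized: bool = False,
) -> float:
    """Quality lost by trusting the method's top-ranked decoy.

    |truth(argmax predicted) - max(truth)|, with predicted ties broken
    lexicographically by decoy id.  With ``normalized=True`` the truth
    vector is min-max normalized first (the multi-target convention).
    """
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.ndim != 1 or p.size < 1:
        raise EvaluationInputError("predicted/truth must be aligned 1-D vectors")
    if ids is not None and len(ids) != p.size:
        raise EvaluationInputError("ids misaligned with scores")
    if normalized:
        t = minmax_normalize(t) if p.size >= 2 else t
    labels = list(ids) if ids is not None else [str(k) for k in range(p.size)]
    top = min(range(p.size), key=lambda k: (-p[k], labels[k]))
    return float(abs(t[top] - t.max()))


def fisher_z_mean(rs: Sequence[float]) -> float:
    """Average correlations via Fisher's z: tanh(mean(atanh(r)))."""
    r = np.clip(np.asarray(rs, dtype=float), -(1 - 1e-12), 1 - 1e-12)
    if r.size == 0:
        return float("nan")
    return float(np.tanh(np.mean(np.arctanh(r))))


@dataclass
class MetricReport:
    """Global and per-target agreement between a scorer and ground truth."""

    truth_metric: str
    global_r: float
    global_rho: float
    per_target_r: float
    per_target_rho: float
    per_target_r_fisher: float
    per_target_rho_fisher: float
    per_target_loss: float
    n_targets: int
    n_decoys: int
    n_degenerate_targets: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(self)])


def _truth_column(df: pd.DataFrame, truth_metric: str) -> pd.Series:
    if truth_metric not in TRUTH_METRICS:
        raise EvaluationInputError(f"unknown truth metric {truth_metric!r}")
    if truth_metric == "G":
        for col in ("tm", "gdt_ts", "lddt"):
            if col not in df.columns:
                raise EvaluationInputError(f"truth metric G requires column {col!r}")
        return pd.Series(
            composite_score(df["tm"].values, df["gdt_ts"].values, df["lddt"].values),
            index=df.index,
        )
    if truth_metric not in df.columns:
        raise EvaluationInputError(f"missing truth column {truth_metric!r}")
    col = df[truth_metric].astype(float)
    if truth_metric == "rmsd":
        col = -col  # lower RMSD is better; flip to higher-is-better
    return col


def correlation_report(table: pd.DataFrame, truth_metric: str = "G") -> MetricReport:
    """Compute the full metric panel for one predictions-vs-truth table.

    ``table`` needs columns target_id, decoy_id, predicted, plus the truth
    columns for ``truth_metric``.  Targets where either vector is constant
    are dropped from correlation averages (their count is reported); the
    top-1 loss is still defined and kept for every target.
    """
    required = {"target_id", "decoy_id", "predicted"}
    if not required.issubset(table.columns):
        raise EvaluationInputError(f"table must have columns {sorted(required)}")
    if table.duplicated(["target_id", "decoy_id"]).any():
        raise EvaluationInputError("duplicate (target_id, decoy_id) rows")

    df = table.copy()
    df["truth"] = _truth_column(df, truth_metric)
    if df["predicted"].isna().any() or df["truth"].isna().any():
        raise EvaluationInputError("NaN in predicted or truth values")

    pooled_pred, pooled_truth = [], []
    rs, rhos, losses = [], [], []
    n_degenerate = 0
    for _, grp in df.groupby("target_id", sort=True):
        if len(grp) < 2:
            raise EvaluationInputError("each target needs >= 2 decoys")
        p = grp["predicted"].to_numpy(dtype=float)
        t = grp["truth"].to_numpy(dtype=float)
        pooled_pred.append(minmax_normalize(p))
        pooled_truth.append(minmax_normalize(t))
        losses.append(top1_loss(p, t, ids=grp["decoy_id"].tolist(), normalized=True))
        if np.ptp(p) == 0 or np.ptp(t) == 0:
            n_degenerate += 1
            continue
        rs.append(float(stats.pearsonr(p, t)[0]))
        rhos.append(float(stats.spearmanr(p, t)[0]))

    gp = np.concatenate(pooled_pred)
    gt = np.concatenate(pooled_truth)
    if np.ptp(gp) == 0 or np.ptp(gt) == 0:
        global_r = global_rho = float("nan")
    else:
        global_r = float(stats.pearsonr(gp, gt)[0])
        global_rho = float(stats.spearmanr(gp, gt)[0])

    return MetricReport(
        truth_metric=truth_metric,
        global_r=global_r,
        global_rho=global_rho,
        per_target_r=float(np.mean(rs)) if rs else float("nan"),
        per_target_rho=float(np.mean(rhos)) if rhos else float("nan"),
        per_target_r_fisher=fisher_z_mean(rs),
        per_target_rho_fisher=fisher_z_mean(rhos),
        per_target_loss=float(np.mean(losses)),
        n_targets=df["target_id"].nunique(),
        n_decoys=len(df),
        n_degenerate_targets=n_degenerate,
    )


def load_eval_table(predictions_csv: str | Path, truth_csv: str | Path) -> pd.DataFrame:
    """Join a predictions CSV (target_id, decoy_id, score) with a truth CSV.

    The truth CSV carries any subset of tm, gdt_ts, lddt, inf_all, rmsd.
    Rows present in only one file are an error (first offenders listed).
    """
    pred = pd.read_csv(predictions_csv)
    truth = pd.read_csv(truth_csv)
    for name, df in (("predictions", pred), ("truth", truth)):
        if not {"target_id", "decoy_id"}.issubset(df.columns):
            raise EvaluationInputError(f"{name} CSV needs target_id and decoy_id")
    score_col = "score" if "score" in pred.columns else "predicted"
    if score_col not in pred.columns:
        raise EvaluationInputError("predictions CSV needs a 'score' column")
    merged = pred.rename(columns={score_col: "predicted"}).merge(
        truth, on=["target_id", "decoy_id"], how="outer", indicator=True
    )
    bad = merged[merged["_merge"] != "both"]
    if len(bad):
        offenders = [
            f"{r.target_id}/{r.decoy_id}" for r in bad.head(5).itertuples()
        ]
        raise EvaluationInputError(
            f"{len(bad)} unmatched (target_id, decoy_id) rows, e.g. {offenders}"
        )
    return merged.drop(columns="_merge")
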