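import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import pearsonr, spearmanr

from oracles import fisher_mean_direct, naive_top1_loss
from parsebp import (
    composite_score,
    correlation_report,
    fisher_z_mean,
    load_eval_table,
    minmax_normalize,
    negate_if_energy,
    top1_loss,
)
from parsebp.errors import EvaluationInputError


class TestCompositeScore:
    def test_perfect_components(self):
        assert composite_score(1, 1, 1) == pytest.approx(1.0, abs=1e-15)
        assert composite_score(0, 0, 0) == 0.0

    def test_weighted_sum(self):
        assert composite_score(0.8, 0.6, 0.7) == pytest.approx(0.70, abs=1e-12)

    def test_missing_component_rejected(self):
        with pytest.raises(EvaluationInputError):
            composite_score(0.5, None, 0.5)
        with pytest.raises(EvaluationInputError):
            composite_score([0.5, np.nan], [0.5, 0.5], [0.5, 0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(EvaluationInputError):
            composite_score(1.2, 0.5, 0.5)


class TestMinMax:
    def test_linear_spread(self):
        assert list(minmax_normalize([2, 4, 6])) == [0.0, 0.5, 1.0]

    def test_constant_maps_to_half(self):
        assert list(minmax_normalize([5, 5, 5])) == [0.5, 0.5, 0.5]

    @given(st.floats(0.1, 50), st.floats(-100, 100))
    def test_affine_invariance(self, scale, shift):
        x = np.array([1.0, 3.0, 7.0, 2.0])
        assert np.allclose(minmax_normalize(x * scale + shift),
                           minmax_normalize(x), atol=1e-9)

    def test_too_few_values_rejected(self):
        with pytest.raises(EvaluationInputError):
            minmax_normalize([1.0])


class TestNegation:
    def test_lower_better_negated(self):
        assert list(negate_if_energy([-3.2, -1.0], "lower_better")) == [3.2, 1.0]

    def test_higher_better_identity(self):
        assert list(negate_if_energy([1.0, 2.0], "higher_better")) == [1.0, 2.0]

    def test_double_application_is_involution(self):
        x = np.array([-3.2, 0.0, 5.5])
        assert np.array_equal(
            negate_if_energy(negate_if_energy(x, "lower_better"), "lower_better"), x
        )


class TestTop1Loss:
    def test_correct_top_pick_has_zero_loss(self):
        assert top1_loss([0.9, 0.1], [0.8, 0.2]) == 0.0

    def test_arithmetic_from_definition(self):
        assert top1_loss([0.1, 0.7], [0.9, 0.6]) == pytest.approx(0.3, abs=1e-15)

    def test_matches_literal_oracle_on_random_tables(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 15))
            pred = rng.uniform(0, 1, n)
            truth = rng.uniform(0, 1, n)
            ids = [f"d{k}" for k in range(n)]
            assert top1_loss(pred, truth, ids=ids) == pytest.approx(
                naive_top1_loss(list(pred), list(truth), ids), abs=0
            )

    def test_predicted_ties_break_by_id(self):
        # both decoys predicted equal; lexicographically smaller id wins
        assert top1_loss([0.5, 0.5], [0.2, 0.9], ids=["a", "b"]) == pytest.approx(0.7)
        assert top1_loss([0.5, 0.5], [0.9, 0.2], ids=["a", "b"]) == 0.0


class TestFisherZ:
    def test_two_target_average(self):
        expected = math.tanh((math.atanh(0.8) + math.atanh(0.6)) / 2)
        assert fisher_z_mean([0.8, 0.6]) == pytest.approx(expected, abs=1e-12)

    def test_matches_direct_oracle(self, rng):
        rs = rng.uniform(-0.99, 0.99, 20)
        assert fisher_z_mean(rs) == pytest.approx(fisher_mean_direct(rs), abs=1e-12)

    def test_perfect_correlations_survive_clipping(self):
        assert abs(fisher_z_mean([1.0, 1.0]) - 1.0) < 1e-9


def _table(rng, n_targets=3, n_decoys=8, noise=0.0):
    rows = []
    for t in range(n_targets):
        truth = rng.uniform(0.2, 0.9, n_decoys)
        pred = truth + rng.normal(0, noise, n_decoys) if noise else truth.copy()
        for k in range(n_decoys):
            rows.append({
                "target_id": f"T{t}", "decoy_id": f"d{k:02d}",
                "predicted": pred[k], "tm": truth[k],
                "gdt_ts": truth[k], "lddt": truth[k],
            })
    return pd.DataFrame(rows)


class TestCorrelationReport:
    def test_perfect_predictions(self, rng):
        report = correlation_report(_table(rng), truth_metric="G")
        assert report.global_r == pytest.approx(1.0, abs=1e-9)
        assert report.global_rho == pytest.approx(1.0, abs=1e-9)
        assert report.per_target_loss == 0.0
        assert report.n_targets == 3

    def test_per_target_averages_match_direct_computation(self, rng):
        df = _table(rng, noise=0.1)
        report = correlation_report(df, truth_metric="G")
        rs, rhos = [], []
        for _, grp in df.groupby("target_id"):
            g = composite_score(grp["tm"].values, grp["gdt_ts"].values, grp["lddt"].values)
            rs.append(pearsonr(grp["predicted"], g)[0])
            rhos.append(spearmanr(grp["predicted"], g)[0])
        assert report.per_target_r == pytest.approx(np.mean(rs), abs=1e-12)
        assert report.per_target_rho == pytest.approx(np.mean(rhos), abs=1e-12)
        assert report.per_target_r_fisher == pytest.approx(fisher_mean_direct(rs), abs=1e-12)

    def test_global_metrics_invariant_to_per_target_affine_rescaling(self, rng):
        df = _table(rng, noise=0.05)
        base = correlation_report(df, truth_metric="G")
        scaled = df.copy()
        for t, factor, shift in (("T0", 10.0, 5.0), ("T1", 0.2, -3.0), ("T2", 1.0, 100.0)):
            sel = scaled["target_id"] == t
            scaled.loc[sel, "predicted"] = scaled.loc[sel, "predicted"] * factor + shift
        rescaled = correlation_report(scaled, truth_metric="G")
        assert rescaled.global_r == pytest.approx(base.global_r, abs=1e-12)
        assert rescaled.global_rho == pytest.approx(base.global_rho, abs=1e-12)

    def test_rmsd_truth_is_negated(self, rng):
        rows = []
        truth_rmsd = [1.0, 5.0, 9.0]
        pred = [0.9, 0.5, 0.1]  # anti-correlated with RMSD = perfectly correct
        for k in range(3):
            rows.append({"target_id": "T0", "decoy_id": f"d{k}",
                         "predicted": pred[k], "rmsd": truth_rmsd[k]})
        report = correlation_report(pd.DataFrame(rows), truth_metric="rmsd")
        assert report.global_r == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_target_dropped_from_correlations_only(self, rng):
        df = _table(rng, n_targets=2, noise=0.1)
        df.loc[df["target_id"] == "T1", "predicted"] = 0.5  # constant predictions
        report = correlation_report(df, truth_metric="G")
        assert report.n_degenerate_targets == 1
        assert np.isfinite(report.per_target_r)

    def test_shuffled_predictions_have_near_zero_mean_rho(self, rng):
        rhos = []
        for _ in range(200):
            truth = rng.uniform(0, 1, 10)
            pred = rng.permutation(truth)
            rhos.append(spearmanr(pred, truth).statistic)
        se = np.std(rhos) / np.sqrt(len(rhos))
        assert abs(np.mean(rhos)) < 2 * se + 1e-9

    @given(st.sampled_from(["exp", "cube", "affine"]))
    def test_spearman_invariant_under_monotone_transforms(self, transform):
        # rank correlations within a target ignore any strictly monotone
        # rescaling of the predictions (the global pooled rho is only
        # affine-invariant, because pooling happens after per-target min-max)
        rng = np.random.default_rng(7)
        df = _table(rng, noise=0.2)
        base = correlation_report(df, truth_metric="G")
        warped = df.copy()
        f = {"exp": np.exp, "cube": lambda x: x**3,
             "affine": lambda x: 4.2 * x + 1.0}[transform]
        warped["predicted"] = f(warped["predicted"])
        report = correlation_report(warped, truth_metric="G")
        assert report.per_target_rho == pytest.approx(base.per_target_rho, abs=1e-12)
        assert report.per_target_rho_fisher == pytest.approx(
            base.per_target_rho_fisher, abs=1e-12)
        if transform == "affine":
            assert report.global_rho == pytest.approx(base.global_rho, abs=1e-12)

    def test_missing_truth_column_rejected(self, rng):
        df = _table(rng).drop(columns=["lddt"])
        with pytest.raises(EvaluationInputError):
            correlation_report(df, truth_metric="G")


class TestLoadEvalTable:
    def test_join_and_mismatch_detection(self, tmp_path, rng):
        df = _table(rng)
        pred = df[["target_id", "decoy_id", "predicted"]].rename(
            columns={"predicted": "score"})
        truth = df[["target_id", "decoy_id", "tm", "gdt_ts", "lddt"]]
        p, t = tmp_path / "pred.csv", tmp_path / "truth.csv"
        pred.to_csv(p, index=False)
        truth.to_csv(t, index=False)
        table = load_eval_table(p, t)
        assert len(table) == len(df)
        pred.iloc[1:].to_csv(p, index=False)
        with pytest.raises(EvaluationInputError, match="unmatched"):
            load_eval_table(p, t)
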