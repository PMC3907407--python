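"""Detection p-values, %P-call, median-array correlation and filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ffpesig import (
    ExpressionMatrix,
    ValidationError,
    detection_pvalues,
    filter_by_pcall,
    intersample_correlation,
    median_profile,
    percent_present,
    qc_report,
    replicate_r2,
    suggest_pcall_threshold,
)
from ffpesig.qc import QCReport


def brute_force_detection_p(matrix: ExpressionMatrix) -> np.ndarray:
    """Independent oracle: add-one empirical rank against the controls."""
    ctrl = matrix.control_values().to_numpy()
    vals = matrix.values.to_numpy()
    n_ctrl = ctrl.shape[0]
    out = np.empty_like(vals)
    for i in range(vals.shape[0]):
        for j in range(vals.shape[1]):
            ge = sum(1 for c in ctrl[:, j] if c >= vals[i, j])
            out[i, j] = (1 + ge) / (1 + n_ctrl)
    return out


class TestDetectionPvalues:
    def test_matches_brute_force_oracle(self, toy_matrix):
        got = detection_pvalues(toy_matrix).detection_p.to_numpy()
        expected = brute_force_detection_p(toy_matrix)
        np.testing.assert_array_equal(got, expected)

    def test_rank_formula_extremes(self):
        # 99 controls; a cell above every control gets p = 1/100, a cell
        # below every control gets p = 1
        genes = ["G0", "G1"] + [f"NEG_{i}" for i in range(99)]
        vals = np.vstack(
            [[1e9], [0.0], np.linspace(10, 100, 99)[:, None]]
        )
        m = ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=["s"]))
        p = detection_pvalues(m).detection_p
        assert p.loc["G0", "s"] == pytest.approx(1 / 100)
        assert p.loc["G1", "s"] == 1.0

    def test_monotone_in_signal_within_sample(self, toy_matrix):
        m = detection_pvalues(toy_matrix)
        v = m.values.iloc[:, 0].to_numpy()
        p = m.detection_p.iloc[:, 0].to_numpy()
        order = np.argsort(v)
        assert (np.diff(p[order]) <= 0).all()

    def test_requires_controls_and_raw_scale(self, toy_matrix):
        no_ctrl = ExpressionMatrix(
            toy_matrix.values.copy(),
            control_flags=pd.Series(False, index=toy_matrix.gene_ids),
        )
        with pytest.raises(ValidationError):
            detection_pvalues(no_ctrl)
        with pytest.raises(ValidationError, match="raw"):
            detection_pvalues(toy_matrix.to_log2())


class TestPercentPresent:
    def test_hand_count(self):
        genes = [f"G{i}" for i in range(10)]
        pvals = [0.01] * 4 + [0.20] * 6
        m = ExpressionMatrix(
            pd.DataFrame(np.ones((10, 1)), index=genes, columns=["s"]),
            detection_p=pd.DataFrame(
                np.array(pvals)[:, None], index=genes, columns=["s"]
            ),
        )
        assert percent_present(m, 0.05)["s"] == pytest.approx(0.40)

    def test_all_detected(self):
        genes = [f"G{i}" for i in range(10)]
        m = ExpressionMatrix(
            pd.DataFrame(np.ones((10, 1)), index=genes, columns=["s"]),
            detection_p=pd.DataFrame(
                np.full((10, 1), 0.001), index=genes, columns=["s"]
            ),
        )
        assert percent_present(m)["s"] == 1.0

    def test_invariant_under_monotone_per_sample_transform(self, toy_matrix):
        # detection is a rank statistic: squaring every signal of a sample
        # (a strictly monotone transform on positives) leaves %P unchanged
        base = percent_present(detection_pvalues(toy_matrix))
        squared = ExpressionMatrix(
            toy_matrix.values**2, control_flags=toy_matrix.control_flags
        )
        np.testing.assert_allclose(
            percent_present(detection_pvalues(squared)).to_numpy(),
            base.to_numpy(),
        )

    def test_missing_detection_p_errors(self, toy_matrix):
        with pytest.raises(ValidationError, match="detection_p"):
            percent_present(toy_matrix)


class TestMedianProfile:
    @pytest.mark.parametrize(
        "values,expected",
        [((1.0, 2.0, 9.0), 2.0), ((1.0, 2.0, 4.0, 8.0), 3.0)],
    )
    def test_odd_and_even_conventions(self, values, expected):
        m = ExpressionMatrix(
            pd.DataFrame(
                [list(values)], index=["G0"],
                columns=[f"s{j}" for j in range(len(values))],
            )
        )
        assert median_profile(m)["G0"] == expected

    def test_identical_samples_and_permutation_invariance(self, toy_matrix):
        prof = median_profile(toy_matrix)
        perm = toy_matrix.subset_samples(list(toy_matrix.sample_ids[::-1]))
        pd.testing.assert_series_equal(prof, median_profile(perm))
        same = ExpressionMatrix(
            pd.concat([toy_matrix.values.iloc[:, [0]]] * 3, axis=1).set_axis(
                ["a", "b", "c"], axis=1
            ),
            control_flags=toy_matrix.control_flags,
        )
        np.testing.assert_allclose(
            median_profile(same).to_numpy(), toy_matrix.values.iloc[:, 0]
        )

    def test_single_sample_errors(self, toy_matrix):
        with pytest.raises(ValidationError):
            median_profile(toy_matrix.subset_samples([toy_matrix.sample_ids[0]]))


class TestIntersampleCorrelation:
    def test_identity_and_anticorrelation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(8, 2, 200)
        genes = [f"G{i}" for i in range(200)]
        m = ExpressionMatrix(
            pd.DataFrame(
                {"same": x, "anti": 16.0 - x}, index=genes
            ),
            scale="log2",
        )
        r = intersample_correlation(m, pd.Series(x, index=genes))
        assert r["same"] == pytest.approx(1.0)
        assert r["anti"] == pytest.approx(-1.0)

    def test_affine_rescaling_invariance(self, toy_matrix):
        prof = median_profile(toy_matrix)
        logm = toy_matrix.to_log2()
        r1 = intersample_correlation(logm, np.log2(prof + 1))
        scaled = logm.copy()
        scaled.values = scaled.values * 3.0 + 7.0
        r2 = intersample_correlation(scaled, np.log2(prof + 1))
        np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-12)

    def test_independent_profiles_near_zero(self):
        # Monte-Carlo: unrelated standard-normal profiles over 8000 genes
        rng = np.random.default_rng(44)
        genes = [f"G{i}" for i in range(8000)]
        vals = pd.DataFrame(
            rng.normal(0, 1, (8000, 20)), index=genes,
            columns=[f"s{j}" for j in range(20)],
        )
        m = ExpressionMatrix(vals, scale="log2")
        prof = pd.Series(rng.normal(0, 1, 8000), index=genes)
        r = intersample_correlation(m, prof)
        assert (r.abs() < 0.05).all()

    def test_zero_variance_sample_warns_nan(self):
        genes = [f"G{i}" for i in range(50)]
        vals = pd.DataFrame(
            {"flat": np.ones(50), "ok": np.arange(50.0)}, index=genes
        )
        m = ExpressionMatrix(vals, scale="log2")
        with pytest.warns(UserWarning, match="zero variance"):
            r = intersample_correlation(m, pd.Series(np.arange(50.0), index=genes))
        assert np.isnan(r["flat"]) and r["ok"] == pytest.approx(1.0)


class TestFilterByPcall:
    def _report(self, pcalls: dict, threshold=0.20) -> QCReport:
        df = pd.DataFrame(
            {
                "pcall": pd.Series(pcalls),
                "median_corr": 0.9,
                "passed": pd.Series(pcalls) >= threshold,
            }
        )
        return QCReport(samples=df, pcall_threshold=threshold)

    def test_boundary_is_strict_below(self, toy_matrix):
        sids = list(toy_matrix.sample_ids)[:4]
        m = toy_matrix.subset_samples(sids)
        report = self._report(dict(zip(sids, [0.10, 0.19, 0.20, 0.55])))
        kept, rep = filter_by_pcall(m, report)
        assert list(kept.sample_ids) == sids[2:]
        assert rep.samples["passed"].all()

    @pytest.mark.parametrize("pcall,passes", [(0.199, False), (0.200, True)])
    def test_threshold_edge(self, toy_matrix, pcall, passes):
        sids = list(toy_matrix.sample_ids)
        pcalls = {s: 0.9 for s in sids}
        pcalls[sids[0]] = pcall
        kept, _ = filter_by_pcall(toy_matrix, self._report(pcalls))
        assert (sids[0] in kept.sample_ids) is passes

    def test_identity_when_all_pass_preserves_order(self, toy_matrix):
        report = self._report({s: 0.5 for s in toy_matrix.sample_ids})
        kept, _ = filter_by_pcall(toy_matrix, report)
        assert list(kept.sample_ids) == list(toy_matrix.sample_ids)

    def test_all_fail_raises_with_diagnostics(self, toy_matrix):
        report = self._report({s: 0.01 for s in toy_matrix.sample_ids})
        with pytest.raises(ValidationError, match="all samples fail"):
            filter_by_pcall(toy_matrix, report)

    def test_retention_matches_survival_model_oracle(self, default_cohort):
        """Realized AS retention tracks a prediction computed directly from
        the generator truth via the fragment-survival formula."""
        from ffpesig.simulate import default_fragment_lengths, _SUB_DEGRADE

        cohort = default_cohort
        report = qc_report(cohort.as_)
        kept, _ = filter_by_pcall(cohort.as_, report)
        realized = kept.n_samples / cohort.as_.n_samples

        lengths = default_fragment_lengths(
            cohort.fc.n_genes - cohort.fc.n_controls, 11 + _SUB_DEGRADE
        )
        fc_vals = cohort.fc.gene_values().to_numpy()
        ctrl = cohort.fc.control_values().to_numpy()
        n_pass = 0
        for j, sid in enumerate(cohort.fc.sample_ids):
            sev = cohort.truth.severity_per_sample[sid]
            # detection needs signal above the 10th-largest control value
            cut = np.sort(ctrl[:, j])[-10]
            expected_pcall = (
                fc_vals[:, j] * np.exp(-sev * lengths) / 40.0 > cut
            ).mean()
            n_pass += expected_pcall >= 0.20
        predicted = n_pass / cohort.fc.n_samples
        assert abs(realized - predicted) <= 0.10


class TestReplicateR2:
    def test_identity_and_affine_invariance(self):
        rng = np.random.default_rng(8)
        a = rng.normal(8, 2, 500)
        assert replicate_r2(a, a) == pytest.approx(1.0)
        assert replicate_r2(a, 2 * a + 3) == pytest.approx(1.0)

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning):
            assert np.isnan(replicate_r2(np.ones(10), np.arange(10.0)))

    def test_archived_section_regime_brackets_reported_band(self, default_cohort):
        """Technical replicates of a degraded extract reproduce at
        R^2 ~ 0.9, the regime reported for archived-section arrays."""
        from ffpesig.simulate import simulate_technical_replicates

        a, b = simulate_technical_replicates(default_cohort.as_, seed=2)
        sev = pd.Series(default_cohort.truth.severity_per_sample)
        typical = (sev - sev.median()).abs().idxmin()
        x = np.log2(a.gene_values()[typical] + 1)
        y = np.log2(b.gene_values()[typical] + 1)
        assert 0.85 <= replicate_r2(x, y) <= 0.95


class TestSuggestPcallThreshold:
    def _step_cohort(self, step_at: float, rng):
        pcalls = pd.Series(np.linspace(0.05, 0.6, 40))
        corr = np.where(pcalls >= step_at, 0.9, 0.5) + rng.normal(0, 0.02, 40)
        return pcalls, pd.Series(corr)

    @pytest.mark.parametrize("step_at", [0.20, 0.35])
    def test_recovers_planted_change_point(self, step_at):
        pcalls, corr = self._step_cohort(step_at, np.random.default_rng(1))
        got = suggest_pcall_threshold(pcalls, corr)
        grid_step = float(np.diff(np.sort(pcalls.unique())).max())
        assert abs(got - step_at) <= grid_step + 1e-9

    def test_monotone_trend_returns_default_with_warning(self):
        pcalls = pd.Series(np.linspace(0.05, 0.6, 40))
        corr = pd.Series(0.4 + 0.8 * pcalls)
        with pytest.warns(UserWarning, match="no sharp"):
            assert suggest_pcall_threshold(pcalls, corr) == 0.20

    def test_degenerate_inputs_return_default(self):
        with pytest.warns(UserWarning):
            got = suggest_pcall_threshold(
                pd.Series([0.3] * 12), pd.Series([0.9] * 12)
            )
        assert got == 0.20


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_qc_report_pass_flag_matches_threshold(seed):
    """passed <=> pcall >= threshold, whatever the data."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i}" for i in range(60)] + [f"NEG_{i}" for i in range(25)]
    m = ExpressionMatrix(
        pd.DataFrame(
            rng.lognormal(4, 1.5, (85, 6)),
            index=genes,
            columns=[f"s{j}" for j in range(6)],
        )
    )
    report = qc_report(m, pcall_threshold=0.3)
    assert (
        report.samples["passed"] == (report.samples["pcall"] >= 0.3)
    ).all()
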