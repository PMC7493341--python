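"""Amplification efficiency, delta-delta-Ct quantification, decision tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from macetools.rtqpcr import (
    amplification_efficiency,
    compare_genotypes,
    concordance,
    ddct,
)
from macetools.rtqpcr import test_regulation as regulation_call
from macetools.synth import SynthConfig, generate_ct_table


class TestEfficiency:
    def test_perfect_doubling_is_100pct(self):
        log_input = np.array([0.0, -1.0, -2.0, -3.0])
        ct = 20.0 - (1.0 / np.log10(2.0)) * log_input  # slope -3.3219...
        res = amplification_efficiency(log_input, ct)
        assert res.efficiency == pytest.approx(1.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0)

    def test_slope_minus_3p6_formula(self):
        log_input = np.array([0.0, -1.0, -2.0, -3.0])
        res = amplification_efficiency(log_input, 20.0 - 3.6 * log_input)
        assert res.efficiency == pytest.approx(10 ** (1 / 3.6) - 1, rel=1e-9)

    def test_positive_slope_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            amplification_efficiency(np.array([0.0, -1, -2]), np.array([24.0, 23, 22]))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            amplification_efficiency(np.array([0.0, -1]), np.array([20.0, 23]))


def ct_rows(gene, role, condition, cts_by_rep):
    rows = []
    for rep, cts in cts_by_rep.items():
        for ct in cts:
            rows.append(
                {"bio_rep": rep, "gene": gene, "role": role,
                 "condition": condition, "timepoint": "8min", "ct": ct}
            )
    return rows


class TestDdct:
    def build(self, target_stress_ct):
        rows = []
        for cond in ("control", "stress"):
            rows += ct_rows("ref", "reference", cond, {"r1": [20.0] * 3})
        rows += ct_rows("tgt", "target", "control", {"r1": [24.0] * 3})
        rows += ct_rows("tgt", "target", "stress", {"r1": [target_stress_ct] * 3})
        return pd.DataFrame(rows)

    def test_zero_ddct_gives_rq_one(self):
        rel = ddct(self.build(24.0), target="tgt", reference="ref")
        assert rel["ddct"].iloc[0] == 0.0
        assert rel["rq"].iloc[0] == 1.0

    def test_minus_one_ddct_gives_rq_two(self):
        rel = ddct(self.build(23.0), target="tgt", reference="ref")
        assert rel["ddct"].iloc[0] == -1.0
        assert rel["rq"].iloc[0] == 2.0

    def test_technical_replicates_averaged_first(self):
        rows = []
        for cond in ("control", "stress"):
            rows += ct_rows("ref", "reference", cond, {"r1": [20.0] * 3})
        rows += ct_rows("tgt", "target", "control", {"r1": [23.0, 24.0, 25.0]})
        rows += ct_rows("tgt", "target", "stress", {"r1": [22.0, 23.0, 24.0]})
        rel = ddct(pd.DataFrame(rows), target="tgt", reference="ref")
        assert rel["ddct"].iloc[0] == pytest.approx(-1.0)

    def test_missing_reference_rejected(self):
        table = pd.DataFrame(ct_rows("tgt", "target", "control", {"r1": [24.0] * 3}))
        with pytest.raises(ValueError):
            ddct(table, target="tgt", reference="ref")

    def test_noise_free_generator_truth_recovered_exactly(self):
        cfg = SynthConfig(seed=1, ct_noise_sd=0.0, qpcr_true_rq=(("tg", 4.0),))
        table, truth = generate_ct_table(cfg)
        rel = ddct(table, target="tg", reference=cfg.qpcr_reference)
        assert (rel["rq"] == 4.0).all()

    def test_rq_invariant_under_global_ct_shift(self):
        cfg = SynthConfig(seed=2, ct_noise_sd=0.1, qpcr_true_rq=(("tg", 2.0),))
        table, _ = generate_ct_table(cfg)
        shifted = table.copy()
        shifted["ct"] = shifted["ct"] + 3.0
        a = ddct(table, target="tg", reference=cfg.qpcr_reference)
        b = ddct(shifted, target="tg", reference=cfg.qpcr_reference)
        assert np.allclose(a["rq"], b["rq"])


class TestRegulationCalls:
    def test_clear_up_regulation(self):
        values = np.array([4.1, 3.9, 4.0])
        call, p = regulation_call(values)
        # independent check: one-sided t against mu0 = 2
        t = (values.mean() - 2.0) / (values.std(ddof=1) / np.sqrt(3))
        assert call == "up"
        assert p == pytest.approx(stats.t.sf(t, df=2))

    def test_clear_down_regulation(self):
        values = np.array([0.2, 0.3, 0.25])
        call, p = regulation_call(values)
        t = (values.mean() - 1.0) / (values.std(ddof=1) / np.sqrt(3))
        assert call == "down"
        assert p == pytest.approx(stats.t.cdf(t, df=2))

    def test_between_thresholds_is_ns(self):
        call, _ = regulation_call(np.array([1.4, 1.5, 1.6]))
        assert call == "ns"

    def test_zero_variance_guard(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            call, p = regulation_call(np.array([1.0, 1.0, 1.0]))
        assert call == "ns"

    def test_type_i_error_at_null_mean_between_thresholds(self):
        """Simulated null at mean 1.5 (inside both one-sided alternatives):
        the fraction of up/down calls stays at or below alpha."""
        rng = np.random.default_rng(42)
        false_calls = 0
        n_sim = 2000
        for _ in range(n_sim):
            values = rng.normal(1.5, 0.3, size=3)
            call, _ = regulation_call(values)
            false_calls += call != "ns"
        assert false_calls / n_sim <= 0.05


class TestCompareGenotypes:
    def test_identical_groups_not_different(self):
        p, different = compare_genotypes(np.array([1.0, 1.1, 0.9]), np.array([1.0, 1.1, 0.9]))
        assert p == pytest.approx(1.0)
        assert not different

    def test_separated_groups_different(self):
        p, different = compare_genotypes(
            np.array([1.0, 1.1, 0.9]), np.array([8.0, 8.2, 7.8])
        )
        assert different and p < 0.05

    def test_single_value_group_rejected(self):
        with pytest.raises(ValueError):
            compare_genotypes(np.array([1.0]), np.array([2.0, 3.0]))


class TestConcordance:
    def test_identical_signs_full_agreement(self):
        a = pd.Series([1.0, -2.0, 3.0, -0.5], index=list("abcd"))
        b = pd.Series([2.0, -1.0, 0.5, -3.0], index=list("abcd"))
        out = concordance(a, b)
        assert out["sign_agreement"] == 1.0

    def test_one_discordant_of_four(self):
        a = pd.Series([1.0, -2.0, 3.0, -0.5], index=list("abcd"))
        b = pd.Series([2.0, -1.0, 0.5, 3.0], index=list("abcd"))
        assert concordance(a, b)["sign_agreement"] == 0.75

    def test_concordant_truth_high_rank_correlation(self):
        rng = np.random.default_rng(6)
        truth = pd.Series(rng.normal(size=30), index=[f"g{i}" for i in range(30)])
        noisy = truth + rng.normal(0, 0.2, size=30)
        assert concordance(truth, noisy)["spearman_rho"] >= 0.9
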