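"""Median split, KM, log-rank and BH-FDR vs. brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from interactome.io import ValidationError
from interactome.survival import (
    fdr_adjust,
    km_curve,
    logrank_test,
    median_split,
    run_survival_screen,
)
from interactome.synthio import SimulationConfig, generate_bundle

from oracles import (
    bh_stepup_oracle,
    km_median_oracle,
    km_product_limit_oracle,
    logrank_oracle,
)


class TestMedianSplit:
    def test_even_split_no_ties(self):
        values = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        high, low = median_split(values)
        assert set(high) == {"c", "d"} and set(low) == {"a", "b"}

    def test_ties_at_median_go_low(self):
        values = pd.Series([1.0, 2.0, 2.0, 3.0], index=list("abcd"))
        high, low = median_split(values)
        assert set(high) == {"d"} and set(low) == {"a", "b", "c"}

    def test_group_sizes_match_counting_oracle(self, rng):
        values = pd.Series(rng.uniform(size=101), index=[f"s{i}" for i in range(101)])
        high, low = median_split(values)
        assert len(high) == int((values > values.median()).sum())
        assert len(low) == 101 - len(high)

    def test_degenerate_and_small_inputs_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            median_split(pd.Series([2.0] * 6, index=list("abcdef")))
        with pytest.raises(ValidationError):
            median_split(pd.Series([1.0, 2.0, 3.0], index=list("abc")))


class TestKMCurve:
    def test_no_censoring_equals_empirical_survival(self):
        times = np.arange(1.0, 11.0)
        events = np.ones(10, bool)
        km = km_curve(times, events)
        for t in times:
            assert km.survival.loc[t] == pytest.approx(1.0 - t / 10.0, abs=1e-12)
        assert km.median == 5.0

    def test_all_censored_never_reaches_median(self):
        km = km_curve(np.array([3.0, 8.0, 12.0]), np.zeros(3, bool))
        assert (km.survival.to_numpy() == 1.0).all()
        assert math.isnan(km.median)

    def test_mixed_censoring_matches_product_limit_oracle(self, rng):
        times = rng.exponential(10.0, 20).round(2)
        events = rng.random(20) < 0.7
        if not events.any():
            events[0] = True
        km = km_curve(times, events)
        for t, s in km_product_limit_oracle(times, events).items():
            assert km.survival.loc[t] == pytest.approx(s, abs=1e-12)
        oracle_median = km_median_oracle(times, events)
        assert (math.isnan(km.median) and math.isnan(oracle_median)) or (
            km.median == pytest.approx(oracle_median)
        )

    def test_negative_times_rejected(self):
        with pytest.raises(ValidationError):
            km_curve(np.array([-1.0, 2.0]), np.array([1, 1]))


class TestLogrank:
    def test_identical_groups_null(self, rng):
        times = rng.exponential(10.0, 25)
        events = rng.random(25) < 0.8
        chi2, p = logrank_test(times, events, times, events)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_o_e_var_tabulation_oracle(self, rng):
        """Seeded equal-rate exponentials: statistic and p within 1e-9 of
        the hand-tabulated hypergeometric O/E/Var computation."""
        for _ in range(20):
            ta = rng.exponential(20.0, 30).round(1)
            tb = rng.exponential(20.0, 30).round(1)
            ea = rng.random(30) < 0.8
            eb = rng.random(30) < 0.8
            if not (ea.any() or eb.any()):
                ea[0] = True
            chi2, p = logrank_test(ta, ea, tb, eb)
            o_chi2, o_p = logrank_oracle(ta, ea, tb, eb)
            assert chi2 == pytest.approx(o_chi2, abs=1e-9)
            assert p == pytest.approx(o_p, abs=1e-9)

    def test_large_effect_detected(self, rng):
        ta = rng.exponential(30.0, 1000)
        tb = rng.exponential(10.0, 1000)  # hazard ratio 3
        ones = np.ones(1000, bool)
        chi2, p = logrank_test(ta, ones, tb, ones)
        o_chi2, o_p = logrank_oracle(ta, ones, tb, ones)
        assert p < 1e-6 and o_p < 1e-6
        assert chi2 == pytest.approx(o_chi2, rel=1e-9)

    def test_label_swap_symmetry(self, rng):
        ta, tb = rng.exponential(10, 15), rng.exponential(15, 20)
        ea, eb = np.ones(15, bool), np.ones(20, bool)
        forward = logrank_test(ta, ea, tb, eb)
        backward = logrank_test(tb, eb, ta, ea)
        assert forward[0] == pytest.approx(backward[0])
        assert forward[1] == pytest.approx(backward[1])

    def test_zero_events_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test(
                np.array([1.0, 2.0]), np.zeros(2, bool),
                np.array([3.0]), np.zeros(1, bool),
            )


class TestFDR:
    def test_single_p_identity(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_textbook_step_up(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones_stay_capped(self):
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_direct_formula_oracle(self, rng):
        for _ in range(100):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            np.testing.assert_allclose(fdr_adjust(p), bh_stepup_oracle(p), atol=1e-12)

    def test_properties(self, rng):
        p = rng.uniform(size=25)
        q = fdr_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        # adjusted values are monotone in the raw ordering
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            fdr_adjust([0.5, 1.2])


class TestScreen:
    def test_planted_protective_gene_ranks_first(self):
        """One strongly protective gene among nulls: smallest FDR p and
        longer median survival in the high-expression group."""
        config = SimulationConfig(
            n_genes=120,
            n_samples=500,
            n_pairs=10,
            n_planted_per_axis=1,
            n_prognostic=1,
            log_hazard_beta=-1.0,
            seed=17,
        )
        bundle = generate_bundle(config)
        target = bundle.prognostic_genes[0]
        nulls = [g for g in bundle.expression.index[-9:]]
        results = run_survival_screen(
            bundle.expression, bundle.clinical, [target] + nulls, "os"
        )
        best = results.loc[results["p_fdr"].idxmin()]
        assert best["gene"] == target
        assert best["median_high"] > best["median_low"]

    def test_empty_gene_list_is_vacuous(self, small_bundle):
        results = run_survival_screen(
            small_bundle.expression, small_bundle.clinical, [], "os"
        )
        assert results.empty

    def test_absent_genes_skipped(self, small_bundle):
        present = list(small_bundle.expression.index[:2])
        results = run_survival_screen(
            small_bundle.expression,
            small_bundle.clinical,
            present + ["NOT_A_GENE"],
            "dfs",
        )
        assert list(results["gene"]) == present

    def test_fdr_family_is_the_screen(self, small_bundle):
        genes = list(small_bundle.expression.index[:8])
        results = run_survival_screen(
            small_bundle.expression, small_bundle.clinical, genes, "os"
        )
        np.testing.assert_allclose(
            results["p_fdr"], bh_stepup_oracle(results["p_raw"].to_numpy()), atol=1e-12
        )
        assert (results["n_high"] + results["n_low"] == len(small_bundle.clinical)).all()

    def test_no_sample_overlap_rejected(self, small_bundle):
        clinical = small_bundle.clinical.copy()
        clinical.index = ["X" + s for s in clinical.index]
        with pytest.raises(ValidationError):
            run_survival_screen(
                small_bundle.expression,
                clinical,
                list(small_bundle.expression.index[:2]),
                "os",
            )


def test_exponential_median_recovery(rng):
    """KM median within 10% of ln2/h for n=1000 draws with light censoring."""
    h = 0.02
    times = rng.exponential(1 / h, 1000)
    censor = rng.uniform(0, 400, 1000)
    observed = times <= censor
    km = km_curve(np.minimum(times, censor), observed)
    assert km.median == pytest.approx(math.log(2) / h, rel=0.10)
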