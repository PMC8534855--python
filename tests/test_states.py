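"""Functional-state crossing, logistic association, chi-square residuals."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from acidscreen import (
    SimulationConfig,
    StateGeneSet,
    chi_square_residuals,
    compound_gene_sets,
    cross_state_compound,
    evaluate_states,
    information_gain,
    logistic_association,
    planted_truth,
    simulate_compound_panel,
    simulate_state_genesets,
    state_information_gain,
)
from acidscreen.states import StateCrossTable

from .oracles import mutual_information_bits


def _state(p_genes, n_genes, name="s"):
    return StateGeneSet(
        name=name,
        directions=pd.Series(
            ["p"] * len(p_genes) + ["n"] * len(n_genes), index=list(p_genes) + list(n_genes)
        ),
    )


def _ct(table):
    t = np.asarray(table, dtype=float)
    return StateCrossTable(state="s", table=t, degenerate=t.sum() == 0, n_overlap=int(t.sum()))


def test_cross_counts_by_direct_set_operations():
    ct = cross_state_compound(_state(["A", "B", "C"], []), {"A", "B"}, {"C"})
    np.testing.assert_array_equal(ct.table, [[2, 0], [1, 0]])
    assert not ct.degenerate


def test_disjoint_sets_flagged_degenerate():
    ct = cross_state_compound(_state(["X"], ["Y"]), {"A"}, {"B"})
    assert ct.degenerate
    with pytest.raises(ValueError, match="undefined"):
        state_information_gain(ct)


@pytest.mark.parametrize(
    "table, expected",
    [([[10, 0], [0, 10]], 1.0), ([[5, 5], [5, 5]], 0.0)],
)
def test_state_ig_endpoints(table, expected):
    assert state_information_gain(_ct(table)) == pytest.approx(expected, abs=1e-12)


@given(st.tuples(*[st.integers(0, 20)] * 4).filter(lambda c: sum(c) > 0))
def test_state_ig_equals_mutual_information(cells):
    table = np.array(cells, dtype=float).reshape(2, 2)
    assert information_gain(table).ig == pytest.approx(
        mutual_information_bits(table), abs=1e-12
    )


def test_state_and_compound_ig_share_one_formula():
    """Relabeling the alphabet (ru/pd -> p/n) cannot change the score."""
    table = [[7, 2], [3, 9]]
    assert state_information_gain(_ct(table)) == information_gain(table).ig


def test_logistic_association_closed_form_and_statsmodels():
    ct = _ct([[20, 10], [10, 20]])
    res = logistic_association(ct)
    assert res.odds_ratio == pytest.approx(4.0)
    se = np.sqrt(1 / 20 + 1 / 10 + 1 / 10 + 1 / 20)
    assert res.extra["se"] == pytest.approx(se)
    assert res.ci_low == pytest.approx(np.exp(np.log(4) - 1.96 * se), rel=1e-3)

    # independent oracle: logistic fit on the expanded 2x2
    y = np.r_[np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)]
    x = np.r_[np.ones(30), np.zeros(30)]
    fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
    assert np.log(res.odds_ratio) == pytest.approx(fit.params[1], abs=1e-6)
    assert res.p == pytest.approx(fit.pvalues[1], rel=1e-4)


def test_logistic_null_table_and_bonferroni():
    res = logistic_association(_ct([[10, 10], [10, 10]]), m_states=14)
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.p == pytest.approx(1.0)
    res2 = logistic_association(_ct([[20, 10], [10, 20]]), m_states=14)
    assert res2.p_adjusted == pytest.approx(min(1.0, 14 * res2.p))
    assert res2.p_adjusted >= res2.p


def test_haldane_correction_and_zero_margin():
    res = logistic_association(_ct([[10, 0], [5, 5]]))
    assert res.haldane_corrected and np.isfinite(res.odds_ratio)
    undef = logistic_association(_ct([[10, 0], [5, 0]]))
    assert undef.undefined and undef.reason == "zero margin"


def test_chi_square_hand_computed_example():
    chi2, p, resid = chi_square_residuals(_ct([[20, 10], [10, 20]]))
    assert chi2 == pytest.approx(20 / 3, abs=1e-3)  # E=15 everywhere, sum (±5)^2/15
    assert p == pytest.approx(stats.chi2.sf(20 / 3, 1), rel=1e-6)
    np.testing.assert_allclose(resid, [[5 / np.sqrt(15), -5 / np.sqrt(15)],
                                       [-5 / np.sqrt(15), 5 / np.sqrt(15)]])


def test_independence_structured_table_has_zero_chi2():
    chi2, p, resid = chi_square_residuals(_ct([[10, 20], [5, 10]]))
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(resid, 0.0, atol=1e-8)


@given(st.tuples(*[st.integers(1, 30)] * 4))
def test_residual_squares_sum_to_chi2(cells):
    ct = _ct(np.array(cells, dtype=float).reshape(2, 2))
    chi2, _, resid = chi_square_residuals(ct)
    assert (resid**2).sum() == pytest.approx(chi2, rel=1e-10)


def test_enriched_state_attains_maximal_ig():
    """The state built from planted RU/PD genes wins against random states
    when crossed with the planted reverser's gene sets."""
    wins = 0
    for seed in range(10):
        cfg = SimulationConfig(seed=seed)
        truth = planted_truth(cfg)
        panel = simulate_compound_panel(cfg, truth)
        states = simulate_state_genesets(cfg, truth)
        # gene-level fold change of the reverser: mean over its probes
        rev = panel.log_ratios.iloc[:, cfg.reverser_index]
        gene_fc = rev.groupby(panel.probe_gene).mean()
        up, down = compound_gene_sets(gene_fc)
        result = evaluate_states(states, up, down)
        wins += result["ig"].idxmax() == states[0].name
    assert wins >= 9


def test_null_states_give_uniform_chi2_pvalues(rng):
    """Random gene/direction assignment yields uniform chi-square p values."""
    pvals = []
    for _ in range(200):
        genes = [f"g{i}" for i in range(200)]
        st_genes = rng.choice(genes, 120, replace=False)
        state = _state(st_genes[:60], st_genes[60:])
        regulated = rng.choice(genes, 140, replace=False)
        up, down = set(regulated[:70]), set(regulated[70:])
        ct = cross_state_compound(state, up, down)
        pvals.append(chi_square_residuals(ct)[1])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01
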