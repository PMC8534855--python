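"""Welch t-test differential expression and the four-type classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from acidscreen import (
    SimulationConfig,
    classify_genes,
    differential_expression_t,
    planted_truth,
    simulate_acidosis_experiment,
)
from acidscreen.pipeline import normalize_counts


def _logm(arr):
    arr = np.asarray(arr, dtype=float)
    cols = [f"a{i}" for i in range(3)] + [f"n{i}" for i in range(3)]
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])], columns=cols), \
        cols[:3], cols[3:]


def test_identical_groups_are_exactly_null():
    logm, a, n = _logm([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
    res = differential_expression_t(logm, a, n)
    assert res.loc["g0", "t"] == 0.0 and res.loc["g0", "t_p"] == 1.0 and res.loc["g0", "fc"] == 0.0


def test_zero_variance_shift_hits_machine_floor():
    logm, a, n = _logm([[2.0, 2.0, 2.0, 1.0, 1.0, 1.0]])
    res = differential_expression_t(logm, a, n)
    assert res.loc["g0", "fc"] == 1.0
    assert res.loc["g0", "t_p"] == np.finfo(float).tiny


def test_matches_scipy_welch(rng):
    logm, a, n = _logm(rng.normal(5, 1, size=(50, 6)))
    res = differential_expression_t(logm, a, n)
    ref_t, ref_p = stats.ttest_ind(logm[a], logm[n], axis=1, equal_var=False)
    np.testing.assert_allclose(res["t"], ref_t, rtol=1e-12)
    np.testing.assert_allclose(res["t_p"], ref_p, rtol=1e-10)


def test_replicate_guard():
    logm, a, n = _logm(np.ones((2, 6)))
    with pytest.raises(ValueError, match="replicates"):
        differential_expression_t(logm, a[:1], n)


def test_planted_power_matches_monte_carlo_oracle():
    """Pipeline rejection rate on planted genes tracks a direct MC power
    estimate on the same generative model (3v3, dispersion 0.1, log2FC 1.5)."""
    impl_rates, oracle_rates = [], []
    rng = np.random.default_rng(77)
    for seed in range(8):
        cfg = SimulationConfig(seed=seed, effect_log2fc=1.5)
        truth = planted_truth(cfg)
        counts, cond = simulate_acidosis_experiment(cfg, truth)
        logm = normalize_counts(counts)
        res = differential_expression_t(
            logm, list(cond.index[cond == "acid"]), list(cond.index[cond == "normal"])
        )
        planted = truth.gene_class != "NA"
        impl_rates.append((res.loc[planted, "t_p"] < 0.05).mean())

        # independent oracle: draw NB counts directly, test with scipy
        n_mc = 400
        base = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, n_mc)
        size = 1.0 / cfg.dispersion
        hits = 0
        for mu in base:
            acid = rng.negative_binomial(size, size / (size + mu * 2**1.5), 3)
            norm = rng.negative_binomial(size, size / (size + mu), 3)
            p = stats.ttest_ind(np.log2(acid + 1.0), np.log2(norm + 1.0), equal_var=False).pvalue
            hits += p < 0.05
        oracle_rates.append(hits / n_mc)
    impl, oracle = np.mean(impl_rates), np.mean(oracle_rates)
    assert abs(impl - oracle) < 0.06  # MC error at these sample sizes
    assert impl > 0.6


@pytest.mark.parametrize(
    "hr, cox_p, fc, t_p, expected",
    [
        (1.4, 0.01, 0.8, 0.001, "RU"),
        (0.7, 0.02, -0.5, 0.03, "PD"),
        (1.4, 0.01, -0.8, 0.001, "RD"),
        (0.7, 0.02, 0.5, 0.03, "PU"),
        (1.4, 0.30, 0.8, 0.001, "NA"),  # fails Cox screen
        (1.4, 0.01, 0.8, 0.30, "NA"),  # fails t screen
        (1.0, 0.01, 0.8, 0.001, "NA"),  # HR exactly 1 excluded
        (1.4, 0.01, 0.0, 0.001, "NA"),  # FC exactly 0 excluded
    ],
)
def test_classification_sign_rules(hr, cox_p, fc, t_p, expected):
    cox = pd.DataFrame({"beta": [np.log(hr)], "hr": [hr], "cox_p": [cox_p]}, index=["g"])
    de = pd.DataFrame({"t": [1.0], "t_p": [t_p], "fc": [fc]}, index=["g"])
    cls = classify_genes(cox, de, alpha=0.05)
    assert cls.table.loc["g", "gene_class"] == expected


def test_classes_partition_universe(rng):
    genes = [f"g{i}" for i in range(300)]
    cox = pd.DataFrame(
        {"beta": rng.normal(size=300), "hr": np.exp(rng.normal(size=300)),
         "cox_p": rng.uniform(size=300)}, index=genes)
    cox["hr"] = np.exp(cox["beta"])
    de = pd.DataFrame(
        {"t": rng.normal(size=300), "t_p": rng.uniform(size=300),
         "fc": rng.normal(size=300)}, index=genes)
    cls = classify_genes(cox, de)
    sizes = cls.class_sizes()
    n_na = (cls.table["gene_class"] == "NA").sum()
    assert sum(sizes.values()) + n_na == 300


def test_null_joint_significance_rate():
    """Fully null screens flag ~ alpha^2 of genes jointly (independent nulls)."""
    rng = np.random.default_rng(5)
    n = 40000
    cox = pd.DataFrame({"beta": rng.normal(size=n), "hr": np.exp(rng.normal(size=n)),
                        "cox_p": rng.uniform(size=n)}, index=range(n))
    de = pd.DataFrame({"t": rng.normal(size=n), "t_p": rng.uniform(size=n),
                       "fc": rng.normal(size=n)}, index=range(n))
    cls = classify_genes(cox, de, alpha=0.05)
    joint = sum(cls.class_sizes().values())
    expected = 0.05**2 * n  # 100
    assert abs(joint - expected) < 4 * np.sqrt(expected)
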