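"""End-to-end composition of the screen on simulated or loaded inputs."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import preprocess, prognosis, survival
from .compound import CompoundPanel, rank_compounds
from .prognosis import ClassifiedGeneSet
from .simulate import SimulationConfig, simulate_all

__all__ = ["normalize_counts", "screen_and_classify", "simulate_and_rank"]


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Median-of-ratios normalization followed by log2(x + 1)."""
    sf = preprocess.size_factors_median_of_ratios(counts)
    norm = counts.div(sf, axis=1)
    return pd.DataFrame(
        np.log2(norm.to_numpy() + 1.0), index=counts.index, columns=counts.columns
    )


def screen_and_classify(
    cohort_expr: pd.DataFrame,
    surv: pd.DataFrame,
    counts: pd.DataFrame,
    conditions: pd.Series,
    alpha: float = 0.05,
) -> ClassifiedGeneSet:
    """Cox screen + acidosis t-test + four-type classification."""
    logm = normalize_counts(counts)
    acid = list(conditions.index[conditions == "acid"])
    normal = list(conditions.index[conditions == "normal"])
    de = prognosis.differential_expression_t(logm, acid, normal)
    cox = survival.cox_screen(cohort_expr, surv)
    return prognosis.classify_genes(cox, de, alpha=alpha)


def simulate_and_rank(config: SimulationConfig, alpha: float = 0.05):
    """Simulate every input, classify genes, rank compounds.

    Returns (truth, classified, ranking DataFrame).
    """
    sim = simulate_all(config)
    classified = screen_and_classify(
        sim["cohort_expression"], sim["survival"], sim["acidosis_counts"],
        sim["conditions"], alpha=alpha,
    )
    ranking = rank_compounds(sim["panel"], classified)
    return sim["truth"], classified, ranking
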