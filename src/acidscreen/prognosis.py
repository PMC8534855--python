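"""Acidosis differential expression and the four-type gene classification.

Genes significant in BOTH a gene-wise Cox survival screen and a Welch
t-test between acidic (pH 6.5) and normal (pH 7.6) cultures are classified
by the signs of the hazard ratio and the acidic-minus-normal log2 fold
change:

    RU: HR > 1, FC > 0   (risk, up in acid)
    PU: HR < 1, FC > 0   (protective, up in acid)
    RD: HR > 1, FC < 0   (risk, down in acid)
    PD: HR < 1, FC < 0   (protective, down in acid)

No multiple-testing adjustment is applied at this stage (recorded in the
output metadata); RU and PD are the downstream compound-screen targets,
since they are the directions through which acidosis worsens prognosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["differential_expression_t", "classify_genes", "ClassifiedGeneSet", "CLASSES"]

CLASSES = ("RU", "PU", "RD", "PD")


def differential_expression_t(
    log_expr: pd.DataFrame,
    acid_cols: list[str],
    normal_cols: list[str],
) -> pd.DataFrame:
    """Welch two-sided t-test per gene on log2 values; FC = mean(acid) - mean(normal).

    Degenerate rows are resolved explicitly: identical groups give t = 0,
    p = 1; a nonzero difference with zero within-group variance gives
    p = smallest positive float (the evidence is beyond machine precision).
    """
    if len(acid_cols) < 2 or len(normal_cols) < 2:
        raise ValueError("need >= 2 replicates in each condition for a t-test")
    a = log_expr.loc[:, acid_cols].to_numpy(dtype=float)
    b = log_expr.loc[:, normal_cols].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    fc = a.mean(axis=1) - b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = fc / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(tstat), df)

    zero_se = se2 == 0
    exact_null = zero_se & (fc == 0)
    tstat[exact_null] = 0.0
    p[exact_null] = 1.0
    beyond = zero_se & (fc != 0)
    tstat[beyond] = np.sign(fc[beyond]) * np.inf
    p[beyond] = np.finfo(float).tiny

    return pd.DataFrame({"t": tstat, "t_p": p, "fc": fc}, index=log_expr.index)


@dataclass
class ClassifiedGeneSet:
    """Four disjoint gene lists plus per-gene supporting statistics.

    ``table`` has one row per gene with columns beta, hr, cox_p, t, t_p, fc
    and ``gene_class`` in {RU, PU, RD, PD, NA}; ``alpha`` is the unadjusted
    per-screen significance threshold used for both tests.
    """

    table: pd.DataFrame
    alpha: float
    metadata: dict = field(default_factory=dict)

    def genes(self, cls: str) -> list[str]:
        if cls not in CLASSES:
            raise ValueError(f"unknown class {cls!r}")
        return list(self.table.index[self.table["gene_class"] == cls])

    @property
    def ru(self) -> list[str]:
        return self.genes("RU")

    @property
    def pu(self) -> list[str]:
        return self.genes("PU")

    @property
    def rd(self) -> list[str]:
        return self.genes("RD")

    @property
    def pd_(self) -> list[str]:
        return self.genes("PD")

    def class_sizes(self) -> dict[str, int]:
        return {c: int((self.table["gene_class"] == c).sum()) for c in CLASSES}


def classify_genes(
    cox: pd.DataFrame,
    de: pd.DataFrame,
    alpha: float = 0.05,
) -> ClassifiedGeneSet:
    """Join the two screens and classify jointly significant genes.

    A gene enters a class iff cox_p < alpha AND t_p < alpha; genes with
    HR = 1 or FC = 0 exactly are excluded (their direction is undefined).
    Genes failing either screen are labeled NA; the four classes plus NA
    partition the gene universe.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    shared = cox.index.intersection(de.index)
    if len(shared) == 0:
        raise ValueError("Cox and t-test screens share no genes")
    tab = cox.loc[shared, ["beta", "hr", "cox_p"]].join(de.loc[shared, ["t", "t_p", "fc"]])

    sig = (
        (tab["cox_p"] < alpha)
        & (tab["t_p"] < alpha)
        & tab["cox_p"].notna()
        & tab["t_p"].notna()
        & (tab["hr"] != 1.0)
        & (tab["fc"] != 0.0)
    )
    cls = pd.Series("NA", index=tab.index, dtype=object)
    risk = tab["hr"] > 1.0
    up = tab["fc"] > 0.0
    cls[sig & risk & up] = "RU"
    cls[sig & ~risk & up] = "PU"
    cls[sig & risk & ~up] = "RD"
    cls[sig & ~risk & ~up] = "PD"
    tab["gene_class"] = cls
    meta = {
        "alpha": alpha,
        "multiple_testing": "none (unadjusted per-screen p < alpha, both screens)",
        "fc_convention": "mean log2(acidic) - mean log2(normal)",
    }
    return ClassifiedGeneSet(table=tab, alpha=alpha, metadata=meta)
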