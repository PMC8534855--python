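"""Functional-state evaluation of a compound's up/down gene sets.

Each functional state (EMT, invasion, ...) is a gene list whose members are
labeled p (positively correlated with the state) or n (negatively
correlated). Crossing the state directions with the compound's up/down
gene sets yields a 2x2 table scored three ways, as in the source analysis
style: information gain (same formula as the compound screen, with the
{p, n} alphabet), a single-predictor logistic association (equivalently
the sample odds ratio with a Wald CI, Bonferroni-corrected across states),
and a Pearson chi-square with per-cell residuals for mosaic-style display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .entropy import information_gain

__all__ = [
    "StateGeneSet",
    "StateCrossTable",
    "AssociationResult",
    "cross_state_compound",
    "state_information_gain",
    "logistic_association",
    "chi_square_residuals",
    "compound_gene_sets",
    "evaluate_states",
]


@dataclass
class StateGeneSet:
    """A named state: genes with direction 'p' (positive) or 'n' (negative)."""

    name: str
    directions: pd.Series  # gene -> 'p' | 'n'

    def __post_init__(self) -> None:
        if self.directions.index.duplicated().any():
            raise ValueError(f"state {self.name!r}: duplicate genes")
        bad = set(self.directions.unique()) - {"p", "n"}
        if bad:
            raise ValueError(f"state {self.name!r}: directions must be p/n, got {sorted(bad)}")


@dataclass
class StateCrossTable:
    """2x2 counts: rows = compound direction (u, d), cols = state direction (p, n)."""

    state: str
    table: np.ndarray
    degenerate: bool
    n_overlap: int


@dataclass
class AssociationResult:
    """Odds ratio with Wald CI and (Bonferroni-adjusted) p from a 2x2 logistic fit."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    p_adjusted: float
    haldane_corrected: bool = False
    undefined: bool = False
    reason: str = ""
    extra: dict = field(default_factory=dict)


def cross_state_compound(
    state: StateGeneSet,
    compound_up: set[str],
    compound_down: set[str],
) -> StateCrossTable:
    """Count genes in (u,p), (u,n), (d,p), (d,n); ignore genes not in the state list."""
    up, down = set(compound_up), set(compound_down)
    if up & down:
        raise ValueError("compound up/down gene sets overlap")
    p_genes = set(state.directions.index[state.directions == "p"])
    n_genes = set(state.directions.index[state.directions == "n"])
    table = np.array(
        [
            [len(up & p_genes), len(up & n_genes)],
            [len(down & p_genes), len(down & n_genes)],
        ],
        dtype=float,
    )
    n_overlap = int(table.sum())
    return StateCrossTable(
        state=state.name, table=table, degenerate=n_overlap == 0, n_overlap=n_overlap
    )


def state_information_gain(ct: StateCrossTable) -> float:
    """IG (bits) of the compound split over the state's p/n labels."""
    if ct.degenerate:
        raise ValueError(f"state {ct.state!r}: empty cross table, IG undefined")
    return information_gain(ct.table).ig


def _zero_margin(table: np.ndarray) -> bool:
    return bool(np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0))


def logistic_association(ct: StateCrossTable, m_states: int = 1) -> AssociationResult:
    """Single-predictor logistic association on the 2x2 table.

    For a binary predictor the logistic MLE slope is the log sample odds
    ratio with Wald SE sqrt(sum of reciprocal cells); a zero cell is
    handled by the Haldane-Anscombe +0.5 correction (flagged). A zero
    margin leaves the association undefined, reported as such. The
    Bonferroni-adjusted p is min(1, m_states * p).
    """
    if m_states < 1:
        raise ValueError("m_states must be >= 1")
    if ct.degenerate:
        return AssociationResult(*[np.nan] * 5, undefined=True, reason="empty table")
    t = ct.table.astype(float)
    if _zero_margin(t):
        return AssociationResult(*[np.nan] * 5, undefined=True, reason="zero margin")
    corrected = bool(np.any(t == 0))
    if corrected:
        t = t + 0.5
    (a, b), (c, d) = t
    log_or = float(np.log(a * d / (b * c)))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    z = log_or / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    ci = (np.exp(log_or - 1.959963984540054 * se), np.exp(log_or + 1.959963984540054 * se))
    return AssociationResult(
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p=p,
        p_adjusted=min(1.0, m_states * p),
        haldane_corrected=corrected,
        extra={"log_or": log_or, "se": se},
    )


def chi_square_residuals(ct: StateCrossTable) -> tuple[float, float, np.ndarray]:
    """Pearson chi-square (no continuity correction) and per-cell residuals.

    Residuals are (O - E)/sqrt(E) with E from the product of margins over
    the total; their squares sum to the chi-square statistic.
    """
    if ct.degenerate:
        raise ValueError(f"state {ct.state!r}: empty cross table")
    t = ct.table.astype(float)
    if _zero_margin(t):
        raise ValueError(f"state {ct.state!r}: zero margin, chi-square undefined")
    chi2, p, _, expected = stats.chi2_contingency(t, correction=False)
    residuals = (t - expected) / np.sqrt(expected)
    return float(chi2), float(p), residuals


def compound_gene_sets(
    gene_log2fc: pd.Series, min_abs_lfc: float = 0.0
) -> tuple[set[str], set[str]]:
    """Split genes by the sign of the compound's log2 fold change.

    ``min_abs_lfc`` = 0 keeps every nonzero gene (sign-only convention, as
    in the compound screen); a positive value restricts to strongly
    regulated genes (|log2FC| >= threshold).
    """
    fc = gene_log2fc.astype(float)
    up = set(fc.index[(fc > 0) & (fc.abs() >= min_abs_lfc)])
    down = set(fc.index[(fc < 0) & (fc.abs() >= min_abs_lfc)])
    return up, down


def evaluate_states(
    states: list[StateGeneSet],
    compound_up: set[str],
    compound_down: set[str],
    m_states: int | None = None,
) -> pd.DataFrame:
    """Cross every state against the compound gene sets; one row per state.

    Bonferroni m defaults to the number of non-degenerate (actually tested)
    states. Degenerate or zero-margin states carry NaN statistics and a
    ``flag`` saying why.
    """
    tables = [cross_state_compound(s, compound_up, compound_down) for s in states]
    if m_states is None:
        m_states = sum(1 for t in tables if not t.degenerate and not _zero_margin(t.table))
    m_states = max(m_states, 1)
    rows = []
    for ct in tables:
        row: dict = {
            "state": ct.state,
            "n_overlap": ct.n_overlap,
            "n_up_p": ct.table[0, 0],
            "n_up_n": ct.table[0, 1],
            "n_down_p": ct.table[1, 0],
            "n_down_n": ct.table[1, 1],
            "ig": np.nan,
            "odds_ratio": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "logit_p": np.nan,
            "logit_p_bonferroni": np.nan,
            "chi2": np.nan,
            "chi2_p": np.nan,
            "flag": "",
        }
        if ct.degenerate:
            row["flag"] = "degenerate: no overlap with compound gene sets"
        else:
            row["ig"] = information_gain(ct.table).ig
            assoc = logistic_association(ct, m_states=m_states)
            if assoc.undefined:
                row["flag"] = f"association undefined: {assoc.reason}"
            else:
                row.update(
                    odds_ratio=assoc.odds_ratio,
                    ci_low=assoc.ci_low,
                    ci_high=assoc.ci_high,
                    logit_p=assoc.p,
                    logit_p_bonferroni=assoc.p_adjusted,
                )
                chi2, p, resid = chi_square_residuals(ct)
                row.update(chi2=chi2, chi2_p=p)
                for i, branch in enumerate("ud"):
                    for j, direction in enumerate("pn"):
                        row[f"resid_{branch}{direction}"] = resid[i, j]
        rows.append(row)
    df = pd.DataFrame(rows).set_index("state")
    df.attrs["m_states"] = m_states
    return df
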