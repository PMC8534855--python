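"""Bulk expression preprocessing: size factors, log transform, probe handling.

Counts are normalized with median-of-ratios size factors (the standard
RNA-seq between-sample normalization: each sample's factor is the median,
over reference genes, of the ratio of its count to the gene's geometric
mean across samples), then transformed log2(x + 1). Microarray probes map
many-to-one onto gene symbols; rows can either stay probe-level with a gene
annotation, or be collapsed to one probe per gene by maximal mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "size_factors_median_of_ratios",
    "log_transform",
    "collapse_or_annotate_probes",
]


@dataclass
class ExpressionMatrix:
    """Expression values (rows = genes or probes, columns = samples).

    ``log_scale`` records whether values are log2(x+1)-transformed;
    ``gene_annotation`` (probe -> gene symbol) is present after probe
    annotation.
    """

    values: pd.DataFrame
    log_scale: bool = False
    row_kind: str = "gene"  # "gene" or "probe"
    gene_annotation: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample (column) identifiers")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("expression values must be finite")


def size_factors_median_of_ratios(counts: pd.DataFrame | ExpressionMatrix) -> pd.Series:
    """Per-sample size factors by the median-of-ratios method.

    factor_j = median over reference genes g of counts[g, j] / geomean_g,
    where geomean_g is the geometric mean of gene g across samples and
    reference genes are those with strictly positive counts in every sample
    (geomean > 0). Factors are rescaled to have geometric mean 1, so a
    single sample gets factor 1 and exact column scalings are recovered
    exactly up to that global convention.
    """
    if isinstance(counts, ExpressionMatrix):
        if counts.log_scale:
            raise ValueError("size factors require raw (non-log) counts")
        counts = counts.values
    x = counts.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    ref = np.all(x > 0, axis=1)
    if not ref.any():
        raise ValueError(
            "no reference genes: every gene contains a zero count in some sample, "
            "so the geometric-mean reference is undefined"
        )
    xr = x[ref]
    log_geomean = np.log(xr).mean(axis=1)
    ratios = np.log(xr) - log_geomean[:, None]
    log_factors = np.median(ratios, axis=0)
    log_factors = log_factors - log_factors.mean()  # geometric mean 1 convention
    return pd.Series(np.exp(log_factors), index=counts.columns, name="size_factor")


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each value x by log2(x + 1); refuses to transform twice."""
    if m.log_scale:
        raise ValueError("matrix is already log-scale; refusing to double-transform")
    vals = m.values.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("log2(x+1) requires nonnegative values")
    out = pd.DataFrame(np.log2(vals + 1.0), index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(
        values=out, log_scale=True, row_kind=m.row_kind, gene_annotation=m.gene_annotation
    )


def collapse_or_annotate_probes(
    m: ExpressionMatrix,
    probe_gene: pd.Series,
    mode: str = "keep_probes",
) -> ExpressionMatrix:
    """Resolve probe -> gene mapping for a probe-level matrix.

    ``keep_probes`` (default): rows stay probe-level but carry their gene
    symbol as an annotation — the compound screen counts probes, not genes.
    ``collapse_max_mean``: one row per gene, keeping the probe with maximal
    mean expression. Probes absent from the map are dropped (count logged),
    never guessed.
    """
    if mode not in ("keep_probes", "collapse_max_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    mapped = m.values.index.intersection(probe_gene.index)
    if len(mapped) == 0:
        raise ValueError("no matrix row is present in the probe->gene map")
    n_dropped = m.values.shape[0] - len(mapped)
    if n_dropped:
        logger.info("dropping %d unmapped probe rows", n_dropped)
    vals = m.values.loc[mapped]
    genes = probe_gene.loc[mapped].astype(str)
    if (genes == "").any():
        raise ValueError("probe map contains empty gene symbols")

    if mode == "keep_probes":
        return ExpressionMatrix(
            values=vals, log_scale=m.log_scale, row_kind="probe", gene_annotation=genes
        )

    means = vals.mean(axis=1)
    best = (
        pd.DataFrame({"gene": genes, "mean": means})
        .sort_values(["gene", "mean"], ascending=[True, False], kind="stable")
        .drop_duplicates("gene")
    )
    out = vals.loc[best.index]
    out.index = best["gene"].to_numpy()
    out = out.sort_index()
    return ExpressionMatrix(values=out, log_scale=m.log_scale, row_kind="gene")
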