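"""Single-cell operations: normalization, marker gating, percent-positive,
and a simplified ligand-receptor co-expression screen.

Tumor cells are extracted by marker rules (e.g. KRT5-, KRT18+, ESR1+ for
ER+ tumor cells) rather than clustering: a cell is kept iff every
positive-predicate marker exceeds its threshold and every
negative-predicate marker does not. "Expressing" a gene means a value > 0
(raw count >= 1), a convention preserved by total-count scaling and log1p.

The ligand-receptor screen is a deliberately simple co-expression test
over a small bundled pair table (paracrine / ECM / contact annotations):
a pair is flagged active for a (sender, receiver) type combination when
the ligand is expressed in enough sender cells and the receptor in enough
receiver cells. Intersecting active pairs with a compound's regulated
genes reports which interactions the compound may modulate. It makes no
claim to model communication probability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from itertools import product

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerRule",
    "normalize_cells",
    "gate_mask",
    "gate_cells",
    "annotate_cell_types",
    "percent_positive",
    "load_lr_pairs",
    "lr_screen",
]

_NORM_FLAG = "acidscreen_normalized"


@dataclass(frozen=True)
class MarkerRule:
    """One gating predicate: gene must be > threshold (positive) or <= (negative)."""

    gene: str
    positive: bool
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")


def _col(adata, gene: str) -> np.ndarray:
    if gene not in adata.var_names:
        raise KeyError(f"gene {gene!r} not present in the bundle")
    j = adata.var_names.get_loc(gene)
    x = adata.X[:, j]
    return np.asarray(x.todense()).ravel() if sparse.issparse(x) else np.asarray(x).ravel()


def normalize_cells(adata, target_sum: float = 1e4):
    """Total-count scale each cell to ``target_sum``, then log1p.

    Cells with zero total counts are dropped (count logged). Raw counts are
    kept in layers['counts'] and the scaled (pre-log) values in
    layers['norm']; X becomes log1p(scaled). Re-normalizing is refused.
    """
    if adata.uns.get(_NORM_FLAG):
        raise ValueError("bundle is already normalized; refusing to normalize twice")
    X = adata.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    keep = totals > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d cells with zero total counts", n_dropped)
        adata = adata[keep].copy()
        totals = totals[keep]
    else:
        adata = adata.copy()
    adata.layers["counts"] = adata.X.copy()
    scale = target_sum / totals
    if sparse.issparse(adata.X):
        norm = sparse.diags(scale) @ adata.X
        adata.layers["norm"] = norm.copy()
        adata.X = norm.log1p()
    else:
        norm = adata.X * scale[:, None]
        adata.layers["norm"] = norm.copy()
        adata.X = np.log1p(norm)
    adata.uns[_NORM_FLAG] = True
    return adata


def gate_mask(adata, rules: list[MarkerRule]) -> np.ndarray:
    """Boolean cell mask for a conjunction of marker rules (order-independent)."""
    if not rules:
        raise ValueError("empty gating rule")
    mask = np.ones(adata.n_obs, dtype=bool)
    for rule in rules:
        v = _col(adata, rule.gene)
        mask &= (v > rule.threshold) if rule.positive else (v <= rule.threshold)
    return mask


def gate_cells(adata, rules: list[MarkerRule]):
    """Subset of cells satisfying every rule; empty subsets warn, not fail."""
    mask = gate_mask(adata, rules)
    if not mask.any():
        warnings.warn("gating rule matched zero cells", stacklevel=2)
    return adata[mask].copy()


def annotate_cell_types(adata, rulesets: dict[str, list[MarkerRule]], key: str = "cell_type"):
    """Assign each cell the first type whose rules it satisfies ('unassigned' else)."""
    assigned = np.full(adata.n_obs, "unassigned", dtype=object)
    taken = np.zeros(adata.n_obs, dtype=bool)
    for name, rules in rulesets.items():
        mask = gate_mask(adata, rules) & ~taken
        assigned[mask] = name
        taken |= mask
    adata.obs[key] = pd.Categorical(assigned)
    return adata


def percent_positive(adata, genes: list[str]) -> pd.Series:
    """Percent of cells with expression > 0 per gene, over the given subset.

    Genes absent from the bundle are reported as missing (NaN, with a
    warning), never as 0% — absence from the matrix is not evidence of
    absence of expression.
    """
    if adata.n_obs == 0:
        raise ValueError("percent_positive undefined on an empty cell subset")
    out = pd.Series(np.nan, index=pd.Index(genes, name="gene"), dtype=float)
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        warnings.warn(f"genes absent from bundle (reported missing): {missing}", stacklevel=2)
    for g in genes:
        if g in adata.var_names:
            out[g] = 100.0 * float((_col(adata, g) > 0).mean())
    return out


def load_lr_pairs() -> pd.DataFrame:
    """Bundled ligand-receptor pair table (columns ligand, receptor, annotation).

    A small curated stand-in covering the interactions discussed for the
    ER+ breast tumor microenvironment (MIF/MDK/APP ligands; CD74, CXCR4,
    CD44, SDC2/4 receptors; collagen/FN1/laminin/SPP1/THBS/TNC ECM
    ligands of CD44/SDC4) — not a comprehensive database.
    """
    with resources.files("acidscreen.data").joinpath("lr_pairs.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def lr_screen(
    adata,
    pairs: pd.DataFrame,
    sender: str,
    compound_deg: dict[str, float] | pd.Series | None = None,
    min_frac: float = 0.10,
    min_mean: float = 0.0,
    type_key: str = "cell_type",
) -> pd.DataFrame:
    """Co-expression screen of ligand-receptor pairs from one sender type.

    For every pair and every receiver type, reports the ligand's
    percent-positive and mean in the sender and the receptor's in the
    receiver. A pair is ``active`` when both fractions reach ``min_frac``
    (default 10%) and both means exceed ``min_mean``. With ``compound_deg``
    (gene -> signed log2FC), active pairs whose ligand or receptor the
    compound regulates are flagged ``modulated`` (signs reported).
    """
    if type_key not in adata.obs:
        raise ValueError(f"missing cell-type annotation {type_key!r}")
    types = [t for t in adata.obs[type_key].unique() if t != "unassigned"]
    if sender not in list(types):
        raise ValueError(f"unknown sender type {sender!r} (have {sorted(map(str, types))})")
    if len(types) < 2:
        raise ValueError("ligand-receptor screen needs >= 2 annotated cell types")
    deg = pd.Series(compound_deg, dtype=float) if compound_deg is not None else pd.Series(dtype=float)

    sender_cells = adata[adata.obs[type_key] == sender]
    rows = []
    for (_, pair), receiver in product(pairs.iterrows(), sorted(map(str, types))):
        lig, rec = pair["ligand"], pair["receptor"]
        if lig not in adata.var_names or rec not in adata.var_names:
            continue
        recv_cells = adata[adata.obs[type_key] == receiver]
        lv = _col(sender_cells, lig)
        rv = _col(recv_cells, rec)
        lfrac, lmean = float((lv > 0).mean()), float(lv.mean())
        rfrac, rmean = float((rv > 0).mean()), float(rv.mean())
        active = (
            lfrac >= min_frac and rfrac >= min_frac and lmean > min_mean and rmean > min_mean
        )
        lig_sign = float(deg.get(lig, np.nan))
        rec_sign = float(deg.get(rec, np.nan))
        rows.append(
            {
                "ligand": lig,
                "receptor": rec,
                "annotation": pair.get("annotation", ""),
                "sender": sender,
                "receiver": receiver,
                "ligand_frac_sender": lfrac,
                "ligand_mean_sender": lmean,
                "receptor_frac_receiver": rfrac,
                "receptor_mean_receiver": rmean,
                "active": active,
                "ligand_log2fc": lig_sign,
                "receptor_log2fc": rec_sign,
                "modulated": active and (np.isfinite(lig_sign) or np.isfinite(rec_sign)),
            }
        )
    return pd.DataFrame(rows)
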