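"""Information-gain ranking of compounds against the RU/PD target set.

For each compound, the target population T is the set of RU/PD-annotated
probes that the panel measures with a nonzero treated-vs-control log
fold change for that compound. Splitting T on the fold-change sign
(u = up-regulated, d = down-regulated by the compound) and scoring the
split with information gain rewards compounds that push risk-up genes down
and protective-down genes up — i.e. that reverse the acidosis signature.
Only the sign of the fold change matters; magnitudes and significance are
not used. Probes with fold change exactly 0 are excluded from T (counted,
not silently assigned a branch), as are target probes the panel does not
measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .entropy import InformationGain, information_gain
from .prognosis import ClassifiedGeneSet

__all__ = [
    "CompoundPanel",
    "TargetSet",
    "CompoundScore",
    "target_set",
    "compound_information_gain",
    "rank_compounds",
]


@dataclass
class CompoundPanel:
    """Probe x compound signed log fold-change matrix plus probe -> gene map."""

    log_ratios: pd.DataFrame
    probe_gene: pd.Series

    def __post_init__(self) -> None:
        if self.log_ratios.index.duplicated().any():
            raise ValueError("duplicate probe identifiers in panel")
        if self.log_ratios.columns.duplicated().any():
            raise ValueError("duplicate compound names in panel")
        if not np.all(np.isfinite(self.log_ratios.to_numpy(dtype=float))):
            raise ValueError("panel log-ratios must be finite")


@dataclass
class TargetSet:
    """Probes labeled 'ru' or 'pd': the population the split is scored on."""

    labels: pd.Series  # probe -> 'ru' | 'pd'

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - {"ru", "pd"}
        if bad:
            raise ValueError(f"target labels must be 'ru'/'pd', got {sorted(bad)}")

    @property
    def n_ru(self) -> int:
        return int((self.labels == "ru").sum())

    @property
    def n_pd(self) -> int:
        return int((self.labels == "pd").sum())


def target_set(classified: ClassifiedGeneSet, probe_gene: pd.Series) -> TargetSet:
    """Annotate panel probes whose gene is classified RU or PD.

    Returns the probe-level target population (a gene classified RU
    contributes every one of its probes as an 'ru' target).
    """
    gene_cls = classified.table["gene_class"]
    shared_genes = set(probe_gene.unique()) & set(gene_cls.index)
    if not shared_genes:
        raise ValueError("panel and classification share no genes")
    cls_of_probe = probe_gene.map(gene_cls)
    keep = cls_of_probe.isin(["RU", "PD"])
    labels = cls_of_probe[keep].map({"RU": "ru", "PD": "pd"})
    return TargetSet(labels=labels)


@dataclass
class CompoundScore:
    """IG result for one compound, with branch breakdown and exclusions.

    ``n_up_pd`` counts protective-down probes up-regulated by the compound
    (PDU) and ``n_down_ru`` risk-up probes down-regulated (RUD) — the two
    desirable reversal directions. ``defined`` is False when no target
    probe has a nonzero measured fold change (flagged, never scored 0).
    """

    compound: str
    defined: bool
    n_t: int
    n_ru: int
    n_pd: int
    n_up: int
    n_down: int
    n_up_ru: int
    n_up_pd: int
    n_down_ru: int
    n_down_pd: int
    excluded_zero: int
    excluded_unmeasured: int
    ig: float = float("nan")
    entropy_parent: float = float("nan")
    detail: InformationGain | None = None


def compound_information_gain(
    target: TargetSet, fold_changes: pd.Series, compound: str = ""
) -> CompoundScore:
    """Score one compound's fold-change split over the target probes.

    ``fold_changes`` is indexed by probe (signed, treated minus control,
    log scale). The effective population is the target probes present in
    ``fold_changes`` with a nonzero value; exclusion counts are recorded.
    """
    labels = target.labels
    measured = labels.index.intersection(fold_changes.index)
    excluded_unmeasured = len(labels) - len(measured)
    fc = fold_changes.loc[measured].astype(float)
    lab = labels.loc[measured]
    nonzero = fc != 0.0
    excluded_zero = int((~nonzero).sum())
    fc, lab = fc[nonzero], lab[nonzero]

    if len(fc) == 0:
        return CompoundScore(
            compound=compound, defined=False, n_t=0, n_ru=0, n_pd=0,
            n_up=0, n_down=0, n_up_ru=0, n_up_pd=0, n_down_ru=0, n_down_pd=0,
            excluded_zero=excluded_zero, excluded_unmeasured=excluded_unmeasured,
        )

    up = fc > 0
    is_ru = (lab == "ru").to_numpy()
    upv = up.to_numpy()
    n_up_ru = int((upv & is_ru).sum())
    n_up_pd = int((upv & ~is_ru).sum())
    n_down_ru = int((~upv & is_ru).sum())
    n_down_pd = int((~upv & ~is_ru).sum())
    # rows: branches (u, d); columns: classes (ru, pd)
    table = np.array([[n_up_ru, n_up_pd], [n_down_ru, n_down_pd]], dtype=float)
    res = information_gain(table)
    return CompoundScore(
        compound=compound,
        defined=True,
        n_t=int(len(fc)),
        n_ru=int(is_ru.sum()),
        n_pd=int((~is_ru).sum()),
        n_up=n_up_ru + n_up_pd,
        n_down=n_down_ru + n_down_pd,
        n_up_ru=n_up_ru,
        n_up_pd=n_up_pd,
        n_down_ru=n_down_ru,
        n_down_pd=n_down_pd,
        excluded_zero=excluded_zero,
        excluded_unmeasured=excluded_unmeasured,
        ig=res.ig,
        entropy_parent=res.entropy_parent,
        detail=res,
    )


_RANK_COLUMNS = [
    "compound", "ig", "entropy_parent", "n_t", "n_ru", "n_pd", "n_up", "n_down",
    "n_up_pd", "n_down_ru", "n_up_ru", "n_down_pd",
    "excluded_zero", "excluded_unmeasured", "defined",
]


def rank_compounds(panel: CompoundPanel, classified: ClassifiedGeneSet) -> pd.DataFrame:
    """Score every panel compound and rank by descending information gain.

    Ties break by larger effective |T|, then lexicographic compound name;
    compounds with an undefined score sort last (flagged via ``defined``).
    Returns one row per compound with the full branch breakdown.
    """
    tgt = target_set(classified, panel.probe_gene)
    rows = []
    for name in panel.log_ratios.columns:
        score = compound_information_gain(tgt, panel.log_ratios[name], compound=str(name))
        rows.append({k: getattr(score, k if k != "compound" else "compound") for k in _RANK_COLUMNS})
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["defined", "ig", "n_t", "compound"],
        ascending=[False, False, False, True],
        kind="stable",
        na_position="last",
    ).reset_index(drop=True)
    df.index.name = "rank"
    df.index = df.index + 1
    return df
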