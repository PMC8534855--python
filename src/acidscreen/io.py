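"""Plain-text readers and writers for every pipeline artifact.

Matrices are tab-separated with a header row and the row identifier in the
first column; single-cell counts use the 10x-style MatrixMarket triplet
(matrix.mtx + features.tsv + barcodes.tsv); planted truth is JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .compound import CompoundPanel
from .simulate import PlantedTruth
from .states import StateGeneSet

__all__ = [
    "write_matrix", "read_matrix", "write_survival", "read_survival",
    "write_probe_map", "read_probe_map", "write_panel", "read_panel",
    "write_states", "read_states", "write_truth", "read_truth",
    "write_cellbundle", "read_cellbundle", "read_gating_rules",
]


def write_matrix(df: pd.DataFrame, path, index_label: str = "gene") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_survival(surv: pd.DataFrame, path) -> None:
    surv.to_csv(path, sep="\t", index_label="patient")


def read_survival(path) -> pd.DataFrame:
    surv = pd.read_csv(path, sep="\t", index_col=0)
    return surv[["time", "event"]]


def write_probe_map(probe_gene: pd.Series, path) -> None:
    probe_gene.rename("gene").to_csv(path, sep="\t", index_label="probe")


def read_probe_map(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df["gene"]


def write_panel(panel: CompoundPanel, matrix_path, map_path) -> None:
    write_matrix(panel.log_ratios, matrix_path, index_label="probe")
    write_probe_map(panel.probe_gene, map_path)


def read_panel(matrix_path, map_path) -> CompoundPanel:
    return CompoundPanel(
        log_ratios=read_matrix(matrix_path), probe_gene=read_probe_map(map_path)
    )


def write_states(states: list[StateGeneSet], path) -> None:
    rows = [
        {"state": s.name, "gene": g, "direction": d}
        for s in states
        for g, d in s.directions.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_states(path) -> list[StateGeneSet]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for name, grp in df.groupby("state", sort=False):
        out.append(
            StateGeneSet(name=str(name), directions=pd.Series(
                grp["direction"].to_numpy(), index=grp["gene"].to_numpy()
            ))
        )
    return out


def write_truth(truth: PlantedTruth, path) -> None:
    payload = {
        "gene_class": truth.gene_class.to_dict(),
        "log_hazard": truth.log_hazard.to_dict(),
        "joint_coef": truth.joint_coef.to_dict(),
        "log2fc": truth.log2fc.to_dict(),
        "is_reverser": {k: bool(v) for k, v in truth.is_reverser.items()},
        "cell_type": truth.cell_type.to_dict() if truth.cell_type is not None else None,
        "active_lr_pairs": (
            truth.active_lr_pairs.to_dict(orient="records")
            if truth.active_lr_pairs is not None
            else None
        ),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path) -> PlantedTruth:
    payload = json.loads(Path(path).read_text())
    return PlantedTruth(
        gene_class=pd.Series(payload["gene_class"]),
        log_hazard=pd.Series(payload["log_hazard"], dtype=float),
        joint_coef=pd.Series(payload["joint_coef"], dtype=float),
        log2fc=pd.Series(payload["log2fc"], dtype=float),
        is_reverser=pd.Series(payload["is_reverser"], dtype=bool),
        cell_type=pd.Series(payload["cell_type"]) if payload["cell_type"] else None,
        active_lr_pairs=(
            pd.DataFrame(payload["active_lr_pairs"]) if payload["active_lr_pairs"] else None
        ),
    )


def write_cellbundle(adata, outdir) -> None:
    """10x-style triplet: matrix.mtx (cells x genes), features.tsv, barcodes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(np.asarray(adata.X))
    spio.mmwrite(str(outdir / "matrix.mtx"), X)
    pd.Series(adata.var_names).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    obs = adata.obs.copy()
    obs.index.name = "barcode"
    obs.to_csv(outdir / "barcodes.tsv", sep="\t")


def read_cellbundle(outdir):
    import anndata as ad

    outdir = Path(outdir)
    X = sparse.csr_matrix(spio.mmread(str(outdir / "matrix.mtx")))
    var_names = pd.read_csv(outdir / "features.tsv", sep="\t", header=None)[0].astype(str)
    obs = pd.read_csv(outdir / "barcodes.tsv", sep="\t", index_col=0)
    return ad.AnnData(
        X=X,
        obs=obs,
        var=pd.DataFrame(index=pd.Index(var_names, name="gene")),
    )


def read_gating_rules(path) -> list:
    """Gating rules from tab-separated columns gene, predicate, threshold."""
    from .sc import MarkerRule

    df = pd.read_csv(path, sep="\t")
    rules = []
    for _, row in df.iterrows():
        pred = str(row["predicate"]).lower()
        if pred not in ("positive", "negative"):
            raise ValueError(f"unknown predicate {row['predicate']!r}")
        rules.append(
            MarkerRule(
                gene=str(row["gene"]),
                positive=pred == "positive",
                threshold=float(row.get("threshold", 0.0)),
            )
        )
    return rules
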