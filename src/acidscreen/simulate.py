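"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the shapes of the study's four data sources so the
whole screen runs with no download:

* a survival cohort whose per-gene log-hazards are planted (TCGA-like);
* a replicated acidic-vs-normal count experiment with planted log2 fold
  changes and planted library-depth multipliers (pH 6.5 vs 7.6 bulk
  RNA-seq-like);
* a probe x compound log-ratio panel containing one planted signature
  reverser among decoys, with a many-probes-per-gene map (microarray
  compound screen-like);
* signed functional-state gene lists, one of which is deliberately
  enriched for the planted RU/PD genes;
* a sparse single-cell count matrix with marker-defined cell types and
  planted ligand-receptor structure.

One global seed drives independent per-stage substreams, so each stage is
reproducible in isolation and identical configs give bit-identical output.

Planted survival effects: RU genes carry a positive and PD genes a negative
marginal log-hazard of magnitude ``effect_loghazard``. Planted genes share
a latent per-patient "acidosis activity" factor (loading ``gene_corr``);
the joint Cox coefficients are scaled so that the stated effect is the
per-gene marginal association a univariate screen estimates, while the
total log-hazard spread stays realistic (~1 on the log scale) instead of
exploding with the number of planted genes. With a single planted gene
this reduces exactly to hazard = exp(effect_loghazard * z).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .compound import CompoundPanel
from .states import StateGeneSet

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "planted_truth",
    "simulate_survival_cohort",
    "simulate_acidosis_experiment",
    "simulate_compound_panel",
    "simulate_state_genesets",
    "simulate_scrna",
    "simulate_all",
    "default_gating_rules",
    "CELL_TYPE_CATALOG",
]

_STAGES = {"truth": 0, "cohort": 1, "acidosis": 2, "panel": 3, "states": 4, "scrna": 5}

_STATE_NAMES = [
    "emt", "invasion", "metastasis", "angiogenesis", "apoptosis", "dna_damage",
    "dna_repair", "differentiation", "proliferation", "cell_cycle", "hypoxia",
    "stemness", "inflammation", "quiescence",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the default study conditions.

    Defaults: 2,000 genes, 500 patients, 3+3 replicate cultures, 50
    compounds with compound 0 the planted reverser, 30 planted risk-up and
    60 planted protective-down genes, |log2FC| = 1.5 in acid, marginal
    |log-hazard| = 0.8 per planted gene, NB dispersion 0.1, ~30% censoring,
    14 states, 5,000 cells in 3 marker-defined types.
    """

    seed: int = 0
    n_genes: int = 2000
    n_patients: int = 500
    n_reps_per_condition: int = 3
    n_compounds: int = 50
    n_probes_per_gene_max: int = 3
    planted_risk_up: int = 30
    planted_protective_down: int = 60
    effect_log2fc: float = 1.5
    effect_loghazard: float = 0.8
    censor_rate: float = 0.3
    depth_multipliers: tuple[float, ...] | None = None
    reverser_index: int = 0
    n_states: int = 14
    n_cells: int = 5000
    n_cell_types: int = 3
    # secondary knobs
    dispersion: float = 0.1
    gene_corr: float = 0.7
    baseline_log_mean: float = math.log(500.0)
    baseline_log_sd: float = 1.0
    baseline_hazard: float = 0.1
    panel_effect: float = 1.0
    panel_noise_sd: float = 0.5
    state_size: int = 50
    state_overlap: int = 25
    marker_on_prob: float = 0.995
    marker_off_prob: float = 0.002
    program_on_prob: float = 0.6
    background_prob: float = 0.02
    n_filler_genes: int = 100
    cell_depth_levels: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_patients": self.n_patients,
            "n_compounds": self.n_compounds,
            "n_probes_per_gene_max": self.n_probes_per_gene_max,
            "n_states": self.n_states,
            "n_cells": self.n_cells,
            "n_cell_types": self.n_cell_types,
            "state_size": self.state_size,
            "n_filler_genes": self.n_filler_genes,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ValueError(f"{name} must be a positive integer (got {value!r})")
        if self.n_reps_per_condition < 2:
            raise ValueError(
                f"n_reps_per_condition must be >= 2 (got {self.n_reps_per_condition!r})"
            )
        for name in ("planted_risk_up", "planted_protective_down"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer (got {v!r})")
        if self.planted_risk_up + self.planted_protective_down > self.n_genes:
            raise ValueError("planted_risk_up + planted_protective_down exceeds n_genes")
        if not 0 <= self.censor_rate < 1:
            raise ValueError(f"censor_rate must be in [0, 1) (got {self.censor_rate!r})")
        if self.depth_multipliers is not None:
            if len(self.depth_multipliers) != 2 * self.n_reps_per_condition:
                raise ValueError(
                    "depth_multipliers length must equal 2 * n_reps_per_condition "
                    f"(expected {2 * self.n_reps_per_condition}, got "
                    f"{len(self.depth_multipliers)})"
                )
            if any(d <= 0 for d in self.depth_multipliers):
                raise ValueError("depth_multipliers must be strictly positive")
        if not 0 <= self.reverser_index < self.n_compounds:
            raise ValueError(
                f"reverser_index must be < n_compounds (got {self.reverser_index!r})"
            )
        if not 0 <= self.gene_corr < 1:
            raise ValueError(f"gene_corr must be in [0, 1) (got {self.gene_corr!r})")
        if self.dispersion < 0:
            raise ValueError(f"dispersion must be >= 0 (got {self.dispersion!r})")
        for name in ("marker_on_prob", "marker_off_prob", "program_on_prob", "background_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1] (got {v!r})")
        if not 1 <= self.n_cell_types <= len(CELL_TYPE_CATALOG):
            raise ValueError(
                f"n_cell_types must be in [1, {len(CELL_TYPE_CATALOG)}] "
                f"(got {self.n_cell_types!r})"
            )
        if any(d <= 0 for d in self.cell_depth_levels):
            raise ValueError("cell_depth_levels must be strictly positive")

    def rng(self, stage: str) -> np.random.Generator:
        """Independent, reproducible substream for one simulation stage."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STAGES[stage],))
        )

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    @property
    def compound_names(self) -> list[str]:
        return [f"C{i:03d}" for i in range(self.n_compounds)]


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator, for oracle-based testing.

    ``log_hazard`` holds per-gene MARGINAL log-hazards (what a univariate
    Cox screen estimates); ``joint_coef`` the coefficients actually summed
    into the patient hazard.
    """

    gene_class: pd.Series  # gene -> 'RU' | 'PD' | 'NA'
    log_hazard: pd.Series
    joint_coef: pd.Series
    log2fc: pd.Series
    is_reverser: pd.Series  # compound -> bool
    cell_type: pd.Series | None = None
    active_lr_pairs: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def planted_truth(config: SimulationConfig) -> PlantedTruth:
    """Draw gene classes / effects and compound flags (stage-0 substream)."""
    rng = config.rng("truth")
    genes = config.gene_names
    m = config.planted_risk_up + config.planted_protective_down
    planted_idx = rng.choice(config.n_genes, size=m, replace=False)
    ru_idx = planted_idx[: config.planted_risk_up]
    pd_idx = planted_idx[config.planted_risk_up:]

    cls = pd.Series("NA", index=genes, dtype=object)
    cls.iloc[ru_idx] = "RU"
    cls.iloc[pd_idx] = "PD"

    sign = pd.Series(0.0, index=genes)
    sign.iloc[ru_idx] = 1.0
    sign.iloc[pd_idx] = -1.0

    log2fc = sign * config.effect_log2fc
    marginal = sign * config.effect_loghazard
    # scale joint coefficients so the per-gene marginal equals effect_loghazard
    # under the shared-factor correlation structure (see module docstring)
    shrink = 1.0 + max(m - 1, 0) * config.gene_corr**2
    joint = marginal / shrink

    reverser = pd.Series(False, index=config.compound_names)
    reverser.iloc[config.reverser_index] = True
    return PlantedTruth(
        gene_class=cls,
        log_hazard=marginal,
        joint_coef=joint,
        log2fc=log2fc,
        is_reverser=reverser,
    )


# ---------------------------------------------------------------------------
# survival cohort


def _calibrate_uniform_censoring(rates: np.ndarray, target: float) -> float:
    """Upper bound c of Uniform(0, c) censoring hitting ``target`` in expectation.

    P(censored | rate) = (1 - exp(-rate*c)) / (rate*c); solved by bisection
    on the cohort mean (monotone decreasing in c).
    """

    def frac_censored(c: float) -> float:
        x = rates * c
        return float(np.mean(np.where(x > 1e-12, (1.0 - np.exp(-x)) / np.maximum(x, 1e-12), 1.0)))

    lo, hi = 1e-9, 1.0
    while frac_censored(hi) > target:
        hi *= 2.0
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac_censored(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_survival_cohort(
    config: SimulationConfig, truth: PlantedTruth | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x patient expression plus a survival table with planted hazards.

    Expression is standardized (log-like) Gaussian; planted genes load on a
    shared latent acidosis-activity factor. Event times are exponential
    given each patient's hazard exp(sum of joint_coef * expression);
    censoring is independent Uniform(0, c) with c calibrated so the
    expected censored fraction is ``censor_rate``.
    """
    if truth is None:
        truth = planted_truth(config)
    rng = config.rng("cohort")
    n_g, n_p = config.n_genes, config.n_patients
    factor = rng.standard_normal(n_p)
    expr = rng.standard_normal((n_g, n_p))

    sign = np.sign(truth.joint_coef.to_numpy())
    planted = sign != 0
    w = config.gene_corr
    expr[planted] = (
        sign[planted, None] * w * factor[None, :]
        + math.sqrt(1.0 - w**2) * expr[planted]
    )

    eta = truth.joint_coef.to_numpy()[planted] @ expr[planted]
    rates = config.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / rates)

    if config.censor_rate > 0:
        c = _calibrate_uniform_censoring(rates, config.censor_rate)
        t_cens = rng.uniform(0.0, c, size=n_p)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n_p, dtype=int)

    patients = [f"P{i:04d}" for i in range(n_p)]
    expr_df = pd.DataFrame(expr, index=config.gene_names, columns=patients)
    surv = pd.DataFrame({"time": time, "event": event}, index=pd.Index(patients, name="patient"))
    return expr_df, surv


# ---------------------------------------------------------------------------
# acidosis count experiment


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def simulate_acidosis_experiment(
    config: SimulationConfig, truth: PlantedTruth | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Replicated two-condition NB counts with planted log2FC and depths.

    Gene baselines are log-normal; planted genes are shifted by
    2**log2fc in the acidic condition; each sample's mean is scaled by its
    depth multiplier. Returns (counts, condition labels); acidic samples
    come first.
    """
    if truth is None:
        truth = planted_truth(config)
    rng = config.rng("acidosis")
    r = config.n_reps_per_condition
    depths = (
        np.asarray(config.depth_multipliers, dtype=float)
        if config.depth_multipliers is not None
        else np.ones(2 * r)
    )
    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)
    lfc = truth.log2fc.to_numpy()
    is_acid = np.r_[np.ones(r, dtype=bool), np.zeros(r, dtype=bool)]
    mean = base[:, None] * np.power(2.0, lfc[:, None] * is_acid[None, :]) * depths[None, :]
    counts = _nb_draw(rng, mean, config.dispersion)
    samples = [f"acid_{i+1}" for i in range(r)] + [f"normal_{i+1}" for i in range(r)]
    counts_df = pd.DataFrame(counts, index=config.gene_names, columns=samples)
    cond = pd.Series(np.where(is_acid, "acid", "normal"), index=samples, name="condition")
    return counts_df, cond


# ---------------------------------------------------------------------------
# compound panel


def simulate_compound_panel(
    config: SimulationConfig, truth: PlantedTruth | None = None
) -> CompoundPanel:
    """Probe x compound signed log-ratios with one planted reverser.

    Each gene gets 1..n_probes_per_gene_max probes. Decoy compounds are
    pure noise (signs independent of class); the reverser's probes on RU
    genes are shifted down and on PD genes up by ``panel_effect``.
    """
    if truth is None:
        truth = planted_truth(config)
    rng = config.rng("panel")
    k = rng.integers(1, config.n_probes_per_gene_max + 1, size=config.n_genes)
    probe_ids, probe_genes = [], []
    for gene, kg in zip(config.gene_names, k):
        for j in range(kg):
            probe_ids.append(f"{gene}_p{j+1}")
            probe_genes.append(gene)
    n_probes = len(probe_ids)

    values = rng.normal(0.0, config.panel_noise_sd, size=(n_probes, config.n_compounds))
    sign = np.sign(truth.log2fc.reindex(probe_genes).to_numpy())
    # the reverser opposes the acidosis direction: down on RU, up on PD
    values[:, config.reverser_index] -= sign * config.panel_effect

    log_ratios = pd.DataFrame(values, index=probe_ids, columns=config.compound_names)
    probe_gene = pd.Series(probe_genes, index=probe_ids, name="gene")
    return CompoundPanel(log_ratios=log_ratios, probe_gene=probe_gene)


# ---------------------------------------------------------------------------
# state gene sets


def simulate_state_genesets(
    config: SimulationConfig, truth: PlantedTruth | None = None
) -> list[StateGeneSet]:
    """Signed state gene lists; state 0 is enriched for the planted classes.

    The enriched state takes up to ``state_overlap`` RU genes as positive
    and the same number of PD genes as negative members, so a signature
    reverser (RU down, PD up) shows a strong direction association there.
    All other states draw random genes with random directions (null).
    """
    if truth is None:
        truth = planted_truth(config)
    rng = config.rng("states")
    names = [
        _STATE_NAMES[i] if i < len(_STATE_NAMES) else f"state_{i}"
        for i in range(config.n_states)
    ]
    ru = list(truth.gene_class.index[truth.gene_class == "RU"])
    pdg = list(truth.gene_class.index[truth.gene_class == "PD"])
    out: list[StateGeneSet] = []
    for i, name in enumerate(names):
        if i == 0 and (ru or pdg):
            n_pos = min(config.state_overlap, len(ru))
            n_neg = min(config.state_overlap, len(pdg))
            pos = rng.choice(ru, size=n_pos, replace=False) if n_pos else np.array([], dtype=object)
            neg = rng.choice(pdg, size=n_neg, replace=False) if n_neg else np.array([], dtype=object)
            genes = np.r_[pos, neg]
            dirs = np.r_[np.full(n_pos, "p"), np.full(n_neg, "n")]
        else:
            size = min(config.state_size, config.n_genes)
            genes = rng.choice(config.gene_names, size=size, replace=False)
            dirs = rng.choice(["p", "n"], size=size)
        out.append(StateGeneSet(name=name, directions=pd.Series(dirs, index=genes)))
    return out


# ---------------------------------------------------------------------------
# single-cell bundle

# type -> (positive markers, negative gating markers, program genes: ligands
# and receptors expressed by that type at program_on_prob)
CELL_TYPE_CATALOG: dict[str, dict[str, list[str]]] = {
    "ERpos_tumor": {
        "pos": ["KRT18", "ESR1"],
        "neg": ["KRT5"],
        "program": ["MIF", "APP", "CD44", "SDC4"],
    },
    "Macrophage": {"pos": ["CD68"], "neg": [], "program": ["CD74", "CXCR4"]},
    "CAF": {"pos": ["DCN"], "neg": [], "program": ["SPP1", "FN1", "COL1A1", "THBS1"]},
    "Endothelial": {"pos": ["VWF"], "neg": [], "program": []},
    "Basal_tumor": {"pos": ["KRT5", "KRT18"], "neg": [], "program": []},
}


def default_gating_rules(n_cell_types: int = 3):
    """Marker gating rules matching the planted cell-type catalog."""
    from .sc import MarkerRule

    names = list(CELL_TYPE_CATALOG)[:n_cell_types]
    rules = {}
    for name in names:
        spec = CELL_TYPE_CATALOG[name]
        rules[name] = [MarkerRule(g, positive=True) for g in spec["pos"]] + [
            MarkerRule(g, positive=False) for g in spec["neg"]
        ]
    return rules


# ligand/receptor genes present in the bundle but only at background level:
# pairs built on them are planted-inactive decoys for the screen
_DECOY_LR_GENES = ["MDK", "SDC2", "TNC", "LAMB3", "PTN", "COL1A2"]


def _expression_prob_table(config: SimulationConfig) -> pd.DataFrame:
    """P(cell expresses gene) per (gene, type) at depth 1."""
    types = list(CELL_TYPE_CATALOG)[: config.n_cell_types]
    marker_genes = sorted({g for t in types for g in CELL_TYPE_CATALOG[t]["pos"] + CELL_TYPE_CATALOG[t]["neg"]})
    program_genes = sorted({g for t in types for g in CELL_TYPE_CATALOG[t]["program"]})
    fillers = [f"F{i:04d}" for i in range(config.n_filler_genes)]
    decoys = [g for g in _DECOY_LR_GENES if g not in marker_genes and g not in program_genes]
    genes = (
        marker_genes
        + [g for g in program_genes if g not in marker_genes]
        + decoys
        + fillers
    )
    probs = pd.DataFrame(config.background_prob, index=genes, columns=types, dtype=float)
    for t in types:
        spec = CELL_TYPE_CATALOG[t]
        other_markers = set(marker_genes) - set(spec["pos"])
        probs.loc[list(other_markers), t] = config.marker_off_prob
        probs.loc[spec["pos"], t] = config.marker_on_prob
        probs.loc[[g for g in program_genes if g not in spec["program"]], t] = np.minimum(
            probs.loc[[g for g in program_genes if g not in spec["program"]], t],
            config.marker_off_prob,
        )
        probs.loc[spec["program"], t] = config.program_on_prob
    return probs


def planted_active_lr_pairs(config: SimulationConfig, pairs: pd.DataFrame) -> pd.DataFrame:
    """Which (ligand, receptor, sender, receiver) combinations are planted active.

    Active means the ligand is a program/marker gene of the sender type and
    the receptor one of the receiver type (expression probability well
    above background); everything else involving genes present in the
    bundle is a planted-inactive decoy.
    """
    probs = _expression_prob_table(config)
    types = list(probs.columns)
    high = config.program_on_prob * 0.9
    rows = []
    for _, pair in pairs.iterrows():
        lig, rec = pair["ligand"], pair["receptor"]
        if lig not in probs.index or rec not in probs.index:
            continue
        for s in types:
            for r in types:
                rows.append(
                    {
                        "ligand": lig,
                        "receptor": rec,
                        "sender": s,
                        "receiver": r,
                        "active": bool(
                            probs.loc[lig, s] >= high and probs.loc[rec, r] >= high
                        ),
                    }
                )
    return pd.DataFrame(rows)


def simulate_scrna(config: SimulationConfig, truth: PlantedTruth | None = None):
    """Sparse cell x gene counts with marker-defined types (AnnData).

    Counts are Poisson with rate -log(1 - p) * depth, so that at depth 1 a
    gene is detected (count >= 1) with exactly its planted probability p.
    Planted labels live in obs['planted_type']; planted depth factors in
    obs['planted_depth']; the active ligand-receptor design in
    uns['planted_active_lr'].
    """
    import anndata as ad

    rng = config.rng("scrna")
    probs = _expression_prob_table(config)
    types = list(probs.columns)
    labels = types_arr = rng.integers(0, len(types), size=config.n_cells)
    depth = np.asarray(config.cell_depth_levels, dtype=float)[
        np.arange(config.n_cells) % len(config.cell_depth_levels)
    ]

    p = np.clip(probs.to_numpy(), 0.0, 1.0 - 1e-12)
    lam = -np.log1p(-p)  # (genes, types)
    cell_lam = lam[:, types_arr] * depth[None, :]  # (genes, cells)
    counts = rng.poisson(cell_lam.T)  # (cells, genes)
    X = sparse.csr_matrix(counts)

    barcodes = [f"CELL{i:05d}" for i in range(config.n_cells)]
    obs = pd.DataFrame(
        {
            "planted_type": pd.Categorical([types[i] for i in labels]),
            "planted_depth": depth,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    var = pd.DataFrame(index=pd.Index(list(probs.index), name="gene"))
    adata = ad.AnnData(X=X, obs=obs, var=var)

    from .sc import load_lr_pairs

    pairs = load_lr_pairs()
    adata.uns["planted_active_lr"] = planted_active_lr_pairs(config, pairs)
    if truth is not None:
        truth.cell_type = obs["planted_type"].astype(str)
        truth.active_lr_pairs = adata.uns["planted_active_lr"]
    return adata


def simulate_all(config: SimulationConfig) -> dict:
    """Run every generator stage; returns a dict of all inputs plus truth."""
    truth = planted_truth(config)
    expr, surv = simulate_survival_cohort(config, truth)
    counts, cond = simulate_acidosis_experiment(config, truth)
    panel = simulate_compound_panel(config, truth)
    state_sets = simulate_state_genesets(config, truth)
    adata = simulate_scrna(config, truth)
    return {
        "truth": truth,
        "cohort_expression": expr,
        "survival": surv,
        "acidosis_counts": counts,
        "conditions": cond,
        "panel": panel,
        "states": state_sets,
        "cells": adata,
    }
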