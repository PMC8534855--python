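"""Single-cell normalization, gating, percent-positive and the LR screen."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from acidscreen import (
    MarkerRule,
    SimulationConfig,
    annotate_cell_types,
    default_gating_rules,
    gate_cells,
    gate_mask,
    load_lr_pairs,
    lr_screen,
    normalize_cells,
    percent_positive,
    simulate_scrna,
)


def _bundle(X, genes, types=None):
    X = sparse.csr_matrix(np.asarray(X))
    obs = pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])])
    if types is not None:
        obs["cell_type"] = pd.Categorical(types)
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))


def test_normalize_symmetry_and_scale_invariance():
    adata = normalize_cells(_bundle([[1, 1], [2, 2]], ["A", "B"]))
    x = adata.X.toarray()
    assert x[0, 0] == pytest.approx(x[0, 1])  # equal counts -> equal values
    assert np.allclose(x[0], x[1])  # doubling a cell's counts changes nothing
    with pytest.raises(ValueError, match="already normalized"):
        normalize_cells(adata)


def test_normalize_drops_zero_cells():
    adata = normalize_cells(_bundle([[0, 0], [3, 1]], ["A", "B"]))
    assert adata.n_obs == 1


def test_normalization_removes_depth_effect():
    """Planted two-depth simulation: size-normalized per-type marker means
    agree across depth strata within 2%."""
    cfg = SimulationConfig(seed=13, n_cells=6000, cell_depth_levels=(1.0, 2.0))
    adata = normalize_cells(simulate_scrna(cfg))
    er = adata[adata.obs["planted_type"] == "ERpos_tumor"]
    norm = er.layers["norm"].toarray()
    shallow = er.obs["planted_depth"].to_numpy() == 1.0
    for gene in ("KRT18", "ESR1"):
        j = er.var_names.get_loc(gene)
        m1, m2 = norm[shallow, j].mean(), norm[~shallow, j].mean()
        assert abs(m1 / m2 - 1) < 0.02


def test_gating_basic_rules():
    adata = _bundle([[0, 5], [3, 4], [0, 0]], ["KRT18", "ESR1"])
    mask = gate_mask(adata, [MarkerRule("KRT18", positive=True)])
    np.testing.assert_array_equal(mask, [False, True, False])
    # contradictory predicates on one gene match nothing
    both = [MarkerRule("ESR1", positive=True), MarkerRule("ESR1", positive=False)]
    with pytest.warns(UserWarning, match="zero cells"):
        sub = gate_cells(adata, both)
    assert sub.n_obs == 0


def test_gating_order_independent(rng):
    adata = _bundle(rng.poisson(1, size=(50, 3)), ["A", "B", "C"])
    rules = [MarkerRule("A", True), MarkerRule("B", False), MarkerRule("C", True)]
    m1 = gate_mask(adata, rules)
    m2 = gate_mask(adata, rules[::-1])
    np.testing.assert_array_equal(m1, m2)


def test_gating_recovers_planted_fractions():
    """Marker gating recovers planted type fractions within 2 points at 5,000 cells."""
    cfg = SimulationConfig(seed=21, n_cells=5000)
    adata = normalize_cells(simulate_scrna(cfg))
    planted = adata.obs["planted_type"].value_counts(normalize=True)
    for name, rules in default_gating_rules(cfg.n_cell_types).items():
        gated_frac = gate_mask(adata, rules).mean()
        assert abs(gated_frac - planted[name]) < 0.02


def test_deterministic_markers_recover_type_exactly():
    cfg = SimulationConfig(seed=22, n_cells=2000, marker_on_prob=1.0, marker_off_prob=0.0)
    adata = normalize_cells(simulate_scrna(cfg))
    adata = annotate_cell_types(adata, default_gating_rules(cfg.n_cell_types))
    assert (adata.obs["cell_type"].astype(str) == adata.obs["planted_type"].astype(str)).all()


def test_percent_positive_semantics():
    adata = _bundle([[2, 0], [1, 0], [5, 0]], ["EXPR", "SILENT"])
    with pytest.warns(UserWarning, match="missing"):
        pct = percent_positive(adata, ["EXPR", "SILENT", "ABSENT"])
    assert pct["EXPR"] == 100.0
    assert pct["SILENT"] == 0.0
    assert np.isnan(pct["ABSENT"])  # absent from matrix is missing, not 0
    with pytest.raises(ValueError, match="empty"):
        percent_positive(adata[[]], ["EXPR"])


def test_percent_positive_matches_planted_probability():
    """Detection probability planted at 0.6: percent-positive lands at
    60 +/- 2 over ~5,000 evaluated tumor cells (binomial expectation)."""
    cfg = SimulationConfig(seed=23, n_cells=15000)
    adata = simulate_scrna(cfg)
    er = adata[adata.obs["planted_type"] == "ERpos_tumor"]
    assert er.n_obs > 4000
    pct = percent_positive(er, ["MIF", "APP"])
    assert abs(pct["MIF"] - 60.0) < 2.0
    assert abs(pct["APP"] - 60.0) < 2.0


def test_percent_positive_invariant_under_normalization():
    cfg = SimulationConfig(seed=24, n_cells=800)
    raw = simulate_scrna(cfg)
    norm = normalize_cells(raw.copy())
    genes = ["MIF", "CD74", "KRT18"]
    raw_pct = percent_positive(raw, genes)
    norm_pct = percent_positive(norm, genes)
    pd.testing.assert_series_equal(raw_pct, norm_pct)


def test_lr_screen_flags_planted_pairs_and_modulation():
    cfg = SimulationConfig(seed=25, n_cells=4000)
    adata = normalize_cells(simulate_scrna(cfg))
    adata = annotate_cell_types(adata, default_gating_rules(cfg.n_cell_types))
    truth = adata.uns["planted_active_lr"]
    res = lr_screen(adata, load_lr_pairs(), sender="ERpos_tumor",
                    compound_deg={"APP": -1.2, "CD44": -0.9})
    merged = res.merge(truth, on=["ligand", "receptor", "sender", "receiver"],
                       suffixes=("", "_planted"))
    assert merged.loc[merged["active_planted"], "active"].all()
    assert not merged.loc[~merged["active_planted"], "active"].any()
    # the down-regulated ligand APP appears in the compound-modulated report
    app = res[(res["ligand"] == "APP") & res["active"]]
    assert len(app) and app["modulated"].all()
    inactive = res[~res["active"]]
    assert not inactive["modulated"].any()


def test_lr_screen_full_fraction_threshold_flags_nothing():
    cfg = SimulationConfig(seed=26, n_cells=1500)
    adata = normalize_cells(simulate_scrna(cfg))
    adata = annotate_cell_types(adata, default_gating_rules(cfg.n_cell_types))
    res = lr_screen(adata, load_lr_pairs(), sender="ERpos_tumor", min_frac=1.0)
    assert not res["active"].any()


def test_lr_screen_guards():
    cfg = SimulationConfig(seed=27, n_cells=300)
    adata = normalize_cells(simulate_scrna(cfg))
    adata = annotate_cell_types(adata, default_gating_rules(cfg.n_cell_types))
    with pytest.raises(ValueError, match="unknown sender"):
        lr_screen(adata, load_lr_pairs(), sender="NoSuchType")
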