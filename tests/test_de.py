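from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rejuvseq.de import (
    ContrastSpec,
    DEParams,
    bh_adjust,
    find_degs,
    fold_change,
    wilcoxon_test,
)
from rejuvseq.de import test_gate as detection_gate  # avoid pytest collection
from rejuvseq.errors import ContractError
from rejuvseq.qc import normalize
from rejuvseq.simulate import SimConfig, simulate

from .conftest import make_adata


def two_group_adata(dense, n_a, cell_type="T"):
    n_cells = np.asarray(dense).shape[1]
    return make_adata(
        dense,
        obs={
            "group": ["Iso-P8"] * n_a + ["Iso-R1"] * (n_cells - n_a),
            "cell_type": [cell_type] * n_cells,
        },
    )


# ---------------------------------------------------------------------- gate

def test_gate_one_sided_min_pct_passes():
    # detected in 15% of group_a (6/40), 0% of group_b, 6 cells total
    dense = np.zeros((1, 60))
    dense[0, :6] = 1
    adata = two_group_adata(dense, n_a=40)
    spec = ContrastSpec.sea(cell_type="T")
    genes = detection_gate(adata, spec, min_pct=0.1, min_cells_feature=5)
    assert list(genes) == ["g0"]


def test_gate_excludes_below_min_pct_in_both():
    dense = np.zeros((1, 200))
    dense[0, :9] = 1  # 9% of 100-cell group_a
    dense[0, 100:109] = 1  # 9% of group_b
    adata = two_group_adata(dense, n_a=100)
    genes = detection_gate(adata, ContrastSpec.sea(cell_type="T"), 0.1, 5)
    assert len(genes) == 0


def test_gate_min_cells_feature_is_combined():
    # 3/6 cells (50%) in group_a detect, none in group_b: passes min_pct
    # but not min_cells_feature=5
    dense = np.zeros((1, 12))
    dense[0, :3] = 1
    adata = two_group_adata(dense, n_a=6)
    assert len(detection_gate(adata, ContrastSpec.sea(cell_type="T"), 0.1, 5)) == 0
    assert list(detection_gate(adata, ContrastSpec.sea(cell_type="T"), 0.1, 3)) == ["g0"]


def test_gate_empty_group_names_it():
    adata = make_adata([[1]], obs={"group": ["Iso-P8"], "cell_type": ["T"]})
    with pytest.raises(ContractError, match="Iso-R1"):
        detection_gate(adata, ContrastSpec.sea(cell_type="T"), 0.1, 5)


# --------------------------------------------------------------- fold change

def test_fold_change_closed_form():
    # group means of expm1(values): a=3, b=1 -> log2(4/2) = 1
    dense = np.array([[np.log1p(3.0)] * 4 + [np.log1p(1.0)] * 4])
    adata = two_group_adata(dense, n_a=4)
    lfc = fold_change(adata, ContrastSpec.sea(cell_type="T"), "g0")
    assert lfc == pytest.approx(1.0, abs=1e-12)


def test_fold_change_symmetry_and_antisymmetry():
    rng = np.random.default_rng(0)
    dense = rng.poisson(2.0, size=(1, 20)).astype(float)
    adata = two_group_adata(np.log1p(dense), n_a=10)
    spec = ContrastSpec.sea(cell_type="T")
    fwd = fold_change(adata, spec, "g0")
    rev = fold_change(adata, spec.reversed_spec(), "g0")
    assert fwd == pytest.approx(-rev, abs=1e-12)
    same = two_group_adata(np.log1p(np.tile(dense[:, :10], 2)), n_a=10)
    assert fold_change(same, spec, "g0") == pytest.approx(0.0, abs=1e-12)


# ------------------------------------------------------------------ wilcoxon

def exact_rank_sum_p(a, b):
    """Full-enumeration two-sided rank-sum p-value (tie-free oracle)."""
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1
    n = len(a)
    observed = ranks[:n].sum()
    sums = [sum(c) for c in combinations(ranks, n)]
    mu = (len(a) * (len(pooled) + 1)) / 2
    dev = abs(observed - mu)
    return float(np.mean([abs(s - mu) >= dev - 1e-12 for s in sums]))


def test_wilcoxon_complete_overlap_is_one():
    assert wilcoxon_test([1, 2, 3], [1, 2, 3]) == 1.0


def test_wilcoxon_exact_separated_groups():
    # n=m=3, complete separation: U=0, exact two-sided p = 2/20 = 0.1
    assert wilcoxon_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)


def test_wilcoxon_matches_enumeration_for_all_small_splits():
    values = np.array([0.3, 1.7, 2.2, 3.9, 5.1, 8.4])
    for idx in combinations(range(6), 3):
        a = values[list(idx)]
        b = values[[i for i in range(6) if i not in idx]]
        assert wilcoxon_test(a, b) == pytest.approx(
            exact_rank_sum_p(a, b), abs=1e-12
        )


def test_wilcoxon_ties_match_permutation_oracle():
    rng = np.random.default_rng(42)
    a = np.array([0, 0, 1, 1, 2, 2, 3, 0, 1, 2, 0, 0, 1, 3, 2, 1, 0, 2, 1, 0,
                  1, 2, 0, 1, 3, 0], dtype=float)
    b = np.array([1, 2, 2, 3, 3, 0, 1, 2, 3, 1, 2, 2, 3, 1, 0, 2, 3, 2, 1, 2,
                  3, 3, 2, 1, 2, 2], dtype=float)
    # permutation oracle on the rank-sum statistic with average ranks
    pooled = np.concatenate([a, b])
    from scipy.stats import rankdata

    obs = rankdata(pooled)[: len(a)].sum()
    mu = len(a) * (len(pooled) + 1) / 2
    n_rep = 100_000
    devs = np.empty(n_rep)
    r = rankdata(pooled)
    for i in range(n_rep):
        perm = rng.permutation(len(pooled))
        devs[i] = abs(r[perm[: len(a)]].sum() - mu)
    p_perm = np.mean(devs >= abs(obs - mu) - 1e-9)
    p = wilcoxon_test(a, b)
    assert p == pytest.approx(p_perm, abs=3 * np.sqrt(p_perm * (1 - p_perm) / n_rep) + 0.005)


def test_wilcoxon_all_identical_returns_one():
    assert wilcoxon_test([2, 2, 2], [2, 2]) == 1.0


def test_wilcoxon_rejects_empty():
    with pytest.raises(ContractError):
        wilcoxon_test([], [1.0])


# ------------------------------------------------------------------------ BH

def test_bh_single_value_identity():
    np.testing.assert_allclose(bh_adjust([0.04]), [0.04])


def test_bh_hand_worked_example():
    # step-up: min over j>=i of p_(j) * n / j -> all 0.04
    np.testing.assert_allclose(
        bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], rtol=1e-12
    )


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=40)
)
def test_bh_adjusted_values_monotone_in_ranks_and_bounded(pvals):
    p = np.asarray(pvals)
    q = bh_adjust(p)
    assert np.all(q <= 1.0 + 1e-12) and np.all(q >= p - 1e-12)
    order = np.argsort(p, kind="mergesort")
    assert np.all(np.diff(q[order]) >= -1e-12)


# ------------------------------------------------------------------ find_degs

def test_find_degs_recovers_planted_two_fold_shift():
    cfg = SimConfig(
        n_genes=300,
        cell_types=(("T", 200),),
        n_planted_up=10,
        n_planted_down=10,
        effect_lfc_range=(1.0, 1.0),
        seed=11,
    )
    adata, truth = simulate(cfg)
    norm = normalize(adata)
    table = find_degs(norm, ContrastSpec.sea(cell_type="T"))
    planted = truth[truth.planted].set_index("gene")
    flagged = table.degs.set_index("gene")
    hits = planted.index.intersection(flagged.index)
    assert len(hits) / len(planted) >= 0.9
    # direction agrees with the planted sign
    agree = (flagged.loc[hits, "direction"] == planted.loc[hits, "direction"]).mean()
    assert agree == 1.0


def test_find_degs_effect_gate_blocks_small_lfc():
    # a tiny but wildly significant shift is not a DEG (|lfc| <= 0.25)
    rng = np.random.default_rng(3)
    base = rng.poisson(20, size=(1, 1200)).astype(float)
    base[0, :600] *= 1.1  # ~0.13 log2 units: far under the 0.25 gate
    adata = two_group_adata(np.log1p(base), n_a=600)
    table = find_degs(adata, ContrastSpec.sea(cell_type="T"), DEParams(min_cells_feature=1))
    rec = table.records.iloc[0]
    assert rec["p_adj"] < 0.05 and abs(rec["avg_log2FC"]) < 0.25
    assert not rec["is_deg"] and rec["direction"] == "none"


def test_find_degs_antisymmetric_under_contrast_reversal(small_norm):
    spec = ContrastSpec.sea(cell_type="Hep")
    fwd = find_degs(small_norm, spec).records.set_index("gene")
    rev = find_degs(small_norm, spec.reversed_spec()).records.set_index("gene")
    assert set(fwd.index) == set(rev.index)
    rev = rev.loc[fwd.index]
    np.testing.assert_allclose(fwd["avg_log2FC"], -rev["avg_log2FC"], atol=1e-10)
    np.testing.assert_allclose(fwd["p_value"], rev["p_value"], rtol=1e-10)


def test_find_degs_null_calibration_single_seed():
    cfg = SimConfig(
        n_genes=500, cell_types=(("T", 100),), n_planted_up=0, n_planted_down=0, seed=5
    )
    adata, _ = simulate(cfg)
    table = find_degs(normalize(adata), ContrastSpec.sea(cell_type="T"))
    assert (table.records["p_value"] < 0.05).mean() < 0.09
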