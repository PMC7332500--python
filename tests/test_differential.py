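"""t-tests from deconvoluted means/SEs, BH correction, hypergeometric overlap."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from decnet import bh_adjust, call_de, celltype_t_test, deconvolve_expression, hypergeom_overlap
from decnet.expression import CellTypeExpression

from conftest import toy_expression_groups


def _expr(means, ses, nu=20, cell_type="cancer"):
    genes = [f"g{i}" for i in range(len(means))]
    return CellTypeExpression(
        E=pd.DataFrame({cell_type: means}, index=genes),
        S=pd.DataFrame({cell_type: ses}, index=genes),
        nu=nu,
        n_samples=nu + 1,
        active_constraints=pd.DataFrame({cell_type: [False] * len(means)}, index=genes),
    )


def test_t_statistic_closed_form():
    """t = (8 - 4) / sqrt(0.25 + 0.25) = 5.65685..."""
    hi = _expr([8.0], [0.5])
    lo = _expr([4.0], [0.5])
    tab = celltype_t_test(hi, lo, "cancer")
    assert tab["t"].iloc[0] == pytest.approx(4 / np.sqrt(0.5), abs=1e-5)
    assert tab["t"].iloc[0] == pytest.approx(5.65685, abs=1e-5)
    # equal component SEs make Welch-Satterthwaite df = 2 * nu
    assert tab["df"].iloc[0] == pytest.approx(40.0)


def test_identical_groups_give_null_result():
    hi = _expr([5.0, 2.0], [0.3, 0.4])
    tab = celltype_t_test(hi, hi, "cancer")
    assert (tab["t"] == 0).all()
    assert (tab["p"] == 1).all()


def test_t_antisymmetry_under_group_swap():
    rng = np.random.default_rng(0)
    hi = _expr(rng.uniform(1, 10, 20), rng.uniform(0.1, 1, 20))
    lo = _expr(rng.uniform(1, 10, 20), rng.uniform(0.1, 1, 20))
    a = celltype_t_test(hi, lo, "cancer")
    b = celltype_t_test(lo, hi, "cancer")
    np.testing.assert_allclose(a["t"], -b["t"], atol=1e-12)
    np.testing.assert_allclose(a["p"], b["p"], atol=1e-12)


def test_zero_se_unequal_means_flagged_degenerate():
    hi = _expr([5.0], [0.0])
    lo = _expr([2.0], [0.0])
    with pytest.warns(UserWarning, match="zero standard error"):
        tab = celltype_t_test(hi, lo, "cancer")
    assert tab["degenerate"].iloc[0]
    assert tab["p"].iloc[0] == 0.0


def _bh_oracle(p):
    """Textbook step-up BH with monotonicity enforcement."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


def test_bh_hand_computed_example():
    """(.01,.02,.03,.04): every q collapses to .04 under step-up."""
    q = bh_adjust([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)
    assert bh_adjust([0.3])[0] == pytest.approx(0.3)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
def test_bh_matches_independent_oracle_and_bounds(p):
    q = bh_adjust(p)
    np.testing.assert_allclose(q, _bh_oracle(p), atol=1e-12)
    assert (q >= np.asarray(p) - 1e-15).all() and (q <= 1 + 1e-15).all()


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 1000))
def test_bh_permutation_equivariance(seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0, 1, 25)
    perm = rng.permutation(25)
    q = bh_adjust(p)
    q_perm = bh_adjust(p[perm])
    np.testing.assert_allclose(q_perm, q[perm], atol=1e-12)


def test_bh_rejects_nan():
    with pytest.raises(ValueError):
        bh_adjust([0.1, float("nan")])


def test_call_de_boundaries():
    tab = pd.DataFrame(
        {
            "q": [0.01, 0.01, 0.06, 0.01],
            "log2fc": [1.0, 0.9, 3.0, -1.5],
        },
        index=["up_exact", "too_small_fc", "not_sig", "down"],
    )
    up, down = call_de(tab)
    assert up == ["up_exact"]
    assert down == ["down"]


def test_hypergeom_matches_enumeration_oracle():
    """N=20, K=5, n=4, x=3: p = (C(5,3)C(15,1) + C(5,4)C(15,0)) / C(20,4)."""
    universe = [f"g{i}" for i in range(20)]
    target = universe[:5]
    query = universe[:3] + [universe[10]]
    res = hypergeom_overlap(query, target, universe)
    oracle = (comb(5, 3) * comb(15, 1) + comb(5, 4) * comb(15, 0)) / comb(20, 4)
    assert oracle == pytest.approx(155 / 4845)
    assert res.p == pytest.approx(oracle, abs=1e-10)
    assert res.overlap == 3


def test_hypergeom_trivial_cases():
    universe = list("abcdefgh")
    assert hypergeom_overlap(["a", "b"], ["c", "d"], universe).p == pytest.approx(1.0)
    full = hypergeom_overlap(universe, universe, universe)
    assert full.p == pytest.approx(1.0)
    with pytest.raises(ValueError):
        hypergeom_overlap(["a"], ["b"], [])


def test_planted_fold_change_detected_with_fdr_control():
    """2.5-fold cancer-only changes: sensitivity >= 0.8, other cell types quiet."""
    G_hi, P_hi, G_lo, P_lo, planted = toy_expression_groups(seed=10)
    fit_hi = deconvolve_expression(G_hi, P_hi)
    fit_lo = deconvolve_expression(G_lo, P_lo)
    tab = celltype_t_test(fit_hi, fit_lo, "cancer")
    up, down = call_de(tab)
    calls = set(up) | set(down)
    assert len(calls & planted) / len(planted) >= 0.8
    assert len(calls - planted) / max(len(calls), 1) <= 0.1
    for ct in ("stroma", "immune"):
        t2 = celltype_t_test(fit_hi, fit_lo, ct)
        u2, d2 = call_de(t2)
        assert len(u2) + len(d2) <= 0.01 * len(t2)


def test_null_type_one_error_calibrated():
    """No planted changes: fraction of p < 0.05 within [0.03, 0.07]."""
    G_hi, P_hi, G_lo, P_lo, _ = toy_expression_groups(
        seed=20, n_genes=1000, n_de=0
    )
    fit_hi = deconvolve_expression(G_hi, P_hi)
    fit_lo = deconvolve_expression(G_lo, P_lo)
    tab = celltype_t_test(fit_hi, fit_lo, "cancer")
    frac = (tab["p"] < 0.05).mean()
    assert 0.03 <= frac <= 0.07
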