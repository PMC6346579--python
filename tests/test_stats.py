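"""Effect sizes, permutation inference, residualization and FDR."""
import itertools

import numpy as np
import pytest
from scipy.stats import rankdata, spearmanr

from wmh_bullseye import (chi2_phi, fdr_adjust, mannwhitney_effect,
                          permutation_p, residualize, spearman_effect)
from wmh_bullseye.stats import (UndefinedStatisticError, _linear_perm_pvalue,
                                cohens_d, mann_whitney_z)


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def test_spearman_identity_and_reversal(rng):
    x = rng.random(30)
    assert spearman_effect(x, x, n_boot=0).value == pytest.approx(1.0)
    assert spearman_effect(x, -x, n_boot=0).value == pytest.approx(-1.0)


def test_spearman_matches_rank_definition_on_small_table():
    x = [3.1, 1.2, 5.5, 2.2, 4.0, 0.7]
    y = [10.0, 4.0, 8.0, 6.0, 12.0, 2.0]
    # brute-force rho from the rank definition (no ties -> 1 - 6 sum d^2 / n(n^2-1))
    rx = [sorted(x).index(v) + 1 for v in x]
    ry = [sorted(y).index(v) + 1 for v in y]
    d2 = sum((a - b) ** 2 for a, b in zip(rx, ry))
    expected = 1 - 6 * d2 / (6 * (36 - 1))
    est = spearman_effect(x, y, n_boot=500, rng=np.random.default_rng(1))
    assert est.value == pytest.approx(expected)
    assert est.ci95[0] <= est.value <= est.ci95[1]


def test_spearman_rejects_constant_input():
    with pytest.raises(UndefinedStatisticError):
        spearman_effect([1, 1, 1, 1], [1, 2, 3, 4], n_boot=0)


# ---------------------------------------------------------------------------
# Mann-Whitney / Cohen's d
# ---------------------------------------------------------------------------

def test_mannwhitney_null_case(rng):
    y = rng.standard_normal(400)
    g = np.zeros(400, dtype=bool)
    g[rng.choice(400, 200, replace=False)] = True
    est = mannwhitney_effect(g, y, n_boot=0)
    assert abs(est.value) < 0.2
    assert abs(est.z) < 2.5


def test_mannwhitney_complete_separation_is_extremal():
    y = np.arange(1, 11, dtype=float)
    g = y > 5
    obs = abs(mann_whitney_z(g, y))
    # exhaustive: no 5-of-10 assignment beats complete separation
    best = max(abs(mann_whitney_z(np.isin(np.arange(10), c), y))
               for c in itertools.combinations(range(10), 5))
    assert obs == pytest.approx(best)
    r1 = rankdata(y)[g].sum()
    u = r1 - 5 * 6 / 2
    assert u in (0.0, 25.0)


def test_cohens_d_recovers_one_sd_shift(rng):
    a = rng.standard_normal(2000)
    b = rng.standard_normal(2000) + 1.0
    g = np.r_[np.zeros(2000, bool), np.ones(2000, bool)]
    assert cohens_d(g, np.r_[a, b]) == pytest.approx(1.0, abs=0.08)


def test_mannwhitney_requires_two_groups():
    with pytest.raises(UndefinedStatisticError):
        mann_whitney_z(np.ones(5, dtype=bool), np.arange(5.0))


# ---------------------------------------------------------------------------
# chi-square / phi
# ---------------------------------------------------------------------------

def test_phi_perfect_association():
    a = np.r_[np.ones(10, bool), np.zeros(10, bool)]
    est = chi2_phi(a, a)
    assert est.value == pytest.approx(1.0)


def test_phi_independence():
    a = np.r_[np.ones(10, bool), np.zeros(10, bool)]
    b = np.tile([True, False], 10)  # every 2x2 cell holds 5
    assert chi2_phi(a, b).value == pytest.approx(0.0, abs=1e-12)


def test_chi2_matches_hand_computation():
    # table [[12, 5], [3, 20]]
    a = np.r_[np.zeros(17, bool), np.ones(23, bool)]
    b = np.r_[np.zeros(12, bool), np.ones(5, bool),
              np.zeros(3, bool), np.ones(20, bool)]
    n = 40.0
    chi2 = 0.0
    table = np.array([[12, 5], [3, 20]], float)
    for i in range(2):
        for j in range(2):
            exp = table[i].sum() * table[:, j].sum() / n
            chi2 += (table[i, j] - exp) ** 2 / exp
    est = chi2_phi(a, b)
    assert est.z == pytest.approx(chi2)
    assert est.value == pytest.approx(np.sqrt(chi2 / n))


def test_phi_zero_margin_raises():
    with pytest.raises(UndefinedStatisticError):
        chi2_phi(np.ones(6, bool), np.r_[np.ones(3, bool), np.zeros(3, bool)])


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------

def _rho(x, y):
    return spearmanr(x, y).statistic


def test_permutation_p_of_monotone_pair_matches_enumeration():
    x = np.arange(6.0)
    y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    exact = sum(abs(_rho(x, p)) >= 1.0 - 1e-12
                for p in itertools.permutations(y)) / 720
    p = permutation_p(_rho, x, y, n_perm=10_000, seed=0)
    assert exact == pytest.approx(2 / 720)
    assert abs(p - exact) < 3 * np.sqrt(exact * (1 - exact) / 10_000) + 1e-4


def test_permutation_p_matches_enumeration_on_arbitrary_data():
    x = np.arange(6.0)
    y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
    obs = abs(_rho(x, y))
    exact = sum(abs(_rho(x, p)) >= obs - 1e-12
                for p in itertools.permutations(y)) / 720
    p = permutation_p(_rho, x, y, n_perm=20_000, seed=1)
    assert abs(p - exact) < 3 * np.sqrt(exact * (1 - exact) / 20_000)


def test_permutation_p_zero_statistic_on_symmetric_null():
    p = permutation_p(lambda x, y: 0.0, np.arange(8), np.arange(8),
                      n_perm=200, seed=0)
    assert p == 1.0


def test_permutation_p_floor_is_one_over_nperm():
    x = np.arange(12.0)
    p = permutation_p(_rho, x, x, n_perm=50, seed=0)
    assert p == 1 / 50


def test_vectorized_engine_agrees_with_generic_loop(rng):
    x = rng.standard_normal(40)
    y = 0.5 * x + rng.standard_normal(40)
    p_generic = permutation_p(_rho, x, y, n_perm=4000, seed=3)
    xr, yr = residualize(x), residualize(y)
    obs = float(xr @ yr / (np.linalg.norm(xr) * np.linalg.norm(yr)))
    coef = xr / (np.linalg.norm(xr) * np.linalg.norm(yr))
    p_fast = _linear_perm_pvalue(coef, yr, obs, 4000,
                                 np.random.default_rng(4))
    # two independent MC estimates of the same p: 4 sigma of the difference
    p_bar = (p_generic + p_fast) / 2
    assert abs(p_generic - p_fast) < 4 * np.sqrt(2 * p_bar * (1 - p_bar) / 4000)


# ---------------------------------------------------------------------------
# residualization (partial Spearman)
# ---------------------------------------------------------------------------

def test_residualize_constant_covariate_centers_ranks():
    y = np.array([10.0, 30.0, 20.0])
    res = residualize(y, np.ones(3))
    np.testing.assert_allclose(res, rankdata(y) - 2.0)
    np.testing.assert_allclose(residualize(y), rankdata(y) - 2.0)


def test_residualize_removes_rank_linear_covariate(rng):
    c = rng.random(50)
    y = 2.0 * c + 1.0  # y is a monotone function of c: identical ranks
    assert np.abs(residualize(y, c)).max() < 1e-9


def test_partial_spearman_matches_textbook_formula(rng):
    x = rng.standard_normal(40)
    c = 0.5 * x + rng.standard_normal(40)
    y = 0.4 * c + rng.standard_normal(40)
    r_xy = spearmanr(x, y).statistic
    r_xc = spearmanr(x, c).statistic
    r_yc = spearmanr(y, c).statistic
    expected = (r_xy - r_xc * r_yc) / np.sqrt((1 - r_xc ** 2) * (1 - r_yc ** 2))
    xr, yr = residualize(x, c), residualize(y, c)
    got = float(xr @ yr / (np.linalg.norm(xr) * np.linalg.norm(yr)))
    assert got == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def _bh_oracle(p):
    """Literal step-up definition: q_i = min_{j>=i} min(1, m p_(j) / j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q_sorted = np.minimum(1.0, p[order] * m / np.arange(1, m + 1))
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = q_sorted
    return q


def test_fdr_hand_example():
    np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])


def test_fdr_trivial_cases():
    np.testing.assert_allclose(fdr_adjust([0.2]), [0.2])
    np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])


def test_fdr_matches_brute_force_oracle(rng):
    p = rng.random(36)
    np.testing.assert_allclose(fdr_adjust(p), _bh_oracle(p), atol=1e-12)
    q = fdr_adjust(p)
    assert (q >= p - 1e-12).all()


def test_fdr_rejects_invalid_pvalues():
    with pytest.raises(ValueError):
        fdr_adjust([0.5, 1.5])
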