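from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from etscan.stats import (
    blaker_two_sided_p,
    bootstrap_ci_logfe,
    build_presence_matrix,
    enrichment_scan,
    ets_count_distribution,
    exact_combination_counts,
    null_intersection_distribution,
    prevalence_table,
    spearman_ets_nutrients,
)
from tests._oracles import blaker_p_exact, hypergeom_pmf_exact, intersection_pmf_enumerate
from tests.conftest import sets_to_matrix


# ---------------------------------------------------------------------------
# exact null distribution
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("N,k1,k2", [(10, 3, 7), (25, 12, 5), (40, 40, 13),
                                     (18, 0, 9), (55, 20, 20)])
def test_two_set_null_is_hypergeometric(N, k1, k2):
    d = null_intersection_distribution(N, [k1, k2])
    ref = sps.hypergeom.pmf(d.support, N, k1, k2)
    np.testing.assert_allclose(d.pmf, ref, atol=1e-13)


def test_zero_size_gives_point_mass_at_zero():
    d = null_intersection_distribution(30, [10, 0, 5])
    assert d.support.tolist() == [0]
    assert d.pmf[0] == pytest.approx(1.0)


def test_three_set_null_matches_exhaustive_enumeration():
    """Tiny instance checked against full enumeration of all subset triples."""
    d = null_intersection_distribution(6, [3, 2, 2])
    ref = intersection_pmf_enumerate(6, (3, 2, 2))
    np.testing.assert_allclose(d.pmf, ref, atol=1e-12)


@given(
    N=st.integers(5, 60),
    m=st.integers(2, 4),
    data=st.data(),
)
@settings(deadline=None, derandomize=True, max_examples=50)
def test_null_distribution_properties(N, m, data):
    """pmf sums to one, mean equals N·∏(size_i/N), permutation-invariant."""
    sizes = [data.draw(st.integers(0, N)) for _ in range(m)]
    d = null_intersection_distribution(N, sizes)
    assert d.pmf.sum() == pytest.approx(1.0, abs=1e-9)
    expected_mean = N * np.prod([s / N for s in sizes])
    assert d.mean() == pytest.approx(expected_mean, rel=1e-6, abs=1e-9)
    perm = list(reversed(sizes))
    d2 = null_intersection_distribution(N, perm)
    np.testing.assert_allclose(d.pmf, d2.pmf, atol=1e-10)


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        null_intersection_distribution(0, [1, 1])
    with pytest.raises(ValueError):
        null_intersection_distribution(10, [11, 2])
    with pytest.raises(ValueError):
        null_intersection_distribution(10, [3])


# ---------------------------------------------------------------------------
# Blaker two-sided p-value
# ---------------------------------------------------------------------------

def test_blaker_equals_exact_rational_oracle():
    N, k1, k2 = 20, 5, 5
    d = null_intersection_distribution(N, [k1, k2])
    pmf_exact = hypergeom_pmf_exact(N, k1, k2)
    for obs in range(min(k1, k2) + 1):
        want = float(blaker_p_exact(pmf_exact, obs))
        got = blaker_two_sided_p(d, obs)
        assert got == pytest.approx(want, rel=1e-11), obs


def test_blaker_at_mode_of_symmetric_pmf_is_one():
    d = null_intersection_distribution(20, [10, 10])  # symmetric around 5
    assert blaker_two_sided_p(d, 5) == pytest.approx(1.0)


def test_blaker_outside_support_rejected():
    d = null_intersection_distribution(20, [5, 5])
    with pytest.raises(ValueError):
        blaker_two_sided_p(d, 6)


@given(seed=st.integers(0, 10_000))
@settings(deadline=None, derandomize=True, max_examples=100)
def test_blaker_bounded_by_tail_probabilities(seed):
    """min-tail ≤ p ≤ min(1, 2·min-tail) for random instances."""
    rng = np.random.default_rng(seed)
    N = int(rng.integers(4, 50))
    m = int(rng.integers(2, 4))
    sizes = [int(rng.integers(1, N + 1)) for _ in range(m)]
    d = null_intersection_distribution(N, sizes)
    obs = int(rng.integers(0, len(d.support)))
    p = blaker_two_sided_p(d, obs)
    cdf = np.cumsum(d.pmf)
    sf = np.cumsum(d.pmf[::-1])[::-1]
    min_tail = min(cdf[obs], sf[obs])
    assert p >= min_tail - 1e-12
    assert p <= min(1.0, 2 * min_tail) + 1e-9


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------

def test_count_distribution_capping():
    df = pd.DataFrame({"n_ets": [0, 0, 1, 2, 12]})
    out = ets_count_distribution(df)
    counts = dict(zip(out["n_ets"].astype(str), out["count"]))
    assert counts["0"] == 2 and counts["1"] == 1 and counts["2"] == 1
    assert counts["10+"] == 1
    assert sum(counts.values()) == 5


def test_prevalence_single_group():
    m = sets_to_matrix(
        [{"E440"}, set(), set(), set()], codes=["E440"], group="Desserts"
    )
    tab = prevalence_table(m)
    assert tab.loc[0, "prevalence_pct"] == pytest.approx(25.0)
    assert tab.loc[0, "n_group"] == 4


def test_exact_combination_counts_upset_semantics():
    sets = [{"E450", "E451"}, {"E450", "E451"}, {"E450"}]
    m = sets_to_matrix(sets, codes=["E450", "E451"])
    tab = exact_combination_counts(m, min_products=1)
    counts = dict(zip(tab["combo"], tab["count"]))
    assert counts == {"E450&E451": 2, "E450": 1}
    assert exact_combination_counts(m, min_products=3).empty


def test_exact_combo_totals_bounded_by_products_with_ets():
    rng = np.random.default_rng(3)
    sets = [frozenset(c for c in ("E450", "E451", "E412") if rng.random() < 0.4)
            for _ in range(300)]
    m = sets_to_matrix(sets, codes=["E412", "E450", "E451"])
    tab = exact_combination_counts(m, min_products=1)
    n_with = sum(1 for s in sets if s)
    assert tab["count"].sum() == n_with


# ---------------------------------------------------------------------------
# enrichment and bootstrap
# ---------------------------------------------------------------------------

def test_perfectly_correlated_pair_fold_enrichment():
    """Two identical columns of size n in a group of N give FE = N/n."""
    N, n = 200, 40
    sets = [{"E412", "E415"}] * n + [set()] * (N - n)
    m = sets_to_matrix(sets, codes=["E412", "E415"])
    res = enrichment_scan(m, B=0, expected_min=0.0, combo_sizes=(2,))
    assert len(res) == 1
    r = res[0]
    assert r.observed == n
    assert r.expected == pytest.approx(n * n / N)
    assert r.fold_enrichment == pytest.approx(N / n)
    assert r.p_two_sided < 1e-6


def test_enrichment_scan_filters():
    """Low-prevalence codes and low-expected combos are excluded."""
    rng = np.random.default_rng(0)
    sets = []
    for _ in range(1000):
        s = set()
        if rng.random() < 0.30:
            s.add("E450")
        if rng.random() < 0.30:
            s.add("E451")
        if rng.random() < 0.002:  # below the 1% prevalence floor
            s.add("E499")
        sets.append(s)
    m = sets_to_matrix(sets, codes=["E450", "E451", "E499"])
    res = enrichment_scan(m, B=0)
    combos = {r.combo for r in res}
    assert combos == {("E450", "E451")}


def test_small_group_skipped_with_warning():
    m = sets_to_matrix([{"E450"}] * 10, codes=["E450"])
    with pytest.warns(UserWarning, match="skipped"):
        assert enrichment_scan(m, B=0, min_group_size=50) == []


def test_bootstrap_constant_combo_zero_width():
    sets = [{"E412", "E415"}] * 50
    m = sets_to_matrix(sets, codes=["E412", "E415"])
    ci, ndeg = bootstrap_ci_logfe(m.data.values, B=200, seed=1)
    assert ndeg == 0
    assert ci[0] == pytest.approx(0.0, abs=1e-12)
    assert ci[1] == pytest.approx(0.0, abs=1e-12)  # log FE ≡ 0, FE ≡ 1


def test_bootstrap_interval_contains_point_estimate():
    rng = np.random.default_rng(5)
    n = 500
    a = rng.random(n) < 0.3
    b = np.where(rng.random(n) < 0.5, a, rng.random(n) < 0.3)  # correlated
    cols = np.column_stack([a, b])
    obs = float(np.logical_and(a, b).sum())
    logfe = np.log(obs / (n * a.mean() * b.mean()))
    ci, ndeg = bootstrap_ci_logfe(cols, B=500, seed=2)
    assert ci[0] <= logfe <= ci[1]


def test_bootstrap_all_degenerate_flagged():
    cols = np.zeros((40, 2), dtype=bool)
    cols[:2, 0] = True  # second column empty => every replicate degenerate
    ci, ndeg = bootstrap_ci_logfe(cols, B=100, seed=0)
    assert ci is None
    assert ndeg == 100


def test_bootstrap_requires_b():
    with pytest.raises(ValueError):
        bootstrap_ci_logfe(np.ones((10, 2), dtype=bool), B=50)


# ---------------------------------------------------------------------------
# Spearman correlations
# ---------------------------------------------------------------------------

def test_spearman_identity_and_constant():
    n = 50
    df = pd.DataFrame({
        "n_ets": np.arange(n) % 8,
        "sugar_g": (np.arange(n) % 8).astype(float),  # identical ranks
        "salt_g": np.ones(n),  # constant -> undefined
    })
    out = spearman_ets_nutrients(df, nutrients=("sugar_g", "salt_g"))
    row = out.set_index("nutrient")
    assert row.loc["sugar_g", "rho"] == pytest.approx(1.0)
    assert bool(row.loc["salt_g", "defined"]) is False


def test_spearman_independent_near_zero():
    rng = np.random.default_rng(11)
    df = pd.DataFrame({
        "n_ets": rng.integers(0, 6, 4000),
        "fat_g": rng.random(4000) * 30,
    })
    out = spearman_ets_nutrients(df, nutrients=("fat_g",))
    assert abs(out.loc[0, "rho"]) < 0.05


# ---------------------------------------------------------------------------
# presence matrix plumbing
# ---------------------------------------------------------------------------

def test_presence_matrix_build_and_lump():
    df = pd.DataFrame({
        "ets_codes": [frozenset({"E450", "E451"}), frozenset({"E400"}),
                      frozenset()],
        "group": ["a", "a", "b"],
    })
    m = build_presence_matrix(df)
    assert m.column_sums().to_dict() == {"E400": 1, "E450": 1, "E451": 1}
    lumped = m.lumped()
    assert set(lumped.codes) == {"E40x", "E45x"}
    assert lumped.data["E45x"].sum() == 1  # both phosphates collapse to one
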