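import math

import numpy as np
import pandas as pd
import pytest

from mintde import (
    ValidationError,
    build_evidence,
    edgington_combined_p,
    edgington_sum,
    fisher_combined,
    irwin_hall_cdf,
    rank_genes,
    select_commonDE,
    select_top_n,
)
from mintde.combine_rank import GeneEvidence, commonDE_tau_for_size


def chi2_6df_sf_oracle(x):
    """Upper tail of chi-square with 6 df via the closed Erlang(3) series."""
    h = x / 2.0
    return math.exp(-h) * (1.0 + h + h * h / 2.0)


def evidence_from_triples(triples):
    p = np.asarray(triples, dtype=float)
    tbl = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(p))],
            "p_x": p[:, 0],
            "p_y": p[:, 1],
            "p_xy": p[:, 2],
            "r": 0.0,
        }
    )
    tbl["s_edgington"] = tbl[["p_x", "p_y", "p_xy"]].sum(axis=1)
    tbl["p_edgington"] = edgington_combined_p(
        tbl["s_edgington"].to_numpy(), k=3
    )
    s, pf = fisher_combined(p[:, 0], p[:, 1], p[:, 2])
    tbl["s_fisher"] = s
    tbl["p_fisher"] = pf
    return GeneEvidence(table=tbl)


class TestEdgingtonSum:
    def test_arithmetic(self):
        assert edgington_sum(0.01, 0.02, 0.03) == pytest.approx(0.06)
        assert edgington_sum(0.0, 0.0, 0.0) == 0.0
        assert edgington_sum(1.0, 1.0, 1.0) == 3.0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            edgington_sum(0.5, 1.5, 0.2)
        with pytest.raises(ValidationError):
            edgington_sum(-0.1, 0.2, 0.2)

    def test_general_k(self):
        assert edgington_sum(0.1, 0.2) == pytest.approx(0.3)
        assert edgington_sum(0.1, 0.2, 0.3, 0.4) == pytest.approx(1.0)


class TestIrwinHall:
    def test_closed_form_cubic_below_one(self):
        for s in (0.06, 0.3, 0.9, 1.0):
            assert irwin_hall_cdf(s, 3) == pytest.approx(s**3 / 6, rel=1e-13)

    def test_symmetry_is_exact_in_float(self):
        # dyadic grid so that 3 - s is exactly representable
        for s in np.arange(0, 97) / 32.0:
            assert irwin_hall_cdf(s, 3) + irwin_hall_cdf(3 - s, 3) == 1.0

    def test_midpoint(self):
        assert irwin_hall_cdf(1.5, 3) == 0.5
        assert irwin_hall_cdf(1.0, 2) == 0.5

    def test_bounds_and_monotone(self):
        grid = np.linspace(0, 3, 301)
        vals = irwin_hall_cdf(grid, 3)
        assert vals[0] == 0.0 and vals[-1] == 1.0
        assert np.all(np.diff(vals) >= 0)

    def test_monte_carlo_cdf(self):
        rng = np.random.default_rng(123)
        sums = rng.random((100_000, 3)).sum(axis=1)
        for s in (0.5, 0.8, 1.5, 2.2):
            emp = np.mean(sums <= s)
            se = np.sqrt(emp * (1 - emp) / sums.size)
            assert abs(irwin_hall_cdf(s, 3) - emp) <= 3 * se

    def test_k2_triangular(self):
        assert irwin_hall_cdf(0.5, 2) == pytest.approx(0.125)
        assert irwin_hall_cdf(1.5, 2) == pytest.approx(0.875)

    def test_rejects_out_of_support(self):
        with pytest.raises(ValidationError):
            irwin_hall_cdf(3.2, 3)


class TestFisherCombined:
    def test_all_ones(self):
        stat, p = fisher_combined(1.0, 1.0, 1.0)
        assert stat == 0.0 and p == 1.0

    def test_matches_chi_square_oracle(self):
        stat, p = fisher_combined(0.05, 0.05, 0.05)
        assert stat == pytest.approx(-6 * math.log(0.05), rel=1e-13)
        assert p == pytest.approx(chi2_6df_sf_oracle(stat), rel=1e-10)

    def test_permutation_symmetry(self):
        a = fisher_combined(0.01, 0.4, 0.9)
        for perm in [(0.4, 0.01, 0.9), (0.9, 0.4, 0.01)]:
            b = fisher_combined(*perm)
            assert b == a

    def test_zero_input_floored(self):
        stat, p = fisher_combined(0.0, 0.5, 0.5)
        assert np.isfinite(stat) and 0 <= p <= 1


class TestRanking:
    def test_monotone_order(self):
        ranked = rank_genes(
            evidence_from_triples([(0.2, 0.2, 0.2), (0.1, 0.1, 0.1)])
        )
        assert list(ranked.table["gene_id"]) == ["g1", "g0"]
        assert list(ranked.table["rank"]) == [1, 2]

    def test_tie_broken_by_smaller_p_xy(self):
        ranked = rank_genes(
            evidence_from_triples([(0.10, 0.05, 0.05), (0.05, 0.10, 0.01),
                                   (0.04, 0.11, 0.05)])
        )
        # all sums are 0.20; order by p_xy then gene_id
        assert list(ranked.table["gene_id"]) == ["g1", "g0", "g2"]

    def test_sum_and_combined_p_rank_identically(self):
        # monotone equivalence, stated tie-robustly: sorting by either key
        # leaves the other nondecreasing
        grid = np.linspace(0.01, 0.99, 5)
        triples = [(a, b, c) for a in grid for b in grid for c in grid]
        ev = evidence_from_triples(triples)
        s = ev.table["s_edgington"].to_numpy()
        p = ev.table["p_edgington"].to_numpy()
        # tolerance at rounding scale: distinct triples with the same
        # mathematical sum can differ by a ulp
        assert np.all(np.diff(p[np.argsort(s, kind="stable")]) >= -1e-12)
        assert np.all(np.diff(s[np.argsort(p, kind="stable")]) >= -1e-12)

    def test_fisher_ranking_uses_p_fisher(self):
        ev = evidence_from_triples([(1e-12, 0.9, 0.9), (0.05, 0.05, 0.05)])
        ranked = rank_genes(ev, method="fisher")
        assert list(ranked.table["gene_id"])[0] == "g0"


class TestSelection:
    def test_top_n_boundaries(self):
        ranked = rank_genes(
            evidence_from_triples([(0.3, 0.3, 0.3), (0.1, 0.1, 0.1),
                                   (0.2, 0.2, 0.2)])
        )
        assert select_top_n(ranked, 3).selected_gene_ids == ["g1", "g2", "g0"]
        assert select_top_n(ranked, 1).selected_gene_ids == ["g1"]
        with pytest.raises(ValidationError):
            select_top_n(ranked, 4)

    def test_commonDE_toy_filter(self):
        class FakeDE:
            def __init__(self, gene_ids, p):
                self.gene_ids = gene_ids
                self.per_gene_p = np.asarray(p)

        genes = [f"g{i}" for i in range(5)]
        de_x = FakeDE(genes, [0.01, 0.04, 0.3, 0.001, 0.9])
        de_y = FakeDE(genes, [0.02, 0.2, 0.01, 0.001, 0.9])
        sel = select_commonDE(de_x, de_y, 0.05, 0.05)
        assert sel.selected_gene_ids == ["g3", "g0"]  # ordered by max p

    def test_commonDE_thresholds_are_strict(self):
        class FakeDE:
            def __init__(self, p):
                self.gene_ids = ["g0", "g1"]
                self.per_gene_p = np.asarray(p)

        de = FakeDE([0.05, 0.01])
        sel = select_commonDE(de, de, 0.05, 0.05)
        assert sel.selected_gene_ids == ["g1"]
        # tau = 1 admits everything with P < 1
        assert len(select_commonDE(de, de, 1.0, 1.0)) == 2
        # near machine-minimum tau admits nothing
        assert len(select_commonDE(de, de, 1e-300, 1e-300)) == 0

    def test_tau_for_size_hits_target(self):
        class FakeDE:
            def __init__(self, p):
                self.gene_ids = [f"g{i}" for i in range(len(p))]
                self.per_gene_p = np.asarray(p)

        rng = np.random.default_rng(0)
        de_x, de_y = FakeDE(rng.random(50)), FakeDE(rng.random(50))
        for n in (1, 10, 50):
            tau = commonDE_tau_for_size(de_x, de_y, n)
            assert len(select_commonDE(de_x, de_y, tau, tau)) == n


def test_edgington_large_p_screens_out_one_sided_evidence():
    """One P near 1 outranks (is worse than) ANY all-moderate triple under
    Edgington, while Fisher can prefer the lopsided gene."""
    lopsided = (1.0, 1e-8, 1e-8)
    moderate = (0.3, 0.3, 0.3)
    assert edgington_sum(*lopsided) >= 1.0
    assert edgington_sum(*moderate) < 1.0
    _, p_lop = fisher_combined(*lopsided)
    _, p_mod = fisher_combined(*moderate)
    assert p_lop < p_mod  # Fisher is carried by the tiny P-values


def test_build_evidence_validates_gene_lists(small_sim):
    from mintde import pairwise_timepoint_tests, within_gene_correlation

    pair, _ = small_sim
    de_x = pairwise_timepoint_tests(pair.x)
    de_y = pairwise_timepoint_tests(pair.y)
    assoc = within_gene_correlation(pair)
    ev = build_evidence(de_x, de_y, assoc)
    np.testing.assert_allclose(
        ev.table["s_edgington"],
        ev.table[["p_x", "p_y", "p_xy"]].sum(axis=1),
    )
    # combined P-values are nondecreasing in each input
    bumped = np.minimum(ev.table["p_xy"].to_numpy() + 0.1, 1.0)
    s_bumped = (
        ev.table["p_x"].to_numpy() + ev.table["p_y"].to_numpy() + bumped
    )
    p2 = edgington_combined_p(s_bumped, k=3)
    assert np.all(p2 >= ev.table["p_edgington"].to_numpy() - 1e-15)
    _, pf2 = fisher_combined(
        ev.table["p_x"].to_numpy(), ev.table["p_y"].to_numpy(), bumped
    )
    assert np.all(pf2 >= ev.table["p_fisher"].to_numpy() - 1e-15)


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st

unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


@settings(derandomize=True, max_examples=200)
@given(p1=unit, p2=unit, p3=unit)
def test_combined_p_values_always_in_unit_interval(p1, p2, p3):
    s = edgington_sum(p1, p2, p3)
    pe = edgington_combined_p(s, 3)
    stat, pf = fisher_combined(p1, p2, p3)
    assert 0.0 <= pe <= 1.0
    assert 0.0 <= pf <= 1.0
    assert stat >= 0.0


@settings(derandomize=True, max_examples=200)
@given(s1=st.floats(0.0, 3.0), s2=st.floats(0.0, 3.0))
def test_irwin_hall_cdf_is_monotone(s1, s2):
    lo, hi = sorted((s1, s2))
    assert irwin_hall_cdf(lo, 3) <= irwin_hall_cdf(hi, 3) + 1e-15


@settings(derandomize=True, max_examples=100)
@given(
    p=st.lists(unit, min_size=2, max_size=6),
)
def test_fisher_statistic_invariant_under_permutation(p):
    import itertools

    stat, pv = fisher_combined(*p)
    perm = list(itertools.islice(itertools.permutations(p), 3))[-1]
    stat2, pv2 = fisher_combined(*perm)
    assert stat == pytest.approx(stat2, rel=1e-12, abs=1e-12)
    assert pv == pytest.approx(pv2, rel=1e-12, abs=1e-12)
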