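"""Group-comparison statistics: adjustments, omnibus tests, branch choice."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cardioafm.stats import (GroupTable, choose_branch, dunn_pairwise, holm,
                             holm_sidak, omnibus_and_pairwise)


def _table(groups: dict) -> GroupTable:
    rows = []
    for g, vals in groups.items():
        for i, v in enumerate(vals):
            rows.append({"sample": f"{g}{i}", "group": g, "value": float(v)})
    return GroupTable(pd.DataFrame(rows))


def _holm_sidak_bruteforce(p):
    """Literal step-down evaluation, one hypothesis at a time."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, val)
        adj[idx] = min(running, 1.0)
    return adj


class TestAdjustments:
    def test_holm_sidak_worked_example(self):
        adj = holm_sidak(np.array([0.01, 0.02, 0.04]))
        np.testing.assert_allclose(adj, [0.029701, 0.039600, 0.040000], atol=1e-9)

    @pytest.mark.parametrize("m", [1, 2, 3, 4, 5, 6])
    def test_holm_sidak_matches_bruteforce(self, m):
        rng = np.random.default_rng(m)
        for _ in range(50):
            p = rng.random(m)
            np.testing.assert_allclose(holm_sidak(p), _holm_sidak_bruteforce(p),
                                       atol=1e-12)

    def test_adjusted_dominates_raw_and_is_monotone(self):
        rng = np.random.default_rng(0)
        for adjuster in (holm_sidak, holm):
            p = rng.random(6)
            adj = adjuster(p)
            assert np.all(adj >= p - 1e-15)
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-15)


class TestOmnibus:
    def test_anova_f_hand_computed(self):
        # SSB = 6 (df 2), SSW = 6 (df 6) -> F = 3.0
        t = _table({"a": [1, 2, 3], "b": [2, 3, 4], "c": [3, 4, 5]})
        rep = omnibus_and_pairwise(t, branch="parametric")
        assert rep.omnibus_statistic == pytest.approx(3.0, abs=1e-12)
        assert rep.omnibus_test == "anova"

    def test_kruskal_wallis_hand_computed(self):
        # rank sums 6 / 15 / 24 over N = 9 -> H = 7.2
        t = _table({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        rep = omnibus_and_pairwise(t, branch="nonparametric")
        assert rep.omnibus_statistic == pytest.approx(7.2, abs=1e-9)
        assert rep.omnibus_test == "kruskal_wallis"

    def test_kw_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        raw = {g: rng.normal(i, 1, 6) for i, g in enumerate("abc")}
        h1 = omnibus_and_pairwise(_table(raw), branch="nonparametric").omnibus_statistic
        warped = {g: np.exp(v) for g, v in raw.items()}
        h2 = omnibus_and_pairwise(_table(warped), branch="nonparametric").omnibus_statistic
        assert h2 == pytest.approx(h1, rel=1e-12)

    def test_se_is_sd_over_sqrt_n(self):
        t = _table({"a": [1.0, 2.0, 3.0, 6.0], "b": [2, 2, 2, 2]})
        rep = omnibus_and_pairwise(t, branch="nonparametric")
        row = rep.group_summary.loc["a"]
        assert row["se"] == pytest.approx(np.std([1, 2, 3, 6], ddof=1) / 2.0, rel=1e-12)

    def test_zero_variance_falls_back_to_ranks(self):
        t = _table({"a": [1, 1, 1], "b": [2, 2, 2]})
        rep = omnibus_and_pairwise(t, branch="parametric")
        assert rep.branch == "nonparametric"
        assert rep.notes


class TestDunn:
    def test_matches_independent_rank_recomputation(self):
        rng = np.random.default_rng(2)
        groups = {"a": rng.normal(0, 1, 4), "b": rng.normal(1, 1, 4),
                  "c": rng.normal(2, 1, 4)}
        result = dunn_pairwise(groups)
        pooled = np.concatenate(list(groups.values()))
        ranks = sps.rankdata(pooled)
        n = pooled.size
        sizes = {g: v.size for g, v in groups.items()}
        mean_rank, pos = {}, 0
        for g, v in groups.items():
            mean_rank[g] = ranks[pos : pos + v.size].mean()
            pos += v.size
        _, counts = np.unique(pooled, return_counts=True)
        ties = np.sum(counts**3 - counts)
        var = n * (n + 1) / 12 - ties / (12 * (n - 1))
        for a, b, z, p in result:
            se = np.sqrt(var * (1 / sizes[a] + 1 / sizes[b]))
            z_expect = (mean_rank[a] - mean_rank[b]) / se
            assert z == pytest.approx(z_expect, rel=1e-12)
            assert p == pytest.approx(2 * sps.norm.sf(abs(z_expect)), rel=1e-12)

    def test_tie_correction_changes_variance(self):
        no_ties = dunn_pairwise({"a": np.array([1.0, 2, 3]), "b": np.array([4.0, 5, 6])})
        with_ties = dunn_pairwise({"a": np.array([1.0, 1, 3]), "b": np.array([4.0, 4, 6])})
        assert no_ties[0][2] != with_ties[0][2]


class TestBranchChoice:
    def test_small_groups_force_nonparametric(self):
        t = _table({"a": [1, 2], "b": [3, 4], "c": [5, 6], "d": [7, 8]})
        with pytest.warns(UserWarning):
            assert choose_branch(t) == "nonparametric"

    def test_heavy_tails_demote(self):
        rng = np.random.default_rng(3)
        t = _table({"a": rng.standard_cauchy(50), "b": rng.normal(0, 1, 50)})
        assert choose_branch(t) == "nonparametric"

    def test_gaussian_groups_stay_parametric_about_95_percent(self):
        rng = np.random.default_rng(4)
        hits = 0
        n_sim = 300
        for _ in range(n_sim):
            t = _table({g: rng.normal(0, 1, 20) for g in "abcd"})
            hits += choose_branch(t) == "parametric"
        rate = hits / n_sim
        assert 0.90 <= rate <= 0.99

    def test_force_overrides(self):
        t = _table({"a": [1, 2], "b": [3, 4]})
        assert choose_branch(t, force="parametric") == "parametric"


class TestReport:
    def test_all_six_contrasts_among_four_groups(self):
        rng = np.random.default_rng(5)
        t = _table({g: rng.normal(0, 1, 5) for g in
                    ("sham_close", "sham_far", "mi_close", "mi_far")})
        rep = omnibus_and_pairwise(t, branch="parametric")
        assert len(rep.pairwise) == 6
        pairs = {frozenset((p.group_a, p.group_b)) for p in rep.pairwise}
        expect = {frozenset(c) for c in itertools.combinations(
            ("sham_close", "sham_far", "mi_close", "mi_far"), 2)}
        assert pairs == expect

    def test_identical_groups_give_unit_adjusted_p(self):
        rng = np.random.default_rng(6)
        base = rng.normal(5, 1, 5)
        t = _table({g: base for g in "abcd"})  # one cohort relabelled four times
        rep = omnibus_and_pairwise(t)
        for pr in rep.pairwise:
            assert pr.p_adjusted == pytest.approx(1.0, abs=1e-9)
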