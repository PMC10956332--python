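"""Cross-species statistics: conversions, Mann-Whitney, Spearman,
order comparisons, percentile reports, BUSCO arithmetic."""

import itertools
import math
import warnings

import numpy as np
import pytest
from scipy import stats as sps

from genarch.annotation_io import BuscoCounts, CValueRecord
from genarch import comparative_stats as cs


class TestPgMbp:
    def test_one_pg_is_978_mbp(self):
        assert cs.pg_to_mbp(1.0) == 978.0

    def test_zero(self):
        assert cs.pg_to_mbp(0.0) == 0.0

    def test_hand_example(self):
        assert cs.pg_to_mbp(0.56) == pytest.approx(547.68)

    def test_round_trip_machine_precision(self):
        for v in np.logspace(-3, 3, 25):
            assert abs(cs.mbp_to_pg(cs.pg_to_mbp(v)) - v) < 1e-12

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cs.pg_to_mbp(-1.0)
        with pytest.raises(ValueError):
            cs.mbp_to_pg(-1.0)


class TestSpeciesMeans:
    def test_duplicates_averaged(self):
        recs = [CValueRecord("X", "O", 0.5), CValueRecord("X", "O", 0.7)]
        (out,) = cs.species_mean_cvalues(recs)
        assert out.c_value_pg == pytest.approx(0.6)

    def test_five_rows_three_species(self):
        recs = [
            CValueRecord("A", "O", 0.5), CValueRecord("A", "O", 0.7),
            CValueRecord("B", "O", 1.0), CValueRecord("B", "O", 1.2),
            CValueRecord("C", "P", 2.0),
        ]
        out = cs.species_mean_cvalues(recs)
        assert [r.species for r in out] == ["A", "B", "C"]

    def test_conflicting_order_names_species(self):
        recs = [CValueRecord("X", "O1", 0.5), CValueRecord("X", "O2", 0.7)]
        with pytest.raises(ValueError, match="X"):
            cs.species_mean_cvalues(recs)


def enumeration_p(x, y):
    """Brute-force exact two-sided p: every assignment of pooled ranks."""
    n1 = len(x)
    pooled = sorted(x + y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj) + 0.5 * sum(
        1 for xi in x for yj in y if xi == yj
    )
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        us.append(sum(1 for a in xs for b in ys if a > b))
    us = np.array(us, dtype=float)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2 * min(p_le, p_ge))


class TestMannWhitney:
    def test_textbook_example(self):
        res = cs.mann_whitney([1, 2], [3, 4])
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(1 / 3)
        assert res.method == "exact"

    def test_identical_samples_give_half_u(self):
        res = cs.mann_whitney([1, 2, 3], [3, 2, 1])
        assert res.u_statistic == pytest.approx(4.5)  # n1*n2/2

    def test_u_from_pair_count_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            x = rng.normal(size=int(rng.integers(1, 10))).tolist()
            y = rng.normal(size=int(rng.integers(1, 10))).tolist()
            res = cs.mann_whitney(x, y)
            brute = sum(1 for a in x for b in y if a > b) + 0.5 * sum(
                1 for a in x for b in y if a == b
            )
            assert res.u_statistic == pytest.approx(brute)

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(22)
        for _ in range(25):
            x = rng.normal(size=int(rng.integers(2, 7))).tolist()
            y = rng.normal(size=int(rng.integers(2, 7))).tolist()
            res = cs.mann_whitney(x, y)
            u, p = enumeration_p(x, y)
            assert res.method == "exact"
            assert res.u_statistic == pytest.approx(u)
            assert res.p_value == pytest.approx(p)

    def test_u_complement_identity(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            x = rng.integers(0, 10, size=int(rng.integers(1, 15))).tolist()
            y = rng.integers(0, 10, size=int(rng.integers(1, 15))).tolist()
            u1 = cs.mann_whitney(x, y).u_statistic
            u2 = cs.mann_whitney(y, x).u_statistic
            assert u1 + u2 == pytest.approx(len(x) * len(y))

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(24)
        x = rng.normal(size=12)
        y = rng.normal(0.8, 1, size=9)
        res = cs.mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.u_statistic == pytest.approx(float(ref.statistic))
        assert res.p_value == pytest.approx(float(ref.pvalue))

    def test_ties_force_normal_approximation(self):
        res = cs.mann_whitney([1, 2, 2, 3], [2, 3, 4, 4])
        assert res.method == "normal_approx"
        ref = sps.mannwhitneyu([1, 2, 2, 3], [2, 3, 4, 4],
                               alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-6)

    def test_large_samples_use_normal_approx_close_to_exact(self):
        rng = np.random.default_rng(25)
        x = rng.normal(size=25)
        y = rng.normal(0.5, 1, size=25)
        res = cs.mann_whitney(x, y)
        assert res.method == "normal_approx"
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=0.05)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            cs.mann_whitney([], [1.0])


class TestNormalityGate:
    def test_lognormal_sample_is_non_normal(self):
        values = np.random.default_rng(1).lognormal(0, 1, size=500)
        assert cs.normality_gate(values) is True

    def test_normal_samples_mostly_pass(self):
        falses = sum(
            not cs.normality_gate(np.random.default_rng(seed).normal(size=500))
            for seed in range(20)
        )
        assert falses >= 18

    def test_degenerate_inputs_warn_and_gate(self):
        with pytest.warns(UserWarning):
            assert cs.normality_gate([1.0, 1.0, 1.0, 1.0]) is True
        with pytest.warns(UserWarning):
            assert cs.normality_gate([1.0, 2.0]) is True


def _order_records(order, values):
    return [
        CValueRecord(f"{order}_{i}", order, v) for i, v in enumerate(values)
    ]


class TestCompareFocalOrder:
    def test_separated_orders_maximally_significant(self):
        rng = np.random.default_rng(31)
        a = rng.uniform(0.5, 1.0, size=20)
        recs = _order_records("A", a) + _order_records("B", a + 10)
        (comp,) = cs.compare_focal_order(recs, "A")
        assert comp.significance_label == "****"
        assert comp.other_mean_pg > comp.focal_mean_pg

    def test_permuted_copy_not_significant(self):
        rng = np.random.default_rng(32)
        a = rng.uniform(0.5, 1.5, size=20)
        recs = _order_records("A", a) + _order_records("B", rng.permutation(a))
        (comp,) = cs.compare_focal_order(recs, "A")
        assert comp.significance_label == "ns"

    def test_two_order_table_single_row(self):
        recs = _order_records("A", [1, 2, 3]) + _order_records("B", [4, 5, 6])
        comps = cs.compare_focal_order(recs, "A")
        assert len(comps) == 1 and comps[0].other_order == "B"

    def test_small_orders_skipped_and_missing_focal_errors(self):
        recs = _order_records("A", [1, 2, 3]) + _order_records("C", [9.0])
        assert cs.compare_focal_order(recs, "A") == []
        with pytest.raises(ValueError):
            cs.compare_focal_order(recs, "Zed")

    def test_welch_option(self):
        recs = _order_records("A", [1.0, 1.1, 0.9, 1.2]) + _order_records(
            "B", [5.0, 5.1, 4.9, 5.2])
        (comp,) = cs.compare_focal_order(recs, "A", test="welch")
        assert comp.test_name == "welch"
        assert comp.test.p_value < 0.001

    def test_star_ladder(self):
        assert cs.significance_label(0.2) == "ns"
        assert cs.significance_label(0.04) == "*"
        assert cs.significance_label(0.004) == "**"
        assert cs.significance_label(0.0004) == "***"
        assert cs.significance_label(0.00004) == "****"


class TestPercentileReport:
    def test_uniform_1_to_100(self):
        recs = []
        for i in range(1, 101):
            order = "Low" if i <= 10 else "High"
            recs.append(CValueRecord(f"sp{i}", order, float(i)))
        report = cs.order_percentile_report(recs, qs=(0.05, 0.10, 0.90))
        assert report.cutoffs[0.05] == pytest.approx(5.95)
        n_below = sum(r.c_value_pg <= report.cutoffs[0.05] for r in recs)
        assert n_below == 5
        low = report.order_shares.set_index("order").loc["Low"]
        assert low["pct_of_order_le_p5"] == pytest.approx(50.0)  # 5 of 10
        assert low["pct_of_subcutoff_p5"] == pytest.approx(100.0)  # all 5 are Low
        high = report.order_shares.set_index("order").loc["High"]
        assert high["pct_of_order_le_p5"] == pytest.approx(0.0)
        assert high["pct_of_subcutoff_p5"] == pytest.approx(0.0)

    def test_single_order_owns_whole_tail(self):
        recs = [CValueRecord(f"s{i}", "Only", float(i + 1)) for i in range(12)]
        report = cs.order_percentile_report(recs, qs=(0.05, 0.5), within_order="Only")
        only = report.order_shares.set_index("order").loc["Only"]
        assert only["pct_of_subcutoff_p5"] == pytest.approx(100.0)
        assert report.within_order[0.5] == pytest.approx(6.5)

    def test_too_few_species_rejected(self):
        recs = [CValueRecord("a", "O", 1.0)] * 5
        with pytest.raises(ValueError):
            cs.order_percentile_report(recs)


class TestSpearman:
    def test_comonotone_is_exactly_one(self):
        assert cs.spearman([1, 2, 3], [10, 20, 30]).rho == 1.0
        assert cs.spearman([1, 2, 3], [3, 2, 1]).rho == -1.0

    def test_tie_case_matches_scipy(self):
        x, y = [1, 2, 2, 3], [1, 2, 3, 4]
        mine = cs.spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert mine.rho == pytest.approx(float(ref.statistic))

    def test_random_cases_match_scipy_including_p(self):
        rng = np.random.default_rng(41)
        for _ in range(30):
            n = int(rng.integers(4, 60))
            x = rng.integers(0, 15, size=n).astype(float)
            y = x * 0.5 + rng.normal(size=n)
            if np.all(x == x[0]):
                continue
            mine = cs.spearman(x, y)
            ref = sps.spearmanr(x, y)
            assert mine.rho == pytest.approx(float(ref.statistic), abs=1e-12)
            assert mine.p_value == pytest.approx(float(ref.pvalue), rel=1e-6)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(1, 100, size=50)
        y = rng.uniform(1, 100, size=50)
        base = cs.spearman(x, y).rho
        assert cs.spearman(np.log(x), y).rho == pytest.approx(base)
        assert cs.spearman(x, y**3).rho == pytest.approx(base)

    def test_errors(self):
        with pytest.raises(ValueError):
            cs.spearman([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            cs.spearman([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            cs.spearman([1, 2], [3, 4])


def _stats(n, rng, permute_te=False):
    sizes = np.sort(rng.integers(300, 3000, size=n)) * 1_000_000
    te = np.linspace(5, 60, n)
    if permute_te:
        te = rng.permutation(te)
    return [
        cs.SpeciesGenomeStats(f"sp{i}", int(sizes[i]), float(te[i]),
                              int(sizes[i] * 0.3), int(sizes[i] * 0.05))
        for i in range(n)
    ]


class TestGenomeCorrelates:
    def test_strictly_increasing_gives_rho_one(self):
        res = cs.genome_correlates(_stats(12, np.random.default_rng(51)))
        assert all(r.rho == 1.0 for r in res.values())

    def test_permuted_te_decorrelates(self):
        rhos = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            res = cs.genome_correlates(_stats(27, rng, permute_te=True))
            rhos.append(abs(res["te_pct"].rho))
        assert np.median(rhos) < 0.5

    def test_two_species_rejected(self):
        with pytest.raises(ValueError):
            cs.genome_correlates(_stats(2, np.random.default_rng(52)))


class TestBuscoPercent:
    def test_published_style_counts(self):
        counts = BuscoCounts(complete=3252, fragmented=198,
                             identified=3459, total=3652)
        assert cs.busco_percent(counts) == 94.7
        assert not counts.consistent  # printed components do not sum

    def test_extremes(self):
        assert cs.busco_percent(BuscoCounts(0, 0, 0, 100)) == 0.0
        assert cs.busco_percent(BuscoCounts(100, 0, 100, 100)) == 100.0
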