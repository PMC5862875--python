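"""Association, signature, outlier, and survival statistics vs oracles."""

from math import comb, lgamma

import numpy as np
import pandas as pd
import pytest

from conftest import make_variants
from mmcap.stats import (
    aid_signature_test,
    build_matrix,
    cox_hr,
    exclude_hypermutators,
    expression_outliers,
    find_motif_sites,
    fisher_exact_1x,
    km_curve,
    logrank_test,
    mutation_burden,
    pairwise_association,
)


# ---------------------------------------------------------------------------
# Oracles


def fisher_oracle(a, b, c, d):
    """Enumerate all 2x2 tables with the observed margins."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = comb(n, c1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {k: comb(r1, k) * comb(n - r1, c1 - k) / denom for k in range(lo, hi + 1)}
    p_co = sum(p for k, p in probs.items() if k >= a)
    p_ex = sum(p for k, p in probs.items() if k <= a)
    return p_co, p_ex


def binom_tail_oracle(k, n, p):
    """P(X >= k) by direct pmf summation via log-gamma."""
    total = 0.0
    for i in range(k, n + 1):
        logp = (
            lgamma(n + 1) - lgamma(i + 1) - lgamma(n - i + 1)
            + i * np.log(p) + (n - i) * np.log1p(-p)
        )
        total += np.exp(logp)
    return total


def motif_oracle(seq):
    """Brute-force 4-mer scan for WRCY (C site) and RGYW (G site)."""
    w, r, y = set("AT"), set("AG"), set("CT")
    sites = set()
    for i in range(len(seq) - 3):
        k = seq[i : i + 4]
        if k[0] in w and k[1] in r and k[2] == "C" and k[3] in y:
            sites.add((i + 2, "+"))
        if k[0] in r and k[1] == "G" and k[2] in y and k[3] in w:
            sites.add((i + 1, "-"))
    return sites


# ---------------------------------------------------------------------------


class TestBuildMatrix:
    def spec(self, samples=("S0", "S1")):
        return {
            "samples": list(samples),
            "snv_genes": ["KRAS", "NRAS", "IGLL5"],
            "composites": {"RAS": ["KRAS", "NRAS"]},
        }

    def test_silent_call_does_not_set_gene_feature(self):
        calls = make_variants([("S0", "KRAS", "silent", 0.4)])
        m = build_matrix(calls, None, None, self.spec())
        assert m.loc["S0", "KRAS"] == 0

    def test_composite_is_or_of_members(self):
        calls = make_variants(
            [("S0", "KRAS", "missense", 0.4), ("S1", "NRAS", "nonsense", 0.3)]
        )
        m = build_matrix(calls, None, None, self.spec())
        assert (m["RAS"] == (m[["KRAS", "NRAS"]].sum(axis=1) > 0).astype(int)).all()
        assert m["RAS"].tolist() == [1, 1]

    def test_empty_inputs_all_zero_with_declared_features(self):
        calls = make_variants([]).reindex(columns=make_variants(
            [("S0", "X", "missense", 0.1)]).columns)
        m = build_matrix(calls, None, None, self.spec())
        assert m.shape == (2, 4)
        assert (m.to_numpy() == 0).all()

    def test_translocation_and_arm_features(self):
        calls = make_variants([("S0", "KRAS", "missense", 0.4)])
        arms = pd.DataFrame(
            [("S1", "chr13", "q", "loss", 1.0)],
            columns=["sample_id", "chrom", "arm", "event", "fraction"],
        )
        tra = pd.DataFrame([("S0", "t(11;14)")], columns=["sample_id", "class"])
        spec = {**self.spec(), "cnv_arms": [("chr13", "q", "loss")],
                "translocations": ["t(11;14)"]}
        m = build_matrix(calls, arms, tra, spec)
        assert m.loc["S1", "del(13q)"] == 1 and m.loc["S0", "del(13q)"] == 0
        assert m.loc["S0", "t(11;14)"] == 1


class TestHypermutators:
    def matrix(self, n):
        return pd.DataFrame({"G": np.zeros(n, dtype=int)},
                            index=[f"S{i}" for i in range(n)])

    def test_extreme_burden_dropped(self):
        burden = pd.Series([*range(1, 11), 200], index=[f"S{i}" for i in range(11)])
        reduced, dropped = exclude_hypermutators(self.matrix(11), burden)
        assert dropped == ["S10"]
        assert len(reduced) == 10

    def test_uniform_burden_nothing_dropped(self):
        burden = pd.Series(5.0, index=[f"S{i}" for i in range(8)])
        _, dropped = exclude_hypermutators(self.matrix(8), burden)
        assert dropped == []

    def test_two_extremes_both_dropped(self):
        burden = pd.Series([*range(1, 11), 150, 200],
                           index=[f"S{i}" for i in range(12)])
        _, dropped = exclude_hypermutators(self.matrix(12), burden)
        assert set(dropped) == {"S10", "S11"}

    def test_burden_per_mb(self):
        calls = make_variants([("S0", "A", "missense", 0.3)] * 3
                              + [("S1", "B", "missense", 0.3)])
        b = mutation_burden(calls, ["S0", "S1", "S2"], panel_mb=3.3)
        assert b["S0"] == pytest.approx(3 / 3.3)
        assert b["S2"] == 0


class TestFisher:
    @pytest.mark.parametrize(
        "table",
        [(10, 0, 0, 10), (0, 10, 10, 0), (5, 5, 5, 5), (3, 7, 2, 8), (1, 0, 0, 0),
         (0, 0, 5, 5), (12, 3, 1, 9)],
    )
    def test_matches_enumeration_oracle(self, table):
        a, b, c, d = table
        odds, p_co, p_ex = fisher_exact_1x(a, b, c, d)
        if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
            assert p_co == p_ex == 1.0
            assert np.isnan(odds)
        else:
            oc, oe = fisher_oracle(a, b, c, d)
            assert p_co == pytest.approx(oc, rel=1e-12)
            assert p_ex == pytest.approx(oe, rel=1e-12)

    def test_matches_scipy_cross_check(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(7)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 15, 4)
            if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
                continue
            _, p_co, p_ex = fisher_exact_1x(int(a), int(b), int(c), int(d))
            assert p_co == pytest.approx(
                fisher_exact([[a, b], [c, d]], alternative="greater")[1], rel=1e-9
            )
            assert p_ex == pytest.approx(
                fisher_exact([[a, b], [c, d]], alternative="less")[1], rel=1e-9
            )

    def test_balanced_independent_features_near_one(self):
        _, p_co, p_ex = fisher_exact_1x(5, 5, 5, 5)
        assert p_co > 0.5 and p_ex > 0.5

    def test_pairwise_direction_and_exclusivity(self):
        rng = np.random.default_rng(0)
        n = 95
        a = np.zeros(n, dtype=int)
        b = np.zeros(n, dtype=int)
        a[:18] = 1
        b[18:18 + 40] = 1  # perfectly exclusive
        m = pd.DataFrame({"IGLL5": a, "RAS": b, "flat": rng.integers(0, 2, n)})
        out = pairwise_association(m)
        row = out[(out["feature_a"] == "IGLL5") & (out["feature_b"] == "RAS")].iloc[0]
        assert row["direction"] == "exclusive"
        assert row["p_exclusive"] < 0.05
        assert row["p_exclusive"] < row["p_cooccur"]
        assert "p_bh" in out.columns

    def test_zero_variance_feature_skipped(self):
        m = pd.DataFrame({"A": [1, 0, 1, 0], "B": [0, 0, 0, 0], "C": [1, 1, 0, 0]})
        out = pairwise_association(m)
        assert set(out["feature_a"]) | set(out["feature_b"]) == {"A", "C"}


class TestMotifScan:
    def test_agct_has_site_at_index_2(self):
        sites = find_motif_sites("AGCT")
        assert any(s.position == 2 and s.strand == "+" for s in sites)

    def test_cccc_has_no_sites(self):
        assert find_motif_sites("CCCC") == []

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), 10_000))
            mine = {(s.position, s.strand) for s in find_motif_sites(seq)}
            assert mine == motif_oracle(seq)

    def test_overlapping_motifs_all_reported(self):
        # AACTACC... craft overlapping WRCY hits: "AACCACT" etc; use a run
        seq = "TACCTACC"  # WRCY at 0-3 (TACC) and 4-7 (TACC)
        sites = [s for s in find_motif_sites(seq) if s.strand == "+"]
        assert {s.position for s in sites} == {2, 6}


class TestAidSignature:
    def test_zero_motif_hits_p_one(self):
        seq = "TACCTTTT" * 50
        variants = pd.DataFrame({"pos": [4], "ref": ["T"], "alt": ["A"]})
        res = aid_signature_test(variants, seq)
        assert res.n_at_motif == 0 and res.p_value == 1.0

    def test_tail_matches_direct_pmf_summation(self):
        seq = "TACC" + "G" * 396  # background_p from sequence composition
        res = aid_signature_test(pd.DataFrame({"pos": [], "ref": [], "alt": []}), seq)
        p = res.background_p
        from scipy.stats import binom

        for k, n in [(20, 40), (3, 40), (40, 40), (1, 10)]:
            mine = float(binom.sf(k - 1, n, p))
            assert mine == pytest.approx(binom_tail_oracle(k, n, p), rel=1e-10, abs=1e-300)

    def test_planted_aid_mutations_enrich(self):
        from mmcap.synthetic import simulate_aid_sequence

        seq, variants = simulate_aid_sequence(10_000, 0.01, 40, 1.0, seed=9)
        res = aid_signature_test(variants, seq)
        assert res.n_at_motif == res.n_mutations == 40
        assert res.p_value < 1e-10

    def test_p_decreases_with_lower_background_density(self):
        from mmcap.synthetic import simulate_aid_sequence

        # densities above the ~0.06 sites/base natural background so planting
        # actually raises the motif fraction
        pvals = []
        for density in (0.30, 0.15, 0.08):
            seq, variants = simulate_aid_sequence(20_000, density, 40, 0.5, seed=13)
            pvals.append(aid_signature_test(variants, seq).p_value)
        assert pvals[0] > pvals[-1]

    def test_no_cg_sequence_rejected(self):
        with pytest.raises(ValueError, match="no C/G"):
            aid_signature_test(pd.DataFrame({"pos": [], "ref": [], "alt": []}), "ATATAT")


class TestExpressionOutliers:
    def test_fence_arithmetic(self):
        flags = expression_outliers(pd.Series([1, 2, 3, 4, 100.0]))
        assert flags.tolist() == [False, False, False, False, True]

    def test_constant_vector_no_outliers(self):
        assert not expression_outliers(pd.Series([5.0] * 10)).any()

    def test_small_spread_no_outliers(self):
        assert not expression_outliers(pd.Series([1.0, 2, 3, 4])).any()

    def test_upper_tail_only(self):
        flags = expression_outliers(pd.Series([-100, 1, 2, 3, 4.0]))
        assert not flags.iloc[0]


def records(times, events, groups):
    return pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(len(times))],
        "time": times, "event": events, "group": groups,
    })


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        rec = records([1, 2, 3], [1, 1, 1], ["a"] * 3)
        km = km_curve(rec)
        assert km["survival"].tolist() == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_all_censored_survival_stays_one(self):
        rec = records([1, 2, 3], [0, 0, 0], ["a"] * 3)
        km = km_curve(rec)
        assert len(km) == 0  # no event times; S == 1 throughout

    def test_hand_computed_product_over_risk_sets(self):
        # times 1,2+,3,4+,5,6 (+ censored): S = (5/6)(3/4)(1/2)... verified by hand
        rec = records([1, 2, 3, 4, 5, 6], [1, 0, 1, 0, 1, 1], ["a"] * 6)
        km = km_curve(rec)
        expected = [5 / 6, 5 / 6 * 3 / 4, 5 / 6 * 3 / 4 * 1 / 2, 0.0]
        assert km["survival"].tolist() == pytest.approx(expected)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(2)
        t = rng.exponential(10, 80)
        e = rng.random(80) < 0.7
        rec = records(t, e.astype(int), ["a"] * 80)
        km = km_curve(rec)
        kmf = KaplanMeierFitter().fit(t, e)
        for row in km.itertuples():
            assert row.survival == pytest.approx(
                float(kmf.survival_function_at_times(row.time).iloc[0]), rel=1e-9
            )


class TestLogRank:
    def test_identical_groups_stat_zero(self):
        rec = records([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1], list("aaabbb"))
        stat, p = logrank_test(rec)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(4)
        t = np.concatenate([rng.exponential(10, 60), rng.exponential(6, 60)])
        e = (rng.random(120) < 0.8).astype(int)
        g = ["a"] * 60 + ["b"] * 60
        stat, p = logrank_test(records(t, e, g))
        ref = ll_logrank(t[:60], t[60:], e[:60], e[60:])
        assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_toy_instance_against_permutation_null(self):
        rng = np.random.default_rng(11)
        t = [1, 3, 5, 7, 2, 4, 6, 8]
        e = [1, 1, 0, 1, 1, 0, 1, 1]
        g = list("aaaabbbb")
        stat, p = logrank_test(records(t, e, g))
        null = []
        ga = np.array(g)
        for _ in range(5_000):
            null.append(logrank_test(records(t, e, rng.permutation(ga)))[0])
        p_perm = np.mean(np.array(null) >= stat - 1e-12)
        assert abs(p - p_perm) < 0.05

    def test_power_under_strong_hazard(self):
        from mmcap.synthetic import simulate_mutation_matrix, simulate_survival

        hits = 0
        reps = 40
        for s in range(reps):
            m = simulate_mutation_matrix({"G": 0.5}, [], 400, seed=s)
            rec = simulate_survival(m, "G", 3.0, 0.01, 0.002, seed=s)
            hits += logrank_test(rec)[1] < 0.05
        assert hits >= int(0.95 * reps)


class TestCox:
    def test_identical_event_processes_hr_near_one(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(10, 400)
        e = np.ones(400, dtype=int)
        g = ["WT"] * 200 + ["mutant"] * 200
        res = cox_hr(records(t, e, g))
        assert 0.8 < res.hazard_ratio < 1.25

    def test_recovers_planted_hazard_ratio(self):
        from mmcap.synthetic import simulate_mutation_matrix, simulate_survival

        m = simulate_mutation_matrix({"G": 0.5}, [], 5000, seed=21)
        rec = simulate_survival(m, "G", 1.46, 0.01, 0.0, seed=21)
        res = cox_hr(rec)
        assert abs(res.hazard_ratio - 1.46) < 0.1
        assert res.ci_low < res.hazard_ratio < res.ci_high

    def test_partial_likelihood_matches_grid_search_oracle(self):
        rec = records([2, 5, 7, 9], [1, 1, 1, 1], ["mutant", "WT", "mutant", "WT"])
        res = cox_hr(rec)
        x = np.array([1.0, 0.0, 1.0, 0.0])
        t = np.array([2.0, 5, 7, 9])

        def pl(beta):
            ll = 0.0
            for i in range(4):
                risk = t >= t[i]
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return ll

        grid = np.linspace(-4, 4, 80_001)
        best = grid[np.argmax([pl(b) for b in grid])]
        assert res.log_hr == pytest.approx(best, abs=2e-4)

    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(9)
        n = 300
        x = (rng.random(n) < 0.4).astype(float)
        t = rng.exponential(10 / (1.8**x))
        e = (rng.random(n) < 0.8).astype(int)
        rec = records(t, e, np.where(x == 1, "mutant", "WT"))
        res = cox_hr(rec)
        df = pd.DataFrame({"t": t, "e": e, "x": x})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert res.log_hr == pytest.approx(float(cph.params_["x"]), abs=1e-4)

    def test_no_events_in_group_non_estimable(self):
        rec = records([1, 2, 3, 4], [1, 1, 0, 0], ["WT", "WT", "mutant", "mutant"])
        res = cox_hr(rec)
        assert not res.estimable and np.isnan(res.hazard_ratio)

    def test_invariant_to_time_rescaling(self):
        rng = np.random.default_rng(14)
        t = rng.exponential(10, 200)
        e = (rng.random(200) < 0.7).astype(int)
        g = np.where(rng.random(200) < 0.5, "mutant", "WT")
        r1 = cox_hr(records(t, e, g))
        r2 = cox_hr(records(t * 365.25, e, g))
        assert r1.hazard_ratio == pytest.approx(r2.hazard_ratio, rel=1e-6)
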