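import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

import phenomix as px
from phenomix.genetics import (
    burden_test,
    classify_variant,
    classify_variants,
    constraint_bin,
    devdeg_enrichment,
    filter_de_novo,
    filter_rare_inherited,
    hypergeom_enrichment,
    odds_ratio_test,
    pgs_compare,
    pli_median_test,
    variant_counts,
)


def vrow(ind="P1", fam="F1", gene="g1", origin="denovo", csq="stop_gained",
         lof=None, mis=None, af=np.nan, pos=100):
    return {
        "individual_id": ind, "family_id": fam, "gene": gene, "origin": origin,
        "consequence": csq, "lof_confidence": lof, "missense_class": mis,
        "allele_frequency": af, "chrom": "chr1", "pos": pos, "ref": "A", "alt": "T",
    }


class TestClassification:
    @pytest.mark.parametrize(
        "csq,lof,mis,expected",
        [
            ("stop_gained", "HC", None, "LoF_HC"),
            ("frameshift_variant", "HC", None, "LoF_HC"),
            ("stop_gained", "LC", None, "other"),
            ("missense_variant", None, "likely_pathogenic", "missense_damaging"),
            ("missense_variant", None, "likely_benign", "other"),
            ("inframe_deletion", None, "likely_pathogenic", "missense_damaging"),
            ("synonymous_variant", None, None, "synonymous"),
            ("intergenic_variant", None, None, "other"),
        ],
    )
    def test_rules(self, csq, lof, mis, expected):
        assert classify_variant(csq, lof, mis) == expected

    def test_vectorized_matches_scalar(self):
        rows = [
            vrow(csq="stop_gained", lof="HC"),
            vrow(csq="missense_variant", mis="likely_benign"),
            vrow(csq="synonymous_variant"),
            vrow(csq="splice_donor_variant", lof="LC"),
        ]
        table = pd.DataFrame(rows)
        vec = classify_variants(table)
        for i, r in table.iterrows():
            assert vec[i] == classify_variant(
                r["consequence"], r["lof_confidence"], r["missense_class"]
            )


class TestDeNovoFilter:
    def test_outlier_excluded(self):
        # 30 individuals with ~2 calls, one with far more
        rows = []
        for i in range(30):
            rows += [vrow(ind=f"P{i}", fam=f"F{i}", pos=1000 + 50 * i + j) for j in range(2)]
        rows += [vrow(ind="P99", fam="F99", pos=90000 + j) for j in range(30)]
        roster = [f"P{i}" for i in range(30)] + ["P99"]
        filtered, counts, report = filter_de_novo(pd.DataFrame(rows), roster)
        assert report["n_outlier_individuals"] == 1
        assert "P99" not in counts.index
        assert not (filtered["individual_id"] == "P99").any()

    def test_nonsingleton_removed_from_all_families(self):
        rows = [
            vrow(ind="P1", fam="F1", pos=500),
            vrow(ind="P2", fam="F2", pos=500),
            vrow(ind="P3", fam="F3", pos=600),
        ]
        filtered, counts, report = filter_de_novo(pd.DataFrame(rows), ["P1", "P2", "P3"])
        assert report["n_nonsingleton_removed"] == 2
        assert set(filtered["individual_id"]) == {"P3"}
        assert counts["P1"] == 0 and counts["P2"] == 0

    def test_zero_call_backfill(self):
        rows = [vrow(ind="P1", fam="F1")]
        _, counts, _ = filter_de_novo(pd.DataFrame(rows), ["P1", "P2", "P3"])
        assert counts["P2"] == 0 and counts["P3"] == 0

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        rows = [
            vrow(ind=f"P{rng.integers(0, 20)}", fam=f"F{i % 20}", pos=int(rng.integers(1, 10**6)))
            for i in range(100)
        ]
        roster = [f"P{i}" for i in range(20)]
        t1, c1, _ = filter_de_novo(pd.DataFrame(rows), roster)
        t2, c2, _ = filter_de_novo(t1, list(c1.index))
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_series_equal(c1, c2)

    def test_count_conservation(self):
        rows = [vrow(ind=f"P{i % 5}", fam=f"F{i % 5}", pos=1000 + i) for i in range(17)]
        filtered, counts, _ = filter_de_novo(pd.DataFrame(rows), [f"P{i}" for i in range(6)])
        assert counts.sum() == len(filtered)

    def test_empty_roster_rejected(self):
        with pytest.raises(ValueError):
            filter_de_novo(pd.DataFrame([vrow()]), [])


class TestRareInheritedFilter:
    def test_threshold(self):
        rows = [
            vrow(origin="inherited", af=0.005, pos=1),
            vrow(origin="inherited", af=0.02, pos=2),
            vrow(origin="inherited", af=np.nan, pos=3),
            vrow(origin="denovo", af=np.nan, pos=4),
        ]
        out = filter_rare_inherited(pd.DataFrame(rows))
        inh = out[out["origin"] == "inherited"]
        assert set(inh["pos"]) == {1, 3}
        assert inh[inh["pos"] == 3]["rare_by_absence"].iloc[0]
        assert not inh[inh["pos"] == 1]["rare_by_absence"].iloc[0]

    def test_invalid_af_rejected(self):
        with pytest.raises(ValueError):
            filter_rare_inherited(pd.DataFrame([vrow(origin="inherited", af=1.5)]))

    def test_idempotent(self):
        rows = [vrow(origin="inherited", af=af, pos=i) for i, af in enumerate([0.001, 0.5, 0.009])]
        t1 = filter_rare_inherited(pd.DataFrame(rows))
        t2 = filter_rare_inherited(t1)
        pd.testing.assert_frame_equal(t1.reset_index(drop=True), t2.reset_index(drop=True))


class TestBurden:
    def test_identical_groups(self):
        counts = pd.Series([1, 2, 0, 1, 2, 0], index=[f"I{i}" for i in range(6)])
        groups = pd.Series(["a", "a", "a", "sibling", "sibling", "sibling"], index=counts.index)
        res = burden_test(counts, groups)
        assert res.iloc[0]["fold_enrichment"] == pytest.approx(1.0)
        assert res.iloc[0]["p"] == pytest.approx(0.5, abs=0.01)

    def test_hand_arithmetic(self):
        counts = pd.Series([3, 1, 2, 1, 0, 1], index=[f"I{i}" for i in range(6)])
        groups = pd.Series(["a"] * 3 + ["sibling"] * 3, index=counts.index)
        res = burden_test(counts, groups)
        row = res.iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["fold_enrichment"] == pytest.approx(3.0)
        # pooled-variance t statistic by hand
        x, y = np.array([3.0, 1, 2]), np.array([1.0, 0, 1])
        sp2 = ((2) * x.var(ddof=1) + (2) * y.var(ddof=1)) / 4
        t = (x.mean() - y.mean()) / np.sqrt(sp2 * (2 / 3))
        assert row["p"] == pytest.approx(float(stats.t.sf(t, 4)), abs=1e-12)
        assert row["se"] == pytest.approx(x.std(ddof=1) / np.sqrt(3))

    def test_empty_sibling_group_rejected(self):
        counts = pd.Series([1, 2], index=["a", "b"])
        groups = pd.Series(["x", "x"], index=counts.index)
        with pytest.raises(ValueError):
            burden_test(counts, groups)

    def test_type_i_error_calibration(self):
        # null Poisson counts both sides: rejection rate ~ alpha
        rng = np.random.default_rng(1)
        n = 500
        reps = 1000
        rejections = 0
        idx = [f"I{i}" for i in range(2 * n)]
        groups = pd.Series(["a"] * n + ["sibling"] * n, index=idx)
        for _ in range(reps):
            counts = pd.Series(rng.poisson(1.0, 2 * n), index=idx)
            res = burden_test(counts, groups)
            rejections += res.iloc[0]["p"] < 0.05
        assert abs(rejections / reps - 0.05) <= 0.02


class TestOddsRatio:
    def _table(self, carriers_by_ind):
        return pd.DataFrame(
            [vrow(ind=i, fam=f"F{i}", gene="g1", csq="stop_gained", lof="HC", pos=k)
             for k, i in enumerate(carriers_by_ind)]
        )

    def test_equal_rates_or_one(self):
        pro_carriers = [f"P{i}" for i in range(10)]
        sib_carriers = [f"S{i}" for i in range(10)]
        table = self._table(pro_carriers + sib_carriers)
        idx = [f"P{i}" for i in range(100)] + [f"S{i}" for i in range(100)]
        groups = pd.Series(["a"] * 100 + ["sibling"] * 100, index=idx)
        res = odds_ratio_test(table, groups, ["g1"], "LoF_HC")
        assert res.iloc[0]["odds_ratio"] == pytest.approx(1.0)

    def test_hand_or(self):
        # 20/100 vs 10/100 -> OR = (20/80)/(10/90) = 2.25
        table = self._table([f"P{i}" for i in range(20)] + [f"S{i}" for i in range(10)])
        idx = [f"P{i}" for i in range(100)] + [f"S{i}" for i in range(100)]
        groups = pd.Series(["a"] * 100 + ["sibling"] * 100, index=idx)
        res = odds_ratio_test(table, groups, ["g1"], "LoF_HC")
        assert res.iloc[0]["odds_ratio"] == pytest.approx(2.25)

    def test_zero_cell_haldane_and_fisher_oracle(self):
        # table (a=5, b=0, c=2, d=10): +0.5 correction on the OR; p by
        # exhaustive hypergeometric enumeration
        table = self._table([f"P{i}" for i in range(5)] + [f"S{i}" for i in range(2)])
        idx = [f"P{i}" for i in range(5)] + [f"S{i}" for i in range(12)]
        groups = pd.Series(["a"] * 5 + ["sibling"] * 12, index=idx)
        res = odds_ratio_test(table, groups, ["g1"], "LoF_HC")
        row = res.iloc[0]
        expected_or = ((5 + 0.5) / (0 + 0.5)) / ((2 + 0.5) / (10 + 0.5))
        assert row["odds_ratio"] == pytest.approx(expected_or)
        # enumeration: P(X >= 5) for X ~ Hypergeom(N=17, K=7 carriers, n=5 in class)
        def hyper_p(a, b, c, d):
            N, K, n = a + b + c + d, a + c, a + b
            return sum(
                comb(K, x, exact=True) * comb(N - K, n - x, exact=True)
                for x in range(a, min(K, n) + 1)
            ) / comb(N, n, exact=True)

        assert row["p"] == pytest.approx(hyper_p(5, 0, 2, 10), rel=1e-10)

    def test_empty_group_rejected(self):
        table = self._table(["P0"])
        groups = pd.Series(["sibling"], index=["S0"])
        with pytest.raises(ValueError):
            odds_ratio_test(table, groups, ["g1"], "LoF_HC")


class TestExactTestOracles:
    """Exact tests agree with direct-summation enumeration on small tables."""

    def test_fisher_upper_tail_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            a, b, c, d = (int(rng.integers(0, 12)) for _ in range(4))
            if (a + b) == 0 or (c + d) == 0:
                continue
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            N, K, n = a + b + c + d, a + c, a + b
            direct = sum(
                comb(K, x, exact=True) * comb(N - K, n - x, exact=True)
                for x in range(a, min(K, n) + 1)
            ) / comb(N, n, exact=True)
            assert p == pytest.approx(direct, rel=1e-9)

    def test_binomial_tails_enumeration(self):
        from phenomix._stats import binom_tails

        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(1, 30))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.random())
            up, lo = binom_tails(k, n, p0)
            direct_up = sum(stats.binom.pmf(x, n, p0) for x in range(k, n + 1))
            direct_lo = sum(stats.binom.pmf(x, n, p0) for x in range(0, k + 1))
            assert up == pytest.approx(direct_up, rel=1e-9, abs=1e-12)
            assert lo == pytest.approx(direct_lo, rel=1e-9, abs=1e-12)

    def test_hypergeom_tail_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            N = int(rng.integers(5, 30))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            p = stats.hypergeom.sf(k - 1, N, K, n)
            direct = sum(
                comb(K, x, exact=True) * comb(N - K, n - x, exact=True)
                for x in range(k, min(K, n) + 1)
            ) / comb(N, n, exact=True)
            assert p == pytest.approx(direct, rel=1e-9, abs=1e-12)


class TestConstraintBin:
    @pytest.mark.parametrize("pli,expected", [
        (0.997, "high"), (0.995, "high"), (0.7, "intermediate"),
        (0.5, "intermediate"), (0.3, "none"), (0.0, "none"),
    ])
    def test_bins(self, pli, expected):
        assert constraint_bin(pli) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            constraint_bin(1.5)


class TestMoodsMedian:
    def test_hand_countable_table(self):
        pli = pd.Series({"a1": 0.1, "a2": 0.3, "b1": 0.8, "b2": 0.9})
        res = pli_median_test(["a1", "a2"], ["b1", "b2"], pli, alternative="less")
        # grand median 0.55; table [[0,2],[2,0]]; one-sided Fisher:
        # P(above_a <= 0) for Hypergeom(N=4, K=2, n=2) = C(2,0)C(2,2)/C(4,2) = 1/6
        assert res["p"] == pytest.approx(1.0 / 6.0, rel=1e-10)
        assert res["median_a"] == pytest.approx(0.2)
        assert res["median_b"] == pytest.approx(0.85)

    def test_shifted_distribution_significant(self):
        rng = np.random.default_rng(5)
        pli = pd.Series(
            np.concatenate([rng.uniform(0, 0.5, 60), rng.uniform(0.5, 1.0, 60)]),
            index=[f"a{i}" for i in range(60)] + [f"b{i}" for i in range(60)],
        )
        res = pli_median_test([f"a{i}" for i in range(60)], [f"b{i}" for i in range(60)], pli)
        assert res["p"] < 0.01

    def test_type_i_error_calibration(self):
        rng = np.random.default_rng(6)
        rejections = 0
        reps = 1000
        genes_a = [f"a{i}" for i in range(40)]
        genes_b = [f"b{i}" for i in range(40)]
        for _ in range(reps):
            pli = pd.Series(rng.random(80), index=genes_a + genes_b)
            res = pli_median_test(genes_a, genes_b, pli)
            rejections += res["p"] < 0.05
        assert abs(rejections / reps - 0.05) <= 0.02 + 0.02  # exact test is conservative

    def test_degenerate_all_equal(self):
        pli = pd.Series({"a": 0.5, "b": 0.5, "c": 0.5})
        res = pli_median_test(["a"], ["b", "c"], pli)
        assert res["degenerate"] and res["p"] == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pli_median_test([], ["b"], pd.Series({"b": 0.5}))


class TestHypergeomEnrichment:
    def test_disjoint_term(self):
        out = hypergeom_enrichment(["g1"], {"t": ["g2", "g3"]}, ["g1", "g2", "g3", "g4"])
        row = out.iloc[0]
        assert row["fold_enrichment"] == 0.0 and row["p"] == pytest.approx(1.0)

    def test_perfect_overlap_example(self):
        # N=100, K_t=10, n=5, k=5 -> FE = 10; p by direct summation
        background = [f"g{i}" for i in range(100)]
        term = background[:10]
        impacted = background[:5]
        out = hypergeom_enrichment(impacted, {"t": term}, background)
        row = out.iloc[0]
        assert row["fold_enrichment"] == pytest.approx(10.0)
        direct = sum(
            comb(10, x, exact=True) * comb(90, 5 - x, exact=True) for x in range(5, 6)
        ) / comb(100, 5, exact=True)
        assert row["p"] == pytest.approx(direct, rel=1e-10)

    def test_term_equals_background(self):
        background = [f"g{i}" for i in range(20)]
        out = hypergeom_enrichment(background[:4], {"t": background}, background)
        row = out.iloc[0]
        assert row["fold_enrichment"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(1.0)

    def test_no_impacted_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment([], {"t": ["g1"]}, ["g1"])


class TestDevdegEnrichment:
    def test_disjoint_set_zero_counts(self):
        table = pd.DataFrame([vrow(ind="P1", fam="F1", gene="g1", lof="HC")])
        groups = pd.Series(["a", "sibling"], index=["P1", "S1"])
        out = devdeg_enrichment(table, groups, {("Up", "glia"): ["g99"]})
        assert (out["mean"].fillna(0) == 0).all()

    def test_pooled_probands_row_present(self):
        table = pd.DataFrame(
            [vrow(ind=f"P{i}", fam=f"F{i}", gene="g1", lof="HC", pos=i) for i in range(6)]
        )
        groups = pd.Series(["a"] * 3 + ["b"] * 3 + ["sibling"] * 4,
                           index=[f"P{i}" for i in range(6)] + [f"S{i}" for i in range(4)])
        out = devdeg_enrichment(table, groups, {("Up", "glia"): ["g1"]})
        pooled = out[out["group"] == "all_probands"]
        assert len(pooled) == 1
        # pooled mean = weighted mean over all probands
        assert pooled.iloc[0]["mean"] == pytest.approx(1.0)
        assert pooled.iloc[0]["n"] == 6


class TestPGSCompare:
    def _setup(self, shift=0.0, n=300, seed=7):
        rng = np.random.default_rng(seed)
        idx = [f"P{i}" for i in range(n)] + [f"S{i}" for i in range(n)]
        groups = pd.Series(["a"] * n + ["sibling"] * n, index=idx)
        sex = rng.integers(0, 2, 2 * n).astype(float)
        pcs = rng.standard_normal((2 * n, 3))
        score = shift * (np.arange(2 * n) < n) + 0.5 * sex + pcs @ [0.3, 0.2, 0.1] + rng.standard_normal(2 * n)
        pgs = pd.DataFrame({"trait": score}, index=idx)
        covs = pd.DataFrame(
            {"sex": sex, "PC1": pcs[:, 0], "PC2": pcs[:, 1], "PC3": pcs[:, 2]}, index=idx
        )
        return pgs, groups, covs

    def test_sibling_normalization(self):
        pgs, groups, covs = self._setup()
        # after residualization + sibling centering/scaling, sibling z-scores
        # have mean 0 and SD 1 by construction
        from phenomix.genetics import pgs_compare

        X = np.column_stack([np.ones(len(covs)), covs.to_numpy()])
        y = pgs["trait"].to_numpy()
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sib = resid[(groups == "sibling").to_numpy()]
        z = (sib - sib.mean()) / sib.std(ddof=1)
        assert abs(z.mean()) < 1e-10 and abs(z.std(ddof=1) - 1) < 1e-10

    def test_residual_orthogonality(self):
        pgs, groups, covs = self._setup()
        X = np.column_stack([np.ones(len(covs)), covs.to_numpy()])
        y = pgs["trait"].to_numpy()
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        for j in range(X.shape[1]):
            assert abs(resid @ X[:, j]) < 1e-8 * np.linalg.norm(resid) * np.linalg.norm(X[:, j])

    def test_shift_recovery(self):
        pgs, groups, covs = self._setup(shift=0.5, n=500)
        out = pgs_compare(pgs, groups, covs, ["trait"])
        row = out.iloc[0]
        assert abs(row["mean"] - 0.5) < 0.1
        assert row["q"] < 0.01

    def test_singular_design_rejected(self):
        pgs, groups, covs = self._setup()
        covs["dup"] = covs["sex"]
        with pytest.raises(ValueError):
            pgs_compare(pgs, groups, covs, ["trait"])


def test_variant_count_conservation():
    rng = np.random.default_rng(8)
    rows = [
        vrow(ind=f"P{rng.integers(0, 10)}", fam="F0", gene=f"g{rng.integers(0, 5)}",
             csq="synonymous_variant", pos=i)
        for i in range(60)
    ]
    table = pd.DataFrame(rows)
    roster = [f"P{i}" for i in range(10)]
    counts = variant_counts(table, roster, "synonymous")
    assert counts.sum() == 60
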