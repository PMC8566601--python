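"""PSI computation, event filtering, moderated testing, genotype models,
pattern assignment, APA ratios, circRNA filtering, normalization."""

import numpy as np
import pandas as pd
import pytest

import cardiosplice as cs
from cardiosplice.splicing import estimate_prior, trigamma_inverse

from oracles import bh_adjust, moderated_ttest_oracle

GENOTYPES = ("WT", "HTZ", "HMZ", "KO")

#: truth pattern -> genotype model the fit should select (patterns
#: without a dedicated model among the four are not scored here)
MODEL_FOR_PATTERN = {
    "dosage_additive": "dosage_additive",
    "hmz_specific": "hmz_specific",
    "htz_specific": "htz_specific",
    "dosage_independent_r636s": "shared_r636s",
}

#: truth pattern -> acceptable (grouping, group) assignments
PATTERN_CONSISTENT = {
    "htz_specific": {("primary", "HTZ")},
    "hmz_specific": {("primary", "HMZ")},
    "ko_specific": {("primary", "KO")},
    "dosage_independent_r636s": {("r636s_aggregate", "R636S")},
    "shared_all": {("any_mutation", "MUT")},
    # a monotone dose profile correlates almost equally with the HMZ
    # indicator and the aggregated R636S indicator
    "dosage_additive": {("r636s_aggregate", "R636S"), ("primary", "HMZ")},
}


class TestComputePsi:
    def test_psi_arithmetic(self, design):
        truths = [cs.SplicingTruth("e", "null", {g: 0.75 for g in GENOTYPES})]
        jc = cs.JunctionCounts(
            pd.DataFrame({"s1": [30]}, index=pd.Index(["e"], name="event_id")),
            pd.DataFrame({"s1": [10]}, index=pd.Index(["e"], name="event_id")),
        )
        assert cs.compute_psi(jc).loc["e", "s1"] == pytest.approx(0.75)

    def test_below_min_total_is_missing(self):
        jc = cs.JunctionCounts(
            pd.DataFrame({"s1": [3]}, index=pd.Index(["e"], name="event_id")),
            pd.DataFrame({"s1": [2]}, index=pd.Index(["e"], name="event_id")),
        )
        assert np.isnan(cs.compute_psi(jc, min_total_reads=10).loc["e", "s1"])

    def test_matches_independent_recomputation(self, standard_junctions):
        jc, _ = standard_junctions
        psi = cs.compute_psi(jc)
        incl = jc.inclusion.to_numpy(float)
        total = incl + jc.exclusion.to_numpy(float)
        want = np.where(total >= 10, incl / np.where(total > 0, total, 1), np.nan)
        np.testing.assert_allclose(
            psi.to_numpy(), want, rtol=0, atol=1e-12, equal_nan=True
        )
        assert ((psi.to_numpy() >= 0) | np.isnan(psi.to_numpy())).all()
        assert ((psi.to_numpy() <= 1) | np.isnan(psi.to_numpy())).all()


class TestFilterEvents:
    @staticmethod
    def toy_psi_and_design():
        design = pd.DataFrame(
            {
                "sample_id": [f"WT_{i}" for i in range(1, 5)]
                + [f"HMZ_{i}" for i in range(1, 5)],
                "genotype": ["WT"] * 4 + ["HMZ"] * 4,
                "batch": ["b1", "b2"] * 4,
            }
        )
        nan = np.nan
        psi = pd.DataFrame(
            {
                # detected everywhere, dPSI 0.11 -> retained
                "ev_keep": [0.80, 0.80, 0.80, 0.80, 0.69, 0.69, 0.69, 0.69],
                # missing in 2 of 4 WT (50% < 75%) -> dropped
                "ev_halfmissing": [nan, nan, 0.8, 0.8, 0.2, 0.2, 0.2, 0.2],
                # detected everywhere, dPSI 0.05 -> dropped
                "ev_smalldelta": [0.50, 0.50, 0.50, 0.50, 0.55, 0.55, 0.55, 0.55],
                # exactly at dPSI 0.1 -> dropped (rule is strict >)
                "ev_boundary": [0.60, 0.60, 0.60, 0.60, 0.70, 0.70, 0.70, 0.70],
                # 3 of 4 detected in each group (75%), dPSI 0.3 -> retained
                "ev_edge_detect": [nan, 0.8, 0.8, 0.8, nan, 0.5, 0.5, 0.5],
            },
            index=design["sample_id"],
        ).T
        psi.columns = design["sample_id"]
        return psi, design

    def test_toy_table_against_rule_by_rule_brute_force(self):
        psi, design = self.toy_psi_and_design()
        kept = cs.filter_events(psi, design, groups=("WT", "HMZ"))
        wt = design.loc[design.genotype == "WT", "sample_id"]
        hmz = design.loc[design.genotype == "HMZ", "sample_id"]
        want = []
        for ev in psi.index:
            a, b = psi.loc[ev, wt], psi.loc[ev, hmz]
            if (
                a.notna().mean() >= 0.75
                and b.notna().mean() >= 0.75
                and abs(a.mean() - b.mean()) > 0.1
            ):
                want.append(ev)
        assert kept == want == ["ev_keep", "ev_edge_detect"]

    def test_synthetic_events_match_brute_force(self, standard_junctions, design):
        jc, _ = standard_junctions
        psi = cs.compute_psi(jc)
        kept = set(cs.filter_events(psi, design, groups=("WT", "HMZ")))
        wt = design.loc[design.genotype == "WT", "sample_id"]
        hmz = design.loc[design.genotype == "HMZ", "sample_id"]
        for ev in psi.index:
            a, b = psi.loc[ev, wt], psi.loc[ev, hmz]
            ok = (
                a.notna().mean() >= 0.75
                and b.notna().mean() >= 0.75
                and abs(a.mean() - b.mean()) > 0.1
            )
            assert (ev in kept) == ok

    def test_empty_group_rejected(self):
        psi, design = self.toy_psi_and_design()
        with pytest.raises(ValueError, match="KO"):
            cs.filter_events(psi, design, groups=("WT", "KO"))


class TestModeratedTtest:
    def test_matches_formula_level_oracle_to_1e8(self, design):
        rng = np.random.default_rng(11)
        samples = design["sample_id"].tolist()
        base = rng.uniform(0.2, 0.8, size=100)
        effects = rng.normal(0, 0.15, size=100)
        is_mut = design["genotype"].isin(["HTZ", "HMZ"]).to_numpy(float)
        psi = pd.DataFrame(
            np.clip(
                base[:, None]
                + effects[:, None] * is_mut[None, :]
                + rng.normal(0, 0.05, size=(100, len(samples))),
                0,
                1,
            ),
            index=[f"ev{i}" for i in range(100)],
            columns=samples,
        )
        contrast = dict(zip(samples, is_mut))
        res = cs.moderated_ttest(psi, design, contrast)
        want, d0, s02 = moderated_ttest_oracle(psi, design, contrast)
        assert res.d0 == pytest.approx(d0, abs=1e-8 * max(1, d0))
        assert res.s0_squared == pytest.approx(s02, rel=1e-8)
        np.testing.assert_allclose(res.table["effect"], want["effect"], atol=1e-8)
        np.testing.assert_allclose(res.table["t"], want["t"], atol=1e-8)
        np.testing.assert_allclose(res.table["p_raw"], want["p_raw"], atol=1e-8)

    def test_identical_residual_variance_gives_ordinary_t(self, design):
        # equal s2 across events -> zero spread in log-variances -> the
        # prior collapses to the common value and t~ equals ordinary t
        samples = design["sample_id"].tolist()
        is_hmz = design.set_index("sample_id")["genotype"].eq("HMZ").astype(float)
        rng = np.random.default_rng(4)
        resid = rng.normal(0, 0.05, size=len(samples))
        psi = pd.DataFrame(
            [0.5 + e * is_hmz[samples].to_numpy() + resid for e in (0.0, 0.1, 0.2)],
            index=["e0", "e1", "e2"],
            columns=samples,
        )
        res = cs.moderated_ttest(psi, design, dict(zip(samples, is_hmz[samples])),
                                 batch_covariate=False)
        tab = res.table
        np.testing.assert_allclose(tab["s2_post"], tab["s2"], rtol=1e-6)
        # with s2_post == s2 the moderated t equals the ordinary OLS t
        import statsmodels.api as sm

        X = sm.add_constant(is_hmz[samples].to_numpy())
        for ev in psi.index:
            fit = sm.OLS(psi.loc[ev].to_numpy(), X).fit()
            assert tab.loc[ev, "t"] == pytest.approx(fit.tvalues[1], rel=1e-6)

    def test_null_contrast_gives_zero_effect_p_one(self, design):
        samples = design["sample_id"].tolist()
        vals = np.tile(np.linspace(0.3, 0.7, 4), 4)  # identical per-group values
        psi = pd.DataFrame([vals, vals * 0.9], index=["a", "b"], columns=samples)
        is_hmz = design.set_index("sample_id")["genotype"].eq("HMZ").astype(float)
        res = cs.moderated_ttest(psi, design, dict(zip(samples, is_hmz[samples])),
                                 batch_covariate=False)
        np.testing.assert_allclose(res.table["effect"], 0, atol=1e-12)
        np.testing.assert_allclose(res.table["p_raw"], 1, atol=1e-9)

    def test_bh_adjustment_matches_definition(self, standard_junctions, design):
        jc, _ = standard_junctions
        psi = cs.compute_psi(jc)
        samples = design["sample_id"].tolist()
        is_mut = design.set_index("sample_id")["genotype"].isin(["HTZ", "HMZ"])
        res = cs.moderated_ttest(psi, design, dict(zip(samples, is_mut[samples].astype(float))))
        p = res.table["p_raw"].to_numpy()
        np.testing.assert_allclose(res.table["p_fdr"], bh_adjust(p), atol=1e-12)
        # monotone non-decreasing in raw-p rank
        order = np.argsort(p)
        assert (np.diff(res.table["p_fdr"].to_numpy()[order]) >= -1e-12).all()

    def test_fdr_p_never_below_raw_p(self, standard_junctions, design):
        jc, _ = standard_junctions
        psi = cs.compute_psi(jc)
        samples = design["sample_id"].tolist()
        dose = design.set_index("sample_id")["genotype"].map(
            {"WT": 0.0, "HTZ": 1.0, "HMZ": 2.0}
        ).dropna()
        res = cs.moderated_ttest(psi, design, dose.to_dict())
        tab = res.table
        assert (tab["p_fdr"] >= tab["p_raw"] - 1e-12).all()
        assert res.d0 >= 0


class TestTrigammaInverse:
    @pytest.mark.parametrize("x", [0.1, 0.5, 1.0, 5.0, 50.0])
    def test_round_trip(self, x):
        from scipy.special import polygamma

        assert trigamma_inverse(float(polygamma(1, x))) == pytest.approx(x, rel=1e-9)

    def test_prior_estimation_recovers_simulated_hyperparameters(self):
        # s^2 ~ s0^2 * chi2_d/d scaled by an F-prior with d0: the moment
        # estimator should land near the generating (d0, s0^2)
        rng = np.random.default_rng(21)
        d0_true, s02_true, d = 8.0, 0.02, 12
        n = 4000
        prior_var = s02_true * d0_true / rng.chisquare(d0_true, size=n)
        s2 = prior_var * rng.chisquare(d, size=n) / d
        d0, s02 = estimate_prior(s2, np.full(n, d))
        assert d0 == pytest.approx(d0_true, rel=0.25)
        assert s02 == pytest.approx(s02_true, rel=0.1)


class TestGenotypeModels:
    def test_dosage_truth_selects_additive_model(self, design):
        truth = cs.SplicingTruth(
            "e", "dosage_additive", {"WT": 0.8, "HTZ": 0.5, "HMZ": 0.2, "KO": 0.8}
        )
        nulls = [
            cs.SplicingTruth(f"n{i}", "null", {g: 0.5 for g in GENOTYPES})
            for i in range(20)
        ]
        jc = cs.simulate_junction_counts(design, [truth] + nulls, depth=200, seed=3)
        res = cs.fit_genotype_models(cs.compute_psi(jc), design)
        assert res.loc["e", "best_model"] == "dosage_additive"
        assert res.loc["e", "significant"]

    def test_hmz_truth_selects_hmz_model(self, design):
        truth = cs.SplicingTruth(
            "e", "hmz_specific", {"WT": 0.8, "HTZ": 0.8, "HMZ": 0.2, "KO": 0.8}
        )
        nulls = [
            cs.SplicingTruth(f"n{i}", "null", {g: 0.5 for g in GENOTYPES})
            for i in range(20)
        ]
        jc = cs.simulate_junction_counts(design, [truth] + nulls, depth=200, seed=3)
        res = cs.fit_genotype_models(cs.compute_psi(jc), design)
        assert res.loc["e", "best_model"] == "hmz_specific"

    def test_constant_psi_is_never_significant(self, design):
        truths = [
            cs.SplicingTruth(f"n{i}", "null", {g: 0.5 for g in GENOTYPES})
            for i in range(30)
        ]
        jc = cs.simulate_junction_counts(design, truths, depth=200, seed=9)
        res = cs.fit_genotype_models(cs.compute_psi(jc), design)
        assert not res["significant"].any()

    def test_missing_genotype_rejected(self, design):
        truths = cs.make_splicing_truths(n_per_pattern=1, n_null=1)
        jc = cs.simulate_junction_counts(design, truths, depth=50, seed=1)
        psi = cs.compute_psi(jc)
        no_ko = design[design["genotype"] != "KO"]
        with pytest.raises(ValueError, match="KO"):
            cs.fit_genotype_models(psi[no_ko["sample_id"]], no_ko)

    def test_pattern_recovery_on_standard_design(self, design):
        # >=90% of modelled patterns recover their generating model;
        # <=10% of null events called at FDR < 0.1 (seeds 1-5)
        hits, total, null_calls, null_total = 0, 0, 0, 0
        for seed in range(1, 6):
            truths = cs.make_splicing_truths(n_per_pattern=20, n_null=40, dpsi=0.3)
            jc = cs.simulate_junction_counts(design, truths, depth=200, seed=seed)
            res = cs.fit_genotype_models(cs.compute_psi(jc), design)
            res = res.join(jc.meta)
            for pattern, model in MODEL_FOR_PATTERN.items():
                sub = res[res["pattern"] == pattern]
                hits += ((sub["best_model"] == model) & sub["significant"]).sum()
                total += len(sub)
            nulls = res[res["pattern"] == "null"]
            null_calls += nulls["significant"].sum()
            null_total += len(nulls)
        assert hits / total >= 0.90
        assert null_calls / null_total <= 0.10


class TestAssignPatterns:
    def test_exact_indicator_vector_matches_with_correlation_one(self, design):
        samples = design["sample_id"].tolist()
        ko = design.set_index("sample_id")["genotype"].eq("KO").astype(float)
        psi = pd.DataFrame([ko[samples].to_numpy()], index=["e"], columns=samples)
        out = cs.assign_patterns(psi, design)
        assert out.loc["e", "group"] == "KO"
        assert out.loc["e", "correlation"] == pytest.approx(1.0)

    def test_constant_vector_is_unassigned(self, design):
        samples = design["sample_id"].tolist()
        psi = pd.DataFrame([[0.5] * len(samples)], index=["e"], columns=samples)
        out = cs.assign_patterns(psi, design)
        assert out.loc["e", "group"] is None

    def test_recovery_of_generating_patterns(self, standard_junctions, design):
        jc, _ = standard_junctions
        psi = cs.compute_psi(jc)
        out = cs.assign_patterns(psi, design).join(jc.meta)
        patterned = out[out["pattern"] != "null"]
        ok = sum(
            (row["grouping"], row["group"]) in PATTERN_CONSISTENT[row["pattern"]]
            for _, row in patterned.iterrows()
        )
        assert ok / len(patterned) >= 0.90

    def test_grouping_must_cover_samples(self, design):
        samples = design["sample_id"].tolist()
        psi = pd.DataFrame([[0.5] * len(samples)], index=["e"], columns=samples)
        with pytest.raises(ValueError, match="cover"):
            cs.assign_patterns(psi, design, groupings={"bad": {"one": samples[:2]}})


class TestApaRatio:
    def test_two_isoform_arithmetic(self):
        tab = pd.DataFrame(
            {"gene_id": ["g", "g"], "utr_isoform_id": ["u1", "u2"],
             "s1": [30.0, 70.0]}
        )
        out = cs.apa_ratio(tab)
        assert out["s1"].tolist() == pytest.approx([0.3, 0.7])

    def test_single_isoform_ratio_is_one(self):
        tab = pd.DataFrame({"gene_id": ["g"], "utr_isoform_id": ["u"], "s1": [5.0]})
        assert cs.apa_ratio(tab)["s1"].tolist() == [1.0]

    def test_zero_total_gives_missing(self):
        tab = pd.DataFrame(
            {"gene_id": ["g", "g"], "utr_isoform_id": ["u1", "u2"], "s1": [0.0, 0.0]}
        )
        assert cs.apa_ratio(tab)["s1"].isna().all()

    def test_per_gene_ratios_sum_to_one(self):
        rng = np.random.default_rng(12)
        rows = []
        for g in range(20):
            for i in range(int(rng.integers(1, 5))):
                rows.append(
                    {"gene_id": f"g{g}", "utr_isoform_id": f"g{g}.u{i}",
                     "s1": float(rng.uniform(0, 100)), "s2": float(rng.uniform(0, 100))}
                )
        out = cs.apa_ratio(pd.DataFrame(rows))
        sums = out.groupby("gene_id")[["s1", "s2"]].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)


class TestCircRnaFilter:
    def test_threshold_on_total_reads(self):
        circs = pd.DataFrame(
            {"circ_id": ["c1", "c2", "c3"], "gene_id": ["g"] * 3,
             "s1": [1, 2, 5], "s2": [0, 0, 0]}
        )
        assert cs.filter_circrna(circs, min_reads=2)["circ_id"].tolist() == ["c2", "c3"]
        assert len(cs.filter_circrna(circs, min_reads=0)) == 3

    def test_matches_brute_force_on_random_records(self):
        rng = np.random.default_rng(8)
        circs = pd.DataFrame(
            {"circ_id": [f"c{i}" for i in range(100)],
             "gene_id": [f"g{i % 30}" for i in range(100)],
             "s1": rng.integers(0, 4, 100), "s2": rng.integers(0, 4, 100)}
        )
        kept = set(cs.filter_circrna(circs, min_reads=2)["circ_id"])
        for _, row in circs.iterrows():
            assert (row["circ_id"] in kept) == (row["s1"] + row["s2"] >= 2)


class TestUpperQuartileNormalize:
    def test_identical_columns_unchanged(self):
        col = [3.0, 0.0, 7.0, 1.0, 9.0]
        counts = pd.DataFrame({"a": col, "b": col})
        norm, factors = cs.upper_quartile_normalize(counts)
        assert factors["a"] == factors["b"]
        np.testing.assert_allclose(norm, counts)

    def test_scaled_column_is_equalized(self):
        rng = np.random.default_rng(2)
        col = rng.integers(1, 100, 50).astype(float)
        counts = pd.DataFrame({"a": col, "b": 2 * col})
        norm, _ = cs.upper_quartile_normalize(counts)
        np.testing.assert_allclose(norm["a"], norm["b"])

    def test_factors_match_percentile_oracle(self):
        rng = np.random.default_rng(31)
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(50, 6)).astype(float),
            columns=[f"s{i}" for i in range(6)],
        )
        _, factors = cs.upper_quartile_normalize(counts)
        for c in counts.columns:
            nz = sorted(v for v in counts[c] if v > 0)
            # linear-interpolation 75th percentile, computed by hand
            h = 0.75 * (len(nz) - 1)
            lo, hi = int(np.floor(h)), int(np.ceil(h))
            want = nz[lo] + (h - lo) * (nz[hi] - nz[lo])
            assert factors[c] == pytest.approx(want)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 0.0]})
        with pytest.raises(ValueError, match="b"):
            cs.upper_quartile_normalize(counts)
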