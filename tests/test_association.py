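import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from m6asig._errors import ValidationError
from m6asig.association import (
    chi_square, clinical_association, cross_cohort_intersect, exact_mc,
    filter_genes_by_frequency, fisher_exact_2x2, foldchange_low_vs_high,
    group_mean_compare, variant_frequency,
)
from m6asig.cohort_io import ClinicalTable, MutationTable
from m6asig.signatures import compute_wre
from m6asig.stratification import StrataAssignment, stratify_all
from m6asig.synthetic import SimulationParams, generate_cohort


def _mutations(n_samples, mutated, gene="CDH1", change="p.X1Y"):
    samples = [f"S{i}" for i in range(n_samples)]
    rec = pd.DataFrame(
        [(samples[i], gene, change) for i in mutated],
        columns=["sample", "gene", "protein_change"])
    return MutationTable(rec, samples=samples)


class TestFrequencyFilter:
    def test_passes_when_above_threshold_in_both(self):
        a = _mutations(78, range(2))
        b = _mutations(289, range(5))
        assert filter_genes_by_frequency(a, b, 0.01) == ["CDH1"]

    def test_excluded_when_one_cohort_low(self):
        a = _mutations(78, range(2))
        b = _mutations(289, range(1))  # 1/289 < 1%
        assert filter_genes_by_frequency(a, b, 0.01) == []

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(12)]
        def random_mut(n, seed):
            r = np.random.default_rng(seed)
            samples = [f"S{i}" for i in range(n)]
            rows = [(s, g, "p.A1B") for s in samples for g in genes
                    if r.random() < 0.05]
            return MutationTable(pd.DataFrame(
                rows, columns=["sample", "gene", "protein_change"]),
                samples=samples)
        a, b = random_mut(60, 1), random_mut(90, 2)
        got = filter_genes_by_frequency(a, b, 0.02)
        want = sorted(
            g for g in genes
            if a.binary_matrix.get(g, pd.Series(0, index=a.samples)).mean() > 0.02
            and b.binary_matrix.get(g, pd.Series(0, index=b.samples)).mean() > 0.02
            and g in a.binary_matrix.columns and g in b.binary_matrix.columns)
        assert got == want

    def test_threshold_bounds(self):
        a = _mutations(10, [0])
        with pytest.raises(ValidationError):
            filter_genes_by_frequency(a, a, 1.0)


def _binary_assignment(n_low, n_high):
    labels = pd.Series(
        ["W^L"] * n_low + ["W^H"] * n_high,
        index=[f"S{i}" for i in range(n_low + n_high)])
    return {"W": StrataAssignment("W", labels)}


class TestFoldChange:
    def test_plug_in_example(self):
        # 5/10 mutated in low vs 1/10 in high -> (5.5/11)/(1.5/11)
        mut = _mutations(20, list(range(5)) + [10])
        fc = foldchange_low_vs_high(mut, _binary_assignment(10, 10))
        assert fc.loc["CDH1", "W"] == pytest.approx(5.5 / 1.5)

    def test_identical_frequencies_give_one(self):
        mut = _mutations(20, [0, 1, 10, 11])
        fc = foldchange_low_vs_high(mut, _binary_assignment(10, 10))
        assert fc.loc["CDH1", "W"] == pytest.approx(1.0)

    def test_empty_indication_group_errors(self):
        mut = _mutations(4, [0])
        labels = pd.Series(["W^L E^L"] * 4, index=[f"S{i}" for i in range(4)])
        with pytest.raises(ValidationError, match="WE"):
            foldchange_low_vs_high(mut, {"WE": StrataAssignment("WE", labels)})

    def test_spiked_gene_up_in_most_schemes(self):
        wins = 0
        runs = 30
        for seed in range(runs):
            cohort = generate_cohort(SimulationParams(
                seed=seed, n_samples=600, n_background_genes=0,
                n_enriched_genes=0))
            asg = stratify_all(compute_wre(cohort.expression))
            fc = foldchange_low_vs_high(cohort.mutations, asg,
                                        genes=cohort.spiked_drivers)
            up = (fc.loc["CDH1"] > 1).sum()
            wins += up >= 6
        assert wins >= int(0.9 * runs)


class TestCrossCohort:
    def test_up_dn_discordant_rules(self):
        fa = pd.DataFrame({"W": [1.5, 0.5, 1.5]}, index=["A", "B", "C"])
        fb = pd.DataFrame({"W": [2.0, 0.8, 0.8]}, index=["A", "B", "C"])
        calls = cross_cohort_intersect(fa, fb)
        assert calls.loc["A", "W"] == "UP"
        assert calls.loc["B", "W"] == "DN"
        assert calls.loc["C", "W"] == "discordant"

    def test_matches_truth_table_on_random_matrices(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(20)]
        schemes = ["W", "R", "E", "WE", "RE", "WR", "WRE"]
        fa = pd.DataFrame(rng.uniform(0.3, 3, (20, 7)), index=genes,
                          columns=schemes)
        fb = pd.DataFrame(rng.uniform(0.3, 3, (20, 7)), index=genes,
                          columns=schemes)
        calls = cross_cohort_intersect(fa, fb)
        for g in genes:
            for s in schemes:
                a, b = fa.loc[g, s], fb.loc[g, s]
                want = "UP" if (a > 1 and b > 1) else \
                       "DN" if (a < 1 and b < 1) else "discordant"
                assert calls.loc[g, s] == want
            n_up = (calls.loc[g, schemes] == "UP").sum()
            n_dn = (calls.loc[g, schemes] == "DN").sum()
            want_cons = "UP" if n_up >= 4 else "DN" if n_dn >= 4 else "discordant"
            assert calls.loc[g, "consensus"] == want_cons

    def test_disjoint_gene_lists_error(self):
        fa = pd.DataFrame({"W": [1.0]}, index=["A"])
        fb = pd.DataFrame({"W": [1.0]}, index=["B"])
        with pytest.raises(ValidationError):
            cross_cohort_intersect(fa, fb)


class TestVariantFrequency:
    def test_fraction_per_group(self):
        mut = _mutations(40, [0, 1, 2], change="p.D254Y")
        asg = _binary_assignment(20, 20)["W"]
        freq = variant_frequency(mut, "CDH1", "p.D254Y", asg)
        low = freq[freq["indication"] == "low"].iloc[0]
        assert low["frequency"] == pytest.approx(3 / 20)

    def test_absent_variant_zero_everywhere(self):
        mut = _mutations(10, [0])
        asg = _binary_assignment(5, 5)["W"]
        freq = variant_frequency(mut, "CDH1", "p.Q999*", asg)
        assert (freq["frequency"] == 0).all()

    def test_random_placement_matches_recount(self):
        rng = np.random.default_rng(7)
        carriers = sorted(rng.choice(30, 8, replace=False))
        mut = _mutations(30, carriers, change="p.D254Y")
        asg = _binary_assignment(15, 15)["W"]
        freq = variant_frequency(mut, "CDH1", "p.D254Y", asg)
        n_low = sum(1 for c in carriers if c < 15)
        assert freq.set_index("indication").loc["low", "n_carrier"] == n_low


class TestFisher:
    def test_flat_table_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_transposition_and_double_swap_invariance(self):
        t = np.array([[7, 2], [5, 9]])
        p = fisher_exact_2x2(t).p_value
        assert fisher_exact_2x2(t.T).p_value == pytest.approx(p, abs=1e-12)
        assert fisher_exact_2x2(t[::-1, ::-1]).p_value == pytest.approx(
            p, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[0, 0], [3, 4]])

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            t = rng.integers(1, 12, (2, 2))
            p = fisher_exact_2x2(t).p_value
            a, b = t[0]
            c, d = t[1]
            n, r1, c1 = t.sum(), a + b, a + c
            support = np.arange(max(0, c1 - (c + d)), min(r1, c1) + 1)
            probs = hypergeom.pmf(support, n, r1, c1)
            obs = hypergeom.pmf(a, n, r1, c1)
            assert p == pytest.approx(probs[probs <= obs * (1 + 1e-7)].sum(),
                                      abs=1e-9)


class TestChiSquare:
    def test_expected_equals_observed(self):
        res = chi_square([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_2x2_closed_formula_agrees(self):
        t = np.array([[10, 20], [20, 10]])
        res = chi_square(t)
        n = t.sum()
        a, b, c, d = t.ravel()
        closed = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        assert res.statistic == pytest.approx(closed, abs=1e-10)

    def test_3x2_matches_summation_oracle(self):
        rng = np.random.default_rng(11)
        t = rng.integers(3, 30, (3, 2))
        res = chi_square(t)
        expected = np.outer(t.sum(1), t.sum(0)) / t.sum()
        stat = ((t - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(stat, abs=1e-10)

    def test_low_expected_flagged(self):
        res = chi_square([[1, 2], [2, 1]])
        assert res.low_expected


class TestExactMC:
    def test_agrees_with_fisher_on_2x2(self):
        t = [[8, 2], [3, 9]]
        exact = fisher_exact_2x2(t).p_value
        mc = exact_mc(t, n_draws=20000, seed=5)
        se = np.sqrt(exact * (1 - exact) / 20000)
        assert abs(mc.p_value - exact) < 3 * se + 2 / 20000

    def test_expectation_table_p_near_one(self):
        res = exact_mc([[10, 10], [10, 10]], n_draws=2000, seed=1)
        assert res.p_value > 0.8

    def test_seed_determinism(self):
        t = [[5, 1], [2, 8]]
        assert exact_mc(t, seed=3).p_value == exact_mc(t, seed=3).p_value


def _printed_clinical():
    """A clinical table realizing the printed TCGA WRE contingency rows."""
    rows = []
    # age <=60: 11 low / 4 high; >60: 18 / 26 (n/a excluded per variable)
    spec = [("low", 50.0, 11), ("low", 70.0, 18),
            ("high", 50.0, 4), ("high", 70.0, 26)]
    i = 0
    for group, age, count in spec:
        for _ in range(count):
            rows.append({"sample": f"P{i}", "group": group, "age": age})
            i += 1
    df = pd.DataFrame(rows).set_index("sample")
    clin = pd.DataFrame({
        "os_months": 10.0, "os_event": 0.0, "gender": "n/a",
        "age_years": df["age"], "lauren": "n/a", "t_stage": "n/a",
        "n_stage": "n/a", "m_stage": "n/a", "stage": "n/a",
        "tmb": np.nan, "msi": "n/a", "ebv": "n/a"}, index=df.index)
    labels = df["group"].map({"low": "WR^dL E^H", "high": "WR^dH E^L"})
    return ClinicalTable(clin), StrataAssignment("WRE", labels)


class TestClinicalAssociation:
    def test_age_dichotomized_at_60_reproduces_printed_p(self):
        clin, asg = _printed_clinical()
        res = clinical_association(clin, asg, variables=("age",))[0]
        assert res.test == "fisher_2x2"
        assert res.p_value == pytest.approx(0.0391, abs=5e-5)

    def test_all_missing_in_one_group_errors(self):
        clin, asg = _printed_clinical()
        with pytest.raises(ValidationError, match="missing"):
            clinical_association(clin, asg, variables=("gender",))

    def test_absent_variable_errors(self):
        clin, asg = _printed_clinical()
        with pytest.raises(ValidationError):
            clinical_association(clin, asg, variables=("karnofsky",))

    def test_lauren_direction_on_synthetic_cohort(self, default_cohort):
        # diffuse excess in the low-indication group, by construction
        asg = stratify_all(compute_wre(default_cohort.expression))["WRE"]
        low = asg.indication_samples("low")
        high = asg.indication_samples("high")
        lauren = default_cohort.clinical.data["lauren"]
        frac_low = (lauren.loc[low] == "Diffuse").mean()
        frac_high = (lauren.loc[high] == "Diffuse").mean()
        assert frac_low > frac_high

    def test_dispatch_override(self):
        clin, asg = _printed_clinical()
        res = clinical_association(clin, asg, variables=("age",),
                                   overrides={"age": "chi_square"})[0]
        assert res.test == "chi_square"


class TestGroupMeanCompare:
    def test_identical_groups(self):
        v = np.array([1.0, 2, 3, 1, 2, 3])
        t, p = group_mean_compare(v, [True, True, True, False, False, False])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_matches_hand_welch(self):
        a = np.array([3.1, 2.9, 3.5, 3.3])
        b = np.array([2.1, 2.6, 2.0])
        t, p = group_mean_compare(np.concatenate([a, b]),
                                  [True] * 4 + [False] * 3)
        va, vb = a.var(ddof=1) / 4, b.var(ddof=1) / 3
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 3 + vb**2 / 2)
        from scipy import stats
        p_hand = 2 * stats.t.sf(abs(t_hand), df)
        assert t == pytest.approx(t_hand, abs=1e-10)
        assert p == pytest.approx(p_hand, abs=1e-10)

    def test_power_on_shifted_groups(self):
        wins = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            v = np.concatenate([rng.normal(0, 1, 100), rng.normal(1, 1, 100)])
            _, p = group_mean_compare(v, [True] * 100 + [False] * 100)
            wins += p < 0.001
        assert wins >= 48

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            group_mean_compare([1.0, 2.0, 3.0], [True, False, False])

    def test_tmb_higher_under_high_m6a(self, default_cohort):
        # the simulated cohort ties TMB positively to the latent m6A level
        asg = stratify_all(compute_wre(default_cohort.expression))["E"]
        ind = asg.indication()
        tmb = default_cohort.clinical.data["tmb"].astype(float)
        t, p = group_mean_compare(tmb, (ind == "high").to_numpy())
        assert t > 0 and p < 0.05
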