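"""Extra-sum-of-squares F test and balanced two-way ANOVA with Tukey."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from casrbias.stats import ec50_f_test, two_way_anova
from casrbias.synthetic import PathwayParams, PhenotypeSpec, generate_dataset
from conftest import make_dataset

CA = PathwayParams(5.0, 100.0, np.log10(3.0), 2.0)


def _sim(name, params, noise, n, seed):
    return generate_dataset(PhenotypeSpec(name, {"Ca": params}, noise_sd=noise,
                                          n_replicates=n, seed=seed))


class TestEc50FTest:
    def test_identical_datasets_give_null_result(self):
        data = _sim("WT", CA, 5.0, 6, 42)
        res = ec50_f_test(data, data, "Ca")
        assert res.rss_null == pytest.approx(res.rss_alt, rel=1e-9)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-6)
        assert res.p_value > 0.999

    def test_shifted_ec50_detected_and_matches_reference_formula(self):
        """A 0.3 log-unit EC50 shift at SD-2 noise is overwhelmingly
        significant, and the F statistic agrees with an independently coded
        computation from the two residual sums of squares."""
        import casrbias.fitting as fitting
        wt = _sim("WT", CA, 2.0, 6, 7)
        shifted = PathwayParams(CA.bottom, CA.top, CA.logec50 + 0.3, CA.hill_slope)
        mut = _sim("mut", shifted, 2.0, 6, 8)
        res = ec50_f_test(wt, mut, "Ca")
        assert res.p_value < 1e-3
        # reference computation on the same fitted rss values
        df_num = res.df_numerator
        df_den = res.df_denominator
        f_ref = ((res.rss_null - res.rss_alt) / df_num) / (res.rss_alt / df_den)
        p_ref = sps.f.sf(f_ref, df_num, df_den)
        assert res.f_statistic == pytest.approx(f_ref, abs=1e-6)
        assert res.p_value == pytest.approx(p_ref, abs=1e-6)
        # degrees of freedom: 108 points, 8 vs 7 parameters
        assert (df_num, df_den) == (1, 100)

    def test_shift_invariance(self):
        """Adding a constant to every response leaves F and p unchanged."""
        wt = _sim("WT", CA, 4.0, 6, 21)
        mut = _sim("mut", CA, 4.0, 6, 22)
        r1 = ec50_f_test(wt, mut, "Ca")
        from casrbias.dataset import Scale
        wt2 = wt.with_responses(wt.data["response"] + 50.0, Scale.RAW)
        mut2 = mut.with_responses(mut.data["response"] + 50.0, Scale.RAW)
        r2 = ec50_f_test(wt2, mut2, "Ca")
        assert r2.f_statistic == pytest.approx(r1.f_statistic, rel=1e-4, abs=1e-6)
        assert r2.p_value == pytest.approx(r1.p_value, abs=1e-6)

    def test_small_null_calibration(self):
        """Null p-values behave like Uniform(0,1) at modest simulation size
        (the full calibration lives in the acceptance suite)."""
        ps = []
        for i in range(60):
            a = _sim("WT", CA, 5.0, 6, 9000 + 2 * i)
            b = _sim("mut", CA, 5.0, 6, 9001 + 2 * i)
            ps.append(ec50_f_test(a, b, "Ca").p_value)
        ps = np.array(ps)
        assert 0.0 <= (ps < 0.05).mean() <= 0.15
        assert sps.kstest(ps, "uniform").statistic < 0.2


def brute_force_anova(df: pd.DataFrame):
    """Two-way ANOVA sums of squares computed from their textbook
    definitions on a balanced table (independent oracle)."""
    gm = df["response"].mean()
    a_means = df.groupby("genotype")["response"].mean()
    b_means = df.groupby("conc_mM")["response"].mean()
    cell = df.groupby(["genotype", "conc_mM"])["response"].mean()
    a, b = len(a_means), len(b_means)
    n = len(df) // (a * b)
    ss_a = b * n * ((a_means - gm) ** 2).sum()
    ss_b = a * n * ((b_means - gm) ** 2).sum()
    ss_ab = n * sum(
        (cell[(g, c)] - a_means[g] - b_means[c] + gm) ** 2
        for g in a_means.index for c in b_means.index
    )
    ss_res = sum(
        (row["response"] - cell[(row["genotype"], row["conc_mM"])]) ** 2
        for _, row in df.iterrows()
    )
    df_a, df_b = a - 1, b - 1
    df_ab, df_res = df_a * df_b, a * b * (n - 1)
    ms_res = ss_res / df_res
    out = {}
    for key, ss, d in (("genotype", ss_a, df_a), ("concentration", ss_b, df_b),
                       ("interaction", ss_ab, df_ab)):
        F = (ss / d) / ms_res
        out[key] = (ss, d, F, sps.f.sf(F, d, df_res))
    out["residual"] = (ss_res, df_res, None, None)
    return out


def _balanced_table(seed, genotypes=("WT", "A", "B"), concs=(0.5, 1, 3, 10), n=4):
    rng = np.random.default_rng(seed)
    rows = []
    for gi, g in enumerate(genotypes):
        for c in concs:
            mu = 10 * gi + 5 * np.log10(c)
            for r in range(n):
                rows.append((g, "Ca", c, r + 1, mu + rng.normal(0, 2)))
    return make_dataset(rows)


class TestTwoWayAnova:
    def test_matches_brute_force_oracle(self):
        data = _balanced_table(seed=5)
        res = two_way_anova(data, "Ca")
        oracle = brute_force_anova(data.data)
        for _, row in res.table.iterrows():
            ss, d, F, p = oracle[row["factor"]]
            assert row["sum_sq"] == pytest.approx(ss, rel=1e-8)
            assert row["df"] == d
            if F is not None:
                assert row["F"] == pytest.approx(F, rel=1e-8)
                assert row["p"] == pytest.approx(p, rel=1e-6, abs=1e-12)

    def test_ss_conservation_identity(self):
        data = _balanced_table(seed=17)
        res = two_way_anova(data, "Ca")
        ss_total = ((data.data["response"] - data.data["response"].mean()) ** 2).sum()
        assert res.table["sum_sq"].sum() == pytest.approx(ss_total, rel=1e-9)

    def test_additive_zero_noise_has_no_interaction(self):
        rows = []
        for gi, g in enumerate(("WT", "mut")):
            for c in (0.5, 1, 3, 10):
                for r in (1, 2):
                    rows.append((g, "Ca", c, r, 7.0 * gi + 3.0 * np.log10(c)))
        res = two_way_anova(make_dataset(rows), "Ca")
        inter = res.table.set_index("factor").loc["interaction", "sum_sq"]
        total = res.table["sum_sq"].sum()
        assert inter <= 1e-9 * max(total, 1.0)

    def test_tukey_identical_groups(self):
        base = _balanced_table(seed=3, genotypes=("WT",))
        clone = base.data.copy()
        clone["genotype"] = "twin"
        both = make_dataset(pd.concat([base.data, clone]).itertuples(index=False))
        res = two_way_anova(both, "Ca")
        assert np.allclose(res.tukey["mean_diff"], 0.0)
        assert np.allclose(res.tukey["q"], 0.0)
        assert (res.tukey["p_adj"] > 0.99).all()

    def test_tukey_layout_per_concentration(self):
        res = two_way_anova(_balanced_table(seed=5), "Ca")
        # 4 concentrations x C(3,2) genotype pairs
        assert len(res.tukey) == 4 * 3
        assert set(res.tukey["conc_mM"]) == {0.5, 1, 3, 10}

    def test_unbalanced_rejected_with_message(self):
        data = _balanced_table(seed=5)
        df = data.data.drop(index=0)
        with pytest.raises(ValueError, match="unbalanced"):
            two_way_anova(make_dataset(df.itertuples(index=False)), "Ca")

    def test_empty_cell_rejected(self):
        data = _balanced_table(seed=5)
        df = data.data
        df = df[~((df["genotype"] == "A") & (df["conc_mM"] == 3))]
        with pytest.raises(ValueError, match="empty"):
            two_way_anova(make_dataset(df.itertuples(index=False)), "Ca")

    def test_shift_invariance(self):
        from casrbias.dataset import Scale
        data = _balanced_table(seed=29)
        shifted = data.with_responses(data.data["response"] + 123.0, Scale.RAW)
        r1 = two_way_anova(data, "Ca")
        r2 = two_way_anova(shifted, "Ca")
        assert np.allclose(r1.table["sum_sq"], r2.table["sum_sq"], rtol=1e-8, atol=1e-6)
        assert np.allclose(r1.tukey["q"], r2.tukey["q"], rtol=1e-8, atol=1e-9)
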