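"""Association engine: carrier tables, crude ORs, logistic fits, comparisons."""

import numpy as np
import pandas as pd
import pytest

from apoeqc import association as assoc
from apoeqc import adjudicate as adj, ld
from apoeqc.errors import EmptyStratumError, NoVariationError
from apoeqc.experiments import run_both_approaches
from apoeqc.simulate import CohortSpec, SimConfig, simulate_dataset


def _df(n_cn, n_ad, carriers_cn, carriers_ad, rng=None):
    """Binary-exposure case-control frame with neutral covariates."""
    g = np.r_[
        np.ones(carriers_ad), np.zeros(n_ad - carriers_ad),
        np.ones(carriers_cn), np.zeros(n_cn - carriers_cn),
    ]
    dx = np.r_[np.repeat("AD", n_ad), np.repeat("CN", n_cn)]
    return pd.DataFrame({"g": g, "dx": dx, "rs439401": g.astype(int)})


class TestCarrierTable:
    # printed-percentage convention: carriers/total to 2 decimals
    @pytest.mark.parametrize(
        "carriers, total, pct",
        [(14, 237, 5.91), (19, 1652, 1.15), (2, 203, 0.99), (0, 150, 0.0)],
    )
    def test_percentages(self, carriers, total, pct):
        df = pd.DataFrame(
            {
                "dx": ["CN"] * total + ["AD"],
                "rs439401": [1] * carriers + [0] * (total - carriers) + [0],
            }
        )
        out = assoc.carrier_table(df).set_index("dx")
        assert out.loc["CN", "carrier_pct"] == pct
        assert out.loc["CN", "carriers"] == carriers

    def test_allelic_maf(self):
        df = pd.DataFrame({"dx": ["CN"] * 4, "rs439401": [0, 1, 1, 2]})
        out = assoc.carrier_table(df).set_index("dx")
        assert out.loc["CN", "maf"] == pytest.approx(4 / 8)

    def test_empty_stratum(self):
        with pytest.raises(EmptyStratumError):
            assoc.carrier_table(pd.DataFrame({"dx": [], "rs439401": []}))


class TestCrudeOR:
    def test_cross_product_worked_example(self):
        # e4/4 carrier counts: 19 exposed / 1633 unexposed AD,
        # 14 exposed / 223 unexposed CN -> OR = 19*223 / (1633*14)
        res = assoc.crude_or(19, 1633, 14, 223)
        assert res.or_ == pytest.approx(0.185, abs=5e-4)

    def test_balanced_table_is_null(self):
        assert assoc.crude_or(5, 5, 5, 5).or_ == pytest.approx(1.0)

    def test_zero_cell_haldane_correction(self):
        res = assoc.crude_or(0, 20, 5, 15)
        assert np.isfinite(res.or_) and res.or_ > 0
        assert "haldane" in res.note

    def test_equals_covariate_free_logistic(self):
        res_crude = assoc.crude_or(30, 170, 20, 180, correction=False)
        fit = assoc.fit_stratum(_df(200, 200, 20, 30), "X", covariates=())
        assert fit.or_ == pytest.approx(res_crude.or_, abs=1e-6)
        assert fit.p == pytest.approx(res_crude.p, abs=1e-6)


class TestFitStratum:
    def test_constant_genotype_raises(self):
        df = _df(50, 50, 0, 0)
        with pytest.raises(NoVariationError):
            assoc.fit_stratum(df, "X", covariates=())

    def test_needs_both_phenotypes(self):
        df = _df(50, 50, 5, 5)
        with pytest.raises(EmptyStratumError):
            assoc.fit_stratum(df.loc[df.dx == "CN"], "X", covariates=())

    def test_recovers_planted_effect(self):
        rng = np.random.default_rng(5)
        n = 6000
        g = rng.binomial(2, 0.3, size=n).astype(float)
        logit = -0.2 + np.log(0.5) * g
        dx = np.where(rng.random(n) < 1 / (1 + np.exp(-logit)), "AD", "CN")
        df = pd.DataFrame({"g": g, "dx": dx, "rs439401": g.astype(int)})
        res = assoc.fit_stratum(df, "X", covariates=())
        assert res.ci_low < 0.5 < res.ci_high

    def test_ci_coverage_of_planted_or(self):
        # Wald 95% CI covers a planted OR=0.5 in >=93% of replicates
        rng = np.random.default_rng(11)
        n, reps, covered = 2500, 300, 0
        for _ in range(reps):
            g = rng.binomial(2, 0.3, size=n).astype(float)
            age = rng.normal(74, 8, size=n)
            sex = rng.random(n) < 0.55
            logit = -0.2 + np.log(0.5) * g
            dx = np.where(rng.random(n) < 1 / (1 + np.exp(-logit)), "AD", "CN")
            df = pd.DataFrame(
                {"g": g, "dx": dx, "age": age,
                 "sex": np.where(sex, "F", "M"), "rs439401": g.astype(int)}
            )
            res = assoc.fit_stratum(df, "X", covariates=("age", "sex"))
            covered += res.ci_low <= 0.5 <= res.ci_high
        assert covered / reps >= 0.93


class TestCompareApproaches:
    def test_error_free_input_identical_rows(self):
        cfg = SimConfig(
            seed=47,
            cohorts=(CohortSpec("X", 4000, "array", 0.0),),
            imputation_error_rate=0.0,
            wgs_error_rate=0.0,
            provided_missing_rate=0.0,
        )
        ds = simulate_dataset(cfg)
        s1, s2 = run_both_approaches(ds)
        out = assoc.compare_approaches(adj.retained(s1), adj.retained(s2))
        a1 = out.loc[out.approach == 1].drop(columns="approach").reset_index(drop=True)
        a2 = out.loc[out.approach == 2].drop(columns="approach").reset_index(drop=True)
        pd.testing.assert_frame_equal(a1, a2)

    def test_false_carrier_purge_lowers_control_frequency(self, small_dataset):
        s1, s2 = run_both_approaches(small_dataset)
        out = assoc.compare_approaches(adj.retained(s1), adj.retained(s2))
        row = out.loc[(out.stratum == ld.E44_ADDITIVE)]
        f1 = row.loc[row.approach == 1, "carrier_freq_CN"].iloc[0]
        f2 = row.loc[row.approach == 2, "carrier_freq_CN"].iloc[0]
        if np.isfinite(f1) and np.isfinite(f2):
            assert f2 <= f1

    def test_unfittable_strata_reported_not_dropped(self):
        subjects = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c", "d"],
                "apoe": ["e4/e4"] * 4,
                "rs439401": [0, 0, 0, 0],
                "dx": ["CN", "AD", "CN", "AD"],
                "age": [70.0] * 4,
                "sex": ["F", "M", "F", "M"],
                **{f"PC{k+1}": [0.0] * 4 for k in range(5)},
                "cohort": ["X"] * 4,
            }
        )
        res = assoc.analyse_strata(subjects)
        assert set(res["stratum"]) == set(ld.STRATA)
        assert res["note"].str.len().gt(0).any()
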