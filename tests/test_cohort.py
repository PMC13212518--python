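"""Trait derivation, germplasm aggregation, correlation and clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from caulipheno.cohort import (aggregate_germplasm, cluster_germplasms,
                               correlation_matrix, derive_plant_traits,
                               validate_against_manual, zscore_table)
from caulipheno.kinetics import CurdKinetics, KineticsSummary

from conftest import series_from


def _kin(t1=50.0, tmax=60.0, t2=70.0, rate=500.0):
    return KineticsSummary(t_infl1=t1, t_infl2=t2, t_max_rate=tmax, max_rate=rate)


def _curd_stats(max_rate=30.0):
    return CurdKinetics(t_peak_rate=88.0, max_rate=max_rate, harvest_day=85.0,
                        harvest_rate=25.0, rate_ratio=25.0 / max_rate,
                        trend_at_harvest="rising")


class TestDeriveTraits:
    def _traits(self, la=10000.0, ca=400.0, tca=66.0, harvest=85.0, ca0=20.0):
        leaf = series_from([1.0, 40.0, harvest], [10.0, la / 2, la], trait="LA")
        curd = series_from([tca, (tca + harvest) / 2, harvest],
                           [ca0, ca / 2, ca], trait="CA")
        return derive_plant_traits(leaf, curd, _kin(), _curd_stats(), tca)

    def test_plant_curd_coordination_ratio(self):
        rec = self._traits(la=10000.0, ca=400.0)
        assert rec["PCC"] == pytest.approx(0.04)

    def test_growth_rhythm_ratio(self):
        rec = self._traits(tca=66.0)
        assert rec["GR"] == pytest.approx(66.0 / 60.0)  # 1.10

    def test_expansion_period_and_rate(self):
        rec = self._traits(tca=70.0, harvest=85.0, ca0=20.0, ca=320.0)
        assert rec["ECEP"] == pytest.approx(15.0)
        assert rec["AER"] == pytest.approx(20.0)

    def test_area_scaling_leaves_ratios_unchanged(self):
        base = self._traits()
        c = 3.0
        leaf = series_from([1.0, 40.0, 85.0], np.array([10.0, 5000.0, 10000.0]) * c,
                           trait="LA")
        curd = series_from([66.0, 75.0, 85.0], np.array([20.0, 200.0, 400.0]) * c,
                           trait="CA")
        kin = _kin(rate=500.0 * c)
        stats = CurdKinetics(t_peak_rate=88.0, max_rate=30.0 * c, harvest_day=85.0,
                             harvest_rate=25.0 * c, rate_ratio=25.0 / 30.0,
                             trend_at_harvest="rising")
        scaled = derive_plant_traits(leaf, curd, kin, stats, 66.0)
        for trait in ("LA", "CA", "MLA_GR", "MCA_GR", "AER"):
            assert scaled[trait] == pytest.approx(c * base[trait])
        for trait in ("GR", "PCC", "ECEP", "TGP", "TCA", "D_LA_RGP"):
            assert scaled[trait] == pytest.approx(base[trait])

    def test_missing_curd_flags_incomplete(self):
        leaf = series_from([1.0, 40.0, 85.0], [10.0, 5000.0, 10000.0], trait="LA")
        rec = derive_plant_traits(leaf, None, _kin(), None, None)
        assert not rec["complete"]
        assert np.isnan(rec["CA"]) and np.isnan(rec["PCC"])


class TestAggregate:
    def test_replicate_mean(self):
        df = pd.DataFrame({
            "germplasm_id": ["g1"] * 3 + ["g2"],
            "LA": [10.0, 20.0, 30.0, 5.0],
            "complete": [True] * 4,
        })
        out = aggregate_germplasm(df).set_index("germplasm_id")
        assert out.loc["g1", "LA"] == pytest.approx(20.0)
        assert out.loc["g2", "LA"] == pytest.approx(5.0)  # single replicate
        assert out.loc["g1", "n"] == 3

    def test_default_cohort_yields_47_germplasms(self, cohort_bundle):
        from caulipheno.experiments import clustering_recovery

        table = clustering_recovery(cohort_bundle)["table"]
        assert len(table) == 47

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            aggregate_germplasm(pd.DataFrame({"LA": [1.0]}))


class TestCorrelation:
    def test_exact_proportionality(self):
        table = pd.DataFrame({"LA": [1.0, 2.0, 3.0, 4.0],
                              "CA": [2.0, 4.0, 6.0, 8.0]})
        r, p = correlation_matrix(table, traits=["LA", "CA"])
        assert r.loc["LA", "CA"] == pytest.approx(1.0)

    def test_matches_bruteforce_definition(self):
        rng = np.random.default_rng(17)
        table = pd.DataFrame(rng.uniform(0, 9, (12, 3)), columns=["LA", "CA", "TCA"])
        r, p = correlation_matrix(table, traits=["LA", "CA", "TCA"])
        x, y = table["LA"].to_numpy(), table["TCA"].to_numpy()
        expected = (np.mean((x - x.mean()) * (y - y.mean()))
                    / (x.std(ddof=0) * y.std(ddof=0)))
        assert r.loc["LA", "TCA"] == pytest.approx(expected, rel=1e-12)
        assert np.allclose(r.values, r.values.T)
        assert np.allclose(np.diag(r.values), 1.0)

    def test_builtin_correlation_recovered_at_n47(self):
        """A generated corr(LA, PCW) = 0.95 lands inside its Fisher-z CI."""
        rng = np.random.default_rng(19)
        n, rho = 47, 0.95
        cov = np.array([[1.0, rho], [rho, 1.0]])
        x = rng.multivariate_normal([0, 0], cov, size=n)
        table = pd.DataFrame(x, columns=["LA", "PCW"])
        r, _ = correlation_matrix(table, traits=["LA", "PCW"])
        z = np.arctanh(rho)
        half = 1.959964 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
        assert lo <= r.loc["LA", "PCW"] <= hi

    def test_constant_column_flagged_nan(self):
        table = pd.DataFrame({"LA": [1.0, 2.0, 3.0], "CA": [5.0, 5.0, 5.0]})
        r, p = correlation_matrix(table, traits=["LA", "CA"])
        assert np.isnan(r.loc["LA", "CA"]) and np.isnan(p.loc["LA", "CA"])

    def test_negative_expansion_tradeoff_sign_recovered(self):
        """AER ~ gain/ECEP: generated anticorrelation comes out negative."""
        rng = np.random.default_rng(23)
        ecep = rng.uniform(8, 25, 47)
        gain = rng.uniform(250, 420, 47)
        table = pd.DataFrame({"ECEP": ecep, "AER": gain / ecep})
        r, _ = correlation_matrix(table, traits=["ECEP", "AER"])
        assert r.loc["ECEP", "AER"] < 0

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            correlation_matrix(pd.DataFrame({"LA": [1.0, 2.0], "CA": [1.0, 2.0]}))


class TestClustering:
    def test_two_separated_clouds_split_perfectly(self):
        rng = np.random.default_rng(29)
        a = rng.normal(0, 0.1, (10, 3))
        b = rng.normal(50, 0.1, (10, 3))
        table = pd.DataFrame(np.vstack([a, b]), columns=["LA", "CA", "TCA"])
        table["germplasm_id"] = [f"g{i}" for i in range(20)]
        res = cluster_germplasms(table, k=2, traits=["LA", "CA", "TCA"])
        truth = [0] * 10 + [1] * 10
        assert adjusted_rand_score(truth, res.labels.to_numpy()) == 1.0

    def test_zscore_contract(self):
        rng = np.random.default_rng(31)
        table = pd.DataFrame(rng.uniform(0, 100, (15, 2)), columns=["LA", "CA"])
        z = zscore_table(table, ["LA", "CA"])
        assert np.allclose(z.mean(), 0.0, atol=1e-9)
        assert np.allclose(z.std(ddof=1), 1.0, atol=1e-9)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(37)
        table = pd.DataFrame(rng.uniform(0, 9, (12, 3)), columns=["LA", "CA", "TCA"])
        table["germplasm_id"] = [f"g{i}" for i in range(12)]
        base = cluster_germplasms(table, k=3, traits=["LA", "CA", "TCA"])
        scaled = table.copy()
        scaled["LA"] = scaled["LA"] * 123.0 - 4.0
        res = cluster_germplasms(scaled, k=3, traits=["LA", "CA", "TCA"])
        assert adjusted_rand_score(base.labels, res.labels) == 1.0

    def test_k_exceeding_rows_rejected(self):
        table = pd.DataFrame({"LA": [1.0, 2.0], "CA": [3.0, 4.0],
                              "germplasm_id": ["a", "b"]})
        with pytest.raises(ValueError):
            cluster_germplasms(table, k=3, traits=["LA", "CA"])


class TestValidateAgainstManual:
    def test_identical_lists(self):
        vals = [10.0, 20.0, 30.0, 40.0]
        out = validate_against_manual(vals, vals)
        assert out["r2"] == pytest.approx(1.0)
        assert out["rmse"] == 0.0
        assert out["slope"] == pytest.approx(1.0)
        assert out["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_small_noise_keeps_r2_high(self):
        rng = np.random.default_rng(41)
        x = rng.uniform(50, 150, 141)
        y = x + rng.normal(0, 0.05 * x.std(), 141)
        out = validate_against_manual(y, x)
        assert out["r2"] >= 0.99  # R2 ~ 1/(1 + sigma^2/var)

    def test_consistent_with_goodness_of_fit(self):
        from caulipheno.models import goodness_of_fit

        rng = np.random.default_rng(43)
        x = rng.uniform(0, 10, 20)
        y = x + rng.normal(0, 1, 20)
        out = validate_against_manual(y, x)
        g = goodness_of_fit(x, y, k=1)
        assert out["r2"] == pytest.approx(g.r2)
        assert out["rmse"] == pytest.approx(g.rmse)
        assert out["mae"] == pytest.approx(g.mae)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            validate_against_manual([1.0, 2.0], [1.0, 2.0, 3.0])
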