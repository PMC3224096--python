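import numpy as np
import pandas as pd
import pytest
from scipy import stats

import spotglow as sg
from conftest import spot_level_matrix


def gene_matrix(values_by_array, transform="log2"):
    arrays = list(values_by_array)
    n = len(next(iter(values_by_array.values())))
    idx = pd.Index([f"g{i}" for i in range(n)], name="gene_id")
    df = pd.DataFrame({a: np.asarray(v, float) for a, v in values_by_array.items()},
                      index=idx)[arrays]
    return sg.TransformedMatrix(df, transform)


class TestGlobalMedianNormalize:
    def test_equalizes_array_medians(self):
        m = gene_matrix({"a1": [8.0, 10.0, 12.0], "a2": [10.0, 12.0, 14.0]})
        out = sg.global_median_normalize(m)
        meds = out.values.median()
        assert meds["a1"] == meds["a2"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = gene_matrix({f"a{i}": rng.normal(10 + i, 2, 51) for i in range(4)})
        once = sg.global_median_normalize(m)
        twice = sg.global_median_normalize(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_within_array_differences_preserved(self):
        rng = np.random.default_rng(1)
        m = gene_matrix({"a1": rng.normal(8, 1, 30), "a2": rng.normal(11, 1, 30)})
        out = sg.global_median_normalize(m)
        for a in ("a1", "a2"):
            np.testing.assert_allclose(
                np.diff(out.values[a]), np.diff(m.values[a]), atol=1e-12
            )

    def test_all_missing_array_rejected(self):
        m = gene_matrix({"a1": [1.0, 2.0], "a2": [np.nan, np.nan]})
        with pytest.raises(sg.ValidationError):
            sg.global_median_normalize(m)


class TestAverageReplicateSpots:
    def test_triplicate_mean_and_partial_missing(self):
        vals = spot_level_matrix(
            {"a1": [1.0, 2.0, 3.0, 1.0, np.nan, 3.0, np.nan, np.nan, np.nan]},
            genes=["g1", "g2", "g3"], n_rep=3,
        )
        tm = sg.TransformedMatrix(vals, "log2")
        out = sg.average_replicate_spots(tm)
        got = out.values["a1"]
        assert got["g1"] == 2.0
        assert got["g2"] == 2.0
        assert np.isnan(got["g3"])


class TestLinearModel:
    def test_constant_groups(self):
        m = gene_matrix({f"A{i}": [1.0] for i in range(5)} | {f"B{i}": [3.0] for i in range(5)})
        design = pd.Series({c: c[0] for c in m.values.columns})
        fits = sg.fit_linear_model(m, design)
        row = fits.table.iloc[0]
        assert row["logfc"] == 2.0 and row["s2"] == 0.0

    def test_hand_computed_example(self):
        m = gene_matrix({"A1": [0.0], "A2": [2.0], "B1": [5.0], "B2": [9.0]})
        design = pd.Series({"A1": "A", "A2": "A", "B1": "B", "B2": "B"})
        row = sg.fit_linear_model(m, design).table.iloc[0]
        assert row["logfc"] == 6.0
        assert row["s2"] == pytest.approx(5.0)
        assert row["df"] == 2.0
        assert row["v"] == pytest.approx(1.0)

    def test_insufficient_replicates_give_missing(self):
        m = gene_matrix({"A1": [1.0], "A2": [2.0], "B1": [5.0], "B2": [np.nan]})
        design = pd.Series({"A1": "A", "A2": "A", "B1": "B", "B2": "B"})
        with pytest.raises(sg.ValidationError):
            sg.fit_linear_model(m, design)
        m2 = gene_matrix({"A1": [1.0, 1.0], "A2": [2.0, 1.0], "B1": [5.0, 2.0],
                          "B2": [np.nan, 2.0]})
        fits = sg.fit_linear_model(m2, design)
        assert np.isnan(fits.table.iloc[0]["logfc"])
        assert np.isfinite(fits.table.iloc[1]["logfc"])


class TestEBayes:
    @staticmethod
    def _null_fits(n_genes=5000, n=5, seed=0, sd_dist=None):
        rng = np.random.default_rng(seed)
        cols = {f"A{i}": None for i in range(n)} | {f"B{i}": None for i in range(n)}
        sds = sd_dist(rng, n_genes) if sd_dist else np.ones(n_genes)
        vals = {c: rng.normal(0, 1, n_genes) * sds for c in cols}
        m = gene_matrix(vals)
        design = pd.Series({c: c[0] for c in m.values.columns})
        return sg.fit_linear_model(m, design)

    def test_d0_zero_equals_classical_t(self):
        fits = self._null_fits(n_genes=300, seed=2)
        de = sg.ebayes_moderate(fits, prior=sg.EBayesPrior(d0=0.0, s0_sq=1.0))
        tab = fits.table
        t_classic = tab["logfc"] / np.sqrt(tab["s2"] * tab["v"])
        p_classic = 2 * stats.t.sf(np.abs(t_classic), tab["df"])
        np.testing.assert_allclose(de.table["t_stat"], t_classic, rtol=1e-12)
        np.testing.assert_allclose(de.table["p"], p_classic, rtol=1e-12)

    def test_large_d0_pins_variances(self):
        fits = self._null_fits(n_genes=200, seed=3)
        s_star = 0.7
        de = sg.ebayes_moderate(fits, prior=sg.EBayesPrior(d0=1e12, s0_sq=s_star))
        t_expected = fits.table["logfc"] / np.sqrt(s_star * fits.table["v"])
        np.testing.assert_allclose(de.table["t_stat"], t_expected, rtol=1e-6)

    def test_null_pvalues_uniform_and_d0_recovered(self):
        d0_true = 4.0
        s0_true = 1.0

        def sd_dist(rng, n):
            # per-gene variance from the scaled inverse-chi-square prior
            return np.sqrt(d0_true * s0_true / rng.chisquare(d0_true, n))

        fits = self._null_fits(n_genes=5000, n=5, seed=4, sd_dist=sd_dist)
        prior = sg.estimate_prior(
            fits.table["s2"].to_numpy(), fits.table["df"].to_numpy()
        )
        assert d0_true / 2 < prior.d0 < d0_true * 2
        de = sg.ebayes_moderate(fits, prior=prior)
        ks = stats.kstest(de.table["p"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_all_zero_variance_rejected(self):
        m = gene_matrix({c: np.ones(20) for c in ["A1", "A2", "B1", "B2"]})
        design = pd.Series({c: c[0] for c in m.values.columns})
        fits = sg.fit_linear_model(m, design)
        with pytest.raises(sg.FittingError):
            sg.estimate_prior(fits.table["s2"].to_numpy(), fits.table["df"].to_numpy())


class TestPipeline:
    def test_noise_free_all_null_gives_exact_zero_logfc(self):
        cfg = sg.SimulationConfig(n_genes=60, grid_shape=(15, 12), eta_sd=0.0,
                                  eps_sd=0.0, prop_de=0.0, seed=6)
        ds, truth = sg.simulate_dataset(cfg)
        de = sg.run_pipeline(ds, "standard", "log2")
        got = de.indexed().loc[truth.table["gene_id"], "logfc"].to_numpy()
        np.testing.assert_allclose(got, 0.0, atol=1e-9)

    def test_noise_free_recovers_true_logfc_up_to_median_shift(self, noise_free_dataset):
        """With no measurement noise the pipeline reproduces every true
        fold-change exactly, modulo the single constant that global-median
        normalization moves between conditions when the DE genes shift the
        array medians."""
        ds, truth = noise_free_dataset
        de = sg.run_pipeline(ds, "standard", "log2")
        got = de.indexed().loc[truth.table["gene_id"], "logfc"].to_numpy()
        resid = got - truth.table["true_logfc"].to_numpy()
        assert np.ptp(resid) < 1e-9  # one common constant, all genes

    def test_none_correction_invariant_to_background(self, small_dataset):
        ds, _ = small_dataset
        de1 = sg.run_pipeline(ds, "none", "log2")
        spots2 = ds.spots.copy()
        spots2["B"] = 3.21
        ds2 = sg.SpotDataset(spots2, ds.n_spot_replicates)
        de2 = sg.run_pipeline(ds2, "none", "log2")
        np.testing.assert_allclose(de1.table["logfc"], de2.table["logfc"], rtol=1e-12)
        np.testing.assert_allclose(de1.table["p"], de2.table["p"], rtol=1e-12)

    @pytest.mark.parametrize("correction", ["standard", "none", "edwards", "normexp"])
    @pytest.mark.parametrize("transform", ["log2", "glog"])
    def test_all_eight_combinations_complete(self, small_dataset, correction, transform):
        ds, truth = small_dataset
        de = sg.run_pipeline(ds.subset_site("site1"), correction, transform)
        assert len(de.table) == len(truth.table)
        assert de.provenance["correction"] == correction
        if transform == "glog":
            assert de.table["logfc"].notna().all()

    def test_no_missing_under_edwards_log2(self, small_dataset):
        ds, _ = small_dataset
        de = sg.run_pipeline(ds, "edwards", "log2")
        assert de.table["logfc"].notna().all() and de.table["p"].notna().all()

    def test_array_shift_equivariance(self, small_dataset):
        """Adding a constant to one array's transformed values changes no
        logfc after global-median normalization."""
        ds, _ = small_dataset
        corrected = sg.correct_standard(ds)
        tm = sg.glog_transform(corrected, sg.GlogParams(0.0, 2.5e4))
        shifted_vals = tm.values.copy()
        shifted_vals[ds.array_ids[0]] += 2.7
        design = ds.array_conditions()

        def logfc_from(vals):
            m = sg.TransformedMatrix(vals, "glog", sg.GlogParams(0.0, 2.5e4))
            gene = sg.average_replicate_spots(sg.global_median_normalize(m))
            return sg.fit_linear_model(gene, design).table["logfc"]

        np.testing.assert_allclose(
            logfc_from(tm.values), logfc_from(shifted_vals), atol=1e-10
        )


class TestHybrid:
    def test_identity_when_inputs_equal(self, small_dataset):
        ds, _ = small_dataset
        de = sg.run_pipeline(ds.subset_site("site1"), "edwards", "glog")
        out = sg.hybrid_combine(de, de)
        np.testing.assert_allclose(out.table["logfc"], de.table["logfc"])
        np.testing.assert_allclose(out.table["p"], de.table["p"])

    def test_takes_logfc_from_log2_and_p_from_glog(self):
        def mk(logfc, p, correction):
            return sg.DEResult(
                pd.DataFrame({"gene_id": ["g1"], "logfc": [logfc], "t_stat": [1.0],
                              "p": [p], "ref_intensity": [5.0]}),
                provenance={"correction": correction},
            )

        out = sg.hybrid_combine(mk(2.5, 0.3, "edwards"), mk(0.9, 1e-9, "edwards"))
        assert out.table.loc[0, "logfc"] == 2.5
        assert out.table.loc[0, "p"] == 1e-9

    def test_gene_set_and_provenance_mismatch_rejected(self):
        def mk(gene, correction):
            return sg.DEResult(
                pd.DataFrame({"gene_id": [gene], "logfc": [1.0], "t_stat": [1.0],
                              "p": [0.5], "ref_intensity": [5.0]}),
                provenance={"correction": correction},
            )

        with pytest.raises(sg.ValidationError):
            sg.hybrid_combine(mk("g1", "edwards"), mk("g2", "edwards"))
        with pytest.raises(sg.ValidationError):
            sg.hybrid_combine(mk("g1", "edwards"), mk("g1", "standard"))
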