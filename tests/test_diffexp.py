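import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ecnorm import (CountMatrix, SampleMetadata, SimulationConfig,
                    ValidationError, bh_adjust, estimate_dispersions,
                    estimate_size_factors, nb_wald_test, simulate_dataset)
from ecnorm.diffexp import DispersionEstimates
from ecnorm.normalization import SizeFactors


def _unit_sf(cm):
    return SizeFactors(cm.sample_ids, np.ones(cm.n_samples))


def _meta_for(cm, n_a):
    n = cm.n_samples
    return SampleMetadata(sample_ids=cm.sample_ids,
                          group=tuple(["A"] * n_a + ["B"] * (n - n_a)),
                          reference="A")


class TestEstimateDispersions:
    def test_constant_gene_has_zero_raw_dispersion(self):
        counts = np.full((2, 8), 50, dtype=np.int64)
        cm = CountMatrix(("g0", "g1"), tuple(f"s{j}" for j in range(8)), counts)
        disp = estimate_dispersions(cm, _unit_sf(cm), _meta_for(cm, 4),
                                    shrink=False)
        assert disp.alpha_raw[0] == 0.0
        assert np.array_equal(disp.alpha, disp.alpha_raw)

    def test_poisson_genes_estimate_near_zero(self):
        cfg = SimulationConfig(n_genes=500, n_per_group=(100, 100), n_stable=0,
                               frac_de=0.0, dispersion=0.0,
                               mean_range=(100.0, 100.0),
                               size_factor_range=(1.0, 1.0), seed=11)
        cm, meta, _truth = simulate_dataset(cfg)
        disp = estimate_dispersions(cm, _unit_sf(cm), meta, shrink=False)
        assert abs(disp.alpha_raw.mean()) < 0.05

    def test_nb_dispersion_recovered(self):
        cfg = SimulationConfig(n_genes=500, n_per_group=(50, 50), n_stable=0,
                               frac_de=0.0, dispersion=0.2,
                               mean_range=(500.0, 500.0),
                               size_factor_range=(1.0, 1.0), seed=12)
        cm, meta, _truth = simulate_dataset(cfg)
        disp = estimate_dispersions(cm, _unit_sf(cm), meta, shrink=False)
        assert 0.15 <= np.median(disp.alpha_raw) <= 0.25

    def test_shrinkage_pulls_raw_toward_trend(self, default_de):
        cm, meta, truth, sf, disp, _res = default_de
        stable = truth.genes["is_stable"].to_numpy()
        # planted low-dispersion genes end up between raw and background
        assert np.median(disp.alpha_raw[stable]) < np.median(disp.alpha[stable])
        assert np.median(disp.alpha[stable]) < np.median(disp.alpha[~stable])

    def test_group_smaller_than_two_rejected_at_design_validation(self):
        # a one-sample group (variance undefined) is caught when the design
        # is constructed, before dispersion estimation can be attempted
        with pytest.raises(ValidationError, match="at least 2"):
            SampleMetadata(("a", "b", "c"), ("A", "A", "B"), reference="A")


class TestNbWaldTest:
    def test_all_zero_gene_reported_na(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(10, 200, size=(4, 8)).astype(np.int64)
        counts[2] = 0
        cm = CountMatrix(tuple(f"g{i}" for i in range(4)),
                         tuple(f"s{j}" for j in range(8)), counts)
        meta = _meta_for(cm, 4)
        sf = _unit_sf(cm)
        disp = estimate_dispersions(cm, sf, meta, shrink=False)
        res = nb_wald_test(cm, sf, disp, meta)
        row = res.set_index("gene_id").loc["g2"]
        assert np.isnan(row["log2fc"]) and np.isnan(row["pvalue"])
        assert not row["converged"]
        assert res.set_index("gene_id")["converged"].drop("g2").all()

    def test_group_label_swap_negates_log2fc(self, default_de):
        cm, meta, _truth, sf, disp, res = default_de
        swapped = meta.with_reference(meta.levels[1])
        res2 = nb_wald_test(cm, sf, disp, swapped)
        ok = res["converged"] & res2["converged"]
        assert np.allclose(res.loc[ok, "log2fc"], -res2.loc[ok, "log2fc"],
                           atol=1e-12)
        assert np.allclose(res.loc[ok, "pvalue"], res2.loc[ok, "pvalue"],
                           atol=1e-12)

    def test_reduces_to_poisson_glm_when_alpha_zero(self):
        import statsmodels.api as sm

        cfg = SimulationConfig(n_genes=20, n_per_group=(10, 10), n_stable=0,
                               frac_de=0.5, lfc=1.0, dispersion=0.0,
                               mean_range=(50.0, 500.0), seed=21)
        cm, meta, _truth = simulate_dataset(cfg)
        sf = estimate_size_factors(cm)
        disp = DispersionEstimates(cm.gene_ids, np.zeros(cm.n_genes),
                                   np.zeros(cm.n_genes),
                                   np.full(cm.n_genes, np.nan))
        res = nb_wald_test(cm, sf, disp, meta)
        x = sm.add_constant(meta.indicator)
        for i in range(cm.n_genes):
            fit = sm.GLM(cm.counts[i], x, family=sm.families.Poisson(),
                         offset=np.log(sf.factors)).fit()
            assert res.loc[i, "log2fc"] * np.log(2) == pytest.approx(
                fit.params[1], abs=1e-8)

    def test_power_increases_with_sample_size(self):
        def power(n):
            cfg = SimulationConfig(n_genes=1000, n_per_group=(n, n),
                                   n_stable=0, frac_de=0.2, lfc=1.0,
                                   lfc_signs="both", dispersion=0.1,
                                   mean_range=(200.0, 200.0), seed=31)
            cm, meta, truth = simulate_dataset(cfg)
            sf = estimate_size_factors(cm)
            disp = estimate_dispersions(cm, sf, meta)
            res = nb_wald_test(cm, sf, disp, meta)
            de = truth.genes["is_de"].to_numpy()
            return (res.loc[de, "pvalue"] <= 0.05).mean()

        assert power(50) > power(10)

    def test_recovers_planted_log2fc(self):
        from ecnorm.benchmarks import log2fc_recovery

        assert log2fc_recovery(104, n_genes=100) == pytest.approx(1.0, abs=0.05)


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.05])[0] == pytest.approx(0.05)

    def test_na_propagates_and_m_counts_only_non_na(self):
        out = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        # m = 2: q = (0.02, 0.02)
        assert np.allclose(out[[0, 2]], [0.02, 0.02])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    def test_matches_independent_step_up_implementation(self):
        def step_up(p):
            p = np.asarray(p, float)
            m = len(p)
            order = np.argsort(p, kind="mergesort")
            q = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * m / rank)
                q[i] = prev
            return q

        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 50))
            assert np.allclose(bh_adjust(p), step_up(p), atol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_output_bounded_between_input_and_one(self, pvals):
        out = bh_adjust(pvals)
        assert np.all(out >= np.asarray(pvals) - 1e-15)
        assert np.all(out <= 1.0 + 1e-15)

    def test_fdr_order_matches_pvalue_order(self, default_de):
        *_rest, res = default_de
        sub = res.dropna(subset=["pvalue"]).sort_values("pvalue")
        assert sub["fdr"].is_monotonic_increasing
        assert (sub["fdr"] >= sub["pvalue"] - 1e-15).all()
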