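"""Generator determinism, planted-effect calibration, analytic oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lincscope.deg import count_deg
from lincscope.simulate import (
    CellSpec,
    SimConfig,
    deg_count_pmf,
    deg_tail_probability,
    default_config,
    expected_category_fractions,
    hit_deg_probability,
    mu_for_tail_probability,
    null_deg_probability,
    simulate_metadata,
    simulate_signatures,
)

P0 = 2 * stats.norm.cdf(-2)  # per-gene null significance probability


def _null_config(n, seed=0):
    spec = CellSpec(
        cell_id="NULL",
        n_signatures=n,
        category_mix={"compound": 1.0},
        hit_count_distribution={0: 1.0},
    )
    return SimConfig(cell_specs=[spec], seed=seed)


class TestSimulateMetadata:
    def test_shape_and_unique_ids(self):
        config = SimConfig(
            cell_specs=[CellSpec("A", 100), CellSpec("B", 100)], seed=1
        )
        meta = simulate_metadata(config)
        assert len(meta) == 200
        assert meta["sig_id"].is_unique
        assert set(meta["cell_id"]) == {"A", "B"}

    def test_determinism(self):
        config = default_config(seed=5, signatures_per_cell=40)
        meta1 = simulate_metadata(config)
        meta2 = simulate_metadata(default_config(seed=5, signatures_per_cell=40))
        pd.testing.assert_frame_equal(meta1, meta2)

    def test_category_mix_within_binomial_error(self):
        p = 0.8
        spec = CellSpec(
            "A", 10_000, category_mix={"compound": p, "control": 1 - p}
        )
        meta = simulate_metadata(SimConfig(cell_specs=[spec], seed=2))
        frac = (meta["pert_category"] == "compound").mean()
        se = math.sqrt(p * (1 - p) / 10_000)
        assert abs(frac - p) < 3 * se

    def test_compounds_have_dose_and_configured_levels(self):
        config = default_config(seed=3, signatures_per_cell=200)
        meta = simulate_metadata(config)
        compounds = meta[meta["pert_category"] == "compound"]
        assert compounds["dose_um"].notna().all()
        assert set(compounds["dose_um"]) <= {0.1, 1.0, 5.0, 10.0}
        assert set(meta["time_h"]) <= {6.0, 24.0, 48.0}
        others = meta[meta["pert_category"] != "compound"]
        assert others["dose_um"].isna().all()

    def test_invalid_config_rejected_before_generation(self):
        spec = CellSpec("A", 10, category_mix={"compound": 0.5})  # sums to 0.5
        with pytest.raises(ValueError, match="probability"):
            simulate_metadata(SimConfig(cell_specs=[spec], seed=0))


class TestSimulateSignatures:
    def test_determinism(self):
        config = _null_config(30, seed=9)
        meta = simulate_metadata(config)
        m1, _ = simulate_signatures(config, meta)
        m2, _ = simulate_signatures(_null_config(30, seed=9), meta)
        np.testing.assert_array_equal(m1.z, m2.z)

    def test_meta_config_mismatch(self):
        config = _null_config(10)
        meta = simulate_metadata(config)
        meta.loc[0, "cell_id"] = "ROGUE"
        with pytest.raises(ValueError, match="ROGUE"):
            simulate_signatures(config, meta)

    def test_null_mean_deg_count(self):
        """Pure-noise signatures average 978 * 2*Phi(-2) ~ 44.5 DEGs."""
        config = _null_config(2000, seed=11)
        meta = simulate_metadata(config)
        matrix, truth = simulate_signatures(config, meta)
        counts = count_deg(matrix)
        expected = 978 * P0
        se = math.sqrt(978 * P0 * (1 - P0) / 2000)
        assert abs(counts["n_total"].mean() - expected) < 3 * se
        assert truth.table["expected_deg"].iloc[0] == pytest.approx(expected)

    def test_planted_hits_raise_deg_count(self):
        """100 hits at mu=6: expected DEGs ~ 100*P(|N(6,1)|>2) + 878*p0 ~ 139.9."""
        spec = CellSpec(
            "A",
            800,
            category_mix={"compound": 1.0},
            hit_count_distribution={100: 1.0},
            base_effect=6.0,
        )
        config = SimConfig(cell_specs=[spec], seed=13)
        meta = simulate_metadata(config)
        matrix, truth = simulate_signatures(config, meta)
        counts = count_deg(matrix)
        q = hit_deg_probability(6.0)
        expected = 100 * q + 878 * P0
        assert expected == pytest.approx(139.9, abs=0.1)
        var = (100 * q * (1 - q) + 878 * P0 * (1 - P0)) / 800
        assert abs(counts["n_total"].mean() - expected) < 3 * math.sqrt(var)
        assert truth.table["expected_deg"].iloc[0] == pytest.approx(expected)

    def test_hit_genes_recorded_and_within_range(self):
        spec = CellSpec(
            "A",
            20,
            category_mix={"compound": 1.0},
            hit_count_distribution={10: 1.0},
            base_effect=4.0,
        )
        config = SimConfig(cell_specs=[spec], seed=1)
        meta = simulate_metadata(config)
        matrix, truth = simulate_signatures(config, meta)
        assert set(truth.hit_genes) == set(meta["sig_id"])
        for sig, idx in truth.hit_genes.items():
            assert len(idx) == 10
            assert 0 <= idx.min() and idx.max() < matrix.n_genes


class TestAnalyticOracles:
    def test_null_probability_closed_form(self):
        assert null_deg_probability() == pytest.approx(2 * stats.norm.cdf(-2), rel=1e-12)

    def test_hit_probability_sign_symmetric_and_monotone(self):
        mus = np.linspace(0, 6, 13)
        qs = [hit_deg_probability(m) for m in mus]
        assert qs[0] == pytest.approx(null_deg_probability())
        assert all(a < b for a, b in zip(qs, qs[1:]))

    def test_pmf_sums_to_one_and_matches_binomial_at_null(self):
        pmf = deg_count_pmf(978, 0, 0.0)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(
            pmf, stats.binom.pmf(np.arange(979), 978, P0), atol=1e-12
        )

    def test_tail_at_one_is_nearly_certain_under_null(self):
        p_ge1 = deg_tail_probability(978, 0, 0.0, 1)
        assert p_ge1 == pytest.approx(1 - (1 - P0) ** 978, abs=1e-15)
        assert p_ge1 > 1 - 1e-15

    def test_tail_matches_brute_force_convolution(self):
        """Mixture tail for 100 hits at mu=6 against an independent
        enumeration over the two binomial components."""
        n_genes, n_hits, mu, k = 978, 100, 6.0, 100
        q = hit_deg_probability(mu)
        total = 0.0
        for h in range(n_hits + 1):  # brute-force double sum
            ph = stats.binom.pmf(h, n_hits, q)
            total += ph * stats.binom.sf(k - h - 1, n_genes - n_hits, P0)
        assert deg_tail_probability(n_genes, n_hits, mu, k) == pytest.approx(
            total, abs=1e-12
        )

    def test_mu_inversion_round_trip(self):
        mu = mu_for_tail_probability(0.6, 978, 150, 50)
        assert deg_tail_probability(978, 150, mu, 50) == pytest.approx(0.6, abs=1e-9)


class TestExpectedCategoryFractions:
    def test_null_config_fractions(self):
        table = expected_category_fractions(_null_config(10), thresholds=(1, 50))
        overall = table[table["stratum_type"] == "overall"].iloc[0]
        assert overall["p_ge_1"] == pytest.approx(1.0, abs=1e-12)
        exact_ge50 = stats.binom.sf(49, 978, P0)
        assert overall["p_ge_50"] == pytest.approx(exact_ge50, rel=1e-9)

    def test_pipeline_converges_to_oracle(self):
        """Empirical stratified fractions approach the exact tails."""
        spec = CellSpec(
            "A",
            6000,
            category_mix={"compound": 1.0},
            dose_levels=(1.0, 10.0),
            time_levels=(6.0, 24.0),
            hit_count_distribution={100: 1.0},
            base_effect=2.0,
            dose_response="increasing",
        )
        config = SimConfig(cell_specs=[spec], seed=21)
        meta = simulate_metadata(config)
        matrix, _ = simulate_signatures(config, meta)
        counts = count_deg(matrix)
        joined = counts.merge(meta, on="sig_id")
        oracle = expected_category_fractions(config, thresholds=(50,))
        for group, low_dose in (("low", True), ("high", False)):
            sel = joined["dose_um"] <= 5 if low_dose else joined["dose_um"] > 5
            empirical = (joined.loc[sel, "n_total"] >= 50).mean()
            expected = oracle.loc[
                (oracle["stratum_type"] == "dose_group") & (oracle["stratum"] == group),
                "p_ge_50",
            ].iloc[0]
            n = int(sel.sum())
            se = math.sqrt(max(expected * (1 - expected), 1e-9) / n)
            assert abs(empirical - expected) < 4 * se
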