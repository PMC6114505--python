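"""DEG counting, cumulative categorization and stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from lincscope.deg import (
    assign_dose_group,
    behavior_direction,
    categorize_counts,
    count_deg,
    filter_analysis_set,
    stratified_category_counts,
)
from lincscope.io import SignatureMatrix


def brute_force_deg(z, z_hi=2.0, z_lo=-2.0):
    """Independent element-by-element oracle for DEG counting."""
    n_up = [0] * z.shape[1]
    n_down = [0] * z.shape[1]
    for i in range(z.shape[0]):
        for j in range(z.shape[1]):
            v = z[i, j]
            if v != v:  # NaN
                continue
            if v > z_hi:
                n_up[j] += 1
            elif v < z_lo:
                n_down[j] += 1
    return n_up, n_down


def _matrix(z):
    z = np.asarray(z, dtype=float)
    return SignatureMatrix(
        gene_ids=[f"g{i}" for i in range(z.shape[0])],
        sig_ids=[f"s{j}" for j in range(z.shape[1])],
        z=z,
    )


class TestCountDeg:
    def test_strict_boundaries(self):
        m = _matrix(np.array([[2.5], [-3.0], [1.9], [-2.0]]))
        rec = count_deg(m).iloc[0]
        assert (rec["n_up"], rec["n_down"], rec["n_total"]) == (1, 1, 2)

    def test_exact_threshold_values_not_significant(self):
        m = _matrix(np.array([[2.0], [-2.0], [2.0000001], [-2.0000001]]))
        rec = count_deg(m).iloc[0]
        assert rec["n_total"] == 2

    def test_all_zero_column(self):
        m = _matrix(np.zeros((5, 1)))
        rec = count_deg(m).iloc[0]
        assert (rec["n_up"], rec["n_down"], rec["n_total"]) == (0, 0, 0)

    def test_nan_excluded_from_both_counts(self):
        m = _matrix(np.array([[np.nan], [3.0], [np.nan], [-3.0]]))
        rec = count_deg(m).iloc[0]
        assert (rec["n_up"], rec["n_down"]) == (1, 1)

    def test_invalid_thresholds(self, small_matrix):
        with pytest.raises(ValueError):
            count_deg(small_matrix, z_hi=-2.0, z_lo=2.0)

    def test_matches_brute_force_with_planted_boundaries(self):
        """Vectorized counts agree exactly with an element loop, including
        values planted exactly at +/-2.0."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            z = rng.normal(scale=2.0, size=(20, 20))
            flat = rng.choice(z.size, size=10, replace=False)
            z.ravel()[flat[:5]] = 2.0
            z.ravel()[flat[5:]] = -2.0
            table = count_deg(_matrix(z))
            up, down = brute_force_deg(z)
            assert list(table["n_up"]) == up
            assert list(table["n_down"]) == down

    @given(
        arrays(
            float,
            (6, 5),
            elements=st.one_of(
                st.just(float("nan")), st.floats(-5, 5, allow_nan=False, width=32)
            ),
        )
    )
    @settings(derandomize=True, max_examples=50)
    def test_total_is_up_plus_down(self, z):
        table = count_deg(_matrix(z))
        assert (table["n_total"] == table["n_up"] + table["n_down"]).all()
        assert (table["n_total"] <= 6).all()


class TestFilterAnalysisSet:
    def test_time_filter(self, toy_meta):
        subset = filter_analysis_set(toy_meta, ["A", "B"], times={6, 24, 48})
        assert set(subset["time_h"]) <= {6.0, 24.0, 48.0}
        assert set(subset["pert_category"]) == {"compound"}
        assert len(subset) == 4

    def test_all_categories_passthrough(self, toy_meta):
        from lincscope.io import CATEGORIES

        subset = filter_analysis_set(
            toy_meta, ["A", "B"], categories=set(CATEGORIES), times={6, 24}
        )
        # only the 96 h shRNA row is removed
        assert len(subset) == 5

    def test_empty_result_is_legal(self, toy_meta):
        subset = filter_analysis_set(toy_meta, ["NOPE"])
        assert subset.empty


def _deg_frame(totals, sig_ids=None, pert_ids=None):
    n = len(totals)
    sig_ids = sig_ids or [f"s{i}" for i in range(n)]
    frame = pd.DataFrame(
        {
            "sig_id": sig_ids,
            "n_up": totals,
            "n_down": [0] * n,
            "n_total": totals,
        }
    )
    meta = pd.DataFrame(
        {
            "sig_id": sig_ids,
            "cell_id": "A",
            "pert_id": pert_ids or [f"p{i}" for i in range(n)],
            "pert_category": "compound",
            "dose_um": 1.0,
            "time_h": 6.0,
        }
    )
    return frame, meta


class TestCategorizeCounts:
    def test_cumulative_profiles(self):
        deg, meta = _deg_frame([0, 10, 120])
        cc = categorize_counts(deg, meta)
        assert cc.profiles_none == 1
        assert cc.profiles == {1: 2, 50: 1, 100: 1}
        assert cc.total_profiles == 3
        assert cc.profiles_none + cc.profiles[1] == cc.total_profiles

    def test_molecule_any_signature_rule(self):
        deg, meta = _deg_frame([5, 60], pert_ids=["mol", "mol"])
        cc = categorize_counts(deg, meta)
        assert cc.total_molecules == 1
        assert cc.molecules == {1: 1, 50: 1, 100: 0}

    def test_any_and_max_rules_coincide(self):
        deg, meta = _deg_frame([0, 10, 120, 55], pert_ids=["a", "a", "b", "b"])
        any_rule = categorize_counts(deg, meta, molecule_rule="any")
        max_rule = categorize_counts(deg, meta, molecule_rule="max")
        assert any_rule.molecules == max_rule.molecules

    def test_orphan_sig_id_is_hard_error(self):
        deg, meta = _deg_frame([1, 2])
        with pytest.raises(ValueError, match="no metadata"):
            categorize_counts(deg, meta.iloc[:1])

    def test_monotone_nesting(self):
        rng = np.random.default_rng(3)
        deg, meta = _deg_frame(list(rng.integers(0, 300, size=50)))
        cc = categorize_counts(deg, meta)
        assert cc.profiles[1] >= cc.profiles[50] >= cc.profiles[100]
        assert cc.molecules[1] >= cc.molecules[50] >= cc.molecules[100]


class TestDoseGroup:
    @pytest.mark.parametrize(
        "dose,expected", [(0.5, "low"), (5.0, "low"), (10.0, "high"), (5.0001, "high")]
    )
    def test_split_at_five_micromolar(self, dose, expected):
        assert assign_dose_group(dose) == expected

    def test_missing_dose_raises(self):
        with pytest.raises(ValueError):
            assign_dose_group(float("nan"))


class TestStratifiedCounts:
    def _toy(self):
        totals = [120, 130, 5, 20, 150, 0]
        sig_ids = [f"s{i}" for i in range(6)]
        deg = pd.DataFrame(
            {"sig_id": sig_ids, "n_up": totals, "n_down": 0, "n_total": totals}
        )
        meta = pd.DataFrame(
            {
                "sig_id": sig_ids,
                "cell_id": ["X", "X", "Y", "Y", "X", "Y"],
                "pert_id": [f"p{i}" for i in range(6)],
                "pert_category": "compound",
                "dose_um": [1.0, 10.0, 1.0, 10.0, np.nan, 2.0],
                "time_h": [6.0, 24.0, 6.0, 24.0, 6.0, 24.0],
            }
        )
        return deg, meta

    def test_planted_separation_by_cell(self):
        deg, meta = self._toy()
        table = stratified_category_counts(deg, meta, by="cell")
        x = table.set_index("cell_id").loc["X"]
        y = table.set_index("cell_id").loc["Y"]
        assert (x["ge_1"], x["ge_50"], x["ge_100"]) == (3, 3, 3)
        assert (y["ge_1"], y["ge_50"], y["ge_100"]) == (2, 0, 0)

    def test_dose_partition_conservation(self):
        deg, meta = self._toy()
        table = stratified_category_counts(deg, meta, by="cell_x_dose_group")
        n_dose_annotated = meta["dose_um"].notna().sum()
        assert table["n_profiles"].sum() == n_dose_annotated
        # none + >=1 = total within every stratum
        assert (table["n_none"] + table["ge_1"] == table["n_profiles"]).all()

    def test_monotone_in_every_stratum(self):
        deg, meta = self._toy()
        for by in ("cell", "cell_x_dose_group", "cell_x_time"):
            table = stratified_category_counts(deg, meta, by=by)
            assert (table["ge_1"] >= table["ge_50"]).all()
            assert (table["ge_50"] >= table["ge_100"]).all()

    def test_unknown_stratifier(self):
        deg, meta = self._toy()
        with pytest.raises(ValueError, match="stratifier"):
            stratified_category_counts(deg, meta, by="plate")


class TestBehaviorDirection:
    def _table(self, a, b):
        return pd.DataFrame(
            {
                "cell_id": ["X", "X"],
                "dose_group": ["low", "high"],
                "ge_100": [a, b],
            }
        )

    def test_increasing(self):
        assert (
            behavior_direction(self._table(100, 150), "X", ("low", "high"), "dose_group")
            == "increasing"
        )

    def test_decreasing(self):
        assert (
            behavior_direction(self._table(150, 100), "X", ("low", "high"), "dose_group")
            == "decreasing"
        )

    def test_tie_is_unchanged(self):
        assert (
            behavior_direction(self._table(100, 100), "X", ("low", "high"), "dose_group")
            == "unchanged"
        )

    def test_missing_level_not_evaluable(self):
        table = self._table(100, 150).iloc[:1]
        assert (
            behavior_direction(table, "X", ("low", "high"), "dose_group")
            == "not_evaluable"
        )
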