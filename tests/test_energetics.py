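"""Relative single-point energies and cross-method comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cageconform import (
    method_agreement,
    relative_energies,
    state_energy_summary,
)
from cageconform.errors import DataError


def make_table(method_energies, states=("closed", "semiopen", "open"), n_per_state=5):
    """method -> {state: base energy}; frames get small deterministic jitter."""
    rows = []
    for method, base in method_energies.items():
        for state in states:
            for k in range(n_per_state):
                rows.append(
                    {
                        "frame_id": f"{state}_{k}",
                        "state": state,
                        "method": method,
                        "energy_kcal_mol": base[state] + 0.1 * k,
                    }
                )
    return pd.DataFrame(rows)


class TestRelativeEnergies:
    def test_single_frame_is_zero(self):
        df = pd.DataFrame(
            [{"frame_id": "a", "state": "closed", "method": "DFT",
              "energy_kcal_mol": -1234.5}]
        )
        out = relative_energies(df)
        assert out["e_rel"].to_numpy() == pytest.approx([0.0])

    def test_simple_offsets(self):
        df = pd.DataFrame(
            [
                {"frame_id": i, "state": "closed", "method": "DFT",
                 "energy_kcal_mol": e}
                for i, e in enumerate([10.0, 12.0, 15.0])
            ]
        )
        out = relative_energies(df)
        assert sorted(out["e_rel"]) == pytest.approx([0.0, 2.0, 5.0])

    def test_state_ordering_preserved_per_method(self):
        table = make_table(
            {
                "DFT": {"closed": 0.0, "semiopen": 3.0, "open": 5.0},
                "FF-ESP": {"closed": -800.0, "semiopen": -796.0, "open": -791.0},
                "MLIP-v2": {"closed": 100.0, "semiopen": 103.2, "open": 104.9},
            }
        )
        out = relative_energies(table)
        for method, grp in out.groupby("method"):
            med = grp.groupby("state")["e_rel"].median()
            assert med["closed"] < med["semiopen"] < med["open"], method

    def test_reference_is_global_across_states(self):
        table = make_table({"DFT": {"closed": 0.0, "semiopen": 3.0, "open": 5.0}})
        out = relative_energies(table)
        # exactly one zero per method, in the lowest-energy state
        zeros = out[out["e_rel"] == 0.0]
        assert len(zeros) == 1
        assert zeros.iloc[0]["state"] == "closed"
        assert (out["e_rel"] >= 0).all()

    def test_duplicate_frame_method_rejected(self):
        df = pd.DataFrame(
            [
                {"frame_id": "a", "state": "closed", "method": "DFT",
                 "energy_kcal_mol": 0.0},
                {"frame_id": "a", "state": "open", "method": "DFT",
                 "energy_kcal_mol": 1.0},
            ]
        )
        with pytest.raises(DataError, match="duplicate"):
            relative_energies(df)


class TestStateEnergySummary:
    def test_five_identical_values(self):
        df = pd.DataFrame(
            [
                {"frame_id": k, "state": "closed", "method": "DFT",
                 "energy_kcal_mol": 7.0}
                for k in range(5)
            ]
        )
        out = state_energy_summary(df)
        row = out.iloc[0]
        assert row["median"] == 0.0
        assert row["q3"] - row["q1"] == 0.0
        assert row["outliers"] == ""

    def test_hand_computed_tukey_outlier(self):
        # values {0,1,2,3,100}: Q1=1, Q3=3, fence=3+1.5*2=6 < 100
        df = pd.DataFrame(
            [
                {"frame_id": k, "state": "open", "method": "FF-MUL",
                 "energy_kcal_mol": v}
                for k, v in enumerate([0.0, 1.0, 2.0, 3.0, 100.0])
            ]
        )
        out = state_energy_summary(df)
        row = out.iloc[0]
        assert row["median"] == 2.0
        assert row["q1"] == 1.0 and row["q3"] == 3.0
        assert row["whisker_hi"] == 3.0
        assert row["outliers"] == "100"

    def test_identical_methods_identical_summaries(self):
        base = {"closed": 0.0, "semiopen": 2.0, "open": 5.0}
        table = make_table({"A": base, "B": dict(base)})
        out = state_energy_summary(table)
        a = out[out["method"] == "A"].drop(columns="method").reset_index(drop=True)
        b = out[out["method"] == "B"].drop(columns="method").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_quantiles_match_sort_and_interpolate_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            vals = rng.normal(size=rng.integers(3, 12))
            df = pd.DataFrame(
                [
                    {"frame_id": k, "state": "closed", "method": "M",
                     "energy_kcal_mol": v}
                    for k, v in enumerate(vals)
                ]
            )
            row = state_energy_summary(df).iloc[0]
            v = np.sort(vals - vals.min())

            def interp(q):
                pos = q * (len(v) - 1)
                lo = int(np.floor(pos))
                hi = min(lo + 1, len(v) - 1)
                return v[lo] + (pos - lo) * (v[hi] - v[lo])

            assert row["q1"] == pytest.approx(interp(0.25))
            assert row["median"] == pytest.approx(interp(0.5))
            assert row["q3"] == pytest.approx(interp(0.75))

    def test_whiskers_within_data_range(self):
        table = make_table({"DFT": {"closed": 0.0, "semiopen": 2.0, "open": 5.0}})
        out = state_energy_summary(table)
        assert (out["q1"] <= out["median"]).all()
        assert (out["median"] <= out["q3"]).all()
        assert (out["whisker_lo"] <= out["q1"]).all()
        assert (out["whisker_hi"] >= out["q3"]).all()


class TestMethodAgreement:
    def test_reference_agrees_with_itself_via_copy(self):
        base = {"closed": 0.0, "semiopen": 2.0, "open": 5.0}
        table = make_table({"DFT": base, "COPY": dict(base)})
        out = method_agreement(table, "DFT")
        assert (out["median_abs_diff"] == 0).all()
        np.testing.assert_allclose(out["rank_correlation"], 1.0)

    def test_constant_offset_cancels(self):
        base = {"closed": 0.0, "semiopen": 2.0, "open": 5.0}
        shifted = {s: v - 750.0 for s, v in base.items()}
        table = make_table({"DFT": base, "FF": shifted})
        out = method_agreement(table, "DFT")
        assert out["median_abs_diff"].to_numpy() == pytest.approx(0.0)

    def test_hundred_kcal_open_state_deviation_is_localized(self):
        base = {"closed": 0.0, "semiopen": 2.0, "open": 5.0}
        deviant = {"closed": 0.0, "semiopen": 2.0, "open": 105.0}
        table = make_table({"DFT": base, "FF-MUL": deviant})
        out = method_agreement(table, "DFT").set_index("state")
        assert out.loc["open", "median_abs_diff"] == pytest.approx(100.0)
        assert out.loc["closed", "median_abs_diff"] == pytest.approx(0.0)

    def test_missing_reference_rejected(self):
        table = make_table({"A": {"closed": 0.0, "semiopen": 1.0, "open": 2.0}})
        with pytest.raises(DataError, match="reference"):
            method_agreement(table, "DFT")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(min_value=-1000, max_value=1000, allow_nan=False))
    def test_summaries_invariant_under_method_shift(self, shift):
        base = {"closed": 0.0, "semiopen": 2.0, "open": 5.0}
        t1 = make_table({"M": base})
        t2 = make_table({"M": {s: v + shift for s, v in base.items()}})
        s1 = state_energy_summary(t1)
        s2 = state_energy_summary(t2)
        for col in ("median", "q1", "q3", "whisker_lo", "whisker_hi"):
            np.testing.assert_allclose(s1[col], s2[col], atol=1e-9)
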