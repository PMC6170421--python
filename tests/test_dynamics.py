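"""Medians, dominance, fold changes, anomaly screening, heatmap extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import micquant as mq
from micquant.dynamics import (
    classify_dominant,
    consecutive_fold_changes,
    detect_anomalies,
    heatmap_table,
    location_medians,
    profiles_to_matrix,
    relative_abundance,
)


def frame(values: dict[str, dict[str, float]]) -> pd.DataFrame:
    """otu -> {sample -> copies} helper."""
    return pd.DataFrame(values).T


def meta_for(samples: list[tuple[str, str, int]]) -> pd.DataFrame:
    return pd.DataFrame(
        {"location": [s[1] for s in samples], "month": [s[2] for s in samples]},
        index=pd.Index([s[0] for s in samples], name="sample_id"),
    )


class TestMedians:
    def test_single_month_is_identity(self):
        copies = frame({"o1": {"s1": 10.0, "s2": 20.0}})
        meta = meta_for([("s1", "A", 1), ("s2", "B", 1)])
        med = location_medians(copies, meta)
        assert med.at["o1", "A"] == 10.0 and med.at["o1", "B"] == 20.0

    def test_median_robust_to_outlier(self):
        copies = frame({"o1": {"s1": 10.0, "s2": 20.0, "s3": 1000.0}})
        meta = meta_for([("s1", "A", 1), ("s2", "A", 2), ("s3", "A", 3)])
        assert location_medians(copies, meta).at["o1", "A"] == 20.0

    def test_matches_numpy_median_oracle(self, rng):
        samples = [(f"s{i}", "ABC"[i % 3], i // 3 + 1) for i in range(12)]
        copies = pd.DataFrame(
            rng.uniform(0, 100, size=(5, 12)),
            index=[f"o{i}" for i in range(5)],
            columns=[s[0] for s in samples],
        )
        meta = meta_for(samples)
        med = location_medians(copies, meta)
        for loc in "ABC":
            cols = [s[0] for s in samples if s[1] == loc]
            assert np.allclose(med[loc], np.median(copies[cols], axis=1))


class TestDominance:
    def test_sole_otu_is_dominant(self):
        med = pd.DataFrame({"A": [100.0]}, index=["o1"])
        assert classify_dominant(med).at["o1", "A"]

    def test_exactly_five_percent_is_not_dominant(self):
        med = pd.DataFrame({"A": [5.0, 95.0]}, index=["o1", "o2"])
        dom = classify_dominant(med, threshold=0.05)
        assert not dom.at["o1", "A"]
        assert dom.at["o2", "A"]

    def test_all_zero_location_has_no_dominants(self):
        med = pd.DataFrame({"A": [0.0, 0.0]}, index=["o1", "o2"])
        assert not classify_dominant(med).any().any()

    def test_relative_abundances_sum_to_one(self, rng):
        med = pd.DataFrame(
            rng.uniform(0, 50, size=(8, 4)), columns=list("ABCD")
        )
        rel = relative_abundance(med)
        assert np.allclose(rel.sum(axis=0), 1.0, atol=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.integers(0, 4),
        st.floats(1.0, 1e4, allow_nan=False),
    )
    def test_raising_an_otu_never_unflags_it(self, row, bump):
        med = pd.DataFrame(
            {"A": [10.0, 20.0, 1.0, 50.0, 19.0]}, index=[f"o{i}" for i in range(5)]
        )
        before = classify_dominant(med)
        med2 = med.copy()
        med2.iloc[row, 0] += bump
        after = classify_dominant(med2)
        if before.iloc[row, 0]:
            assert after.iloc[row, 0]


class TestFoldChanges:
    def test_twofold_decrease_boundary_not_significant(self):
        med = pd.DataFrame({"A": [200.0], "B": [100.0]}, index=["o1"])
        fc = consecutive_fold_changes(med, pseudo_floor=1e-9)
        row = fc.iloc[0]
        assert row["ratio"] == pytest.approx(0.5, rel=1e-6)
        assert not row["significant"]

    def test_threefold_increase_significant(self):
        med = pd.DataFrame({"A": [100.0], "B": [300.0]}, index=["o1"])
        row = consecutive_fold_changes(med, pseudo_floor=1e-9).iloc[0]
        assert row["log2_ratio"] == pytest.approx(np.log2(3), rel=1e-6)
        assert row["significant"]

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1e5, allow_nan=False), min_size=2, max_size=6))
    def test_antisymmetry_under_pair_reversal(self, vals):
        med = pd.DataFrame({"A": vals, "B": list(reversed(vals))})
        fwd = consecutive_fold_changes(med, pseudo_floor=0.5)
        rev = consecutive_fold_changes(med[["B", "A"]], pseudo_floor=0.5)
        assert np.allclose(fwd["log2_ratio"], -rev["log2_ratio"])


class TestAnomalies:
    @staticmethod
    def flat_campaign(n_otus=100, boost=None):
        samples = [
            (f"{loc}-M{m}", loc, m) for m in (1, 2, 3) for loc in ("A", "B")
        ]
        meta = meta_for(samples)
        base = np.linspace(10, 1000, n_otus)
        copies = pd.DataFrame(
            {sid: base * 0.45 if loc == "B" else base for sid, loc, m in samples},
            index=[f"o{i}" for i in range(n_otus)],
        )
        if boost:
            month, otus, factor = boost
            copies.loc[copies.index[otus], f"B-M{month}"] *= factor
        return copies, meta

    def test_no_boost_no_flags(self):
        copies, meta = self.flat_campaign()
        assert detect_anomalies(copies, meta, pseudo_floor=0.5).empty

    def test_single_boosted_otu_below_fraction_threshold(self):
        copies, meta = self.flat_campaign(boost=(2, range(1), 10.0))
        assert detect_anomalies(copies, meta, pseudo_floor=0.5).empty

    def test_mass_boost_is_flagged(self):
        copies, meta = self.flat_campaign(boost=(2, range(40), 10.0))
        out = detect_anomalies(copies, meta, pseudo_floor=0.5)
        assert len(out) == 1
        assert out.iloc[0]["month"] == 2 and out.iloc[0]["pair"] == "A->B"
        assert out.iloc[0]["n_otus_boosted"] == 40


class TestHeatmap:
    def test_roundtrip_and_shape(self, default_campaign):
        _, truth, bundle = default_campaign
        copies, meta, _ = profiles_to_matrix(bundle.profiles)
        subset = truth.front_otus + truth.back_otus
        tbl = heatmap_table(copies, meta, subset, temperature=truth.temperature)
        assert len(tbl) == len(meta) * len(subset)
        for _, row in tbl.sample(25, random_state=0).iterrows():
            sid = f"{row['location']}-M{row['month']}"
            assert row["copies"] == copies.at[row["otu_id"], sid]
            assert row["temperature"] == truth.temperature.at[
                row["location"], row["month"]
            ]

    def test_unknown_otu_raises(self, default_campaign):
        _, _, bundle = default_campaign
        copies, meta, _ = profiles_to_matrix(bundle.profiles)
        with pytest.raises(KeyError):
            heatmap_table(copies, meta, ["NOPE_001"])


class TestCampaignRecovery:
    def test_engineered_structure_recovered(self, default_campaign):
        """Dominants, kill-off, regrowth, trends and the anomaly all surface."""
        _, truth, bundle = default_campaign
        dyn = bundle.dynamics
        assert set(dyn.dominant_otus) == set(truth.front_otus) | set(truth.back_otus)
        fc = dyn.fold_changes
        ab = fc[fc["pair"] == "A->B"].set_index("otu_id")
        bc = fc[fc["pair"] == "B->C"].set_index("otu_id")
        for otu in truth.front_otus:
            assert ab.at[otu, "significant"] and ab.at[otu, "ratio"] < 0.5
        for otu in truth.back_otus:
            assert bc.at[otu, "significant"] and bc.at[otu, "ratio"] > 2.0
        for otu in truth.front_otus:
            assert dyn.trends.at[otu, "rs"] < 0
            assert dyn.trends.at[otu, "p_value"] < 0.05
        for otu in truth.back_otus:
            assert dyn.trends.at[otu, "rs"] > 0
            assert dyn.trends.at[otu, "p_value"] < 0.05
        an = dyn.anomalies
        assert ((an["month"] == 3) & (an["pair"] == "A->B")).any()
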