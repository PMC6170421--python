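"""Calibration arithmetic, NEC subtraction, replicate consensus, recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import micquant as mq
from conftest import make_table, run_campaign

CAL = mq.CalibrationConfig(ic_copies=10_000, volume_scale=1.0)


def brute_force_sample(
    counts: dict[str, list[int]],
    nec_counts: list[dict[str, list[int]]],
    ic_copies: float,
    volume_scale: float,
    consensus_min: int = 2,
):
    """Independent plain-Python re-implementation: calibrate, average the NEC,
    subtract with clipping (no clearance margin), 2-of-k consensus, mean merge."""
    otus = [o for o in counts if o != "IC"]
    n_reps = len(counts["IC"])

    def calibrated(tbl, rep):
        return {
            o: tbl[o][rep] / tbl["IC"][rep] * ic_copies * volume_scale for o in otus
        }

    nec_cols = []
    for tbl in nec_counts:
        for rep in range(len(tbl["IC"])):
            if tbl["IC"][rep] > 0:
                nec_cols.append(
                    {o: tbl.get(o, [0] * 9)[rep] / tbl["IC"][rep] * ic_copies * volume_scale for o in otus}
                )
    contamination = {
        o: sum(c[o] for c in nec_cols) / len(nec_cols) if nec_cols else 0.0
        for o in otus
    }
    reps = []
    for rep in range(n_reps):
        if counts["IC"][rep] == 0:
            continue
        cal = calibrated(counts, rep)
        reps.append({o: max(0.0, cal[o] - contamination[o]) for o in otus})
    out = {}
    for o in otus:
        nonzero = sum(1 for r in reps if r[o] > 0)
        mean = sum(r[o] for r in reps) / len(reps)
        out[o] = mean if nonzero >= consensus_min else 0.0
    return out


class TestCalibration:
    def test_forced_arithmetic(self):
        counts = pd.Series({"OTU_A": 500, "IC": 1000})
        copies, lod = mq.calibrate_replicate(counts, CAL)
        assert copies["OTU_A"] == pytest.approx(5000.0)
        assert lod == pytest.approx(10.0)

    def test_reads_equal_calibrator_gives_spike_copies(self):
        cal = mq.CalibrationConfig(ic_copies=12_345, volume_scale=2.5)
        counts = pd.Series({"OTU_A": 777, "IC": 777})
        copies, _ = mq.calibrate_replicate(counts, cal)
        assert copies["OTU_A"] == pytest.approx(cal.ic_copies * cal.volume_scale)

    def test_zero_reads_zero_copies(self):
        copies, _ = mq.calibrate_replicate(pd.Series({"OTU_A": 0, "IC": 50}), CAL)
        assert copies["OTU_A"] == 0.0

    def test_zero_calibrator_is_invalid_never_imputed(self):
        with pytest.raises(mq.InvalidReplicateError):
            mq.calibrate_replicate(pd.Series({"OTU_A": 10, "IC": 0}), CAL)

    def test_linearity_in_spike_copies(self):
        counts = pd.Series({"OTU_A": 123, "OTU_B": 7, "IC": 456})
        base, base_lod = mq.calibrate_replicate(counts, CAL)
        for c in (2.0, 10.0, 0.5):
            scaled, lod = mq.calibrate_replicate(
                counts, mq.CalibrationConfig(ic_copies=CAL.ic_copies * c)
            )
            assert np.allclose(scaled, base * c)
            assert lod == pytest.approx(base_lod * c)

    def test_scale_invariance_of_read_counts(self):
        counts = pd.Series({"OTU_A": 123, "OTU_B": 7, "IC": 456})
        base, _ = mq.calibrate_replicate(counts, CAL)
        scaled, _ = mq.calibrate_replicate(counts * 13, CAL)
        assert np.allclose(scaled, base)


class TestNEC:
    def test_zero_nec_means_zero_contamination(self):
        nec = make_table(
            {"OTU_A": [0, 0, 0], "IC": [100, 100, 100]}, sample_type="nec"
        )
        prof = mq.nec_profile([nec], CAL)
        assert (prof.copies == 0).all()

    def test_mean_of_replicates(self):
        # three replicates calibrating to 30, 60, 90 copies -> mean 60
        nec = make_table(
            {"OTU_A": [3, 6, 9], "IC": [1000, 1000, 1000]}, sample_type="nec"
        )
        prof = mq.nec_profile([nec], CAL)
        assert prof.copies["OTU_A"] == pytest.approx(60.0)

    def test_all_invalid_replicates_raise(self):
        nec = make_table({"OTU_A": [3, 6], "IC": [0, 0]}, sample_type="nec")
        with pytest.raises(mq.UnquantifiableSampleError):
            mq.nec_profile([nec], CAL)

    def test_contamination_level_recovered(self):
        errs = []
        for seed in range(50):
            cfg = mq.SimulationConfig(
                seed=seed, n_months=1, read_depth=100_000, anomaly_month=None
            )
            truth = mq.simulate_truth(cfg)
            necs = [
                t for t in mq.simulate_reads(truth, cfg) if t.sample_type == "nec"
            ]
            prof = mq.nec_profile(necs, mq.CalibrationConfig(ic_copies=cfg.ic_copies))
            est = prof.copies.reindex(truth.contamination_copies.index)
            errs.append(float(np.mean(np.abs(est - 200.0) / 200.0)))
        assert np.mean(errs) < 0.10


class TestDecontaminate:
    def test_simple_subtraction_and_clip(self):
        s = pd.Series({"a": 100.0, "b": 20.0})
        c = pd.Series({"a": 30.0, "b": 30.0})
        out = mq.decontaminate(s, c)
        assert out["a"] == pytest.approx(70.0)
        assert out["b"] == 0.0

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1e6, allow_nan=False),
                st.floats(0, 1e6, allow_nan=False),
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_clip_property(self, pairs):
        s = pd.Series([p[0] for p in pairs])
        c = pd.Series([p[1] for p in pairs])
        out = mq.decontaminate(s, c)
        expected = np.where(c >= s, 0.0, s - c)
        assert np.allclose(out, expected)


class TestMerge:
    def test_mean_of_three(self):
        df = pd.DataFrame({"r1": [100.0], "r2": [110.0], "r3": [120.0]}, index=["a"])
        copies, detected, lod = mq.merge_replicates(df, [1.0, 2.0, 1.5])
        assert copies["a"] == pytest.approx(110.0)
        assert detected["a"] == 3
        assert lod == 2.0

    def test_consensus_rule_zeroes_single_detection(self):
        df = pd.DataFrame({"r1": [100.0], "r2": [0.0], "r3": [0.0]}, index=["a"])
        copies, detected, _ = mq.merge_replicates(df, [1, 1, 1])
        assert copies["a"] == 0.0
        assert detected["a"] == 1

    def test_too_few_valid_replicates(self):
        df = pd.DataFrame({"r1": [100.0]}, index=["a"])
        with pytest.raises(mq.UnquantifiableSampleError):
            mq.merge_replicates(df, [1.0])

    def test_consensus_reduces_false_positives(self):
        """2-of-3 consensus strictly cuts contamination carry-through when the
        clearance margin is off, and never invents new signal."""
        fp_with = fp_without = 0
        for seed in range(8):
            for consensus, bucket in ((2, "with"), (0, "without")):
                cfg, truth, bundle = run_campaign(
                    seed,
                    sim_overrides={"n_months": 1, "anomaly_month": None},
                    pipe_overrides={
                        "nec_margin_z": 0.0,
                        "consensus_min_replicates": consensus,
                    },
                )
                cont_ids = truth.contamination_copies.index
                fp = sum(
                    int((p.copies.reindex(cont_ids, fill_value=0) > 0).sum())
                    for p in bundle.profiles
                )
                if bucket == "with":
                    fp_with += fp
                else:
                    fp_without += fp
        assert fp_with < fp_without


class TestEndToEnd:
    def test_brute_force_oracle_equality(self, rng):
        """calibrate + subtract + merge on tiny tables == independent oracle."""
        cal = mq.CalibrationConfig(ic_copies=5000, volume_scale=3.0)
        for trial in range(25):
            otus = [f"O{i}" for i in range(int(rng.integers(1, 6)))]
            counts = {o: list(rng.integers(0, 50, 3)) for o in otus}
            counts["IC"] = list(rng.integers(1, 2000, 3))
            nec_counts = {o: list(rng.integers(0, 5, 3)) for o in otus}
            nec_counts["IC"] = list(rng.integers(1, 2000, 3))
            table = make_table(counts)
            nec = make_table(nec_counts, sample_id="NEC", sample_type="nec")
            profile = mq.quantify_sample(
                table, mq.nec_profile([nec], cal), cal, nec_margin_z=0.0
            )
            expected = brute_force_sample(
                counts, [nec_counts], cal.ic_copies, cal.volume_scale
            )
            for o in otus:
                assert profile.copies[o] == pytest.approx(expected[o], abs=1e-9)

    def test_contamination_only_otus_reach_exact_zero(self, default_campaign):
        cfg, truth, bundle = default_campaign
        cont_ids = truth.contamination_copies.index
        for p in bundle.profiles:
            assert (p.copies.reindex(cont_ids, fill_value=0) == 0).all()

    def test_copies_recovered_from_deep_replicates(self):
        """Parameter recovery: per-OTU copies track the simulator's truth."""
        rel_errs = []
        for seed in range(20):
            cfg, truth, bundle = run_campaign(
                seed,
                sim_overrides={
                    "n_months": 1,
                    "read_depth": 100_000,
                    "anomaly_month": None,
                },
            )
            for p in bundle.profiles:
                t = truth.true_copies[(p.location, p.month)]
                qual = t > 10 * p.lod
                est = p.copies.reindex(t.index, fill_value=0.0)
                rel_errs.extend(((est[qual] - t[qual]) / t[qual]).tolist())
        assert np.sqrt(np.mean(np.square(rel_errs))) < 0.10

    def test_totals_and_richness(self, default_campaign):
        cfg, truth, bundle = default_campaign
        p = bundle.profiles[0]
        assert mq.total_biomass(p) == pytest.approx(p.copies.sum())
        assert mq.observed_richness(p) == int((p.copies > 0).sum())
        empty = mq.AbsoluteProfile(
            sample_id="empty",
            copies=pd.Series(dtype=float),
            n_replicates_detected=pd.Series(dtype=int),
            lod=1.0,
            n_valid_replicates=3,
            location="A",
            month=1,
        )
        assert mq.total_biomass(empty) == 0.0
        assert mq.observed_richness(empty) == 0

    def test_median_richness_matches_study_scale(self):
        """Observed per-sample richness centres near 69 of 143 community OTUs."""
        rich = []
        for seed in range(5):
            _, _, bundle = run_campaign(seed)
            rich += [mq.observed_richness(p) for p in bundle.profiles]
        assert 0.9 * 69 <= np.median(rich) <= 1.1 * 69
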