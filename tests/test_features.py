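"""Feature-bank correctness against a naively coded one-formula-at-a-time oracle."""

import math

import numpy as np
import pytest

from fogcast.features import (
    ChannelWindow,
    FEATURE_IDS,
    FEATURE_REGISTRY,
    compute_features,
    compute_features_bulk,
    compute_freq_features,
    compute_time_features,
    extract_matrix,
    feature_names,
    standardize,
)
from fogcast.preprocess import SegmentationParams, segment_and_label
from fogcast.synth import GaitSimParams, simulate_recording


# --- independent oracle: plain-Python, one formula at a time -----------------

def oracle_features(x, fs):
    x = [float(v) for v in x]
    ns = len(x)
    out = {}
    out["F01"] = max(x)
    out["F02"] = min(x)
    out["F03"] = sum(abs(v) for v in x) / ns
    out["F04"] = max(x) - min(x)
    out["F05"] = math.sqrt(sum(v * v for v in x) / ns)
    out["F06"] = sum(x) / ns
    mean = out["F06"]
    var = sum((v - mean) ** 2 for v in x) / ns
    sd = math.sqrt(var)
    out["F07"] = sd
    out["F08"] = (sum((v - mean) ** 3 for v in x) / ns) / sd**3 if sd else 0.0
    out["F09"] = (sum((v - mean) ** 4 for v in x) / ns) / var**2 if sd else 0.0
    out["F10"] = var
    maxabs = max(abs(v) for v in x)
    out["F11"] = out["F05"] / out["F03"] if out["F03"] else 0.0
    out["F12"] = maxabs / out["F05"] if out["F05"] else 0.0
    out["F13"] = mean / sd if sd else 0.0
    out["F14"] = sum((v / sd) ** 3 for v in x) / ns if sd else 0.0
    out["F15"] = sum((v / sd) ** 4 for v in x) / ns if sd else 0.0
    smr = (sum(math.sqrt(abs(v)) for v in x) / ns) ** 2
    out["F16"] = maxabs / smr if smr else 0.0
    out["F17"] = maxabs / out["F03"] if out["F03"] else 0.0
    dx = []
    for i in range(ns):
        nxt = x[(i + 1) % ns]
        prv = x[(i - 1) % ns]
        dx.append(x[i] * x[i] - nxt * prv)
    dmean = sum(dx) / ns
    dvar = sum((v - dmean) ** 2 for v in dx) / ns
    out["F18"] = (sum((v - dmean) ** 4 for v in dx) / ns) / dvar**2 if dvar else 0.0

    # one-sided DFT magnitude, DC excluded, Nfft = Ns
    nbins = ns // 2
    amp, freq = [], []
    for j in range(1, nbins + 1):
        re = sum(x[i] * math.cos(-2 * math.pi * j * i / ns) for i in range(ns))
        im = sum(x[i] * math.sin(-2 * math.pi * j * i / ns) for i in range(ns))
        amp.append(math.hypot(re, im))
        freq.append(j * fs / ns)
    total = sum(amp)
    out["F19"] = total / nbins
    if total:
        out["F20"] = sum(f * a for f, a in zip(freq, amp)) / total
        out["F21"] = math.sqrt(sum(f * f * a for f, a in zip(freq, amp)) / total)
        out["F22"] = sum((f - out["F20"]) ** 2 * a for f, a in zip(freq, amp)) / total
    else:
        out["F20"] = out["F21"] = out["F22"] = 0.0
    return out


class TestAgainstOracle:
    def test_hand_computed_two_sample_window(self):
        fv = compute_time_features(ChannelWindow(np.array([3.0, 4.0]), 100.0))
        assert fv.values["F05"] == pytest.approx(math.sqrt(12.5))
        assert fv.values["F04"] == 1.0
        assert fv.values["F06"] == 3.5

    def test_constant_window_degenerate_rules(self):
        fv = compute_time_features(ChannelWindow(np.full(32, 2.5), 100.0))
        for fid in ("F11", "F12", "F17"):
            assert fv.values[fid] == 1.0
        assert fv.values["F04"] == 0.0
        for fid in ("F08", "F09", "F13", "F14", "F15"):
            assert fv.values[fid] == 0.0
        assert fv.degenerate

    def test_full_bank_matches_oracle(self, rng):
        """1000 random windows: every feature within 1e-10 relative."""
        for i in range(1000):
            ns = int(rng.choice([16, 24, 32, 33]))
            x = rng.standard_normal(ns) * rng.uniform(0.1, 5)
            bank, _ = compute_features_bulk(x[None, :], 100.0)
            want = oracle_features(x, 100.0)
            for j, fid in enumerate(FEATURE_IDS):
                assert bank[0, j] == pytest.approx(
                    want[fid], rel=1e-10, abs=1e-12
                ), fid

    def test_zero_window_spectrum_rule(self):
        fv = compute_freq_features(ChannelWindow(np.zeros(64), 100.0))
        assert all(fv.values[f] == 0.0 for f in ("F19", "F20", "F21", "F22"))

    def test_pure_tone_center_frequency(self):
        fs, ns, f0 = 100.0, 500, 5.0
        t = np.arange(ns) / fs
        fv = compute_freq_features(ChannelWindow(np.sin(2 * np.pi * f0 * t), fs))
        assert fv.values["F20"] == pytest.approx(f0, abs=fs / ns)
        assert fv.values["F22"] <= (fs / ns) ** 2 + 1e-9


class TestInvariants:
    @pytest.mark.parametrize("trial", range(20))
    def test_moment_and_range_identities(self, rng, trial):
        x = rng.standard_normal(int(rng.integers(8, 200)))
        fv = compute_features(ChannelWindow(x, 100.0)).values
        assert fv["F04"] == fv["F01"] - fv["F02"]
        assert fv["F05"] ** 2 == pytest.approx(fv["F10"] + fv["F06"] ** 2, rel=1e-9)
        assert fv["F17"] >= fv["F12"] >= 1.0
        assert fv["F21"] ** 2 >= fv["F20"] ** 2 - 1e-9  # Jensen

    def test_scale_invariance_and_homogeneity(self, rng):
        x = rng.standard_normal(128)
        c = 3.7
        a = compute_features(ChannelWindow(x, 100.0)).values
        b = compute_features(ChannelWindow(c * x, 100.0)).values
        for fid in ("F08", "F09", "F11", "F12", "F15", "F16", "F17"):
            assert b[fid] == pytest.approx(a[fid], rel=1e-9), fid
        for fid in ("F05", "F07"):
            assert b[fid] == pytest.approx(c * a[fid], rel=1e-9)

    def test_strict_clearance_mode_duplicates_crest(self, rng):
        x = rng.standard_normal(64)
        strict = compute_features(ChannelWindow(x, 100.0), strict_clearance=True).values
        assert strict["F16"] == strict["F12"]
        conventional = compute_features(ChannelWindow(x, 100.0)).values
        assert conventional["F16"] != conventional["F12"]

    def test_registry_has_22_definitions(self):
        assert len(FEATURE_REGISTRY) == 22
        assert list(FEATURE_REGISTRY) == list(FEATURE_IDS)


class TestExtractMatrix:
    def test_seven_sensor_recording_gives_924_columns(self):
        rec, ann = simulate_recording(GaitSimParams(seed=1), 20.0)
        ws = segment_and_label(rec, ann, SegmentationParams(128, 64, 150))
        fm = extract_matrix(ws)
        assert fm.features.shape == (len(ws), 7 * 6 * 22)
        assert fm.features.columns[0] == "sensor1_accX_F01"
        assert fm.features.columns[-1] == "sensor7_gyrZ_F22"

    def test_single_sensor_gives_132_columns(self):
        rec, ann = simulate_recording(GaitSimParams(n_sensors=1, seed=1), 20.0)
        ws = segment_and_label(rec, ann, SegmentationParams(128, 64, 150))
        fm = extract_matrix(ws)
        assert fm.features.shape[1] == 132

    def test_row_independence_under_window_permutation(self):
        rec, ann = simulate_recording(GaitSimParams(n_sensors=1, seed=2), 20.0)
        ws = segment_and_label(rec, ann, SegmentationParams(100, 50, 150))
        fm = extract_matrix(ws)
        import copy

        ws2 = copy.copy(ws)
        perm = list(reversed(range(len(ws.windows))))
        ws2.windows = [ws.windows[i] for i in perm]
        fm2 = extract_matrix(ws2)
        # batched FFTs may round differently per SIMD lane; equality is to
        # numerical precision, not bitwise
        np.testing.assert_allclose(
            fm2.features.to_numpy(), fm.features.to_numpy()[perm], rtol=1e-12, atol=1e-12
        )


class TestStandardize:
    def _tiny(self, values, labels=None, pids=None):
        import pandas as pd
        from fogcast.features import FeatureMatrix

        arr = np.asarray(values, float)
        n = len(arr)
        return FeatureMatrix(
            features=pd.DataFrame(arr, columns=[f"c{i}" for i in range(arr.shape[1])]),
            labels=pd.Series(labels or ["normal"] * n),
            patient_ids=pd.Series(pids or ["p"] * n),
        )

    def test_population_sd_scaling(self):
        fm = self._tiny([[1.0], [2.0], [3.0]])
        z = standardize(fm, np.array([True, True, True]))
        np.testing.assert_allclose(
            z.features["c0"].to_numpy(), [-1.224744871, 0.0, 1.224744871], rtol=1e-9
        )

    def test_constant_column_flagged_and_passed_through(self):
        fm = self._tiny([[1.0, 7.0], [2.0, 7.0], [3.0, 7.0]])
        z = standardize(fm, np.array([True, True, True]))
        assert z.zero_sd_columns == ["c1"]
        np.testing.assert_array_equal(z.features["c1"].to_numpy(), [7.0, 7.0, 7.0])

    def test_test_rows_use_training_parameters(self, rng):
        vals = rng.standard_normal((20, 3))
        fm = self._tiny(vals)
        mask = np.zeros(20, bool)
        mask[:12] = True
        z = standardize(fm, mask)
        mu = vals[:12].mean(axis=0)
        sd = vals[:12].std(axis=0)
        np.testing.assert_allclose(
            z.features.to_numpy(), (vals - mu) / sd, rtol=1e-10
        )
        # training rows: mean ~ 0, sd ~ 1
        ztr = z.features.to_numpy()[mask]
        assert np.all(np.abs(ztr.mean(axis=0)) < 1e-10)
        np.testing.assert_allclose(ztr.std(axis=0), 1.0, rtol=1e-9)

    def test_empty_training_mask_rejected(self):
        fm = self._tiny([[1.0], [2.0]])
        with pytest.raises(ValueError):
            standardize(fm, np.array([False, False]))


def test_feature_name_layout():
    names = feature_names(["sensor1_accX", "sensor1_accY"])
    assert names[:2] == ["sensor1_accX_F01", "sensor1_accX_F02"]
    assert len(names) == 44
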