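import itertools
import warnings

import numpy as np
import pytest

from emotiwin.features import (
    EYE_EVENT_NAMES,
    SEVEN_STATS,
    TIME_DOMAIN_NAMES,
    WAVEFORM_NAMES,
    extract_window_features,
    eye_event_features,
    eye_feature_names,
    feature_manifest,
    first_order_difference,
    mfcc_window_features,
    pixel_change_rate,
    time_domain_features,
    video_window_features,
    waveform_features,
)
from emotiwin.mfcc import mfcc
from emotiwin.windowing import Window


def brute_time_domain(x):
    """Independent textbook recomputation of the time-domain statistics."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    return {
        "max": max(x), "min": min(x), "mean": mean,
        "median": sorted(x)[n // 2] if n % 2 else (sorted(x)[n // 2 - 1] + sorted(x)[n // 2]) / 2,
        "range": max(x) - min(x), "std": var ** 0.5, "var": var,
        "energy": sum(v ** 2 for v in x),
        "mean_amplitude": sum(abs(v) for v in x) / n,
        "rms": (sum(v ** 2 for v in x) / n) ** 0.5,
    }


def brute_waveform(x):
    x = np.asarray(x, dtype=float)
    td = brute_time_domain(x)
    peak = max(abs(v) for v in x)
    sigma = td["std"]
    m3 = sum((v - td["mean"]) ** 3 for v in x) / len(x)
    m4 = sum((v - td["mean"]) ** 4 for v in x) / len(x)
    return {
        "crest_factor": peak / td["rms"],
        "waveform_factor": td["rms"] / td["mean_amplitude"],
        "skewness_factor": m3 / sigma ** 3,
        "impulse_factor": peak / td["mean_amplitude"],
        "clearance_factor": peak / (sum(abs(v) ** 0.5 for v in x) / len(x)) ** 2,
        "kurtosis_factor": m4 / sigma ** 4,
    }


def test_time_domain_trivial_examples():
    fv = time_domain_features([1, 1, 1, 1]).as_dict()
    assert fv["max"] == fv["min"] == fv["mean"] == fv["median"] == 1
    assert fv["range"] == fv["std"] == fv["var"] == 0
    assert fv["energy"] == 4 and fv["rms"] == 1
    fv2 = time_domain_features([-2, 2]).as_dict()
    assert fv2["mean"] == 0 and fv2["mean_amplitude"] == 2
    assert fv2["rms"] == 2 and fv2["energy"] == 8


def test_time_domain_matches_brute_force(rng):
    for _ in range(30):
        x = rng.normal(0, 3, int(rng.integers(2, 200)))
        fv = time_domain_features(x).as_dict()
        ref = brute_time_domain(x)
        for k in TIME_DOMAIN_NAMES:
            assert fv[k] == pytest.approx(ref[k], rel=1e-9, abs=1e-12), k
    with pytest.raises(ValueError):
        time_domain_features([1.0])


def test_waveform_constant_signal_unit_ratios():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fv = waveform_features([2.5] * 10)
    d = fv.as_dict()
    assert d["crest_factor"] == d["waveform_factor"] == d["impulse_factor"] == 1.0
    assert d["clearance_factor"] == pytest.approx(1.0)
    assert fv.degenerate


def test_waveform_matches_brute_force(rng):
    for _ in range(30):
        x = rng.normal(0.5, 2, int(rng.integers(3, 200)))
        fv = waveform_features(x).as_dict()
        ref = brute_waveform(x)
        for k in WAVEFORM_NAMES:
            assert fv[k] == pytest.approx(ref[k], rel=1e-9), k


def test_sine_crest_factor_sqrt2():
    x = np.sin(2 * np.pi * np.arange(100000) / 1000.0)
    assert waveform_features(x).as_dict()["crest_factor"] == pytest.approx(
        np.sqrt(2), rel=0.01
    )


def test_gaussian_moment_factors():
    x = np.random.default_rng(0).normal(0, 1, 100000)
    d = waveform_features(x).as_dict()
    assert abs(d["skewness_factor"]) < 0.1
    assert d["kurtosis_factor"] == pytest.approx(3.0, abs=0.1)


def test_shift_and_scale_behaviour(rng):
    x = rng.normal(0, 1, 100)
    c = 2.7
    td0, td1 = time_domain_features(x).as_dict(), time_domain_features(x + c).as_dict()
    for k in ("mean", "median", "max", "min"):
        assert td1[k] == pytest.approx(td0[k] + c, rel=1e-9)
    for k in ("std", "var", "range"):
        assert td1[k] == pytest.approx(td0[k], rel=1e-9)
    w0, w1 = waveform_features(x).as_dict(), waveform_features(3.3 * x).as_dict()
    for k in ("crest_factor", "waveform_factor", "impulse_factor", "clearance_factor"):
        assert w1[k] == pytest.approx(w0[k], rel=1e-9)


def test_first_order_difference(rng):
    np.testing.assert_array_equal(first_order_difference([1, 2, 4]), [1, 2])
    np.testing.assert_array_equal(first_order_difference([5, 5, 5]), [0, 0])
    x = rng.normal(size=50)
    np.testing.assert_allclose(
        first_order_difference(x), [x[i + 1] - x[i] for i in range(49)], rtol=1e-15
    )


def test_eye_event_features_examples():
    gaze = np.zeros((120, 2))
    fv = eye_event_features(["fixation"] * 120, gaze, 60.0).as_dict()
    assert fv["fixation_time_s"] == 2.0 and fv["saccade_time_s"] == 0.0

    states = ["fixation", "fixation", "saccade", "saccade", "fixation"]
    fv2 = eye_event_features(states, np.zeros((5, 2)), 60.0).as_dict()
    assert fv2["saccade_time_s"] == pytest.approx(2 / 60)
    assert fv2["saccade_count"] == 1


def test_eye_event_runs_match_runlength_oracle(rng):
    for _ in range(30):
        states = rng.choice(["fixation", "saccade", "blink"], size=60).tolist()
        gaze = rng.normal(0, 10, (60, 2))
        fv = eye_event_features(states, gaze, 60.0).as_dict()
        runs = [k for k, _ in itertools.groupby(states)]
        assert fv["saccade_count"] == sum(1 for k in runs if k == "saccade")
        d = np.abs(np.diff(gaze, axis=0))
        assert fv["gaze_diff_x"] == pytest.approx(d[:, 0].mean(), rel=1e-9)
        assert fv["gaze_diff_y"] == pytest.approx(d[:, 1].mean(), rel=1e-9)


def test_mfcc_silence_and_tone_vs_noise(rng):
    sr = 8000
    silence = np.zeros(sr)
    m = mfcc(silence, sr)
    # all frames identical -> temporal difference exactly zero
    assert np.all(np.diff(m, axis=1) == 0)

    t = np.arange(sr) / sr
    tone = 0.1 * np.sin(2 * np.pi * 440 * t)
    noise = rng.normal(0, 1, sr)
    noise *= np.sqrt(np.mean(tone ** 2) / np.mean(noise ** 2))
    mt, mn = mfcc(tone, sr).mean(axis=1), mfcc(noise, sr).mean(axis=1)
    assert np.linalg.norm(mt - mn) > 1.0

    with pytest.raises(ValueError, match="frame"):
        mfcc(np.zeros(10), sr)


def test_mfcc_window_statistics_match_oracle(rng):
    sr = 8000
    audio = rng.normal(0, 0.1, sr * 2).astype(np.float32)
    w = Window(0, 90)  # 1.5 s at 60 Hz
    fv = mfcc_window_features(audio, sr, w, 60.0).as_dict()
    m = mfcc(audio[: int(1.5 * sr)], sr)
    ref = brute_time_domain(m.ravel())
    for k in SEVEN_STATS:
        assert fv[f"mfcc_{k}"] == pytest.approx(ref[k], rel=1e-9), k
    refd = brute_time_domain(np.diff(m, axis=1).ravel())
    for k in SEVEN_STATS:
        assert fv[f"mfcc_diff_{k}"] == pytest.approx(refd[k], rel=1e-9), k


def test_pixel_change_rate_examples_and_oracle(rng):
    a = rng.uniform(0, 255, (5, 8, 8))
    same = np.stack([a[0], a[0]])
    assert pixel_change_rate(same)[0] == 0.0
    plus1 = np.stack([a[0], a[0] + 1.0])
    assert pixel_change_rate(plus1)[0] == pytest.approx(1.0)

    z = pixel_change_rate(a)
    for t in range(1, 5):
        acc = 0.0
        for i in range(8):
            for j in range(8):
                acc += abs(a[t, i, j] - a[t - 1, i, j])
        assert z[t - 1] == pytest.approx(acc / 64, rel=1e-9)
    # pair-order symmetry and joint constant-shift invariance
    pair = a[:2]
    assert pixel_change_rate(pair[::-1])[0] == pytest.approx(
        pixel_change_rate(pair)[0], rel=1e-12)
    assert pixel_change_rate(pair + 7.0)[0] == pytest.approx(
        pixel_change_rate(pair)[0], rel=1e-12)
    # signed variant cancels a symmetric change
    up_down = np.stack([a[0], a[0] + np.where(np.arange(64).reshape(8, 8) % 2, 1, -1)])
    assert abs(pixel_change_rate(up_down, signed=True)[0]) < 1e-9
    with pytest.raises(ValueError):
        pixel_change_rate(a[:1])


def test_video_window_features_delegate(rng):
    frames = rng.uniform(0, 255, (60, 8, 8))
    w = Window(0, 60)
    fv = video_window_features(frames, w, video_rate_hz=60.0, frame_rate_hz=60.0)
    ref = brute_time_domain(pixel_change_rate(frames))
    for k in SEVEN_STATS:
        assert fv.as_dict()[f"z_{k}"] == pytest.approx(ref[k], rel=1e-9)


def test_extract_window_features_manifest_and_determinism(bundle):
    w = Window(0, 60)
    out1 = extract_window_features(bundle, w, ("eye", "audio", "video"))
    out2 = extract_window_features(bundle, w, ("eye", "audio", "video"))
    manifest = feature_manifest(("eye", "audio", "video"))
    for mod in ("eye", "audio", "video"):
        assert out1[mod].names == manifest[mod]
        np.testing.assert_array_equal(out1[mod].values, out2[mod].values)


def test_manifest_covers_published_feature_families():
    names = set(eye_feature_names())
    for stem in TIME_DOMAIN_NAMES:
        assert f"pd_{stem}" in names and f"pd_diff_{stem}" in names
    for stem in WAVEFORM_NAMES:
        assert f"pd_{stem}" in names and f"pd_diff_{stem}" in names
    assert set(EYE_EVENT_NAMES) <= names
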