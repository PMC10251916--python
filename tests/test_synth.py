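import numpy as np
import pytest
from scipy import signal

from herdsense import io, synth


def test_single_bout_duration_and_labels():
    models, _ = synth.default_profile("separable")
    sched = synth.BehaviourSchedule([("resting", 8.0)])
    trace = synth.simulate_trace(sched, models, seed=0)
    assert len(trace) == 40
    assert set(trace.labels) == {"resting"}
    np.testing.assert_allclose(np.diff(trace.t), 0.2, atol=1e-9)


def test_degenerate_model_is_constant():
    models = {"resting": synth.BehaviourModel(
        mean=(0.1, 0.2, 0.9), noise_sd=(0.0, 0.0, 0.0))}
    sched = synth.BehaviourSchedule([("resting", 10.0)])
    trace = synth.simulate_trace(sched, models, seed=1)
    np.testing.assert_allclose(
        trace.xyz, np.tile([0.1, 0.2, 0.9], (len(trace), 1)), atol=1e-12)


def test_oscillation_dominant_frequency():
    """A 1.0 Hz chewing oscillation shows up as the spectral peak."""
    models = {"ruminating": synth.BehaviourModel(
        mean=(0.3, 0.1, 0.9), noise_sd=(0.02, 0.02, 0.02),
        osc_amp=(0.0, 0.0, 0.3), osc_freq=1.0)}
    sched = synth.BehaviourSchedule([("ruminating", 200.0)])
    trace = synth.simulate_trace(sched, models, seed=2)
    z = trace.xyz[:, 2] - trace.xyz[:, 2].mean()
    freqs, power = signal.periodogram(z, fs=5.0)
    assert freqs[np.argmax(power)] == pytest.approx(1.0, abs=0.05)


def test_nyquist_guard():
    with pytest.raises(ValueError, match="Nyquist"):
        synth.BehaviourModel(mean=(0, 0, 1), noise_sd=(0.1, 0.1, 0.1),
                             osc_amp=(0, 0, 0.1), osc_freq=3.0)


def test_unknown_behaviour_in_schedule():
    models, _ = synth.default_profile("separable")
    sched = synth.BehaviourSchedule([("grazing", 10.0)])
    with pytest.raises(KeyError, match="grazing"):
        synth.simulate_trace(sched, models, seed=0)


def test_profiles_are_constants():
    a_models, a_mix = synth.default_profile("separable")
    b_models, b_mix = synth.default_profile("separable")
    assert a_models == b_models
    assert a_mix == b_mix
    with pytest.raises(ValueError):
        synth.default_profile("impossible")


def test_separable_profile_centroid_classification():
    """With zero noise, nearest mean orientation is a perfect
    classifier for the orientation-only classes."""
    models, _ = synth.default_profile("separable")
    still = {"standing_still", "resting"}
    means = {b: np.asarray(m.mean) for b, m in models.items()
             if b in still}
    for b in still:
        quiet = synth.BehaviourModel(mean=models[b].mean,
                                     noise_sd=(0.0, 0.0, 0.0))
        trace = synth.simulate_trace(
            synth.BehaviourSchedule([(b, 5.0)]), {b: quiet}, seed=0)
        sample = trace.xyz[0]
        nearest = min(means, key=lambda c: np.linalg.norm(sample - means[c]))
        assert nearest == b


def test_class_mix_ordering():
    """Resting is the most frequent behaviour, ruminating the least."""
    mix = synth.CLASS_TIME_SHARE
    assert max(mix, key=mix.get) == "resting"
    assert min(mix, key=mix.get) == "ruminating"
    traces = synth.simulate_dataset(n_cows=4, minutes_per_cow=60,
                                    difficulty="realistic", seed=5)
    labels = np.concatenate([io.drop_unclear(t).labels for t in traces])
    counts = {b: int((labels == b).sum()) for b in io.CLASSES}
    assert max(counts, key=counts.get) == "resting"
    assert min(counts, key=counts.get) == "ruminating"


def test_schedule_respects_mix_and_durations():
    rng = np.random.default_rng(0)
    sched = synth.sample_schedule(3600, synth.CLASS_TIME_SHARE, rng,
                                  unclear_fraction=0.0)
    assert all(d > 0 for _, d in sched.bouts)
    assert sched.total_seconds == pytest.approx(3600, abs=1.0)
    assert all(b in io.CLASSES for b, _ in sched.bouts)
    # no immediate repeats among model classes
    clear = [b for b, _ in sched.bouts]
    assert all(a != b for a, b in zip(clear, clear[1:]))


def test_dataset_sizes():
    traces = synth.simulate_dataset(n_cows=1, minutes_per_cow=1.0,
                                    seed=0, unclear_fraction=0.0)
    assert len(traces) == 1
    assert len(traces[0]) == 300  # 1 min at 5 Hz


def test_dataset_reproducible_byte_identical(tmp_path):
    for d in ("a", "b"):
        (tmp_path / d).mkdir()
        for tr in synth.simulate_dataset(n_cows=2, minutes_per_cow=2,
                                         seed=42):
            io.write_trace(tr, tmp_path / d / f"{tr.cow_id}.csv")
    for f in (tmp_path / "a").iterdir():
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()
    # a different seed gives different data
    other = synth.simulate_dataset(n_cows=2, minutes_per_cow=2, seed=43)
    base = synth.simulate_dataset(n_cows=2, minutes_per_cow=2, seed=42)
    assert not np.array_equal(other[0].xyz[:100], base[0].xyz[:100])


def test_bout_means_converge_to_model_means():
    """Law of large numbers: empirical bout mean approaches the model
    orientation within 3*sd/sqrt(n) on every axis."""
    models, _ = synth.default_profile("separable")
    m = models["resting"]
    sched = synth.BehaviourSchedule([("resting", 600.0)])
    trace = synth.simulate_trace(sched, {"resting": m}, seed=3)
    n = len(trace)
    tol = 3 * np.asarray(m.noise_sd) / np.sqrt(n)
    err = np.abs(trace.xyz.mean(axis=0) - np.asarray(m.mean))
    assert np.all(err < tol), (err, tol)
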