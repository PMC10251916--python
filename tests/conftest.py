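import numpy as np
import pytest

from herdsense import model, pipeline, synth, windowing


@pytest.fixture()
def csv_factory(tmp_path):
    """Write a trace CSV from parallel value lists; returns the path."""

    def write(rows: list[str], header="timestamp,ax,ay,az,behaviour",
              name="trace.csv"):
        path = tmp_path / name
        path.write_text("\n".join([header, *rows]) + "\n")
        return path

    return write


def _desk_split(seed=7):
    traces = synth.simulate_dataset(n_cows=2, minutes_per_cow=20,
                                    difficulty="separable", seed=seed)
    cfg = pipeline.RunConfig(seed=seed)
    frames, _ = pipeline.featurize_traces(traces, cfg)
    units = pipeline.build_windows(frames, cfg)
    return windowing.split_dataset(units, seed=seed)


@pytest.fixture(scope="session")
def small_split():
    """A small separable-profile split shared across model tests."""
    return _desk_split()


@pytest.fixture(scope="session")
def fitted(small_split):
    """A classifier trained briefly on the small separable split."""
    clf = model.BehaviourCNN(small_split)
    return clf.fit(model.TrainConfig(epochs=8, seed=7))
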