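import numpy as np
import pytest

import falltiers as ft


@pytest.fixture(scope="session")
def stream_config():
    return ft.StreamConfig()


@pytest.fixture
def gravity_frame(stream_config):
    """60 identical resting samples (0, 0, 1 g)."""
    n = stream_config.frame_length
    data = np.tile([0.0, 0.0, ft.STANDARD_GRAVITY], (n, 1))
    t = np.arange(n) * stream_config.sampling_interval
    return ft.AccelFrame(data, t, frame_index=0)


def make_frame(data, frame_index=0, dt=0.05):
    data = np.asarray(data, dtype=float)
    return ft.AccelFrame(data, np.arange(len(data)) * dt, frame_index=frame_index)


@pytest.fixture(scope="session")
def trained_model():
    """A 5-feature gain-ratio tree trained on a small synthetic event set."""
    cfg = ft.PipelineConfig(seed=11)
    trace, manifest = ft.generate_benchmark(40, 120, seed=cfg.subseed("generate"))
    data = ft.training_dataset(trace, manifest)
    ranking = ft.oner_rank(data, seed=cfg.subseed("selection"))
    subset = ft.select_top_k(ranking, 5)
    return ft.train_tree(data.project(subset), seed=cfg.subseed("training"))


@pytest.fixture(scope="session")
def small_benchmark():
    trace, manifest = ft.generate_benchmark(30, 90, seed=123)
    return trace, manifest
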