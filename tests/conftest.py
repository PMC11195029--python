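import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from astroevents import detection, synthetic

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def benchmark_scene():
    """Rendered ground-truthed scene used by detection-recovery tests."""
    scene = synthetic.detection_benchmark_scene(seed=7)
    table = synthetic.generate_event_table(scene)
    video, labels = synthetic.render_video(table, scene)
    return scene, table, video, labels


@pytest.fixture(scope="session")
def benchmark_detection(benchmark_scene, tmp_path_factory):
    """Default-config detection run on the benchmark scene."""
    _, _, video, _ = benchmark_scene
    out = tmp_path_factory.mktemp("detect") / "events.roi"
    return detection.detect(video, detection.DetectionConfig(), out)


@pytest.fixture
def small_collection(tmp_path, rng):
    """Tiny hand-built event collection (3 events on an 12x8x8 video)."""
    video = rng.normal(0.0, 0.1, (12, 8, 8)) + 1.0
    mask = np.zeros((12, 8, 8), dtype=bool)
    mask[2:5, 1:3, 1:3] = True      # event 1: frames 2..4
    mask[6:8, 5:7, 2:4] = True      # event 2: frames 6..7
    mask[9:12, 4:6, 5:8] = True     # event 3: frames 9..11
    video[mask] += 5.0
    labels = detection.label_events(mask, 26)
    coll = detection.extract_events(labels, video, tmp_path / "small.roi")
    return coll, video, labels
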