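import numpy as np
import pandas as pd
import pytest

import ifquant as q


@pytest.fixture(scope="session")
def small_scene():
    """A 512x512 scene with 120 cells, shared across read-only tests."""
    params = q.SceneParams(image_shape=(512, 512), pixel_size=0.325,
                           n_cells=120, seed=42)
    image, truth = q.generate_scene(params)
    return params, image, truth


@pytest.fixture(scope="session")
def classified_records(small_scene):
    """Measured, filtered, normalized and classified records of small_scene."""
    _, image, _ = small_scene
    labels, _ = q.segment_nuclei(image, "Hoechst")
    records = q.measure_objects(labels, image)
    filtered, _ = q.size_filter(records)
    normalized, baselines = q.baseline_normalize(filtered, ["Sox10", "tdTomato"])
    calls = q.classify_markers(normalized, q.thresholds_from_preset("tracer_pair2"))
    return calls, baselines


def make_records(areas, image_id="img0", **raw_channels):
    """Hand-built record frame with given areas and raw channel values."""
    n = len(areas)
    data = {"image_id": image_id, "label": np.arange(1, n + 1),
            "area_um2": np.asarray(areas, dtype=float),
            "n_pixels": np.ones(n, dtype=int)}
    for ch, vals in raw_channels.items():
        data[f"raw_{ch}"] = np.asarray(vals, dtype=float)
    return pd.DataFrame(data)
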