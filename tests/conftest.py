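from pathlib import Path

import numpy as np
import pytest

from salamivision import PhantomSpec, PipelineConfig, generate_study
from salamivision.reporting import measure_directory

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_spec():
    """Factory for fast 256 px phantoms used throughout the unit tests."""

    def make(**kw) -> PhantomSpec:
        base = dict(image_size=(256, 256), slice_radius=105, coverage=0.12, seed=0)
        base.update(kw)
        return PhantomSpec(**base)

    return make


@pytest.fixture(scope="session")
def small_study(tmp_path_factory, small_spec):
    """A measured 3-sample x 3-replicate phantom study (shared, read-only).

    Returns (images_dir, results_dir, ground_truth_table).
    """
    root = tmp_path_factory.mktemp("study")
    img_dir, out_dir = root / "images", root / "results"
    specs = {
        "A": small_spec(coverage=0.09, seed=0),
        "B": small_spec(coverage=0.13, seed=0),
        "C": small_spec(coverage=0.17, seed=0),
    }
    truth = generate_study(img_dir, specs=specs, replicates=3, seed=5)
    measure_directory(img_dir, out_dir, PipelineConfig(), cm_per_pixel=0.02)
    return img_dir, out_dir, truth


@pytest.fixture(scope="session")
def reference_summary_path() -> Path:
    return DATA_DIR / "reference_sample_summary.csv"


def solid_image(color, size=(32, 32)) -> np.ndarray:
    arr = np.empty((*size, 3), dtype=np.uint8)
    arr[:] = color
    return arr
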