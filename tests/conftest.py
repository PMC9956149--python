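import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fusagg.imgsim import GeneratorConfig

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def small_config() -> GeneratorConfig:
    """A fast field: a handful of small cells in a 160x160 frame."""
    return GeneratorConfig(
        frame_shape=(160, 160),
        n_cells=8,
        transfected_fraction=1.0,
        cell_radius_px=(8.0, 1.0),
        cell_mean_intensity=100.0,
        background_level=2.0,
        background_noise_sd=0.5,
        aggregates_per_cell_lambda=0.0,
    )


def flood_fill_components(binary: np.ndarray) -> list[set[tuple[int, int]]]:
    """Brute-force 8-connected components by breadth-first flood fill.

    Independent oracle for the labelling used in segmentation; intended for
    small (<= 64x64) grids.
    """
    binary = np.asarray(binary, dtype=bool)
    visited = np.zeros_like(binary)
    components: list[set[tuple[int, int]]] = []
    h, w = binary.shape
    for si, sj in zip(*np.nonzero(binary)):
        if visited[si, sj]:
            continue
        queue = [(int(si), int(sj))]
        visited[si, sj] = True
        comp: set[tuple[int, int]] = set()
        while queue:
            i, j = queue.pop()
            comp.add((i, j))
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ni, nj = i + di, j + dj
                    if 0 <= ni < h and 0 <= nj < w and binary[ni, nj] and not visited[ni, nj]:
                        visited[ni, nj] = True
                        queue.append((ni, nj))
        components.append(comp)
    return components
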