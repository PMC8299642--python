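import numpy as np
import pytest

from tuberphen.synthetic_fixtures import (
    LeafT2Scenario,
    PlantImageScenario,
    default_mri_scene,
    make_mri_scene,
    make_plant_images,
)


@pytest.fixture(scope="session")
def plant_fixture():
    """One rendered plant image at canopy closure with its ground truth."""
    scenario = PlantImageScenario(seed=7, dases=(46,))
    (image, truth), = make_plant_images(scenario)
    return image, truth


@pytest.fixture(scope="session")
def mri_sessions():
    """Default 6-tuber + mother scene, all four sessions."""
    return make_mri_scene(default_mri_scene(seed=3))


def iou(a, b) -> float:
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 1.0


def dice(a, b) -> float:
    denom = a.sum() + b.sum()
    return float(2.0 * (a & b).sum() / denom) if denom else 1.0


def flood_fill_count(binary: np.ndarray, connectivity: int):
    """Brute-force BFS connected-component oracle for 3-D binary arrays."""
    binary = np.asarray(binary, dtype=bool)
    if connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                   (0, 0, 1), (0, 0, -1)]
    else:
        offsets = [(dz, dy, dx)
                   for dz in (-1, 0, 1) for dy in (-1, 0, 1)
                   for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
    visited = np.zeros_like(binary, dtype=bool)
    sizes = []
    shape = binary.shape
    for start in zip(*np.nonzero(binary)):
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        size = 0
        while stack:
            z, y, x = stack.pop()
            size += 1
            for dz, dy, dx in offsets:
                nz, ny, nx = z + dz, y + dy, x + dx
                if 0 <= nz < shape[0] and 0 <= ny < shape[1] \
                        and 0 <= nx < shape[2] and binary[nz, ny, nx] \
                        and not visited[nz, ny, nx]:
                    visited[nz, ny, nx] = True
                    stack.append((nz, ny, nx))
        sizes.append(size)
    return len(sizes), sorted(sizes)
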