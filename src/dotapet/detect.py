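"""From score maps to candidate lesions.

Prediction maps are binarized at a fixed score threshold (default 0.05,
strict ``>``), grouped into 8-connected components within each trans-axial
slice — the network treats every slice as a discrete entity, so components
are 2D — and small components are removed by a pixel-area noise filter
(components with area below the filter are dropped; area equal to the
filter is kept).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

STANDARD_AREA_FILTERS = (5, 7, 10, 15, 20)

_STRUCT_8 = np.ones((3, 3), bool)
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class DetectionConfig:
    binarize_threshold: float = 0.05
    area_filter_px: int = 15
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not 0.0 <= self.binarize_threshold < 1.0:
            raise ValueError("binarize_threshold must be in [0, 1)")
        if self.area_filter_px < 0:
            raise ValueError("area_filter_px must be non-negative")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class Component:
    """One connected component of candidate lesion pixels.

    In the detection pipeline components are 2D: ``coords`` holds (row, col)
    pairs on slice ``slice_index``.  The annotation stage matches 3D lesion
    objects instead; those components carry (slice, row, col) triples and a
    ``slice_index`` of −1.
    """

    component_id: int
    slice_index: int
    coords: tuple[tuple[int, ...], ...]
    mean_score: float
    peak_score: float

    @property
    def area(self) -> int:
        return len(self.coords)

    @property
    def voxels(self) -> frozenset[tuple[int, int, int]]:
        if self.coords and len(self.coords[0]) == 3:
            return frozenset(self.coords)
        z = self.slice_index
        return frozenset((z, r, c) for r, c in self.coords)


@dataclass
class ComponentSet:
    components: list[Component] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.components)

    def __iter__(self):
        return iter(self.components)

    def areas(self) -> list[int]:
        return [c.area for c in self.components]


def binarize(score_map: np.ndarray, threshold: float) -> np.ndarray:
    """Pixel is lesion iff score strictly exceeds the threshold."""
    score_map = np.asarray(score_map)
    if score_map.min() < 0 or score_map.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    return score_map > threshold


def connected_components(binary: np.ndarray, connectivity: int = 8,
                         slice_index: int = 0,
                         score_map: np.ndarray | None = None,
                         first_id: int = 1) -> ComponentSet:
    """Label one binary slice; label order follows the row-major first pixel."""
    structure = _STRUCT_8 if connectivity == 8 else _STRUCT_4
    labeled, n = ndimage.label(binary, structure=structure)
    comps = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labeled == lab)
        if score_map is not None:
            vals = score_map[tuple(coords.T)]
            mean_s, peak_s = float(vals.mean()), float(vals.max())
        else:
            mean_s = peak_s = 1.0
        comps.append(Component(first_id + lab - 1, slice_index,
                               tuple((int(r), int(c)) for r, c in coords),
                               mean_s, peak_s))
    return ComponentSet(comps)


def stack_components(binary_stack: np.ndarray, connectivity: int = 8,
                     score_stack: np.ndarray | None = None) -> ComponentSet:
    """Per-slice components over a whole study, ids unique across slices."""
    comps: list[Component] = []
    next_id = 1
    for z in range(binary_stack.shape[0]):
        cs = connected_components(
            binary_stack[z], connectivity, slice_index=z,
            score_map=None if score_stack is None else score_stack[z],
            first_id=next_id)
        comps.extend(cs.components)
        next_id += len(cs)
    return ComponentSet(comps)


def area_filter(components: ComponentSet, min_area_px: int) -> ComponentSet:
    """Drop components whose pixel area is below the filter (strictly)."""
    return ComponentSet([c for c in components if c.area >= min_area_px])


def detect_stack(score_stack: np.ndarray,
                 config: DetectionConfig = DetectionConfig()) -> ComponentSet:
    """binarize → per-slice connected components → area filter."""
    binary = binarize(score_stack, config.binarize_threshold)
    comps = stack_components(binary, config.connectivity, score_stack)
    return area_filter(comps, config.area_filter_px)


def components_to_mask(components: ComponentSet,
                       shape: tuple[int, int, int]) -> np.ndarray:
    out = np.zeros(shape, bool)
    for comp in components:
        for z, r, c in comp.voxels:
            out[z, r, c] = True
    return out
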