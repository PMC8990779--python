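"""Connected-component berry counting with geometric and qualitative filters.

Counting operates exclusively on pixels of the berry class; the edge
class exists to keep touching berries as separate components.  Every
extracted component then has to survive four filter stages before it is
counted:

1. *size* — components smaller than ``min_area`` pixels (default 25) are
   artifacts, not berries;
2. *shape* — berries are roughly round, so the minor/major axis ratio
   must reach ``min_axis_ratio`` (default 0.3);
3. *fill* — the actual pixel area must reach a fraction of the expected
   circle area pi*r^2, with the radius taken as the mean of the two
   semi-axes;
4. *edge support* — a confident berry is well surrounded by berry-edge
   pixels, measured as the fraction of its boundary pixels with an edge
   pixel in their 8-neighbourhood.

The stage that first rejects a component is recorded, so counts can be
audited per filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from . import masks

FILTER_STAGES = ("size", "shape", "fill", "edge")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the four berry filter stages."""

    min_area: int = 25
    min_axis_ratio: float = 0.3
    area_fill_fraction: float = 0.5
    edge_surround_fraction: float = 0.5
    connectivity: int = 8

    def __post_init__(self):
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        for name in ("min_axis_ratio", "area_fill_fraction", "edge_surround_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class BerryComponent:
    """One connected berry-class region and its moment geometry."""

    label: int
    pixels: np.ndarray            # (n, 2) array of (row, col) coordinates
    area: int
    centroid: tuple[float, float]
    major_axis: float             # full axis lengths of the equivalent ellipse
    minor_axis: float
    edge_surround: float = float("nan")
    rejected_by: str | None = None

    @property
    def axis_ratio(self) -> float:
        return self.minor_axis / self.major_axis

    @property
    def radius(self) -> float:
        """Mean of the two semi-axes, the radius used by the fill filter."""
        return (self.minor_axis + self.major_axis) / 4.0

    @property
    def expected_area(self) -> float:
        return math.pi * self.radius ** 2


@dataclass
class CountResult:
    count: int
    retained: list[BerryComponent] = field(default_factory=list)
    rejected: list[BerryComponent] = field(default_factory=list)

    def rejected_by_stage(self) -> dict[str, int]:
        out = {stage: 0 for stage in FILTER_STAGES}
        for comp in self.rejected:
            out[comp.rejected_by] += 1
        return out


def _component_axes(coords: np.ndarray) -> tuple[float, float]:
    """Full major/minor axis lengths of the equivalent ellipse of a pixel set.

    Uses the eigenvalues of the second central moment matrix, with a
    1/12 per-pixel variance term so that thin or single-row regions get
    a nonzero minor axis reflecting their 1-pixel extent.  A degenerate
    single pixel reports both axes as 1.
    """
    if len(coords) == 1:
        return 1.0, 1.0
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords) + np.eye(2) / 12.0
    evals = np.linalg.eigvalsh(cov)
    minor, major = (4.0 * np.sqrt(np.maximum(evals, 0.0))).tolist()
    return max(major, 1.0), max(min(minor, major), 1.0)


def extract_components(mask, config: FilterConfig | None = None) -> list[BerryComponent]:
    """Partition the berry-class pixels of ``mask`` into connected components."""
    config = config or FilterConfig()
    m = masks.as_mask(mask)
    berry = m == masks.BERRY
    labels = measure.label(berry, connectivity=1 if config.connectivity == 4 else 2)
    comps: list[BerryComponent] = []
    for lab in range(1, labels.max() + 1):
        coords = np.argwhere(labels == lab)
        major, minor = _component_axes(coords)
        comps.append(
            BerryComponent(
                label=lab,
                pixels=coords,
                area=len(coords),
                centroid=tuple(coords.mean(axis=0)),
                major_axis=major,
                minor_axis=minor,
            )
        )
    return comps


def _edge_surround(component: BerryComponent, mask: np.ndarray) -> float:
    """Fraction of boundary pixels with a berry-edge pixel in the 8-neighbourhood."""
    grid = np.zeros(mask.shape, dtype=bool)
    grid[component.pixels[:, 0], component.pixels[:, 1]] = True
    interior = ndimage.binary_erosion(grid, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]), border_value=0)
    boundary = grid & ~interior
    edge = mask == masks.BERRY_EDGE
    edge_near = ndimage.binary_dilation(edge, structure=np.ones((3, 3), bool))
    n_boundary = np.count_nonzero(boundary)
    if n_boundary == 0:
        return 0.0
    return float(np.count_nonzero(boundary & edge_near) / n_boundary)


def _first_failing_stage(c: BerryComponent, config: FilterConfig) -> str | None:
    if c.area < config.min_area:
        return "size"
    if c.axis_ratio < config.min_axis_ratio:
        return "shape"
    if c.area < config.area_fill_fraction * c.expected_area:
        return "fill"
    if c.edge_surround < config.edge_surround_fraction:
        return "edge"
    return None


def filter_components(
    components: list[BerryComponent], config: FilterConfig | None = None
) -> CountResult:
    """Apply the four filter stages; rejection records the first failing stage."""
    config = config or FilterConfig()
    retained, rejected = [], []
    for c in components:
        stage = _first_failing_stage(c, config)
        if stage is None:
            retained.append(c)
        else:
            c.rejected_by = stage
            rejected.append(c)
    return CountResult(count=len(retained), retained=retained, rejected=rejected)


def count_berries(mask, config: FilterConfig | None = None) -> CountResult:
    """Count berries in a mask: extract components, measure, filter."""
    config = config or FilterConfig()
    m = masks.as_mask(mask)
    comps = extract_components(m, config)
    for c in comps:
        c.edge_surround = _edge_surround(c, m)
    return filter_components(comps, config)


def berry_size_stats(result: CountResult) -> list[tuple[float, float]]:
    """(area, diameter) per retained berry; diameter is the equivalent-circle one."""
    return [(float(c.area), 2.0 * math.sqrt(c.area / math.pi)) for c in result.retained]


class BerryCounter:
    """Estimator-style wrapper around :func:`count_berries`.

    ``predict`` maps a list of masks to an integer count per mask, which
    composes with model-selection utilities expecting the
    fit/predict protocol.  There is nothing to fit; ``fit`` validates
    the configuration and returns ``self``.
    """

    def __init__(self, min_area: int = 25, min_axis_ratio: float = 0.3,
                 area_fill_fraction: float = 0.5,
                 edge_surround_fraction: float = 0.5, connectivity: int = 8):
        self.min_area = min_area
        self.min_axis_ratio = min_axis_ratio
        self.area_fill_fraction = area_fill_fraction
        self.edge_surround_fraction = edge_surround_fraction
        self.connectivity = connectivity

    def get_params(self, deep: bool = True) -> dict:
        return {
            "min_area": self.min_area,
            "min_axis_ratio": self.min_axis_ratio,
            "area_fill_fraction": self.area_fill_fraction,
            "edge_surround_fraction": self.edge_surround_fraction,
            "connectivity": self.connectivity,
        }

    def set_params(self, **params) -> "BerryCounter":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @property
    def config(self) -> FilterConfig:
        return FilterConfig(**self.get_params())

    def fit(self, X=None, y=None) -> "BerryCounter":
        self.config_ = self.config  # validates thresholds
        return self

    def count(self, mask) -> CountResult:
        return count_berries(mask, self.config)

    def predict(self, X) -> np.ndarray:
        return np.array([self.count(m).count for m in X], dtype=int)
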