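"""Stroma CD3 density from an IHC slide: a reference brown-blob cell
detector, patch-grid stroma area, and centroid-in-stroma counting.

The detector is a documented stand-in for dedicated cell-segmentation
software: it thresholds a brown-likeness channel (min(R, G) relative to B,
the DAB chromogen proxy), labels 8-connected components and keeps those
within an area window.  Density = cells with centroid in an STR grid cell
divided by the stroma area in mm^2; the area uses the stride footprint so
overlapping patches are not double-counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure

from deepimmune.tissue_maps import SegmentationMap, TissueClass

log = logging.getLogger(__name__)

DETECTIONS_CSV_COLUMNS = ["slide_id", "x_px", "y_px", "area_px2"]
DENSITY_CSV_COLUMNS = [
    "patient_id", "n_cells_in_stroma", "stroma_area_mm2", "density_cells_per_mm2",
]


@dataclass
class CellDetections:
    """CD3+ cell centroids in slide pixel coordinates (origin top-left,
    x rightward, y downward) with component areas in px^2."""

    slide_id: str
    cells: np.ndarray  # (n, 3): x_px, y_px, area_px2

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float).reshape(-1, 3)
        if self.cells.size and np.any(self.cells[:, 2] <= 0):
            raise ValueError("cell areas must be positive")

    def __len__(self) -> int:
        return self.cells.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slide_id": self.slide_id,
                "x_px": self.cells[:, 0],
                "y_px": self.cells[:, 1],
                "area_px2": self.cells[:, 2],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, slide_id: str) -> "CellDetections":
        sub = df[df["slide_id"] == slide_id]
        return cls(slide_id, sub[["x_px", "y_px", "area_px2"]].to_numpy())


@dataclass(frozen=True)
class DensityResult:
    slide_id: str
    n_cells_in_stroma: int
    stroma_area_mm2: float
    density_cells_per_mm2: float


def brown_channel(image: np.ndarray) -> np.ndarray:
    """Unit-scaled brown-likeness: how much min(R, G) exceeds B."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB raster")
    img = image.astype(float)
    return np.clip((np.minimum(img[..., 0], img[..., 1]) - img[..., 2]) / 255.0, 0, 1)


def detect_cells(
    ihc_image: np.ndarray,
    slide_id: str = "slide",
    min_area_px2: int = 30,
    max_area_px2: int = 5000,
    intensity_threshold: float = 0.3,
) -> CellDetections:
    """Reference blob detector for DAB-brown cells on synthetic IHC rasters."""
    if not (0 < min_area_px2 <= max_area_px2):
        raise ValueError("need 0 < min_area_px2 <= max_area_px2")
    mask = brown_channel(ihc_image) > intensity_threshold
    labelled = measure.label(mask, connectivity=2)
    cells = []
    for region in measure.regionprops(labelled):
        if min_area_px2 <= region.area <= max_area_px2:
            cy, cx = region.centroid
            cells.append((cx, cy, float(region.area)))
    return CellDetections(slide_id, np.array(cells, dtype=float).reshape(-1, 3))


def stroma_area_mm2(seg: SegmentationMap) -> float:
    """Stroma area: #STR cells x (stride_px * mpp)^2 / 1e6 mm^2."""
    n_str = int(np.sum(seg.labels == TissueClass.STR))
    if n_str == 0:
        raise ValueError("no stroma ROI")
    cell_um = seg.meta.stride_px * seg.meta.microns_per_pixel
    return n_str * cell_um**2 / 1e6


def stroma_cd3_density(
    detections: CellDetections, seg: SegmentationMap
) -> DensityResult:
    """Count detections whose centroid falls in an STR grid cell and divide
    by the stroma area.  Grid cell (r, c) covers the half-open stride
    footprint [r*stride, (r+1)*stride) x [c*stride, (c+1)*stride)."""
    area = stroma_area_mm2(seg)
    stride = seg.meta.stride_px
    n_in = 0
    if len(detections):
        cc = np.floor(detections.cells[:, 0] / stride).astype(int)
        rr = np.floor(detections.cells[:, 1] / stride).astype(int)
        rows, cols = seg.shape
        inside = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
        n_in = int(
            np.sum(seg.labels[rr[inside], cc[inside]] == TissueClass.STR)
        )
    return DensityResult(
        slide_id=detections.slide_id,
        n_cells_in_stroma=n_in,
        stroma_area_mm2=area,
        density_cells_per_mm2=n_in / area,
    )


def group_density_summary(
    densities: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    pairs: list[tuple] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean/sd/n plus Welch t-tests for group pairs.

    Pairs default to all pairs of observed group labels; any pair involving
    a group with fewer than 2 patients is skipped with a warning.
    Returns (summary table indexed by group, pairwise test table).
    """
    df = pd.DataFrame({"density": np.asarray(densities, dtype=float),
                       "group": np.asarray(groups)})
    summary = df.groupby("group")["density"].agg(mean="mean", sd="std", n="size")
    if pairs is None:
        pairs = list(combinations(summary.index.tolist(), 2))
    tests = []
    for a, b in pairs:
        na = int(summary.loc[a, "n"]) if a in summary.index else 0
        nb = int(summary.loc[b, "n"]) if b in summary.index else 0
        if na < 2 or nb < 2:
            log.warning("skipping pair (%s, %s): group with < 2 patients", a, b)
            continue
        xa = df.loc[df["group"] == a, "density"]
        xb = df.loc[df["group"] == b, "density"]
        t, p = stats.ttest_ind(xa, xb, equal_var=False)
        tests.append({"group_a": a, "group_b": b, "t": float(t), "p": float(p)})
    return summary, pd.DataFrame(tests, columns=["group_a", "group_b", "t", "p"])


def write_densities(results: list[DensityResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": r.slide_id,
                "n_cells_in_stroma": r.n_cells_in_stroma,
                "stroma_area_mm2": r.stroma_area_mm2,
                "density_cells_per_mm2": r.density_cells_per_mm2,
            }
            for r in results
        ],
        columns=DENSITY_CSV_COLUMNS,
    ).to_csv(path, index=False, float_format="%.10g")
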