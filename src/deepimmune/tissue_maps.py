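"""Data model, I/O, tiling and max-probability segmentation for patch-grid
tissue probability maps.

A slide is tiled into overlapping ``patch_size_px`` square patches on a
regular stride grid; a pluggable classifier assigns each patch a probability
vector over the nine fixed tissue classes.  The per-patch argmax defines the
tissue segmentation used by all downstream scores.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

#: The nine tissue classes, in fixed alphabetical order.  This order is
#: shared by every probability map, file and colour table in the package.
CLASS_LABELS: tuple[str, ...] = (
    "ADI", "BAC", "DEB", "LYM", "MUC", "MUS", "NOR", "STR", "TUM",
)

N_CLASSES = len(CLASS_LABELS)


class TissueClass(enum.IntEnum):
    """Tissue category of a patch; integer value is the fixed class index."""

    ADI = 0  # adipose
    BAC = 1  # slide background
    DEB = 2  # debris
    LYM = 3  # lymphocyte aggregates
    MUC = 4  # mucus
    MUS = 5  # smooth muscle
    NOR = 6  # normal mucosa
    STR = 7  # stroma
    TUM = 8  # tumour epithelium


@dataclass(frozen=True)
class SlideMeta:
    """Tiling and physical metadata for one slide."""

    slide_id: str
    patch_size_px: int = 224
    stride_px: int = 112
    microns_per_pixel: float = 0.5
    stain: str = "HE"

    def __post_init__(self) -> None:
        if self.patch_size_px <= 0:
            raise ValueError("patch_size_px must be positive")
        if not (0 < self.stride_px <= self.patch_size_px):
            raise ValueError("stride_px must satisfy 0 < stride <= patch_size")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        if self.stain not in ("HE", "IHC"):
            raise ValueError(f"stain must be 'HE' or 'IHC', got {self.stain!r}")


@dataclass
class ProbabilityMap:
    """Per-slide grid of 9-class patch probabilities.

    ``grid[r, c, k]`` is P(class k | patch anchored at pixel
    (r * stride, c * stride)).  Each cell's vector sums to 1.
    """

    meta: SlideMeta
    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.validate()

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape[0], self.grid.shape[1]

    def validate(self) -> None:
        if self.grid.ndim != 3 or self.grid.shape[2] != N_CLASSES:
            raise ValueError(
                f"grid must be rows x cols x {N_CLASSES}, got {self.grid.shape}"
            )
        if self.grid.shape[0] < 1 or self.grid.shape[1] < 1:
            raise ValueError("grid must have at least one cell")
        if np.any(self.grid < 0) or np.any(self.grid > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        sums = self.grid.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = np.argwhere(np.abs(sums - 1.0) > 1e-6)[0]
            raise ValueError(
                f"cell {tuple(bad)} probabilities sum to {sums[tuple(bad)]:.8f}, not 1"
            )


@dataclass
class SegmentationMap:
    """Per-grid-cell tissue label (argmax of a :class:`ProbabilityMap`)."""

    meta: SlideMeta
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= N_CLASSES:
            raise ValueError("labels contain invalid class indices")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def tile_grid(
    image_height_px: int,
    image_width_px: int,
    patch_size_px: int = 224,
    stride_px: int = 112,
) -> list[tuple[int, int, int, int]]:
    """Enumerate patch anchors ``(row, col, y_px, x_px)`` over an image.

    Patches lie fully inside the image; incomplete right/bottom margins are
    dropped.  Grid extent per axis is ``floor((dim - patch) / stride) + 1``.
    """
    if not (0 < stride_px <= patch_size_px):
        raise ValueError("stride_px must satisfy 0 < stride <= patch_size")
    if image_height_px < patch_size_px or image_width_px < patch_size_px:
        raise ValueError(
            "slide too small to tile: "
            f"{image_height_px}x{image_width_px} < patch {patch_size_px}"
        )
    n_rows = (image_height_px - patch_size_px) // stride_px + 1
    n_cols = (image_width_px - patch_size_px) // stride_px + 1
    return [
        (r, c, r * stride_px, c * stride_px)
        for r in range(n_rows)
        for c in range(n_cols)
    ]


def classify_patches(
    image: np.ndarray,
    anchors: Sequence[tuple[int, int, int, int]],
    classifier: Callable[[np.ndarray], np.ndarray],
    meta: SlideMeta,
) -> ProbabilityMap:
    """Run a pluggable patch classifier over a tiling grid.

    ``classifier`` maps an RGB patch to a vector of 9 nonnegative scores,
    which are renormalized to sum to 1 before storage.  Defines the contract
    any patch classifier (trained CNN or mock) must satisfy.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be an H x W x 3 RGB raster")
    n_rows = max(a[0] for a in anchors) + 1
    n_cols = max(a[1] for a in anchors) + 1
    grid = np.zeros((n_rows, n_cols, N_CLASSES), dtype=float)
    p = meta.patch_size_px
    for r, c, y, x in anchors:
        patch = image[y : y + p, x : x + p]
        out = np.asarray(classifier(patch), dtype=float).ravel()
        if out.shape != (N_CLASSES,):
            raise ValueError(
                f"classifier returned {out.shape[0]}-vector for patch "
                f"(row={r}, col={c}); expected {N_CLASSES}"
            )
        if np.any(out < 0):
            raise ValueError(
                f"classifier returned negative score for patch (row={r}, col={c})"
            )
        total = out.sum()
        if total <= 0:
            raise ValueError(
                f"classifier returned all-zero vector for patch (row={r}, col={c})"
            )
        grid[r, c] = out / total
    return ProbabilityMap(meta=meta, grid=grid)


def segment(pmap: ProbabilityMap) -> SegmentationMap:
    """Max-probability tissue segmentation; exact ties take the lowest index."""
    pmap.validate()
    labels = np.argmax(pmap.grid, axis=2)  # np.argmax already takes first max
    return SegmentationMap(meta=pmap.meta, labels=labels)


# ---------------------------------------------------------------------------
# On-disk map store: <slide_dir>/meta.json plus probs.npz or probs.csv

def _meta_to_dict(meta: SlideMeta) -> dict:
    return {
        "slide_id": meta.slide_id,
        "patch_size_px": meta.patch_size_px,
        "stride_px": meta.stride_px,
        "microns_per_pixel": meta.microns_per_pixel,
        "stain": meta.stain,
        "class_order": list(CLASS_LABELS),
    }


def write_map(pmap: ProbabilityMap, slide_dir: str | Path, fmt: str = "csv") -> Path:
    """Write a probability map to ``slide_dir`` in the dense npz or the
    long-format CSV dialect.  Returns the directory written."""
    slide_dir = Path(slide_dir)
    slide_dir.mkdir(parents=True, exist_ok=True)
    (slide_dir / "meta.json").write_text(json.dumps(_meta_to_dict(pmap.meta), indent=1))
    if fmt == "npz":
        np.savez(slide_dir / "probs.npz", grid=pmap.grid)
    elif fmt == "csv":
        rows, cols = pmap.shape
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        df = pd.DataFrame({"row": rr.ravel(), "col": cc.ravel()})
        flat = pmap.grid.reshape(-1, N_CLASSES)
        for k, lab in enumerate(CLASS_LABELS):
            df[lab] = flat[:, k]
        df.to_csv(slide_dir / "probs.csv", index=False, float_format="%.12g")
    else:
        raise ValueError(f"unknown map format {fmt!r}; use 'npz' or 'csv'")
    return slide_dir


def read_map(slide_dir: str | Path) -> ProbabilityMap:
    """Read a probability map written by :func:`write_map` (either dialect)."""
    slide_dir = Path(slide_dir)
    meta_path = slide_dir / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata file {meta_path}")
    raw = json.loads(meta_path.read_text())
    required = {"slide_id", "patch_size_px", "stride_px", "microns_per_pixel",
                "stain", "class_order"}
    missing = required - raw.keys()
    if missing:
        raise ValueError(f"meta.json missing keys: {sorted(missing)}")
    if tuple(raw["class_order"]) != CLASS_LABELS:
        raise ValueError(
            "class order mismatch: file declares "
            f"{raw['class_order']}, expected {list(CLASS_LABELS)}"
        )
    meta = SlideMeta(
        slide_id=raw["slide_id"],
        patch_size_px=int(raw["patch_size_px"]),
        stride_px=int(raw["stride_px"]),
        microns_per_pixel=float(raw["microns_per_pixel"]),
        stain=raw["stain"],
    )
    npz_path = slide_dir / "probs.npz"
    csv_path = slide_dir / "probs.csv"
    if npz_path.exists():
        with np.load(npz_path) as data:
            grid = data["grid"]
    elif csv_path.exists():
        df = pd.read_csv(csv_path)
        expected_cols = ["row", "col", *CLASS_LABELS]
        if list(df.columns) != expected_cols:
            raise ValueError(
                f"probs.csv columns {list(df.columns)} do not match {expected_cols}"
            )
        rows = int(df["row"].max()) + 1
        cols = int(df["col"].max()) + 1
        if len(df) != rows * cols:
            raise ValueError(
                f"probs.csv has {len(df)} rows; expected {rows * cols} "
                f"for a {rows}x{cols} grid"
            )
        grid = np.zeros((rows, cols, N_CLASSES), dtype=float)
        grid[df["row"].to_numpy(), df["col"].to_numpy()] = df[list(CLASS_LABELS)].to_numpy()
    else:
        raise FileNotFoundError(f"no probs.npz or probs.csv in {slide_dir}")
    return ProbabilityMap(meta=meta, grid=grid)
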