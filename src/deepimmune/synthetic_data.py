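"""Synthetic cohorts with the statistical structure the analysis assumes.

Generates (a) pixel-level tissue label rasters and RGB renderings with a
colour-lookup mock patch classifier, (b) a fast path producing patch-grid
probability maps directly, and (c) whole cohorts: clinical covariates,
CD3 detections placed in stroma at group-calibrated densities, and
exponential survival calibrated to group 5-year rates.

Default group parameters (CD3 density means 844/1088/1246/1708 cells/mm^2
for composite scores 1-4; 5-year survivals 58.2%/69.2%/77.1%/87.4%) mirror
the cohort-level quantities the recovery tests target; every default is
overridable.  The exponential form makes hazard ratios between groups
analytically available: lambda_g = -ln(S5_g) / 5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from skimage import draw

from deepimmune.ihc_density import CellDetections, stroma_area_mm2
from deepimmune.tissue_maps import (
    CLASS_LABELS,
    N_CLASSES,
    ProbabilityMap,
    SegmentationMap,
    SlideMeta,
    TissueClass,
)

#: Fixed render colours, one distinct RGB per tissue class (index order).
CLASS_COLORS: dict[int, tuple[int, int, int]] = {
    TissueClass.ADI: (255, 220, 150),
    TissueClass.BAC: (255, 255, 255),
    TissueClass.DEB: (120, 120, 120),
    TissueClass.LYM: (60, 60, 200),
    TissueClass.MUC: (170, 255, 255),
    TissueClass.MUS: (200, 120, 255),
    TissueClass.NOR: (80, 200, 80),
    TissueClass.STR: (255, 150, 200),
    TissueClass.TUM: (200, 40, 40),
}

_COLOR_TO_CLASS = {color: int(idx) for idx, color in CLASS_COLORS.items()}


@dataclass
class SimConfig:
    """All generator knobs; ``seed`` fully determines every output."""

    n_patients: int = 60
    cohort_id: str = "sim"
    # stroma fraction target distribution (clipped)
    tsr_mean: float = 0.5
    tsr_sd: float = 0.15
    # latent infiltration level theta ~ Uniform(theta_range)
    theta_range: tuple[float, float] = (0.02, 0.48)
    theta_cutpoints: tuple[float, float] | None = None  # default: range tertiles
    dirichlet_alpha: float | None = 200.0  # None -> noiseless maps
    grid_dims: tuple[int, int] = (30, 30)
    patch_size_px: int = 224
    stride_px: int = 112
    microns_per_pixel: float = 0.5
    tsr_cutoff: float = 0.5
    # CD3 density per composite score group 1..4, cells/mm^2
    group_density_means: tuple[float, ...] = (844.0, 1088.0, 1246.0, 1708.0)
    density_sd_frac: float = 0.10
    # 5-year survival per composite score group 1..4
    group_five_year_survival: tuple[float, ...] = (0.582, 0.692, 0.771, 0.874)
    censor_horizon_years: float = 10.0
    dropout_rate: float = 0.0
    # covariate distributions
    age_mean: float = 62.0
    age_sd: float = 11.0
    p_female: float = 0.4
    stage_probs: tuple[float, float, float] = (0.2, 0.45, 0.35)
    p_rectum: float = 0.45
    p_high_grade: float = 0.2
    p_cea_abnormal: float = 0.3
    stage_score_assoc: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for s5 in self.group_five_year_survival:
            if not (0 < s5 < 1):
                raise ValueError(f"group 5-year survival {s5} must lie in (0, 1)")
        lo, hi = self.theta_range
        if not (0 <= lo < hi <= 1):
            raise ValueError("theta_range must satisfy 0 <= lo < hi <= 1")

    @property
    def hazards(self) -> tuple[float, ...]:
        """Exponential rate per score group: lambda_g = -ln(S5_g)/5."""
        return tuple(-math.log(s5) / 5.0 for s5 in self.group_five_year_survival)

    @property
    def theta_cuts(self) -> tuple[float, float]:
        if self.theta_cutpoints is not None:
            return self.theta_cutpoints
        lo, hi = self.theta_range
        return (lo + (hi - lo) / 3.0, lo + 2.0 * (hi - lo) / 3.0)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("theta_range", "theta_cutpoints", "grid_dims",
                    "group_density_means", "group_five_year_survival",
                    "stage_probs"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SimulatedCohort:
    """Everything :func:`simulate_cohort` emits, keyed by patient id."""

    config: SimConfig
    clinical: pd.DataFrame
    truth: pd.DataFrame
    maps: dict[str, tuple[ProbabilityMap, SegmentationMap]]
    ihc_segs: dict[str, SegmentationMap]
    detections: dict[str, CellDetections]


# ---------------------------------------------------------------------------
# label rasters, rendering, mock classifier

def simulate_label_image(
    target_tsr: float,
    theta: float,
    dims: tuple[int, int] = (448, 448),
    seed: int = 0,
    tolerance: float = 0.02,
    max_iter: int = 500,
) -> np.ndarray:
    """Pixel-level class-coded raster: a tumour-bed canvas with planted
    stroma ellipses (grown until the STR/(STR+TUM) pixel fraction is within
    ``tolerance`` of ``target_tsr``), lymphocyte-aggregate disks inside the
    stroma with coverage ``theta``, and a background/normal border."""
    if not (0 <= target_tsr <= 1) or not (0 <= theta <= 1):
        raise ValueError("target_tsr and theta must lie in [0, 1]")
    h, w = dims
    rng = np.random.default_rng(seed)
    labels = np.full((h, w), int(TissueClass.TUM), dtype=np.int8)
    margin = max(4, min(h, w) // 12)
    if h <= 2 * margin or w <= 2 * margin:
        raise ValueError(f"dims {dims} too small for a tumour bed with margin {margin}")
    # border: outer half background, inner half normal mucosa / adipose
    yy, xx = np.mgrid[0:h, 0:w]
    edge_dist = np.minimum.reduce([yy, xx, h - 1 - yy, w - 1 - xx])
    labels[edge_dist < margin // 2] = int(TissueClass.BAC)
    inner_ring = (edge_dist >= margin // 2) & (edge_dist < margin)
    labels[inner_ring & (xx < w // 2)] = int(TissueClass.NOR)
    labels[inner_ring & (xx >= w // 2)] = int(TissueClass.ADI)
    bed = edge_dist >= margin
    n_bed = int(bed.sum())

    if target_tsr > 0:
        max_r = max(3, min(h, w) // 6)
        for _ in range(max_iter):
            n_str = int(np.sum(labels[bed] == TissueClass.STR))
            frac = n_str / n_bed
            if abs(frac - target_tsr) <= tolerance:
                break
            deficit_px = (target_tsr - frac) * n_bed
            if deficit_px <= 0:
                break
            r = min(max_r, max(2.0, math.sqrt(deficit_px / math.pi)))
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            ry = r * rng.uniform(0.7, 1.3)
            rx = r * rng.uniform(0.7, 1.3)
            rr, cc = draw.ellipse(cy, cx, ry, rx, shape=(h, w))
            keep = bed[rr, cc]
            labels[rr[keep], cc[keep]] = int(TissueClass.STR)
        n_str = int(np.sum(labels[bed] == TissueClass.STR))
        if abs(n_str / n_bed - target_tsr) > tolerance:
            raise ValueError(
                f"could not reach stroma target {target_tsr} at dims {dims} "
                f"within {max_iter} iterations (got {n_str / n_bed:.3f})"
            )

    if theta > 0:
        str_mask = labels == TissueClass.STR
        n_str_px = int(str_mask.sum())
        target_lym = int(round(theta * n_str_px))
        ys, xs = np.nonzero(str_mask)
        planted = 0
        for _ in range(max_iter * 10):
            if planted >= target_lym or ys.size == 0:
                break
            i = rng.integers(ys.size)
            r = rng.uniform(2, 5)
            rr, cc = draw.disk((ys[i], xs[i]), r, shape=(h, w))
            keep = labels[rr, cc] == TissueClass.STR
            labels[rr[keep], cc[keep]] = int(TissueClass.LYM)
            planted += int(keep.sum())
    return labels


def render_rgb(labels: np.ndarray) -> np.ndarray:
    """Map a class-coded raster to RGB with the fixed colour table."""
    labels = np.asarray(labels)
    out = np.zeros((*labels.shape, 3), dtype=np.uint8)
    for idx, color in CLASS_COLORS.items():
        out[labels == idx] = color
    return out


def save_image(rgb: np.ndarray, path: str | Path) -> None:
    """Write a rendered RGB raster as PNG/TIFF."""
    Image.fromarray(np.asarray(rgb, dtype=np.uint8)).save(path)


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF raster back as an H x W x 3 uint8 array."""
    return np.asarray(Image.open(path).convert("RGB"))


def make_mock_classifier(alpha: float | None = None, rng=None):
    """Colour-lookup patch classifier for rendered synthetic slides.

    Returns per-class pixel fractions of the patch, optionally perturbed
    with Dirichlet(alpha * fractions) noise on the observed support;
    ``alpha=None`` (or inf) gives exact fractions.
    """
    noiseless = alpha is None or not np.isfinite(alpha)
    if not noiseless and rng is None:
        rng = np.random.default_rng()

    def classify(patch: np.ndarray) -> np.ndarray:
        flat = np.asarray(patch).reshape(-1, 3)
        colors, counts = np.unique(flat, axis=0, return_counts=True)
        frac = np.zeros(N_CLASSES)
        for color, count in zip(colors, counts):
            idx = _COLOR_TO_CLASS.get(tuple(int(v) for v in color))
            if idx is None:
                raise ValueError(f"unknown color {tuple(color)} in patch")
            frac[idx] += count
        frac /= frac.sum()
        if noiseless:
            return frac
        out = np.zeros(N_CLASSES)
        support = frac > 0
        if support.sum() == 1:
            return frac
        out[support] = rng.dirichlet(alpha * frac[support])
        return out

    return classify


# ---------------------------------------------------------------------------
# fast path: probability maps without images

def simulate_probability_map(
    target_tsr: float,
    theta: float,
    grid_dims: tuple[int, int] = (30, 30),
    alpha: float | None = None,
    seed: int = 0,
    meta: SlideMeta | None = None,
) -> tuple[ProbabilityMap, np.ndarray]:
    """Directly simulate a patch-grid probability map and its true labels.

    Interior (tumour-bed) cells are split STR/TUM to hit ``target_tsr`` up
    to grid quantization; STR cells put Beta(theta*alpha, (1-theta)*alpha)
    mass on LYM (mean theta; exact for alpha=None) and the rest on STR;
    other cells concentrate on their true label.  A one-cell border of
    NOR/ADI/BAC surrounds the bed on grids of at least 3x3.
    """
    if not (0 <= target_tsr <= 1) or not (0 <= theta <= 1):
        raise ValueError("target_tsr and theta must lie in [0, 1]")
    rows, cols = grid_dims
    if rows < 1 or cols < 1:
        raise ValueError("grid_dims must be positive")
    rng = np.random.default_rng(seed)
    if meta is None:
        meta = SlideMeta(slide_id=f"sim-{seed}", stain="HE")

    labels = np.full((rows, cols), int(TissueClass.TUM), dtype=np.int8)
    if rows >= 3 and cols >= 3:
        border = np.zeros((rows, cols), dtype=bool)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        labels[border] = rng.choice(
            [int(TissueClass.NOR), int(TissueClass.ADI), int(TissueClass.BAC)],
            size=int(border.sum()),
        )
        bed = ~border
    else:
        bed = np.ones((rows, cols), dtype=bool)
    n_bed = int(bed.sum())
    n_str = int(round(target_tsr * n_bed))
    if target_tsr > 0:
        n_str = max(n_str, 1)
    if target_tsr < 1:
        n_str = min(n_str, n_bed - 1)
    if abs(n_str / n_bed - target_tsr) > 0.5 / n_bed + 1e-12:
        raise ValueError(
            f"grid {grid_dims} too small to represent stroma target {target_tsr}"
        )
    bed_idx = np.flatnonzero(bed.ravel())
    rng.shuffle(bed_idx)
    flat = labels.ravel()
    flat[bed_idx[:n_str]] = int(TissueClass.STR)
    flat[bed_idx[n_str:]] = int(TissueClass.TUM)

    noiseless = alpha is None or not np.isfinite(alpha)
    grid = np.zeros((rows, cols, N_CLASSES))
    for r in range(rows):
        for c in range(cols):
            lab = labels[r, c]
            vec = np.zeros(N_CLASSES)
            if lab == TissueClass.STR:
                if noiseless or theta in (0.0, 1.0):
                    p_lym = theta
                else:
                    p_lym = rng.beta(theta * alpha, (1.0 - theta) * alpha)
                vec[TissueClass.LYM] = p_lym
                vec[TissueClass.STR] = 1.0 - p_lym
            elif noiseless:
                vec[lab] = 1.0
            else:
                base = np.full(N_CLASSES, 0.1 / N_CLASSES)
                base[lab] += 0.9
                vec = rng.dirichlet(alpha * base)
            grid[r, c] = vec
    return ProbabilityMap(meta=meta, grid=grid), labels


# ---------------------------------------------------------------------------
# survival and detection primitives

def simulate_exponential_group(
    n: int,
    rate: float,
    rng: np.random.Generator,
    horizon: float = math.inf,
    dropout_rate: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with optional uniform dropout and an
    administrative censoring horizon.  Returns (observed times, events)."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    t = rng.exponential(1.0 / rate, size=n)
    c = np.full(n, math.inf)
    if dropout_rate > 0:
        dropped = rng.random(n) < dropout_rate
        c[dropped] = rng.uniform(0.0, t[dropped])
    if math.isfinite(horizon):
        c = np.minimum(c, horizon)
    observed = np.minimum(t, c)
    events = (t <= c).astype(int)
    return np.maximum(observed, 1e-9), events


def simulate_survival(
    n: int,
    five_year_survival: float,
    rng: np.random.Generator,
    horizon: float = 10.0,
    dropout_rate: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential survival calibrated so S(5) = ``five_year_survival``."""
    if not (0 < five_year_survival < 1):
        raise ValueError("five_year_survival must lie in (0, 1)")
    rate = -math.log(five_year_survival) / 5.0
    return simulate_exponential_group(n, rate, rng, horizon, dropout_rate)


def place_detections(
    seg: SegmentationMap,
    density_per_mm2: float,
    rng: np.random.Generator,
    cell_area_px2: float = 50.0,
    slide_id: str | None = None,
) -> CellDetections:
    """Scatter ``round(density * stroma_area)`` cells uniformly over the
    stroma grid cells' stride footprints."""
    area = stroma_area_mm2(seg)
    n = int(round(density_per_mm2 * area))
    str_cells = np.argwhere(seg.labels == TissueClass.STR)
    stride = seg.meta.stride_px
    idx = rng.integers(0, len(str_cells), size=n)
    offsets = rng.uniform(0.0, stride, size=(n, 2))
    y = str_cells[idx, 0] * stride + offsets[:, 0]
    x = str_cells[idx, 1] * stride + offsets[:, 1]
    cells = np.column_stack([x, y, np.full(n, cell_area_px2)])
    return CellDetections(slide_id or seg.meta.slide_id, cells)


# ---------------------------------------------------------------------------
# full cohort

def _truncated_normal(rng, mean, sd, low=0.0):
    if sd == 0:
        return float(mean)
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > low:
            return float(v)
    raise RuntimeError("truncated normal sampling failed")


def _stage_probs_for_score(config: SimConfig, score: int) -> np.ndarray:
    p = np.array(config.stage_probs, dtype=float)
    a = config.stage_score_assoc
    if a != 0.0:
        # low scores shifted toward stage III, high toward stage I
        tilt = a * (2.5 - score) / 1.5
        p = p * np.array([max(0.0, 1.0 - tilt), 1.0, max(0.0, 1.0 + tilt)])
    return p / p.sum()


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate one cohort: maps, IHC segmentations + CD3 detections,
    clinical covariates and survival, all reproducible from ``config.seed``.

    The truth table records the generator's own grouping (stroma fraction
    against the cutoff, theta against its cutpoints) which drives both the
    CD3 density group mean and the survival hazard.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.theta_range
    cut1, cut2 = config.theta_cuts
    hazards = config.hazards

    clinical_rows, truth_rows = [], []
    maps: dict[str, tuple[ProbabilityMap, SegmentationMap]] = {}
    ihc_segs: dict[str, SegmentationMap] = {}
    detections: dict[str, CellDetections] = {}

    for i in range(config.n_patients):
        pid = f"{config.cohort_id}-{i:04d}"
        tsr = float(np.clip(rng.normal(config.tsr_mean, config.tsr_sd), 0.05, 0.95))
        theta = float(rng.uniform(lo, hi))
        tsr_points = 0 if tsr >= config.tsr_cutoff else 1
        til_points = 1 if theta <= cut1 else (2 if theta <= cut2 else 3)
        score = tsr_points + til_points

        map_seed = int(rng.integers(0, 2**31 - 1))
        he_meta = SlideMeta(
            slide_id=pid,
            patch_size_px=config.patch_size_px,
            stride_px=config.stride_px,
            microns_per_pixel=config.microns_per_pixel,
            stain="HE",
        )
        pmap, true_labels = simulate_probability_map(
            tsr, theta, config.grid_dims, config.dirichlet_alpha, map_seed, he_meta
        )
        true_seg = SegmentationMap(meta=he_meta, labels=true_labels)
        maps[pid] = (pmap, true_seg)

        ihc_meta = SlideMeta(
            slide_id=pid,
            patch_size_px=config.patch_size_px,
            stride_px=config.stride_px,
            microns_per_pixel=config.microns_per_pixel,
            stain="IHC",
        )
        ihc_seg = SegmentationMap(meta=ihc_meta, labels=true_labels.copy())
        ihc_segs[pid] = ihc_seg
        mu = config.group_density_means[score - 1]
        density_true = _truncated_normal(rng, mu, config.density_sd_frac * mu)
        detections[pid] = place_detections(ihc_seg, density_true, rng)

        t_obs, ev = simulate_survival(
            1,
            config.group_five_year_survival[score - 1],
            rng,
            config.censor_horizon_years,
            config.dropout_rate,
        )

        age = float(rng.normal(config.age_mean, config.age_sd))
        sex = "female" if rng.random() < config.p_female else "male"
        stage = rng.choice(["I", "II", "III"], p=_stage_probs_for_score(config, score))
        location = "rectum" if rng.random() < config.p_rectum else "colon"
        grade = "high" if rng.random() < config.p_high_grade else "low"
        cea = "abnormal" if rng.random() < config.p_cea_abnormal else "normal"

        clinical_rows.append(
            {
                "patient_id": pid,
                "cohort": config.cohort_id,
                "age": age,
                "sex": sex,
                "stage": stage,
                "location": location,
                "grade": grade,
                "cea": cea,
                "os_years": float(t_obs[0]),
                "os_event": int(ev[0]),
            }
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "tsr_target": tsr,
                "theta": theta,
                "tsr_group_true": "high" if tsr_points == 0 else "low",
                "til_group_true": ("low", "middle", "high")[til_points - 1],
                "immune_score_true": score,
                "density_true": density_true,
                "hazard": hazards[score - 1],
            }
        )

    return SimulatedCohort(
        config=config,
        clinical=pd.DataFrame(clinical_rows),
        truth=pd.DataFrame(truth_rows),
        maps=maps,
        ihc_segs=ihc_segs,
        detections=detections,
    )


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> Path:
    """Emit the cohort in the file dialects the other modules consume:
    per-slide map directories (CSV dialect), a combined detections CSV,
    clinical.csv, truth.csv and the generator config."""
    from deepimmune.tissue_maps import write_map

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort.clinical.to_csv(out_dir / "clinical.csv", index=False, float_format="%.10g")
    cohort.truth.to_csv(out_dir / "truth.csv", index=False, float_format="%.10g")
    cohort.config.to_yaml(out_dir / "sim_config.yaml")
    for pid, (pmap, _) in cohort.maps.items():
        write_map(pmap, out_dir / "maps" / pid, fmt="csv")
    for pid, seg in cohort.ihc_segs.items():
        onehot = np.zeros((*seg.labels.shape, N_CLASSES))
        rr, cc = np.mgrid[0 : seg.labels.shape[0], 0 : seg.labels.shape[1]]
        onehot[rr.ravel(), cc.ravel(), seg.labels.ravel()] = 1.0
        write_map(ProbabilityMap(meta=seg.meta, grid=onehot),
                  out_dir / "ihc_maps" / pid, fmt="csv")
    det_frames = [d.to_frame() for d in cohort.detections.values()]
    pd.concat(det_frames, ignore_index=True).to_csv(
        out_dir / "detections.csv", index=False, float_format="%.10g"
    )
    return out_dir
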