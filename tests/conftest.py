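import numpy as np
import pytest

from deepimmune.tissue_maps import (
    N_CLASSES,
    ProbabilityMap,
    SegmentationMap,
    SlideMeta,
    TissueClass,
)


def onehot_grid(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    grid = np.zeros((*labels.shape, N_CLASSES))
    rr, cc = np.mgrid[0 : labels.shape[0], 0 : labels.shape[1]]
    grid[rr.ravel(), cc.ravel(), labels.ravel()] = 1.0
    return grid


def make_pmap(labels, p_lym=0.0, meta=None) -> ProbabilityMap:
    """Probability map concentrated on ``labels``; STR cells optionally put
    ``p_lym`` mass on LYM (scalar or per-cell array)."""
    labels = np.asarray(labels)
    grid = onehot_grid(labels)
    p_lym = np.broadcast_to(np.asarray(p_lym, dtype=float), labels.shape)
    str_mask = labels == TissueClass.STR
    grid[str_mask, TissueClass.LYM] = p_lym[str_mask]
    grid[str_mask, TissueClass.STR] = 1.0 - p_lym[str_mask]
    return ProbabilityMap(meta=meta or SlideMeta("test"), grid=grid)


def make_seg(labels, meta=None) -> SegmentationMap:
    return SegmentationMap(meta=meta or SlideMeta("test"), labels=np.asarray(labels))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
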