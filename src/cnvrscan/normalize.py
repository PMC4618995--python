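"""GC-bias adjustment and within/between-sample standardization.

GC content modulates Illumina read depth, so raw counts are rescaled per
sample by the ratio of the sample's global median to the median of windows
with similar GC (r' = r * m / m_GC). Counts are then standardized within
each sample (z-score over retained windows) and between samples (each
window centered on its across-sample median), which suppresses shared
mappability artifacts while preserving cross-sample copy-number contrasts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInputError, InvalidParameterError
from .windows import STAGE_GC, STAGE_RAW, STAGE_STD, DepthMatrix, WindowGrid

log = logging.getLogger(__name__)


@dataclass
class GCAdjustConfig:
    bin_width: float = 0.01
    min_windows: int = 10  # bins with fewer windows fall back to the global median

    def __post_init__(self):
        if not (0 < self.bin_width <= 1):
            raise InvalidParameterError("bin_width must be in (0, 1]")
        if self.min_windows < 1:
            raise InvalidParameterError("min_windows must be >= 1")


def gc_adjust(matrix: DepthMatrix, grid: WindowGrid,
              config: GCAdjustConfig = None) -> DepthMatrix:
    """Median-ratio GC adjustment: per sample, r' = r * m / m_GC.

    m is the sample's median count over retained windows; m_GC the median
    over windows sharing the same GC bin. Bins below ``min_windows`` use m
    (no-op); a zero m_GC in a populated bin makes those windows missing.
    """
    if matrix.stage != STAGE_RAW:
        raise InvalidParameterError("gc_adjust expects a raw-stage matrix")
    config = config or GCAdjustConfig()
    gc = grid.retained["gc"].to_numpy(dtype=float)
    if np.all(np.isnan(gc)):
        raise ConfigurationError("grid has no GC fractions; provide a reference or GC track")
    if len(gc) != len(matrix.values):
        raise InvalidParameterError("matrix rows do not match retained windows")

    nbins = int(np.ceil(1.0 / config.bin_width))
    bins = np.minimum((gc / config.bin_width).astype(float), nbins - 1)
    bins = np.where(np.isnan(gc), -1, bins).astype(np.int64)

    vals = matrix.values.to_numpy(dtype=float)
    out = np.empty_like(vals)
    n_flagged = 0
    for j, sample in enumerate(matrix.values.columns):
        col = vals[:, j]
        finite = np.isfinite(col)
        if not np.any(finite) or np.nansum(col) == 0:
            raise DegenerateInputError(f"sample {sample!r} has all-zero counts")
        m = np.nanmedian(col)
        factor = np.ones(len(col))
        for b in np.unique(bins):
            sel = bins == b
            if b < 0 or sel.sum() < config.min_windows:
                continue  # fallback: global median, factor 1
            m_gc = np.nanmedian(col[sel])
            if m_gc == 0:
                factor[sel] = np.nan
                n_flagged += int(sel.sum())
            else:
                factor[sel] = m / m_gc
        out[:, j] = col * factor
    if n_flagged:
        log.warning("gc_adjust: %d window values flagged missing (zero bin median)",
                    n_flagged)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.advance(values, STAGE_GC, gc_config=vars(config))


def standardize(matrix: DepthMatrix) -> DepthMatrix:
    """Two-stage standardization: within-sample z-score, then per-window
    centering on the across-sample median.

    A zero-variance sample standardizes to all zeros with a warning.
    Missing values are excluded from means/medians and stay missing.
    """
    if matrix.stage != STAGE_GC:
        raise InvalidParameterError("standardize expects a gc_adjusted matrix")
    vals = matrix.values.to_numpy(dtype=float)
    if vals.shape[0] < 2:
        raise DegenerateInputError("need at least 2 retained windows to standardize")

    z = np.empty_like(vals)
    for j, sample in enumerate(matrix.values.columns):
        col = vals[:, j]
        mu = np.nanmean(col)
        sd = np.nanstd(col, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            log.warning("standardize: sample %r has zero variance; set to 0", sample)
            z[:, j] = np.where(np.isfinite(col), 0.0, np.nan)
        else:
            z[:, j] = (col - mu) / sd

    med = np.nanmedian(z, axis=1, keepdims=True)
    centered = z - med
    values = pd.DataFrame(centered, index=matrix.values.index,
                          columns=matrix.values.columns)
    return matrix.advance(values, STAGE_STD)
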