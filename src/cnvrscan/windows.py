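"""Fixed-width window grids, read-level filters and the raw count matrix.

Read depth is summarized in non-overlapping windows (3,000 bp by default)
tiled from position 0 of each chromosome; a trailing partial window is
dropped so every window has equal exposure. Windows with more than 50% Ns
or fully covered by exclusion masks (organelle / repeat intervals) are
removed from analysis; partially masked windows are retained but reads
overlapping a mask by at least one base pair are discarded.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import intervals as iv
from .errors import ConfigurationError, InvalidParameterError, ValidationError

log = logging.getLogger(__name__)

RETAINED = "retained"
REMOVED_N = "removed_N"
REMOVED_MASK = "removed_mask"

STAGE_RAW = "raw"
STAGE_GC = "gc_adjusted"
STAGE_STD = "standardized"
_STAGE_ORDER = [STAGE_RAW, STAGE_GC, STAGE_STD]


@dataclass
class FilterConfig:
    """Read- and window-level quality filters."""

    mapq_min: int = 20
    window_size: int = 3000
    n_fraction_max: float = 0.5
    drop_duplicates: bool = True

    def __post_init__(self):
        if self.mapq_min < 0:
            raise InvalidParameterError("mapq_min must be >= 0")
        if not (0 < self.n_fraction_max <= 1):
            raise InvalidParameterError("n_fraction_max must be in (0, 1]")
        if self.window_size <= 0:
            raise InvalidParameterError("window_size must be positive")


@dataclass
class WindowGrid:
    """Fixed-width window coordinates with GC/N tracks and retention status.

    ``windows`` columns: chrom, start, end, gc, n_frac, status. Rows are
    sorted by (chromosome, start) and non-overlapping. ``masks`` holds
    merged per-chromosome exclusion intervals for read-level filtering.
    """

    windows: pd.DataFrame
    window_size: int
    chrom_lengths: dict
    masks: dict = field(default_factory=dict)

    @property
    def retained(self) -> pd.DataFrame:
        return self.windows[self.windows["status"] == RETAINED]

    @property
    def n_retained(self) -> int:
        return int((self.windows["status"] == RETAINED).sum())

    def retained_bp(self) -> int:
        return self.n_retained * self.window_size

    def copy(self) -> "WindowGrid":
        return WindowGrid(self.windows.copy(), self.window_size,
                          dict(self.chrom_lengths),
                          {c: m.copy() for c, m in self.masks.items()})


@dataclass
class DepthMatrix:
    """Windows x samples depth values at a tagged processing stage.

    Rows align positionally with the retained windows of the grid the
    matrix was built from. Stage transitions only move forward:
    raw -> gc_adjusted -> standardized.
    """

    values: pd.DataFrame
    stage: str = STAGE_RAW
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.stage not in _STAGE_ORDER:
            raise InvalidParameterError(f"unknown stage {self.stage!r}")
        if self.stage == STAGE_RAW:
            vals = self.values.to_numpy()
            finite = vals[np.isfinite(vals)]
            if np.any(finite < 0) or np.any(finite != np.round(finite)):
                raise ValidationError("raw counts must be non-negative integers")

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    def advance(self, new_values: pd.DataFrame, stage: str, **meta) -> "DepthMatrix":
        if _STAGE_ORDER.index(stage) != _STAGE_ORDER.index(self.stage) + 1:
            raise ValidationError(f"illegal stage transition {self.stage} -> {stage}")
        return DepthMatrix(new_values, stage=stage, meta={**self.meta, **meta})


def _gc_n_from_sequence(seq: str) -> tuple:
    s = seq.upper()
    n = s.count("N")
    gc = s.count("G") + s.count("C")
    acgt = len(s) - n
    return (gc / acgt if acgt else np.nan, n / len(s) if len(s) else np.nan)


def build_windows(chrom_lengths: Mapping[str, int], window_size: int = 3000,
                  reference=None, gc: Mapping[str, Sequence] = None,
                  n_frac: Mapping[str, Sequence] = None,
                  n_fraction_max: float = 0.5) -> WindowGrid:
    """Tile each chromosome from 0 with equal-width windows.

    Trailing partial windows are dropped. GC and N fractions come from the
    ``reference`` (a path, ``pyfaidx.Fasta``, or dict of sequences) when
    given, otherwise from per-window tracks ``gc`` / ``n_frac``; with
    neither, GC is NaN (later stages that need it will raise). Windows
    whose N fraction exceeds ``n_fraction_max`` are removed.
    """
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise InvalidParameterError(f"chromosome {chrom!r} has non-positive length")
    if window_size <= 0:
        raise InvalidParameterError("window_size must be positive")

    seqs = None
    if reference is not None:
        if isinstance(reference, (str,)):
            import pyfaidx
            seqs = pyfaidx.Fasta(reference)
        else:
            seqs = reference

    rows = []
    for chrom, length in chrom_lengths.items():
        n_win = length // window_size
        starts = np.arange(n_win, dtype=np.int64) * window_size
        g = np.full(n_win, np.nan)
        nf = np.zeros(n_win)
        if seqs is not None:
            chrom_seq = str(seqs[chrom][:]) if not isinstance(seqs, dict) else seqs[chrom]
            for i, s in enumerate(starts):
                g[i], nf[i] = _gc_n_from_sequence(chrom_seq[s:s + window_size])
        else:
            if gc is not None and chrom in gc:
                g = np.asarray(gc[chrom], dtype=float)[:n_win]
            if n_frac is not None and chrom in n_frac:
                nf = np.asarray(n_frac[chrom], dtype=float)[:n_win]
        for i in range(n_win):
            rows.append((chrom, int(starts[i]), int(starts[i]) + window_size,
                         g[i], nf[i]))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gc", "n_frac"])
    df["status"] = np.where(df["n_frac"] > n_fraction_max, REMOVED_N, RETAINED)
    return WindowGrid(df.reset_index(drop=True), window_size, dict(chrom_lengths))


def apply_exclusion_masks(grid: WindowGrid, exclusions) -> WindowGrid:
    """Record exclusion intervals and remove fully covered windows.

    ``exclusions`` is a DataFrame with chrom/start/end columns or an
    iterable of (chrom, start, end) tuples. Windows fully covered by the
    merged exclusion set become ``removed_mask``; partial coverage leaves
    the window retained but is stored for read-level filtering.
    """
    if isinstance(exclusions, pd.DataFrame):
        recs = exclusions[["chrom", "start", "end"]].itertuples(index=False)
    else:
        recs = exclusions
    per_chrom: dict = {}
    unknown = set()
    for chrom, start, end in recs:
        if chrom not in grid.chrom_lengths:
            unknown.add(chrom)
            continue
        per_chrom.setdefault(chrom, []).append((int(start), int(end)))
    if unknown:
        raise ValidationError(
            f"exclusion intervals reference unknown chromosomes: {sorted(unknown)}")

    out = grid.copy()
    for chrom, ivals in per_chrom.items():
        merged = iv.merge_intervals(ivals)
        prev = out.masks.get(chrom)
        if prev is not None and len(prev):
            merged = iv.merge_intervals(np.vstack([prev, merged]))
        out.masks[chrom] = merged
        sel = out.windows["chrom"] == chrom
        w = out.windows.loc[sel]
        cov = iv.overlap_bp(w["start"].to_numpy(), w["end"].to_numpy(), merged)
        fully = cov == grid.window_size
        idx = w.index[fully & (w["status"] == RETAINED)]
        out.windows.loc[idx, "status"] = REMOVED_MASK
    return out


def count_reads(alignment_path, grid: WindowGrid, config: FilterConfig = None,
                sample_name: str = None) -> DepthMatrix:
    """Count retained reads per window for one sample from a SAM/BAM file.

    A read increments the window containing its leftmost aligned base.
    Reads that are unmapped, secondary/supplementary, duplicate-flagged,
    below the MAPQ cutoff, or overlapping any exclusion mask by at least
    one base pair are excluded; so are reads landing in removed windows or
    beyond the tiled region. A per-category tally is stored in ``meta``.
    """
    import pysam

    config = config or FilterConfig(window_size=grid.window_size)
    if config.window_size != grid.window_size:
        raise ValidationError("FilterConfig window size differs from the grid's")

    try:
        af = pysam.AlignmentFile(str(alignment_path), "r", check_sq=False)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read alignment file {alignment_path}: {exc}") from exc

    with af:
        file_chroms = set(af.references or [])
        missing = file_chroms - set(grid.chrom_lengths)
        if missing:
            raise ValidationError(
                f"alignment header chromosomes absent from grid: {sorted(missing)}")
        if sample_name is None:
            rgs = (af.header.to_dict().get("RG") or [])
            sample_name = rgs[0].get("SM") if rgs else None
        if sample_name is None:
            import os
            sample_name = os.path.splitext(os.path.basename(str(alignment_path)))[0]

        win_status = {}
        for chrom in grid.chrom_lengths:
            sub = grid.windows[grid.windows["chrom"] == chrom]
            win_status[chrom] = sub["status"].to_numpy()
        counts = {c: np.zeros(len(s), dtype=np.int64) for c, s in win_status.items()}
        tally = {k: 0 for k in ("records", "unmapped", "secondary_supplementary",
                                "duplicate", "low_mapq", "mask_overlap",
                                "outside_windows", "removed_window", "counted")}

        for read in af:
            tally["records"] += 1
            if read.is_unmapped:
                tally["unmapped"] += 1
                continue
            if read.is_secondary or read.is_supplementary:
                tally["secondary_supplementary"] += 1
                continue
            if config.drop_duplicates and read.is_duplicate:
                tally["duplicate"] += 1
                continue
            if read.mapping_quality < config.mapq_min:
                tally["low_mapq"] += 1
                continue
            chrom = read.reference_name
            mask = grid.masks.get(chrom)
            if mask is not None and len(mask):
                ov = iv.overlap_bp([read.reference_start], [read.reference_end], mask)
                if ov[0] >= 1:
                    tally["mask_overlap"] += 1
                    continue
            widx = read.reference_start // grid.window_size
            status = win_status[chrom]
            if widx >= len(status):
                tally["outside_windows"] += 1
                continue
            if status[widx] != RETAINED:
                tally["removed_window"] += 1
                continue
            counts[chrom][widx] += 1
            tally["counted"] += 1

    parts = []
    for chrom in grid.chrom_lengths:
        keep = win_status[chrom] == RETAINED
        parts.append(counts[chrom][keep])
    col = np.concatenate(parts) if parts else np.array([], dtype=np.int64)
    retained = grid.retained
    values = pd.DataFrame({sample_name: col},
                          index=pd.MultiIndex.from_frame(retained[["chrom", "start"]]))
    log.info("counted %s: %s", sample_name, tally)
    return DepthMatrix(values, stage=STAGE_RAW, meta={"tally": {sample_name: tally}})


def assemble_cohort(matrices: Sequence[DepthMatrix],
                    sample_names: Sequence[str] = None) -> DepthMatrix:
    """Column-bind single-sample raw matrices into a cohort matrix."""
    if not matrices:
        raise ValidationError("no matrices to assemble")
    first = matrices[0]
    for m in matrices[1:]:
        if m.stage != first.stage:
            raise ValidationError("stage mismatch across samples")
        if len(m.values) != len(first.values) or not m.values.index.equals(first.values.index):
            raise ValidationError("window grids differ across samples")
    cols = {}
    tally = {}
    for m in matrices:
        for name in m.values.columns:
            cols[name] = m.values[name]
        tally.update(m.meta.get("tally", {}))
    if sample_names is not None:
        missing = [s for s in sample_names if s not in cols]
        if missing:
            raise ValidationError(f"samples missing from inputs: {missing}")
        cols = {s: cols[s] for s in sample_names}
    values = pd.DataFrame(cols, index=first.values.index)
    return DepthMatrix(values, stage=first.stage, meta={"tally": tally})
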