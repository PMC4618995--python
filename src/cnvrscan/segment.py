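"""Binary segmentation of standardized per-window signals.

Each sample's signal is segmented per chromosome into regions of constant
mean by recursive binary segmentation with the circular (two-boundary)
split statistic: at every recursion the arc [i, j) maximizing the
pooled-variance two-sample t-statistic between the values inside and
outside the arc is proposed — single-boundary splits are the arcs anchored
at either end — and the split is accepted when the observed maximum
exceeds the (1 - alpha) quantile of maxima obtained by permuting the
values within the current segment. The two-boundary scan is what gives
the method power against short interior copy-number events on long
chromosomes. The mean of each final segment, broadcast to its member
windows, is that window's segmentation score: positive scores mark
elevated read depth, negative scores reduced depth.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidParameterError, ValidationError
from .windows import STAGE_STD, DepthMatrix, WindowGrid

_VAR_FLOOR = 1e-12  # keeps the statistic ordered when a split is noise-free


@dataclass
class SegConfig:
    alpha: float = 0.01
    n_permutations: int = 100
    min_width: int = 2
    max_arc: int = 100  # longest interior arc scanned; edge splits are unbounded
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise InvalidParameterError("alpha must be in (0, 1)")
        if self.min_width < 1:
            raise InvalidParameterError("min_width must be >= 1")
        if self.n_permutations < 1:
            raise InvalidParameterError("n_permutations must be >= 1")
        if self.max_arc < self.min_width:
            raise InvalidParameterError("max_arc must be >= min_width")


@dataclass
class ProfileEntry:
    """Segments for one sample x chromosome over its finite-window index space.

    ``rows`` are positional indices into the grid's retained windows;
    ``segments`` are (lo, hi_inclusive, score) triples over 0..len(rows)-1.
    """

    sample: str
    chrom: str
    rows: np.ndarray
    segments: List[Tuple[int, int, float]]


@dataclass
class SegmentProfile:
    entries: Dict[Tuple[str, str], ProfileEntry] = field(default_factory=dict)

    def add(self, entry: ProfileEntry):
        self.entries[(entry.sample, entry.chrom)] = entry


def _arc_t(n, n_in, s_in, q_in, s_tot, q_tot):
    """|t| between inside/outside an arc from sums and sums of squares."""
    n_out = n - n_in
    s_out = s_tot - s_in
    q_out = q_tot - q_in
    m_in = s_in / n_in
    m_out = s_out / n_out
    ss = (q_in - s_in * m_in) + (q_out - s_out * m_out)
    dof = max(n - 2, 1)
    pooled = np.maximum(ss / dof, _VAR_FLOOR)
    return np.abs(m_in - m_out) / np.sqrt(pooled * (1.0 / n_in + 1.0 / n_out))


def max_t_split(x: np.ndarray, min_width: int,
                max_arc: int = None) -> Tuple[int, int, float]:
    """Best arc ``[i, j)`` (inside vs outside) and its |t| statistic.

    Single-boundary splits (i == 0 or j == n) are scanned at every length;
    interior arcs are scanned up to ``max_arc`` windows. Interior arcs keep
    both flanking pieces at least ``min_width`` wide so no short fragment
    segment can be created. Ties resolve to the leftmost start, then the
    shortest arc. Returns (-1, -1, 0.0) when no admissible arc exists.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 * min_width:
        return -1, -1, 0.0
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])
    s_tot, q_tot = cs[-1], cs2[-1]
    best = (0.0, -1, -1)  # (stat, i, j); compare on -stat for leftmost wins

    # single-boundary splits: arcs anchored at the left end
    ks = np.arange(min_width, n - min_width + 1)
    t = _arc_t(n, ks.astype(float), cs[ks], cs2[ks], s_tot, q_tot)
    bi = int(np.argmax(t))
    if t[bi] > best[0]:
        best = (float(t[bi]), 0, int(ks[bi]))

    # interior arcs up to max_arc, both flanks at least min_width;
    # vectorized over starts, one pass per arc length (cache-friendly)
    cap = n - min_width if max_arc is None else min(max_arc, n - min_width)
    i1 = n - 2 * min_width  # largest admissible interior start
    if cap >= min_width and i1 >= min_width:
        for length in range(min_width, cap + 1):
            hi_start = min(i1, n - min_width - length)
            if hi_start < min_width:
                break
            starts = np.arange(min_width, hi_start + 1)
            ends = starts + length
            t = _arc_t(n, float(length), cs[ends] - cs[starts],
                       cs2[ends] - cs2[starts], s_tot, q_tot)
            bi = int(np.argmax(t))
            # ties resolve to leftmost start, then shortest arc: a later
            # (longer) arc only displaces an equal-stat one when it starts
            # strictly further left
            if t[bi] > best[0] or (t[bi] == best[0] and best[1] > 0
                                   and starts[bi] < best[1]):
                best = (float(t[bi]), int(starts[bi]), int(starts[bi] + length))
    stat, i, j = best
    return i, j, stat


def _rng_for(seed: int, sample_idx: int, chrom_idx: int) -> np.random.Generator:
    # independent, reproducible stream per (sample, chromosome)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(sample_idx, chrom_idx)))


def segment_values(values: np.ndarray, config: SegConfig = None,
                   rng: np.random.Generator = None) -> List[Tuple[int, int, float]]:
    """Segment one finite-valued vector; returns (lo, hi_inclusive, mean) triples."""
    config = config or SegConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    x = np.asarray(values, dtype=float)
    if len(x) == 0 or not np.all(np.isfinite(x)):
        raise DegenerateInputError("segmentation input must be non-empty and finite")

    boundaries: List[int] = []
    stack = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        seg = x[lo:hi]
        i, j, stat = max_t_split(seg, config.min_width, config.max_arc)
        if i < 0 or stat == 0.0:
            continue
        perm_stats = np.empty(config.n_permutations)
        for b in range(config.n_permutations):
            perm_stats[b] = max_t_split(rng.permutation(seg), config.min_width,
                                        config.max_arc)[2]
        if stat > np.quantile(perm_stats, 1 - config.alpha):
            new_cuts = {lo + i, lo + j} - {lo, hi}
            boundaries.extend(new_cuts)
            pieces = sorted(new_cuts | {lo, hi})
            for a, b in zip(pieces[:-1], pieces[1:]):
                stack.append((a, b))

    cuts = sorted(set(boundaries) - {0}) + [len(x)]
    segments = []
    lo = 0
    for c in cuts:
        segments.append((lo, c - 1, float(np.mean(x[lo:c]))))
        lo = c
    # maximal merge: adjacent segments with identical score collapse
    merged = [segments[0]]
    for slo, shi, sc in segments[1:]:
        plo, phi, psc = merged[-1]
        if sc == psc:
            merged[-1] = (plo, shi, psc)
        else:
            merged.append((slo, shi, sc))
    return merged


def segment_sample(values, sample: str, chrom: str, rows: np.ndarray,
                   config: SegConfig = None,
                   rng: np.random.Generator = None) -> ProfileEntry:
    """Segment one sample x chromosome signal, skipping missing windows."""
    x = np.asarray(values, dtype=float)
    rows = np.asarray(rows, dtype=np.int64)
    finite = np.isfinite(x)
    if not np.any(finite):
        raise DegenerateInputError(f"all values missing for {sample}/{chrom}")
    segs = segment_values(x[finite], config=config, rng=rng)
    return ProfileEntry(sample=sample, chrom=chrom, rows=rows[finite], segments=segs)


def segment_cohort(matrix: DepthMatrix, grid: WindowGrid,
                   config: SegConfig = None) -> SegmentProfile:
    """Segment every sample on every chromosome of a standardized matrix."""
    if matrix.stage != STAGE_STD:
        raise InvalidParameterError("segmentation expects a standardized matrix")
    config = config or SegConfig()
    retained = grid.retained.reset_index(drop=True)
    chroms = list(dict.fromkeys(retained["chrom"]))
    profile = SegmentProfile()
    vals = matrix.values.to_numpy(dtype=float)
    for si, sample in enumerate(matrix.values.columns):
        for ci, chrom in enumerate(chroms):
            rows = np.flatnonzero((retained["chrom"] == chrom).to_numpy())
            entry = segment_sample(vals[rows, si], sample, chrom, rows,
                                   config=config,
                                   rng=_rng_for(config.seed, si, ci))
            profile.add(entry)
    return profile


def scores_from_segments(profile: SegmentProfile, grid: WindowGrid,
                         samples=None) -> pd.DataFrame:
    """Broadcast segment means to member windows (the segmentation-score matrix).

    Rows align with the grid's retained windows; windows not covered by a
    sample's profile (missing input) carry NaN.
    """
    retained = grid.retained.reset_index(drop=True)
    n = len(retained)
    if samples is None:
        samples = list(dict.fromkeys(s for s, _ in profile.entries))
    mat = np.full((n, len(samples)), np.nan)
    for (sample, chrom), entry in profile.entries.items():
        if sample not in samples:
            continue
        j = samples.index(sample)
        covered = np.zeros(len(entry.rows), dtype=bool)
        for lo, hi, sc in entry.segments:
            if lo < 0 or hi >= len(entry.rows) or lo > hi:
                raise ValidationError(
                    f"segment ({lo},{hi}) outside index space for {sample}/{chrom}")
            covered[lo:hi + 1] = True
            mat[entry.rows[lo:hi + 1], j] = sc
        if not covered.all():
            raise ValidationError(f"profile for {sample}/{chrom} leaves windows uncovered")
    index = pd.MultiIndex.from_frame(retained[["chrom", "start"]])
    return pd.DataFrame(mat, index=index, columns=samples)
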