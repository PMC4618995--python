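"""Cross-sample CNVR calling from segmentation scores.

For every window the variability of segmentation scores across samples is
summarized by a trimmed standard deviation (one minimum and one maximum
value removed before computing the n-1 SD), which absorbs single-sample
outliers driven by noise at low coverage. Significance is calibrated by a
permutation scheme that shuffles the order of each sample's segments
within each chromosome and rotates the re-laid vector by a uniform
circular offset — preserving segment lengths, scores and their
autocorrelation while placing segments uniformly over the chromosome —
and recomputes the trimmed SD, yielding an empirical FDR per threshold;
per-chromosome FDRs are averaged with weights proportional to chromosome
length. Without the rotation a segment could only start at partial sums
of the other segments' lengths; on profiles with few segments per
chromosome that pins short segments to the chromosome ends, piling all
samples' extreme segments onto the same windows and inflating the null. Windows whose trimmed SD exceeds the chosen
threshold (0.25 by default) are merged with genomically adjacent
qualifying windows into CNVRs; a removed window between two qualifying
windows splits the run into two regions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidParameterError, ValidationError
from .segment import ProfileEntry, SegmentProfile
from .windows import RETAINED, WindowGrid

DEFAULT_THRESHOLD = 0.25


def trimmed_sd(values) -> float:
    """SD (n-1 denominator) after removing one min and one max instance.

    Requires at least 4 finite values so that at least two remain.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 4:
        raise DegenerateInputError("trimmed_sd needs >= 4 finite values")
    core = np.sort(x)[1:-1]
    return float(np.std(core, ddof=1))


def trimmed_sd_track(scores: pd.DataFrame) -> pd.Series:
    """Per-window trimmed SD across samples; NaN where < 4 samples are finite."""
    vals = scores.to_numpy(dtype=float)
    return pd.Series(_trimmed_sd_rows(vals), index=scores.index, name="trimmed_sd")


def _trimmed_sd_rows(vals: np.ndarray) -> np.ndarray:
    finite = np.isfinite(vals)
    nfin = finite.sum(axis=1)
    filled = np.where(finite, vals, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        # center each row first so the sums-of-squares shortcut stays
        # well-conditioned even with large offsets or outliers
        mean = np.nansum(filled, axis=1) / np.maximum(nfin, 1)
        filled = filled - mean[:, None]
        s = np.nansum(filled, axis=1)
        q = np.nansum(filled * filled, axis=1)
        mn = np.nanmin(np.where(finite, filled, np.inf), axis=1)
        mx = np.nanmax(np.where(finite, filled, -np.inf), axis=1)
    n = nfin - 2
    s1 = s - mn - mx
    q1 = q - mn * mn - mx * mx
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (q1 - s1 * s1 / n) / (n - 1)
    out = np.sqrt(np.maximum(var, 0.0))
    out[nfin < 4] = np.nan
    return out


def permute_profile(entry: ProfileEntry, rng: np.random.Generator) -> ProfileEntry:
    """Randomly reorder a chromosome's segments, re-laid over the same windows."""
    segs = entry.segments
    order = rng.permutation(len(segs))
    new_segs = []
    lo = 0
    for i in order:
        slo, shi, sc = segs[i]
        width = shi - slo + 1
        new_segs.append((lo, lo + width - 1, sc))
        lo += width
    return ProfileEntry(sample=entry.sample, chrom=entry.chrom,
                        rows=entry.rows, segments=new_segs)


@dataclass
class FDRCurve:
    """Empirical FDR per chromosome and genome-wide, per threshold."""

    per_chrom: pd.DataFrame  # chrom, threshold, observed, perm_mean, fdr
    genome_wide: pd.DataFrame  # threshold, fdr
    n_permutations: int

    def threshold_at(self, fdr_ceiling: float) -> float:
        """Smallest tabulated threshold with genome-wide FDR <= the ceiling."""
        gw = self.genome_wide.dropna(subset=["fdr"]).sort_values("threshold")
        ok = gw[gw["fdr"] <= fdr_ceiling]
        if ok.empty:
            return float("nan")
        return float(ok["threshold"].iloc[0])


def _entry_arrays(entry: ProfileEntry):
    lengths = np.array([hi - lo + 1 for lo, hi, _ in entry.segments], dtype=np.int64)
    scores = np.array([sc for _, _, sc in entry.segments], dtype=float)
    return lengths, scores


def empirical_fdr(scores: pd.DataFrame, profile: SegmentProfile, grid: WindowGrid,
                  thresholds: Sequence[float], n_permutations: int = 10_000,
                  seed: int = 0) -> FDRCurve:
    """Permutation FDR of the trimmed-SD statistic at the given thresholds.

    Per chromosome and threshold t:
    FDR(t) = mean over permutations of #(permuted trimmed SD > t) divided by
    #(observed trimmed SD > t), clipped to [0, 1]; undefined (NaN) when no
    window exceeds t. The genome-wide curve averages defined per-chromosome
    FDRs weighted by chromosome length.

    Each permutation reorders a sample's segments uniformly, re-lays them
    end-to-end, and applies an independent uniform circular rotation; the
    rotation preserves each window-value multiset (and hence every segment
    except the one split at the wrap point) while decoupling placement from
    the other segments' lengths.
    """
    if n_permutations < 1:
        raise InvalidParameterError("n_permutations must be >= 1")
    thresholds = np.asarray(sorted(thresholds), dtype=float)
    if np.any(thresholds <= 0):
        raise InvalidParameterError("thresholds must be positive")
    if scores.shape[1] < 4:
        raise DegenerateInputError("empirical_fdr needs >= 4 samples")

    retained = grid.retained.reset_index(drop=True)
    chroms = list(dict.fromkeys(retained["chrom"]))
    samples = list(scores.columns)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(77,)))

    rows_out = []
    for chrom in chroms:
        rows = np.flatnonzero((retained["chrom"] == chrom).to_numpy())
        if len(rows) == 0:
            continue
        obs = _trimmed_sd_rows(scores.to_numpy(dtype=float)[rows])
        observed_counts = np.array([(obs > t).sum() for t in thresholds])

        entries = []
        row_pos = {r: i for i, r in enumerate(rows)}
        for sample in samples:
            entry = profile.entries.get((sample, chrom))
            if entry is None:
                raise ValidationError(f"profile missing for {sample}/{chrom}")
            pos = np.array([row_pos[r] for r in entry.rows], dtype=np.int64)
            entries.append((pos, *_entry_arrays(entry)))

        perm_counts = np.zeros(len(thresholds))
        mat = np.full((len(rows), len(samples)), np.nan)
        for _ in range(n_permutations):
            for j, (pos, lengths, segscores) in enumerate(entries):
                order = rng.permutation(len(lengths))
                laid = np.repeat(segscores[order], lengths[order])
                mat[pos, j] = np.roll(laid, rng.integers(len(laid)))
            tsd = _trimmed_sd_rows(mat)
            for ti, t in enumerate(thresholds):
                perm_counts[ti] += (tsd > t).sum()
        perm_mean = perm_counts / n_permutations

        for ti, t in enumerate(thresholds):
            oc = observed_counts[ti]
            fdr = np.nan if oc == 0 else min(perm_mean[ti] / oc, 1.0)
            rows_out.append((chrom, float(t), int(oc), float(perm_mean[ti]), fdr))

    per_chrom = pd.DataFrame(rows_out,
                             columns=["chrom", "threshold", "observed",
                                      "perm_mean", "fdr"])
    lengths = pd.Series(grid.chrom_lengths)
    gw_rows = []
    for t in thresholds:
        sub = per_chrom[(per_chrom["threshold"] == t) & per_chrom["fdr"].notna()]
        if sub.empty:
            gw_rows.append((float(t), np.nan))
        else:
            w = lengths[sub["chrom"]].to_numpy(dtype=float)
            gw_rows.append((float(t), float(np.average(sub["fdr"], weights=w))))
    genome_wide = pd.DataFrame(gw_rows, columns=["threshold", "fdr"])
    return FDRCurve(per_chrom=per_chrom, genome_wide=genome_wide,
                    n_permutations=n_permutations)


@dataclass
class CNVRSet:
    """Called copy-number variable regions with trimmed-SD context.

    ``regions`` columns: chrom, start, end, n_windows, peak_tsd, mean_tsd,
    rows (member positional indices into the retained window set).
    """

    regions: pd.DataFrame
    threshold: float
    total_bp: int
    genome_fraction: float

    def __len__(self):
        return len(self.regions)

    def intervals_by_chrom(self) -> Dict[str, np.ndarray]:
        out: Dict[str, np.ndarray] = {}
        for chrom, sub in self.regions.groupby("chrom", sort=False):
            out[chrom] = sub[["start", "end"]].to_numpy(dtype=np.int64)
        return out


def call_cnvrs(track: pd.Series, grid: WindowGrid,
               threshold: float = DEFAULT_THRESHOLD) -> CNVRSet:
    """Merge adjacent retained windows with trimmed SD strictly above threshold.

    Two qualifying windows join the same region only when genomically
    adjacent (no removed window between them).
    """
    retained = grid.retained.reset_index(drop=True)
    tsd = np.asarray(track, dtype=float)
    if len(tsd) != len(retained):
        raise ValidationError("track length does not match retained windows")
    hot = np.flatnonzero(tsd > threshold)

    regions: List[dict] = []
    current: List[int] = []

    def flush():
        if not current:
            return
        sub = retained.iloc[current]
        regions.append({
            "chrom": sub["chrom"].iloc[0],
            "start": int(sub["start"].iloc[0]),
            "end": int(sub["end"].iloc[-1]),
            "n_windows": len(current),
            "peak_tsd": float(np.max(tsd[current])),
            "mean_tsd": float(np.mean(tsd[current])),
            "rows": list(current),
        })

    for i in hot:
        if current:
            prev = current[-1]
            same = (retained["chrom"].iloc[prev] == retained["chrom"].iloc[i]
                    and retained["end"].iloc[prev] == retained["start"].iloc[i])
            if not same:
                flush()
                current = []
        current.append(int(i))
    flush()

    df = pd.DataFrame(regions, columns=["chrom", "start", "end", "n_windows",
                                        "peak_tsd", "mean_tsd", "rows"])
    total = int((df["end"] - df["start"]).sum()) if len(df) else 0
    retained_bp = grid.retained_bp()
    frac = total / retained_bp if retained_bp else 0.0
    return CNVRSet(regions=df, threshold=threshold, total_bp=total,
                   genome_fraction=frac)


def summarize_cnvrs(cnvrs: CNVRSet, grid: WindowGrid) -> dict:
    """Headline CNVR statistics: count, length distribution, genome fraction."""
    df = cnvrs.regions
    if len(df) == 0:
        return {"count": 0, "total_bp": 0, "min_bp": 0, "mean_bp": 0.0,
                "median_bp": 0.0, "max_bp": 0, "genome_fraction": 0.0,
                "per_chromosome_fraction": {}}
    lengths = (df["end"] - df["start"]).to_numpy()
    retained = grid.retained
    per_chrom = {}
    for chrom in grid.chrom_lengths:
        cbp = int((retained["chrom"] == chrom).sum()) * grid.window_size
        rbp = int((df.loc[df["chrom"] == chrom, "end"]
                   - df.loc[df["chrom"] == chrom, "start"]).sum())
        per_chrom[chrom] = rbp / cbp if cbp else 0.0
    return {
        "count": int(len(df)),
        "total_bp": int(lengths.sum()),
        "min_bp": int(lengths.min()),
        "mean_bp": float(lengths.mean()),
        "median_bp": float(np.median(lengths)),
        "max_bp": int(lengths.max()),
        "genome_fraction": cnvrs.genome_fraction,
        "per_chromosome_fraction": per_chrom,
    }
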