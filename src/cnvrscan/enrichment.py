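"""Gene, GO, repeat and GC enrichment analyses around called CNVRs.

A gene model overlaps a CNVR when strictly more than 70% of its bases lie
within the union of CNVR intervals. Class enrichment (e.g. resistance
genes) and per-GO-term enrichment use Fisher's exact test; GO p-values are
Benjamini-Hochberg adjusted. Repeat elements are tested on entire
containment within the merged 10-kb flanking regions of CNVRs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import intervals as iv
from .calling import CNVRSet
from .errors import DegenerateInputError, ValidationError
from .stats import EnrichmentResult, bh_adjust, fisher_exact_2x2
from .windows import WindowGrid

FEATURE_COLUMNS = ["chrom", "start", "end", "feature_id", "feature_class"]


@dataclass
class RegionSet:
    """Merged, sorted, disjoint intervals keyed by chromosome."""

    by_chrom: Dict[str, np.ndarray]

    @classmethod
    def from_intervals(cls, records: Iterable) -> "RegionSet":
        per: Dict[str, list] = {}
        for chrom, start, end in records:
            per.setdefault(chrom, []).append((int(start), int(end)))
        return cls({c: iv.merge_intervals(v) for c, v in per.items()})

    @property
    def total_bp(self) -> int:
        return sum(iv.total_bp(arr) for arr in self.by_chrom.values())

    def get(self, chrom: str) -> np.ndarray:
        return self.by_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))


def _cnvr_regions(cnvrs: CNVRSet) -> RegionSet:
    return RegionSet({c: iv.merge_intervals(a)
                      for c, a in cnvrs.intervals_by_chrom().items()})


def feature_overlap_fraction(features: pd.DataFrame, regions: RegionSet) -> np.ndarray:
    """Fraction of each feature's bases covered by the region union."""
    lengths = (features["end"] - features["start"]).to_numpy(dtype=float)
    if np.any(lengths <= 0):
        bad = features.loc[lengths <= 0, "feature_id"].tolist()
        raise ValidationError(f"zero-length features: {bad[:5]}")
    features = features.reset_index(drop=True)
    frac = np.zeros(len(features))
    for chrom, sub in features.groupby("chrom", sort=False):
        arr = regions.get(chrom)
        ov = iv.overlap_bp(sub["start"].to_numpy(), sub["end"].to_numpy(), arr)
        frac[sub.index.to_numpy()] = ov / (sub["end"] - sub["start"]).to_numpy()
    return frac


def gene_overlap(features: pd.DataFrame, cnvrs: CNVRSet,
                 min_fraction: float = 0.70) -> pd.DataFrame:
    """Features with strictly more than ``min_fraction`` of bases inside CNVRs."""
    features = features.reset_index(drop=True)
    frac = feature_overlap_fraction(features, _cnvr_regions(cnvrs))
    return features.loc[frac > min_fraction].reset_index(drop=True)


def class_enrichment(features: pd.DataFrame, in_cnvr: pd.DataFrame,
                     class_label: str) -> EnrichmentResult:
    """Fisher test of a feature class (e.g. r_gene) inside vs outside CNVRs."""
    if not (features["feature_class"] == class_label).any():
        raise DegenerateInputError(f"no features of class {class_label!r}")
    in_ids = set(in_cnvr["feature_id"])
    is_in = features["feature_id"].isin(in_ids).to_numpy()
    is_class = (features["feature_class"] == class_label).to_numpy()
    a = int((is_class & is_in).sum())
    b = int((~is_class & is_in).sum())
    c = int((is_class & ~is_in).sum())
    d = int((~is_class & ~is_in).sum())
    # fold compares the class share among in-CNVR vs outside features
    return fisher_exact_2x2([[a, b], [c, d]],
                            row_labels=(class_label, f"non-{class_label}"),
                            col_labels=("in_cnvr", "outside"))


def go_enrichment(go_map: pd.DataFrame, all_genes: Iterable,
                  in_cnvr_genes: Iterable) -> pd.DataFrame:
    """Per-GO-term Fisher enrichment of in-CNVR genes, BH-adjusted.

    ``go_map`` columns: gene_id, term_id and optionally term_name.
    """
    if go_map.empty:
        raise ValidationError("GO map is empty")
    all_genes = set(all_genes)
    in_genes = set(in_cnvr_genes) & all_genes
    gmap = go_map[go_map["gene_id"].isin(all_genes)]
    if gmap.empty:
        raise ValidationError("GO map references no known gene identifiers")
    n_all = len(all_genes)
    n_in = len(in_genes)
    rows = []
    for term_id, sub in gmap.groupby("term_id", sort=True):
        members = set(sub["gene_id"])
        a = len(members & in_genes)
        b = n_in - a
        c = len(members) - a
        d = n_all - n_in - c
        res = fisher_exact_2x2([[a, b], [c, d]],
                               row_labels=("term", "non-term"),
                               col_labels=("in_cnvr", "outside"))
        name = sub["term_name"].iloc[0] if "term_name" in sub.columns else ""
        rows.append((term_id, name, a, len(members), res.fold, res.p_value))
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "in_cnvr_genes",
                                     "term_genes", "fold", "p_value"])
    df["p_adjusted"] = bh_adjust(df["p_value"].to_numpy())
    return df.sort_values("p_adjusted", kind="stable").reset_index(drop=True)


def flanking_regions(cnvrs: CNVRSet, chrom_lengths: Dict[str, int],
                     pad: int = 10_000) -> RegionSet:
    """Each CNVR expanded by ``pad`` on both sides, clipped and merged."""
    if pad < 0:
        raise ValidationError("pad must be >= 0")
    out = {}
    for chrom, arr in cnvrs.intervals_by_chrom().items():
        out[chrom] = iv.pad_and_clip(arr, pad, chrom_lengths[chrom])
    return RegionSet(out)


def regions_from_features(features: pd.DataFrame, chrom_lengths: Dict[str, int],
                          pad: int = 10_000) -> RegionSet:
    """Merged pad-expanded regions around arbitrary features (e.g. gene flanks)."""
    out = {}
    for chrom, sub in features.groupby("chrom", sort=False):
        arr = sub[["start", "end"]].to_numpy(dtype=np.int64)
        out[chrom] = iv.pad_and_clip(arr, pad, chrom_lengths[chrom])
    return RegionSet(out)


def repeat_enrichment(repeats: pd.DataFrame, flanks: RegionSet,
                      analyzed: RegionSet) -> pd.DataFrame:
    """Per-repeat-class containment counts in CNVR flanks with Fisher tests.

    A repeat element counts as in-flank only when entirely contained in a
    flank interval. Expected in-flank counts scale the class total by the
    flank share of analyzed bases.
    """
    contained = np.zeros(len(repeats), dtype=bool)
    repeats = repeats.reset_index(drop=True)
    for chrom, sub in repeats.groupby("chrom", sort=False):
        arr = flanks.get(chrom)
        idx = np.flatnonzero((repeats["chrom"] == chrom).to_numpy())
        contained[idx] = iv.fully_contained(sub["start"].to_numpy(),
                                            sub["end"].to_numpy(), arr)
    frac = flanks.total_bp / analyzed.total_bp if analyzed.total_bp else np.nan
    classes = repeats["feature_class"].to_numpy()
    rows = []
    for cls in pd.unique(classes):
        is_cls = classes == cls
        a = int((is_cls & contained).sum())
        b = int((is_cls & ~contained).sum())
        c = int((~is_cls & contained).sum())
        d = int((~is_cls & ~contained).sum())
        expected = is_cls.sum() * frac
        res = fisher_exact_2x2([[a, c], [b, d]],
                               row_labels=("in_flank", "outside"),
                               col_labels=(cls, "other"))
        rows.append((cls, a, float(expected), b, res.odds_ratio,
                     a / expected if expected else np.nan, res.p_value))
    return pd.DataFrame(rows, columns=["feature_class", "observed", "expected",
                                       "outside", "odds_ratio", "obs_over_exp",
                                       "p_value"])


def region_gc(regions: RegionSet, grid: WindowGrid) -> pd.Series:
    """Per-chromosome mean GC of windows overlapping the regions, weighted
    by overlap length."""
    retained = grid.retained
    out = {}
    any_nonempty = False
    for chrom in grid.chrom_lengths:
        arr = regions.get(chrom)
        sub = retained[retained["chrom"] == chrom]
        if len(arr) == 0 or sub.empty:
            out[chrom] = np.nan
            continue
        ov = iv.overlap_bp(sub["start"].to_numpy(), sub["end"].to_numpy(), arr)
        w = ov.astype(float)
        gc = sub["gc"].to_numpy(dtype=float)
        ok = (w > 0) & np.isfinite(gc)
        if not ok.any():
            out[chrom] = np.nan
            continue
        any_nonempty = True
        out[chrom] = float(np.average(gc[ok], weights=w[ok]))
    if not any_nonempty:
        raise DegenerateInputError("region set overlaps no retained windows")
    return pd.Series(out, name="mean_gc")


def compare_region_gc(regions_a: RegionSet, regions_b: RegionSet,
                      grid: WindowGrid) -> dict:
    """Paired two-sided t-test of per-chromosome mean GC between two region sets."""
    gc_a = region_gc(regions_a, grid)
    gc_b = region_gc(regions_b, grid)
    paired = pd.DataFrame({"a": gc_a, "b": gc_b}).dropna()
    diffs = paired["a"] - paired["b"]
    if len(paired) < 2 or np.allclose(diffs, 0):
        return {"mean_gc_a": float(gc_a.mean()), "mean_gc_b": float(gc_b.mean()),
                "t": np.nan, "p_value": np.nan, "degenerate": True,
                "n_chromosomes": int(len(paired))}
    t, p = sps.ttest_rel(paired["a"], paired["b"])
    return {"mean_gc_a": float(gc_a.mean()), "mean_gc_b": float(gc_b.mean()),
            "t": float(t), "p_value": float(p), "degenerate": False,
            "n_chromosomes": int(len(paired))}
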