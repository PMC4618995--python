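"""SNP-array B-allele-frequency validation of candidate CNVRs.

Array genotyping assumes two copies; inside a CNVR, genotypes like AAB or
hemizygous AØ shift the B-allele frequency away from the clean diploid
clusters at 0, 0.5 and 1. A SNP whose BAF falls in [0.05, 0.35] or
[0.65, 0.95] (endpoints inclusive) in at least 10% of samples is flagged
as aberrant; enrichment of aberrant SNPs inside CNVRs is an independent
check that called regions reflect real copy-number variation rather than
read-depth artifacts.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calling import CNVRSet
from .errors import InvalidParameterError, ValidationError
from .stats import EnrichmentResult, fisher_exact_2x2
from .windows import RETAINED, WindowGrid

log = logging.getLogger(__name__)

META_COLUMNS = ["snp_id", "chrom", "pos"]


@dataclass
class BAFConfig:
    """Aberrant-BAF ranges and the minimum carrier fraction."""

    lo: float = 0.05
    hi: float = 0.35
    lo2: float = 0.65
    hi2: float = 0.95
    min_carrier_fraction: float = 0.10

    def __post_init__(self):
        for v in (self.lo, self.hi, self.lo2, self.hi2):
            if not (0 < v < 1):
                raise InvalidParameterError("aberrant range endpoints must be in (0, 1)")
        if not (0 < self.min_carrier_fraction <= 1):
            raise InvalidParameterError("min_carrier_fraction must be in (0, 1]")

    def carrier_threshold(self, n_samples: int) -> int:
        """Minimum count of aberrant-range samples for a SNP to qualify."""
        return math.ceil(self.min_carrier_fraction * n_samples)


def _sample_columns(table: pd.DataFrame) -> list:
    return [c for c in table.columns if c not in META_COLUMNS]


def _validate_table(table: pd.DataFrame):
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"BAF table missing columns {missing}")
    vals = table[_sample_columns(table)].to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if np.any((finite < 0) | (finite > 1)):
        raise ValidationError("BAF values must lie in [0, 1]")


def filter_snps(table: pd.DataFrame, grid: WindowGrid) -> pd.DataFrame:
    """Drop SNPs that fall in removed windows or outside the tiled region."""
    _validate_table(table)
    keep = np.zeros(len(table), dtype=bool)
    status_by_chrom = {
        chrom: sub["status"].to_numpy()
        for chrom, sub in grid.windows.groupby("chrom", sort=False)
    }
    for i, (chrom, pos) in enumerate(zip(table["chrom"], table["pos"])):
        status = status_by_chrom.get(chrom)
        if status is None:
            continue
        w = int(pos) // grid.window_size
        if w < len(status) and status[w] == RETAINED:
            keep[i] = True
    dropped = int((~keep).sum())
    if dropped:
        log.info("filter_snps: dropped %d of %d SNPs in removed/untiled regions",
                 dropped, len(table))
    return table.loc[keep].reset_index(drop=True)


def classify_aberrant(table: pd.DataFrame, config: BAFConfig = None) -> pd.Series:
    """Flag SNPs whose BAF is aberrant in at least the carrier fraction of samples.

    Missing BAFs count as non-aberrant observations (the denominator is the
    full sample count).
    """
    config = config or BAFConfig()
    _validate_table(table)
    samples = _sample_columns(table)
    if not samples:
        raise ValidationError("BAF table has no sample columns")
    vals = table[samples].to_numpy(dtype=float)
    in_range = (((vals >= config.lo) & (vals <= config.hi))
                | ((vals >= config.lo2) & (vals <= config.hi2)))
    in_range = np.where(np.isfinite(vals), in_range, False)
    thr = config.carrier_threshold(len(samples))
    flags = in_range.sum(axis=1) >= thr
    return pd.Series(flags, index=table.index, name="aberrant")


def snp_in_cnvr(table: pd.DataFrame, cnvrs: CNVRSet) -> pd.Series:
    """True where the SNP position lies inside a CNVR's half-open interval."""
    flags = np.zeros(len(table), dtype=bool)
    by_chrom = cnvrs.intervals_by_chrom()
    for chrom, arr in by_chrom.items():
        sel = (table["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        pos = table.loc[sel, "pos"].to_numpy(dtype=np.int64)
        idx = np.searchsorted(arr[:, 0], pos, side="right") - 1
        ok = idx >= 0
        safe = np.clip(idx, 0, None)
        flags[sel] = ok & (pos < arr[safe, 1])
    return pd.Series(flags, index=table.index, name="in_cnvr")


def cnvr_baf_tests(table: pd.DataFrame, aberrant: pd.Series, cnvrs: CNVRSet,
                   grid: WindowGrid = None) -> dict:
    """Enrichment of aberrant SNPs inside CNVRs, and SNP depletion in CNVRs.

    Enrichment: Fisher exact on aberrant/disomic x in/out counts.
    Depletion: binomial test of the in-CNVR SNP count against the CNVR
    fraction of analyzed bases (requires ``grid``).
    """
    if len(cnvrs) == 0:
        log.warning("cnvr_baf_tests: empty CNVR set; tests undefined")
        return {"enrichment": None, "depletion": None}
    inside = snp_in_cnvr(table, cnvrs)
    ab = aberrant.to_numpy(dtype=bool)
    ins = inside.to_numpy(dtype=bool)
    a = int((ab & ins).sum())
    b = int((ab & ~ins).sum())
    c = int((~ab & ins).sum())
    d = int((~ab & ~ins).sum())
    enrichment = fisher_exact_2x2([[a, b], [c, d]],
                                  row_labels=("aberrant", "disomic"),
                                  col_labels=("in_cnvr", "outside"))
    depletion = None
    if grid is not None:
        frac = cnvrs.total_bp / grid.retained_bp()
        res = sps.binomtest(int(ins.sum()), n=len(table), p=frac,
                            alternative="two-sided")
        depletion = {
            "in_cnvr": int(ins.sum()),
            "total": int(len(table)),
            "expected_fraction": frac,
            "observed_fraction": float(ins.sum() / len(table)),
            "p_value": float(res.pvalue),
        }
    return {"enrichment": enrichment, "depletion": depletion}
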