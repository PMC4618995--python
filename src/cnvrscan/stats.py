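"""Shared contingency-table statistics: Fisher's exact test and BH adjustment."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = ["EnrichmentResult", "fisher_exact_2x2", "bh_adjust"]


@dataclass
class EnrichmentResult:
    """Outcome of a 2x2 enrichment/depletion test.

    ``fold`` is the rate ratio (a/(a+b)) / (c/(c+d)); ``odds_ratio`` is the
    sample odds ratio ad/bc (inf or 0 at zero cells). ``degenerate`` marks
    tables where one of the rates is undefined.
    """

    table: np.ndarray
    odds_ratio: float
    fold: float
    p_value: float
    row_labels: tuple = ("group", "non-group")
    col_labels: tuple = ("inside", "outside")
    degenerate: bool = field(default=False)

    def as_dict(self) -> dict:
        a, b = self.table[0]
        c, d = self.table[1]
        return {
            "a": int(a), "b": int(b), "c": int(c), "d": int(d),
            "odds_ratio": self.odds_ratio, "fold": self.fold,
            "p_value": self.p_value, "degenerate": self.degenerate,
        }


def fisher_exact_2x2(table, row_labels=("group", "non-group"),
                     col_labels=("inside", "outside")) -> EnrichmentResult:
    """Two-sided Fisher's exact test on a 2x2 table of non-negative integers.

    The two-sided p-value sums hypergeometric point probabilities of every
    table with the same margins whose probability does not exceed that of
    the observed table.
    """
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValidationError("contingency table contains negative counts")
    if arr.sum() == 0:
        raise ValidationError("contingency table has no observations")
    a, b = arr[0]
    c, d = arr[1]

    _, p = sps.fisher_exact(arr, alternative="two-sided")

    if b * c == 0:
        odds = np.inf if a * d > 0 else (0.0 if a + d == 0 or b + c > 0 else np.nan)
        if a * d == 0:
            odds = np.nan  # 0/0: no information
    else:
        odds = (a * d) / (b * c)

    degenerate = False
    if a + b == 0 or c + d == 0:
        fold = np.nan
        degenerate = True
    else:
        rate_in = a / (a + b)
        rate_out = c / (c + d)
        if rate_out == 0:
            fold = np.inf if rate_in > 0 else np.nan
            degenerate = rate_in == 0
        else:
            fold = rate_in / rate_out
    return EnrichmentResult(table=arr, odds_ratio=float(odds), fold=float(fold),
                            p_value=float(p), row_labels=tuple(row_labels),
                            col_labels=tuple(col_labels), degenerate=degenerate)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR control)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
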