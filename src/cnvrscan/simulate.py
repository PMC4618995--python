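"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a low-coverage resequencing cohort on a toy
multi-chromosome genome: planted multi-copy-state CNVRs, per-window GC
fractions with a unimodal multiplicative depth bias, overdispersed
(negative-binomial) window counts proportional to copy number, masked and
N-rich regions, gene/repeat annotations with configurable resistance-gene
clustering inside CNVRs, and SNP-array BAF matrices with disomic clusters
at {0, 0.5, 1} and CNV-distorted clusters. Every generator is a pure
function of its parameters and seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import intervals as iv
from .errors import InvalidParameterError, PlacementError
from .windows import WindowGrid, DepthMatrix, STAGE_RAW, apply_exclusion_masks, build_windows

DEFAULT_WINDOW = 3000


@dataclass
class GenomeSpec:
    """A toy reference: chromosome sizes, per-window GC, masked/N intervals."""

    chrom_lengths: Dict[str, int]
    window_size: int
    gc: Dict[str, np.ndarray]  # per-window GC fraction per chromosome
    masked: List[Tuple[str, int, int, str]] = field(default_factory=list)
    n_rich: List[Tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise InvalidParameterError(f"chromosome {chrom} has non-positive length")
            g = np.asarray(self.gc[chrom], dtype=float)
            if np.any((g < 0) | (g > 1)):
                raise InvalidParameterError("GC fractions must lie in [0, 1]")
        for chrom, start, end, *_ in list(self.masked) + list(self.n_rich):
            if not (0 <= start <= end <= self.chrom_lengths[chrom]):
                raise InvalidParameterError("interval outside its chromosome")

    def n_windows(self, chrom: str) -> int:
        return self.chrom_lengths[chrom] // self.window_size

    def to_grid(self) -> WindowGrid:
        """Build the analysis window grid with GC/N tracks and exclusion masks."""
        n_frac = {}
        for chrom in self.chrom_lengths:
            n = self.n_windows(chrom)
            nf = np.zeros(n)
            ivals = [(s, e) for c, s, e in self.n_rich if c == chrom]
            if ivals:
                merged = iv.merge_intervals(ivals)
                starts = np.arange(n, dtype=np.int64) * self.window_size
                nf = iv.overlap_bp(starts, starts + self.window_size,
                                   merged) / self.window_size
            n_frac[chrom] = nf
        grid = build_windows(self.chrom_lengths, self.window_size,
                             gc=self.gc, n_frac=n_frac)
        excl = [(c, s, e) for c, s, e, _ in self.masked]
        if excl:
            grid = apply_exclusion_masks(grid, excl)
        return grid


@dataclass
class CNVPlan:
    """Ground-truth CNVR intervals and per-sample integer copy states."""

    regions: pd.DataFrame  # chrom, start, end
    states: np.ndarray  # (n_cnvrs, n_samples), diploid baseline 2
    sample_names: List[str]

    def __len__(self):
        return len(self.regions)

    def intervals_by_chrom(self) -> Dict[str, np.ndarray]:
        out = {}
        for chrom, sub in self.regions.groupby("chrom", sort=False):
            out[chrom] = sub[["start", "end"]].to_numpy(dtype=np.int64)
        return out


@dataclass
class SimParams:
    """Cohort-level depth-model parameters.

    ``coverage`` is per-sample fold-coverage (scalar or one value per
    sample); the default range matches a low-coverage cohort spanning
    roughly 1x to 5x. ``dispersion`` is the negative-binomial size
    parameter (variance = mu + mu^2 / dispersion; ``inf`` gives Poisson).
    ``gc_bias_strength`` scales a quadratic multiplicative bias peaking at
    GC = ``gc_bias_peak``; 0 disables it.
    """

    n_samples: int = 30
    coverage: object = None  # scalar, sequence, or None -> spread over [0.95, 4.96]
    dispersion: float = 50.0
    gc_bias_strength: float = 4.0
    gc_bias_peak: float = 0.40
    read_length: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise InvalidParameterError("n_samples must be >= 1")
        if not (self.dispersion > 0):
            raise InvalidParameterError("dispersion must be positive")
        if self.read_length <= 0:
            raise InvalidParameterError("read_length must be positive")

    def coverages(self) -> np.ndarray:
        if self.coverage is None:
            return np.linspace(0.95, 4.96, self.n_samples)
        cov = np.broadcast_to(np.asarray(self.coverage, dtype=float),
                              (self.n_samples,)).copy()
        if np.any(cov <= 0):
            raise InvalidParameterError("coverage must be positive")
        return cov

    def gc_bias(self, gc: np.ndarray) -> np.ndarray:
        """Multiplicative depth factor, 1 at the peak GC, floored at 0.05."""
        b = 1.0 - self.gc_bias_strength * (np.asarray(gc, dtype=float)
                                           - self.gc_bias_peak) ** 2
        return np.maximum(b, 0.05)


def _random_intervals(rng, length: int, target_bp: int, mean_len: int) -> list:
    """Random intervals until ~target_bp of the chromosome is covered."""
    out = []
    covered = 0
    guard = 0
    while covered < target_bp and guard < 10_000:
        guard += 1
        w = max(int(rng.exponential(mean_len)), mean_len // 4)
        s = int(rng.integers(0, max(length - w, 1)))
        out.append((s, min(s + w, length)))
        merged = iv.merge_intervals(out)
        covered = iv.total_bp(merged)
    return [tuple(x) for x in iv.merge_intervals(out)] if out else []


def simulate_genome(n_chromosomes: int, chromosome_length: int,
                    mask_fraction: float = 0.0, seed: int = 0,
                    window_size: int = DEFAULT_WINDOW,
                    n_rich_fraction: float = 0.0,
                    gc_beta: Tuple[float, float] = (57.0, 93.0)) -> GenomeSpec:
    """Toy genome with Beta-distributed per-window GC (mean 0.38 by default)
    and random masked / N-rich intervals covering about the given fractions."""
    if n_chromosomes < 1:
        raise InvalidParameterError("n_chromosomes must be >= 1")
    if chromosome_length <= 0:
        raise InvalidParameterError("chromosome_length must be positive")
    if not (0 <= mask_fraction < 0.9):
        raise InvalidParameterError("mask_fraction must be in [0, 0.9)")
    rng = np.random.default_rng(seed)
    lengths = {f"chr{i + 1}": int(chromosome_length) for i in range(n_chromosomes)}
    gc = {c: rng.beta(*gc_beta, size=L // window_size)
          for c, L in lengths.items()}
    masked = []
    n_rich = []
    for chrom, L in lengths.items():
        if mask_fraction > 0:
            for s, e in _random_intervals(rng, L, int(mask_fraction * L),
                                          mean_len=5 * window_size):
                cls = "organelle" if rng.random() < 0.2 else "repeat"
                masked.append((chrom, int(s), int(e), cls))
        if n_rich_fraction > 0:
            for s, e in _random_intervals(rng, L, int(n_rich_fraction * L),
                                          mean_len=2 * window_size):
                n_rich.append((chrom, int(s), int(e)))
    return GenomeSpec(lengths, window_size, gc, masked, n_rich)


def plant_cnvrs(genome: GenomeSpec, n_cnvrs: int,
                size_range: Tuple[int, int] = (3_000, 99_000),
                copy_states: Dict[int, float] = None,
                n_samples: int = 30, seed: int = 0,
                carrier_probability: float = 0.15,
                max_tries: int = 2_000) -> CNVPlan:
    """Place non-overlapping, window-aligned true CNVRs away from masks.

    Each sample is independently a carrier at each CNVR with probability
    ``carrier_probability``; carriers draw their copy state from
    ``copy_states`` (a distribution over {0..4}) and non-carriers stay
    diploid, so most samples are diploid at any one region as in real
    cohorts. Each CNVR is forced to keep at least one diploid and at least
    one non-diploid sample.
    """
    if n_cnvrs < 0:
        raise InvalidParameterError("n_cnvrs must be >= 0")
    copy_states = copy_states or {0: 0.1, 1: 0.3, 3: 0.4, 4: 0.2}
    states_support = np.array(sorted(copy_states), dtype=int)
    probs = np.array([copy_states[s] for s in states_support], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    sample_names = [f"S{i + 1:02d}" for i in range(n_samples)]
    if n_cnvrs == 0:
        return CNVPlan(pd.DataFrame(columns=["chrom", "start", "end"]),
                       np.zeros((0, n_samples), dtype=int), sample_names)

    w = genome.window_size
    masked_by_chrom = {c: iv.merge_intervals([(s, e) for cc, s, e, _ in genome.masked
                                              if cc == c] +
                                             [(s, e) for cc, s, e in genome.n_rich
                                              if cc == c])
                       for c in genome.chrom_lengths}
    chroms = list(genome.chrom_lengths)
    placed: Dict[str, list] = {c: [] for c in chroms}
    rows = []
    for _ in range(n_cnvrs):
        ok = False
        for _try in range(max_tries):
            chrom = chroms[int(rng.integers(len(chroms)))]
            size_bp = int(rng.integers(size_range[0], size_range[1] + 1))
            n_win = max(1, int(round(size_bp / w)))
            total_win = genome.n_windows(chrom)
            if n_win >= total_win:
                continue
            s_win = int(rng.integers(0, total_win - n_win + 1))
            start, end = s_win * w, (s_win + n_win) * w
            mask = masked_by_chrom[chrom]
            if len(mask) and iv.overlap_bp([start], [end], mask)[0] > 0:
                continue
            # keep one window of separation so planted regions never merge
            clash = any(start < pe + w and end + w > ps
                        for ps, pe in placed[chrom])
            if clash:
                continue
            placed[chrom].append((start, end))
            rows.append((chrom, start, end))
            ok = True
            break
        if not ok:
            raise PlacementError("could not place a CNVR after bounded retries")

    regions = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    order = regions.sort_values(["chrom", "start"]).index
    regions = regions.loc[order].reset_index(drop=True)

    if not (0 < carrier_probability <= 1):
        raise InvalidParameterError("carrier_probability must be in (0, 1]")
    carrier = rng.random((n_cnvrs, n_samples)) < carrier_probability
    drawn = rng.choice(states_support, size=(n_cnvrs, n_samples), p=probs)
    states = np.where(carrier, drawn, 2)
    non_diploid = states_support[states_support != 2]
    fallback = int(non_diploid[0]) if len(non_diploid) else 3
    for i in range(n_cnvrs):
        if not np.any(states[i] == 2):
            states[i, int(rng.integers(n_samples))] = 2
        if not np.any(states[i] != 2):
            j = int(rng.integers(n_samples))
            states[i, j] = fallback
    return CNVPlan(regions, states.astype(int), sample_names)


def _copy_matrix(genome: GenomeSpec, plan: CNVPlan, grid: WindowGrid) -> np.ndarray:
    """Per retained window x sample copy number (diploid 2 outside CNVRs)."""
    retained = grid.retained.reset_index(drop=True)
    n_samples = plan.states.shape[1] if len(plan) else 0
    copy = np.full((len(retained), max(n_samples, 1)), 2.0)
    for ri, (_, region) in enumerate(plan.regions.iterrows()):
        sel = ((retained["chrom"] == region["chrom"])
               & (retained["start"] >= region["start"])
               & (retained["end"] <= region["end"])).to_numpy()
        copy[sel, :] = plan.states[ri][None, :]
    return copy


def simulate_depth(genome: GenomeSpec, plan: CNVPlan, params: SimParams,
                   grid: WindowGrid = None) -> DepthMatrix:
    """Negative-binomial window counts: mean = base_s * (copy/2) * gcbias(GC).

    ``base_s`` is coverage * window_size / read_length, the expected read
    count of a diploid window at the sample's coverage.
    """
    grid = grid or genome.to_grid()
    retained = grid.retained.reset_index(drop=True)
    rng = np.random.default_rng(params.seed)
    cov = params.coverages()
    n_samples = params.n_samples
    if len(plan) and plan.states.shape[1] != n_samples:
        raise InvalidParameterError("plan and params disagree on sample count")
    gc = retained["gc"].to_numpy(dtype=float)
    bias = params.gc_bias(gc)
    copy = _copy_matrix(genome, plan, grid)
    if copy.shape[1] == 1 and n_samples > 1:
        copy = np.repeat(copy, n_samples, axis=1)
    base = cov * genome.window_size / params.read_length
    mu = base[None, :] * (copy / 2.0) * bias[:, None]
    if math.isinf(params.dispersion):
        counts = rng.poisson(mu)
    else:
        k = params.dispersion
        counts = np.where(mu > 0,
                          rng.negative_binomial(k, k / (k + np.maximum(mu, 1e-300))),
                          0)
    names = plan.sample_names if len(plan) else [f"S{i + 1:02d}" for i in range(n_samples)]
    values = pd.DataFrame(counts.astype(np.int64),
                          index=pd.MultiIndex.from_frame(retained[["chrom", "start"]]),
                          columns=names[:n_samples])
    return DepthMatrix(values, stage=STAGE_RAW,
                       meta={"coverage": cov.tolist(), "dispersion": params.dispersion})


def simulate_baf(plan: CNVPlan, genome: GenomeSpec, n_snps: int, n_samples: int,
                 noise_sd: float = 0.02, aberrant_fraction_in_cnvr: float = 1.0,
                 seed: int = 0) -> pd.DataFrame:
    """SNP-array BAF table with diploid clusters and CNV-distorted clusters.

    Disomic calls cluster at {0, 0.5, 1}. Inside a CNVR, carrier samples
    (copy state != 2) draw from duplication clusters {1/3, 2/3} when
    heterozygous, or homozygote-only {0, 1} patterns under hemizygous
    deletion; zero-copy samples are missing. Gaussian noise is truncated
    to [0, 1].
    """
    if n_snps < 1:
        raise InvalidParameterError("n_snps must be >= 1")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    chroms = list(genome.chrom_lengths)
    chrom_choice = rng.integers(0, len(chroms), size=n_snps)
    pos = np.array([int(rng.integers(0, genome.chrom_lengths[chroms[c]]))
                    for c in chrom_choice], dtype=np.int64)
    snp_chrom = [chroms[c] for c in chrom_choice]

    by_chrom = plan.intervals_by_chrom()
    region_idx = np.full(n_snps, -1)
    offsets = {}
    off = 0
    for chrom, sub in plan.regions.groupby("chrom", sort=False):
        offsets[chrom] = sub.index.to_numpy()
    for i in range(n_snps):
        arr = by_chrom.get(snp_chrom[i])
        if arr is None or len(arr) == 0:
            continue
        j = np.searchsorted(arr[:, 0], pos[i], side="right") - 1
        if j >= 0 and pos[i] < arr[j, 1]:
            region_idx[i] = offsets[snp_chrom[i]][j]

    baf = np.empty((n_snps, n_samples))
    geno = rng.choice([0.0, 0.5, 1.0], size=(n_snps, n_samples),
                      p=[0.25, 0.5, 0.25])
    distort = rng.random((n_snps, n_samples)) < aberrant_fraction_in_cnvr
    for i in range(n_snps):
        baf[i] = geno[i]
        r = region_idx[i]
        if r < 0:
            continue
        states = plan.states[r]
        for s in range(n_samples):
            st = states[s % plan.states.shape[1]]
            if st == 2 or not distort[i, s]:
                continue
            if st == 0:
                baf[i, s] = np.nan
            elif st == 1:
                # hemizygous: heterozygotes collapse to a single allele
                if geno[i, s] == 0.5:
                    baf[i, s] = float(rng.integers(0, 2))
            else:
                # duplication: AAB / ABB style clusters
                if geno[i, s] == 0.5:
                    baf[i, s] = 1.0 / 3 if rng.random() < 0.5 else 2.0 / 3
    if noise_sd > 0:
        noise = rng.normal(0, noise_sd, size=baf.shape)
        baf = np.clip(baf + noise, 0.0, 1.0)

    table = pd.DataFrame({"snp_id": [f"snp{i + 1}" for i in range(n_snps)],
                          "chrom": snp_chrom, "pos": pos})
    for s in range(n_samples):
        table[f"A{s + 1:03d}"] = baf[:, s]
    return table.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def simulate_annotations(genome: GenomeSpec, plan: CNVPlan, n_genes: int = 5_000,
                         r_gene_fraction: float = 0.02,
                         r_gene_cnvr_enrichment: float = 1.0,
                         repeat_classes: Sequence[str] = ("Gypsy", "Copia", "LINE"),
                         n_repeats: int = 2_000, seed: int = 0) -> pd.DataFrame:
    """BED-like gene and repeat annotations.

    Non-R genes and repeats place uniformly; an R gene's odds of landing
    inside a true CNVR are multiplied by ``r_gene_cnvr_enrichment``.
    """
    if not (0 <= r_gene_fraction <= 1):
        raise InvalidParameterError("r_gene_fraction must be in [0, 1]")
    if r_gene_cnvr_enrichment < 1:
        raise InvalidParameterError("enrichment must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = list(genome.chrom_lengths)
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()
    total_bp = lengths.sum()
    cnvr_bp = int((plan.regions["end"] - plan.regions["start"]).sum()) if len(plan) else 0
    f = cnvr_bp / total_bp if total_bp else 0.0
    e = r_gene_cnvr_enrichment
    p_in = (e * f) / (e * f + (1 - f)) if f > 0 else 0.0
    regions = plan.regions

    def uniform_pos(size_bp):
        ci = int(rng.choice(len(chroms), p=chrom_p))
        chrom = chroms[ci]
        start = int(rng.integers(0, max(genome.chrom_lengths[chrom] - size_bp, 1)))
        return chrom, start

    rows = []
    n_r = int(round(n_genes * r_gene_fraction))
    for i in range(n_genes):
        size = int(rng.integers(1_000, 5_001))
        is_r = i < n_r
        if is_r and len(regions) and rng.random() < p_in:
            ri = int(rng.integers(len(regions)))
            reg = regions.iloc[ri]
            span = reg["end"] - reg["start"]
            size = min(size, int(span))
            start = int(reg["start"] + rng.integers(0, span - size + 1))
            chrom = reg["chrom"]
        else:
            chrom, start = uniform_pos(size)
        rows.append((chrom, start, start + size, f"gene{i + 1}",
                     "r_gene" if is_r else "gene"))
    for i in range(n_repeats):
        size = int(rng.integers(300, 5_001))
        chrom, start = uniform_pos(size)
        cls = repeat_classes[int(rng.integers(len(repeat_classes)))]
        rows.append((chrom, start, start + size, f"rep{i + 1}", f"repeat:{cls}"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "feature_id",
                                     "feature_class"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def standard_cohort(seed: int = 0, n_samples: int = 30, coverage: float = 3.0,
                    n_cnvrs: int = 20, size_range: Tuple[int, int] = (9_000, 60_000),
                    n_chromosomes: int = 2, chromosome_length: int = 18_000_000,
                    copy_states: Dict[int, float] = None,
                    carrier_probability: float = 0.15,
                    mask_fraction: float = 0.05):
    """The reference synthetic cohort used for end-to-end recovery checks.

    Thirty samples at 3x coverage with twenty 9-60 kb CNVRs planted on two
    18-Mb chromosomes put roughly 2% of the analyzed genome inside CNVRs
    with 4-5 carriers per region — population-scale proportions for common
    CNVs in a resequencing cohort. Returns (genome, plan, params, grid,
    raw DepthMatrix).
    """
    ss = np.random.SeedSequence(seed)
    s_genome, s_plan, s_depth = (int(c.generate_state(1)[0] >> 33)
                                 for c in ss.spawn(3))
    genome = simulate_genome(n_chromosomes, chromosome_length,
                             mask_fraction=mask_fraction, seed=s_genome)
    plan = plant_cnvrs(genome, n_cnvrs, size_range,
                       copy_states or {0: 0.1, 1: 0.3, 3: 0.4, 4: 0.2},
                       n_samples=n_samples, seed=s_plan,
                       carrier_probability=carrier_probability)
    params = SimParams(n_samples=n_samples, coverage=coverage, seed=s_depth)
    grid = genome.to_grid()
    matrix = simulate_depth(genome, plan, params, grid)
    return genome, plan, params, grid, matrix


def emit_alignment_fixture(genome: GenomeSpec, plan: CNVPlan, params: SimParams,
                           path, sample_index: int = 0,
                           duplicate_fraction: float = 0.0,
                           low_mapq_fraction: float = 0.0,
                           max_reads: int = 100_000) -> int:
    """Write a small sorted SAM file matching the depth model for one sample.

    Reads are placed wholly inside their window so the leftmost-base
    counting rule recovers the simulated per-window counts. Returns the
    number of reads written.
    """
    import pysam

    matrix = simulate_depth(genome, plan, params)
    counts = matrix.values.iloc[:, sample_index].to_numpy()
    total = int(counts.sum())
    if total > max_reads:
        raise InvalidParameterError(
            f"fixture would contain {total} reads (> {max_reads}); reduce coverage")
    grid = genome.to_grid()
    retained = grid.retained.reset_index(drop=True)
    rng = np.random.default_rng(params.seed + 104_729)
    rl = params.read_length

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": c, "LN": int(L)} for c, L in genome.chrom_lengths.items()]}
    n_written = 0
    try:
        out = pysam.AlignmentFile(str(path), "wh", header=header)
    except OSError as exc:
        raise IOError(f"cannot write SAM fixture to {path}: {exc}") from exc
    with out:
        refs = {c: i for i, c in enumerate(genome.chrom_lengths)}
        for chrom, sub in retained.groupby("chrom", sort=False):
            recs = []
            for (_, win), c in zip(sub.iterrows(), counts[sub.index.to_numpy()]):
                if c == 0:
                    continue
                starts = win["start"] + rng.integers(0, grid.window_size - rl,
                                                     size=int(c))
                recs.extend(int(s) for s in starts)
            recs.sort()
            for ri, start in enumerate(recs):
                a = pysam.AlignedSegment()
                a.query_name = f"{chrom}_r{ri}"
                a.reference_id = refs[chrom]
                a.reference_start = start
                a.mapping_quality = 19 if rng.random() < low_mapq_fraction else 60
                a.cigarstring = f"{rl}M"
                a.query_sequence = "A" * rl
                a.flag = 0
                if rng.random() < duplicate_fraction:
                    a.flag |= 1024
                out.write(a)
                n_written += 1
    return n_written
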