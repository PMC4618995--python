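"""Trimmed SD, segment-shuffling permutation FDR, and CNVR calling."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cnvrscan.calling import (CNVRSet, FDRCurve, call_cnvrs, empirical_fdr,
                              permute_profile, summarize_cnvrs, trimmed_sd,
                              trimmed_sd_track)
from cnvrscan.errors import DegenerateInputError, InvalidParameterError
from cnvrscan.segment import ProfileEntry, SegmentProfile
from cnvrscan.windows import build_windows

W = 3000


def grid_one_chrom(n_windows, n_rich=()):
    gc = np.full(n_windows, 0.4)
    nf = np.zeros(n_windows)
    for i in n_rich:
        nf[i] = 1.0
    return build_windows({"c": n_windows * W}, W, gc={"c": gc}, n_frac={"c": nf})


def scores_frame(mat, grid):
    retained = grid.retained
    idx = pd.MultiIndex.from_frame(retained[["chrom", "start"]])
    return pd.DataFrame(np.asarray(mat, float), index=idx,
                        columns=[f"S{j + 1}" for j in range(np.shape(mat)[1])])


def brute_trimmed_sd(values):
    x = np.sort(np.asarray(values, float))
    return float(np.std(x[1:-1], ddof=1))


# ---------------------------------------------------------------- trimmed SD

def test_trimmed_sd_hand_examples():
    assert trimmed_sd([1, 2, 3, 4, 5]) == pytest.approx(1.0)
    assert trimmed_sd([7, 7, 7, 7]) == pytest.approx(0.0)
    assert trimmed_sd([0, 0, 0, 10]) == pytest.approx(0.0)  # outlier absorbed


def test_trimmed_sd_removes_one_instance_under_ties():
    # min 1 appears twice: only one instance removed
    assert trimmed_sd([1, 1, 2, 9]) == pytest.approx(np.std([1, 2], ddof=1))


def test_trimmed_sd_needs_four_values():
    with pytest.raises(DegenerateInputError):
        trimmed_sd([1, 2, 3])
    with pytest.raises(DegenerateInputError):
        trimmed_sd([1, 2, np.nan, np.nan])


def test_trimmed_sd_brute_force_oracle():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        n = int(rng.integers(4, 40))
        x = rng.normal(0, rng.uniform(0.1, 5), size=n)
        assert trimmed_sd(x) == pytest.approx(brute_trimmed_sd(x),
                                              rel=1e-9, abs=1e-12)


def test_trimmed_sd_track_vectorized_matches_scalar():
    rng = np.random.default_rng(1)
    grid = grid_one_chrom(50)
    mat = rng.normal(size=(50, 8))
    mat[3, :5] = np.nan  # 3 finite -> NaN row... keep >=4 elsewhere
    mat[3, :] = np.nan
    mat[3, :3] = [1.0, 2.0, 3.0]
    scores = scores_frame(mat, grid)
    track = trimmed_sd_track(scores)
    assert np.isnan(track.iloc[3])
    for i in (0, 10, 49):
        assert track.iloc[i] == pytest.approx(brute_trimmed_sd(mat[i]))


# ------------------------------------------------------------ permute_profile

def entry(segments, rows=None):
    n = sum(hi - lo + 1 for lo, hi, _ in segments)
    return ProfileEntry("S1", "c", rows if rows is not None else np.arange(n),
                        list(segments))


def test_permute_single_segment_identity():
    e = entry([(0, 9, 1.5)])
    rng = np.random.default_rng(0)
    assert permute_profile(e, rng).segments == [(0, 9, 1.5)]


def test_permute_conserves_multiset_and_tiles():
    e = entry([(0, 4, 1.0), (5, 6, -2.0), (7, 19, 0.3)])
    rng = np.random.default_rng(1)
    for _ in range(20):
        p = permute_profile(e, rng)
        assert p.segments[0][0] == 0 and p.segments[-1][1] == 19
        for (a, b, _), (c, d, _) in zip(p.segments[:-1], p.segments[1:]):
            assert c == b + 1
        got = sorted((hi - lo + 1, sc) for lo, hi, sc in p.segments)
        want = sorted((hi - lo + 1, sc) for lo, hi, sc in e.segments)
        assert got == want


def test_permute_two_segments_uniform_orders():
    e = entry([(0, 2, 1.0), (3, 4, 2.0)])
    rng = np.random.default_rng(2)
    first = sum(permute_profile(e, rng).segments[0][2] == 1.0
                for _ in range(1000))
    stat, p = sps.chisquare([first, 1000 - first])
    assert p > 1e-3


# --------------------------------------------------------------- empirical FDR

def toy_profile_and_scores(rng, n_samples=8, n_windows=60, n_segments=6):
    """Random segment profiles; observed scores drawn by permuting segments
    (a global null by construction)."""
    grid = grid_one_chrom(n_windows)
    profile = SegmentProfile()
    mat = np.empty((n_windows, n_samples))
    for j in range(n_samples):
        cuts = np.sort(rng.choice(np.arange(1, n_windows), size=n_segments - 1,
                                  replace=False))
        bounds = np.concatenate([[0], cuts, [n_windows]])
        segs = [(int(a), int(b - 1), float(rng.normal(0, 1)))
                for a, b in zip(bounds[:-1], bounds[1:])]
        e = ProfileEntry(f"S{j + 1}", "c", np.arange(n_windows), segs)
        drawn = permute_profile(e, rng)
        for lo, hi, sc in drawn.segments:
            mat[lo:hi + 1, j] = sc
        profile.add(e)
    return grid, profile, scores_frame(mat, grid)


def test_empirical_fdr_global_null_near_one():
    rng = np.random.default_rng(3)
    grid, profile, scores = toy_profile_and_scores(rng)
    curve = empirical_fdr(scores, profile, grid, thresholds=[0.05, 0.1, 0.2],
                          n_permutations=400, seed=0)
    sub = curve.per_chrom[curve.per_chrom["observed"] >= 10]
    assert len(sub) > 0
    assert (sub["fdr"] >= 0.8).all()


def test_empirical_fdr_weight_identity_equal_lengths():
    rng = np.random.default_rng(4)
    n = 40
    grid = build_windows({"c1": n * W, "c2": n * W}, W,
                         gc={"c1": np.full(n, 0.4), "c2": np.full(n, 0.4)})
    profile = SegmentProfile()
    mat = np.empty((2 * n, 6))
    for j in range(6):
        for ci, chrom in enumerate(("c1", "c2")):
            rows = np.arange(ci * n, (ci + 1) * n)
            segs = [(0, n // 2 - 1, float(rng.normal())),
                    (n // 2, n - 1, float(rng.normal()))]
            profile.add(ProfileEntry(f"S{j + 1}", chrom, rows, segs))
            for lo, hi, sc in segs:
                mat[rows[lo:hi + 1], j] = sc
    scores = scores_frame(mat, grid)
    curve = empirical_fdr(scores, profile, grid, thresholds=[0.05, 0.2],
                          n_permutations=100, seed=1)
    for t in (0.05, 0.2):
        sub = curve.per_chrom[(curve.per_chrom["threshold"] == t)
                              & curve.per_chrom["fdr"].notna()]
        gw = curve.genome_wide.loc[curve.genome_wide["threshold"] == t,
                                   "fdr"].iloc[0]
        if len(sub):
            assert gw == pytest.approx(sub["fdr"].mean())
        else:
            assert np.isnan(gw)


def test_empirical_fdr_undefined_when_no_observed_exceedance():
    rng = np.random.default_rng(5)
    grid, profile, scores = toy_profile_and_scores(rng)
    big = float(np.nanmax(trimmed_sd_track(scores))) + 1.0
    curve = empirical_fdr(scores, profile, grid, thresholds=[big],
                          n_permutations=50, seed=0)
    assert np.isnan(curve.genome_wide["fdr"]).all()
    assert np.isnan(curve.threshold_at(0.15))


def test_empirical_fdr_validation():
    rng = np.random.default_rng(6)
    grid, profile, scores = toy_profile_and_scores(rng)
    with pytest.raises(InvalidParameterError):
        empirical_fdr(scores, profile, grid, [0.0], n_permutations=10)
    with pytest.raises(InvalidParameterError):
        empirical_fdr(scores, profile, grid, [0.1], n_permutations=0)
    with pytest.raises(DegenerateInputError):
        empirical_fdr(scores.iloc[:, :3], profile, grid, [0.1], n_permutations=10)


def test_fdr_threshold_at():
    gw = pd.DataFrame({"threshold": [0.1, 0.2, 0.3],
                       "fdr": [0.5, 0.12, np.nan]})
    curve = FDRCurve(per_chrom=pd.DataFrame(), genome_wide=gw, n_permutations=10)
    assert curve.threshold_at(0.15) == 0.2
    assert np.isnan(curve.threshold_at(0.01))


# ------------------------------------------------------------------- calling

def test_call_cnvrs_empty_below_threshold():
    grid = grid_one_chrom(10)
    track = pd.Series(np.full(10, 0.25))  # equal to threshold: strict rule
    cnvrs = call_cnvrs(track, grid, threshold=0.25)
    assert len(cnvrs) == 0
    assert cnvrs.total_bp == 0 and cnvrs.genome_fraction == 0.0


def test_call_cnvrs_contiguous_run_merges():
    grid = grid_one_chrom(10)
    tsd = np.zeros(10)
    tsd[5:8] = 0.3
    cnvrs = call_cnvrs(pd.Series(tsd), grid, threshold=0.25)
    assert len(cnvrs) == 1
    r = cnvrs.regions.iloc[0]
    assert (r["start"], r["end"]) == (5 * W, 8 * W)
    assert r["end"] - r["start"] == 9000
    assert r["n_windows"] == 3
    assert cnvrs.genome_fraction == pytest.approx(9000 / (10 * W))


def test_call_cnvrs_removed_window_splits():
    grid = grid_one_chrom(10, n_rich=[6])  # window 6 removed
    n_ret = grid.n_retained
    assert n_ret == 9
    tsd = np.zeros(n_ret)
    # retained positions 5 and 6 correspond to genomic windows 5 and 7
    tsd[5] = 0.4
    tsd[6] = 0.4
    cnvrs = call_cnvrs(pd.Series(tsd), grid, threshold=0.25)
    assert len(cnvrs) == 2
    assert cnvrs.regions["start"].tolist() == [5 * W, 7 * W]


def test_call_cnvrs_chromosome_boundary_never_merges():
    n = 4
    grid = build_windows({"c1": n * W, "c2": n * W}, W,
                         gc={"c1": np.full(n, 0.4), "c2": np.full(n, 0.4)})
    tsd = np.zeros(2 * n)
    tsd[n - 1] = 0.4  # last window of c1
    tsd[n] = 0.4      # first window of c2
    cnvrs = call_cnvrs(pd.Series(tsd), grid, threshold=0.25)
    assert len(cnvrs) == 2
    assert cnvrs.regions["chrom"].tolist() == ["c1", "c2"]


def test_calling_invariant_to_sample_order():
    rng = np.random.default_rng(7)
    grid = grid_one_chrom(40)
    mat = rng.normal(size=(40, 10))
    scores = scores_frame(mat, grid)
    shuffled = scores[list(rng.permutation(scores.columns))]
    t1 = trimmed_sd_track(scores)
    t2 = trimmed_sd_track(shuffled)
    assert np.allclose(t1.to_numpy(), t2.to_numpy())


def test_summarize_cnvrs():
    grid = grid_one_chrom(20)
    tsd = np.zeros(20)
    tsd[2] = 0.3                  # 3 kb region
    tsd[10:13] = 0.3              # 9 kb region
    cnvrs = call_cnvrs(pd.Series(tsd), grid, threshold=0.25)
    s = summarize_cnvrs(cnvrs, grid)
    assert s["count"] == 2
    assert s["min_bp"] == 3000 and s["max_bp"] == 9000
    assert s["mean_bp"] == pytest.approx(6000)
    assert s["median_bp"] == pytest.approx(6000)
    assert s["total_bp"] == 12000
    assert s["genome_fraction"] == pytest.approx(12000 / (20 * W))

    empty = call_cnvrs(pd.Series(np.zeros(20)), grid)
    s0 = summarize_cnvrs(empty, grid)
    assert s0["count"] == 0 and s0["total_bp"] == 0
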