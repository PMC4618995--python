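"""Synthetic-cohort generator: determinism, depth model, BAF clusters,
annotations and the SAM fixture round trip."""
import numpy as np
import pandas as pd
import pytest

from cnvrscan.errors import InvalidParameterError
from cnvrscan.normalize import gc_adjust, standardize
from cnvrscan.simulate import (CNVPlan, GenomeSpec, SimParams,
                               emit_alignment_fixture, plant_cnvrs,
                               simulate_annotations, simulate_baf,
                               simulate_depth, simulate_genome, standard_cohort)
from cnvrscan.windows import FilterConfig, count_reads

W = 3000


def test_simulate_genome_deterministic_and_shapes():
    g1 = simulate_genome(2, 300_000, mask_fraction=0.1, seed=5)
    g2 = simulate_genome(2, 300_000, mask_fraction=0.1, seed=5)
    assert list(g1.chrom_lengths) == ["chr1", "chr2"]
    assert all(np.array_equal(g1.gc[c], g2.gc[c]) for c in g1.chrom_lengths)
    assert g1.masked == g2.masked
    g3 = simulate_genome(2, 300_000, mask_fraction=0.1, seed=6)
    assert not all(np.array_equal(g1.gc[c], g3.gc[c]) for c in g1.chrom_lengths)
    assert len(g1.gc["chr1"]) == 100
    assert np.all((g1.gc["chr1"] >= 0) & (g1.gc["chr1"] <= 1))


def test_simulate_genome_gc_distribution():
    g = simulate_genome(1, 9_000_000, seed=0)
    assert g.gc["chr1"].mean() == pytest.approx(0.38, abs=0.01)


def test_genome_grid_masks_and_n_windows():
    g = simulate_genome(1, 600_000, mask_fraction=0.2, n_rich_fraction=0.05,
                        seed=2)
    grid = g.to_grid()
    assert grid.n_retained < len(grid.windows)
    statuses = set(grid.windows["status"])
    assert "removed_mask" in statuses or "removed_N" in statuses
    assert grid.masks  # read-level masks recorded


def test_genome_validation():
    with pytest.raises(InvalidParameterError):
        simulate_genome(0, 1000)
    with pytest.raises(InvalidParameterError):
        simulate_genome(1, 1000, mask_fraction=0.95)
    with pytest.raises(InvalidParameterError):
        GenomeSpec({"c": 9000}, W, {"c": np.array([0.4, 1.2, 0.4])})


def test_plant_cnvrs_geometry_and_carriers():
    g = simulate_genome(2, 1_200_000, mask_fraction=0.1, seed=3)
    n_samples = 200
    plan = plant_cnvrs(g, 8, (9_000, 30_000), n_samples=n_samples, seed=4,
                       carrier_probability=0.15)
    assert len(plan) == 8
    r = plan.regions
    # window-aligned and within chromosomes
    assert ((r["start"] % W == 0) & (r["end"] % W == 0)).all()
    # non-overlapping with >= 1 window separation per chromosome
    for _, sub in r.groupby("chrom"):
        s = sub.sort_values("start")
        assert (s["start"].to_numpy()[1:] - s["end"].to_numpy()[:-1] >= W).all()
    # no overlap with masked intervals
    from cnvrscan import intervals as iv
    for chrom, sub in r.groupby("chrom"):
        masked = iv.merge_intervals([(s, e) for c, s, e, _ in g.masked
                                     if c == chrom])
        if len(masked):
            ov = iv.overlap_bp(sub["start"].to_numpy(), sub["end"].to_numpy(),
                               masked)
            assert (ov == 0).all()
    # Bernoulli carrier rate near 15%, every region mixed
    carrier_frac = (plan.states != 2).mean()
    assert 0.10 < carrier_frac < 0.20
    assert np.all((plan.states != 2).any(axis=1))
    assert np.all((plan.states == 2).any(axis=1))
    assert set(np.unique(plan.states)) <= {0, 1, 2, 3, 4}


def test_plant_cnvrs_zero_and_validation():
    g = simulate_genome(1, 300_000, seed=0)
    plan = plant_cnvrs(g, 0, n_samples=5, seed=0)
    assert len(plan) == 0 and plan.states.shape == (0, 5)
    with pytest.raises(InvalidParameterError):
        plant_cnvrs(g, 2, n_samples=5, seed=0, carrier_probability=0.0)


def test_simulate_depth_mean_model():
    # law of large numbers: window count mean ~= coverage*W/read_len * bias
    g = simulate_genome(1, 9_000_000, mask_fraction=0.0, seed=1)
    plan = plant_cnvrs(g, 0, n_samples=2, seed=0)
    params = SimParams(n_samples=2, coverage=3.0, seed=7, gc_bias_strength=0.0)
    m = simulate_depth(g, plan, params)
    base = 3.0 * W / params.read_length  # 90
    assert m.values.to_numpy().mean() == pytest.approx(base, rel=0.02)
    # overdispersion: variance above Poisson, near NB with k=50
    v = m.values.to_numpy()[:, 0]
    expected_var = base + base ** 2 / 50
    assert np.var(v) == pytest.approx(expected_var, rel=0.15)


def test_simulate_depth_copy_ratio():
    g = simulate_genome(1, 3_000_000, seed=2)
    plan = plant_cnvrs(g, 1, (300_000, 600_000), copy_states={4: 1.0},
                       n_samples=40, seed=3, carrier_probability=0.99)
    params = SimParams(n_samples=40, coverage=3.0, seed=8, gc_bias_strength=0.0)
    grid = g.to_grid()
    m = simulate_depth(g, plan, params, grid)
    retained = grid.retained.reset_index(drop=True)
    region = plan.regions.iloc[0]
    inside = ((retained["start"] >= region["start"])
              & (retained["end"] <= region["end"])).to_numpy()
    carriers = plan.states[0] == 4
    vals = m.values.to_numpy()
    ratio = vals[inside][:, carriers].mean() / vals[~inside][:, carriers].mean()
    assert ratio == pytest.approx(2.0, rel=0.05)


def test_simulate_depth_deterministic_and_poisson():
    g = simulate_genome(1, 300_000, seed=0)
    plan = plant_cnvrs(g, 0, n_samples=3, seed=0)
    p = SimParams(n_samples=3, coverage=2.0, seed=9)
    a = simulate_depth(g, plan, p).values
    b = simulate_depth(g, plan, p).values
    assert a.equals(b)
    pois = SimParams(n_samples=3, coverage=2.0, seed=9, dispersion=float("inf"))
    m = simulate_depth(g, plan, pois)
    assert (m.values.to_numpy() >= 0).all()


def test_gc_bias_shape():
    p = SimParams(gc_bias_strength=4.0, gc_bias_peak=0.40)
    assert p.gc_bias(np.array([0.40]))[0] == pytest.approx(1.0)
    assert p.gc_bias(np.array([0.20]))[0] == pytest.approx(1 - 4 * 0.04)
    assert p.gc_bias(np.array([0.95]))[0] == 0.05  # floor


def test_simulate_baf_cluster_values():
    g = simulate_genome(1, 600_000, seed=4)
    plan = plant_cnvrs(g, 2, (60_000, 90_000), n_samples=20, seed=5,
                       carrier_probability=0.3)
    t = simulate_baf(plan, g, n_snps=400, n_samples=20, noise_sd=0.0, seed=6)
    vals = t[[c for c in t.columns if c.startswith("A")]].to_numpy()
    finite = vals[np.isfinite(vals)]
    clusters = {0.0, 0.5, 1.0, 1 / 3, 2 / 3}
    assert all(any(abs(v - c) < 1e-9 for c in clusters) for v in finite.ravel())
    # intermediate clusters appear only inside CNVRs
    from cnvrscan.baf import snp_in_cnvr
    from tests_helpers import make_cnvrset_from_plan
    cn = make_cnvrset_from_plan(plan)
    inside = snp_in_cnvr(t, cn).to_numpy()
    mid = np.isclose(vals, 1 / 3) | np.isclose(vals, 2 / 3)
    assert not mid[~inside].any()
    # zero-copy samples are missing somewhere inside
    if (plan.states == 0).any():
        assert np.isnan(vals[inside]).any()


def test_simulate_baf_noise_bounds_and_determinism():
    g = simulate_genome(1, 300_000, seed=4)
    plan = plant_cnvrs(g, 1, (30_000, 60_000), n_samples=10, seed=5)
    a = simulate_baf(plan, g, 100, 10, noise_sd=0.05, seed=1)
    b = simulate_baf(plan, g, 100, 10, noise_sd=0.05, seed=1)
    assert a.equals(b)
    vals = a[[c for c in a.columns if c.startswith("A")]].to_numpy()
    finite = vals[np.isfinite(vals)]
    assert ((finite >= 0) & (finite <= 1)).all()


def test_simulate_annotations_enrichment_knob():
    g = simulate_genome(2, 3_000_000, seed=6)
    plan = plant_cnvrs(g, 10, (30_000, 90_000), n_samples=10, seed=7)
    flat = simulate_annotations(g, plan, n_genes=3000, r_gene_fraction=0.05,
                                r_gene_cnvr_enrichment=1.0, seed=8)
    rich = simulate_annotations(g, plan, n_genes=3000, r_gene_fraction=0.05,
                                r_gene_cnvr_enrichment=30.0, seed=8)
    from tests_helpers import make_cnvrset_from_plan
    from cnvrscan.enrichment import feature_overlap_fraction, RegionSet
    rs = RegionSet.from_intervals(
        (r.chrom, r.start, r.end) for r in plan.regions.itertuples())

    def r_gene_in_frac(df):
        r = df[df["feature_class"] == "r_gene"]
        return (feature_overlap_fraction(r, rs) > 0.7).mean()

    assert r_gene_in_frac(rich) > r_gene_in_frac(flat) + 0.1
    assert set(flat["feature_class"]) >= {"gene", "r_gene", "repeat:Gypsy"}


def test_standard_cohort_shapes_and_determinism():
    g1, p1, s1, grid1, m1 = standard_cohort(seed=3, n_samples=6, n_cnvrs=3,
                                            n_chromosomes=1,
                                            chromosome_length=600_000)
    g2, p2, s2, grid2, m2 = standard_cohort(seed=3, n_samples=6, n_cnvrs=3,
                                            n_chromosomes=1,
                                            chromosome_length=600_000)
    assert m1.values.equals(m2.values)
    assert p1.regions.equals(p2.regions)
    assert m1.values.shape == (grid1.n_retained, 6)


def test_alignment_fixture_round_trip(tmp_path):
    # counts recovered by count_reads equal the simulated counts exactly
    g = simulate_genome(1, 150_000, mask_fraction=0.0, seed=9)
    plan = plant_cnvrs(g, 1, (9_000, 15_000), n_samples=2, seed=10)
    params = SimParams(n_samples=2, coverage=1.0, seed=11)
    path = tmp_path / "s1.sam"
    n = emit_alignment_fixture(g, plan, params, path, sample_index=0)
    assert n > 0
    grid = g.to_grid()
    m = count_reads(path, grid, FilterConfig(mapq_min=20, window_size=W))
    want = simulate_depth(g, plan, params).values.iloc[:, 0].to_numpy()
    assert (m.values.iloc[:, 0].to_numpy() == want).all()


def test_alignment_fixture_filters(tmp_path):
    g = simulate_genome(1, 150_000, mask_fraction=0.0, seed=9)
    plan = plant_cnvrs(g, 0, n_samples=1, seed=0)
    params = SimParams(n_samples=1, coverage=1.0, seed=12)
    path = tmp_path / "s.sam"
    emit_alignment_fixture(g, plan, params, path, duplicate_fraction=0.3,
                           low_mapq_fraction=0.3)
    grid = g.to_grid()
    m = count_reads(path, grid, FilterConfig(mapq_min=20, window_size=W))
    tally = next(iter(m.meta["tally"].values()))
    assert tally["duplicate"] > 0 and tally["low_mapq"] > 0
    want = simulate_depth(g, plan, params).values.iloc[:, 0].to_numpy().sum()
    assert tally["records"] == want


def test_alignment_fixture_read_cap(tmp_path):
    g = simulate_genome(1, 600_000, seed=0)
    plan = plant_cnvrs(g, 0, n_samples=1, seed=0)
    params = SimParams(n_samples=1, coverage=5.0, seed=0)
    with pytest.raises(InvalidParameterError):
        emit_alignment_fixture(g, plan, params, tmp_path / "x.sam", max_reads=10)
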