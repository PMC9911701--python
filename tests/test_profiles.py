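"""Coverage matrices, metaprofiles, fold-change and attenuation summaries."""

import numpy as np
import pandas as pd
import pytest

import spikequant as sq
from spikequant.profiles import (
    CoverageTrack,
    ProfileMatrix,
    attenuation_summary,
    coverage_matrix,
    foldchange_profile,
    metaprofile,
    promoter_body_signal,
)

BW = 50


def track(values, strand=".", chrom="chr1"):
    return CoverageTrack(data={chrom: np.asarray(values, float)}, bin_width=BW,
                         strand=strand)


def region_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "id"])


def test_constant_track_fills_matrix():
    plus = track(np.full(200, 3.0), "+")
    minus = track(np.zeros(200), "-")
    regions = region_df([("chr1", 4000, 6000, "+", "g0")])
    mat = coverage_matrix(plus, minus, regions, upstream=1000, downstream=1000)
    assert mat.values.shape == (1, 40)
    assert np.allclose(mat.values, 3.0)
    assert mat.mask.all()


def test_matrix_equals_hand_indexed_slice():
    vals = np.arange(10.0)
    plus = track(vals, "+")
    minus = track(np.zeros(10), "-")
    regions = region_df([("chr1", 200, 400, "+", "g0")])
    mat = coverage_matrix(plus, minus, regions, upstream=100, downstream=100)
    np.testing.assert_array_equal(mat.values[0], vals[2:6])


def test_minus_strand_rows_reversed_and_from_minus_track():
    plus = track(np.arange(20.0), "+")
    minus = track(np.arange(20.0) * 10, "-")
    regions = region_df([("chr1", 400, 800, "-", "g0")])  # TSS at 800
    mat = coverage_matrix(plus, minus, regions, upstream=100, downstream=200)
    # sense window runs 800-100 .. 800+200 in transcription orientation:
    # genomic bins 17,16,15,14,13,12 descending from TSS
    np.testing.assert_array_equal(mat.values[0], [170, 160, 150, 140, 130, 120])


def test_strand_mode_swap_symmetry():
    plus = track(np.arange(20.0), "+")
    minus = track(np.arange(20.0) * 10, "-")
    regions = region_df([("chr1", 400, 800, "+", "g0")])
    sense = coverage_matrix(plus, minus, regions, upstream=100, downstream=100,
                            strand_mode="sense")
    anti = coverage_matrix(minus, plus, regions, upstream=100, downstream=100,
                           strand_mode="antisense")
    np.testing.assert_array_equal(sense.values, anti.values)


def test_out_of_range_bins_masked_zero():
    plus = track(np.full(10, 2.0), "+")
    minus = track(np.zeros(10), "-")
    regions = region_df([("chr1", 100, 400, "+", "g0")])
    mat = coverage_matrix(plus, minus, regions, upstream=300, downstream=100)
    assert not mat.mask[0, :4].any()
    assert np.allclose(mat.values[0, :4], 0.0)
    assert mat.mask[0, 4:].all()


def test_bin_width_mismatch_rejected():
    plus = track(np.zeros(10), "+")
    minus = CoverageTrack(data={"chr1": np.zeros(5)}, bin_width=100, strand="-")
    with pytest.raises(ValueError, match="bin width"):
        coverage_matrix(plus, minus, region_df([("chr1", 0, 100, "+", "g")]),
                        upstream=100, downstream=100)


def test_matrix_matches_bruteforce_random_instances():
    rng = np.random.default_rng(12)
    for trial in range(25):
        n_bins = 100
        pvals = rng.poisson(5, n_bins).astype(float)
        mvals = rng.poisson(5, n_bins).astype(float)
        plus, minus = track(pvals, "+"), track(mvals, "-")
        rows = []
        for i in range(rng.integers(1, 8)):
            a = int(rng.integers(10, 80)) * BW
            rows.append(("chr1", a, a + int(rng.integers(4, 20)) * BW,
                         rng.choice(["+", "-"]), f"r{i}"))
        regions = region_df(rows)
        up, down = 200, 400
        mat = coverage_matrix(plus, minus, regions, upstream=up, downstream=down)
        for i, (_, a, b, strand, _) in enumerate(rows):
            src = pvals if strand == "+" else mvals
            tss = a if strand == "+" else b
            if strand == "+":
                idx = [tss // BW - up // BW + k for k in range((up + down) // BW)]
            else:
                idx = [tss // BW + up // BW - 1 - k for k in range((up + down) // BW)]
            expected = [src[j] if 0 <= j < n_bins else 0.0 for j in idx]
            np.testing.assert_array_equal(mat.values[i], expected)


def test_metaprofile_single_region_is_row():
    plus = track(np.arange(30.0), "+")
    minus = track(np.zeros(30), "-")
    regions = region_df([("chr1", 500, 1000, "+", "g0")])
    mat = coverage_matrix(plus, minus, regions, upstream=200, downstream=200)
    meta = metaprofile(mat)
    np.testing.assert_array_equal(meta["mean"], mat.values[0])
    assert (meta["n"] == 1).all()


def test_metaprofile_mean_of_rows():
    pm = ProfileMatrix(
        values=np.array([[0.0] * 5, [2.0] * 5]),
        mask=np.ones((2, 5), bool),
        region_ids=["a", "b"],
        offsets=np.arange(5) * 50.0,
        bin_width=50,
    )
    meta = metaprofile(pm)
    assert np.allclose(meta["mean"], 1.0)


def test_metaprofile_matches_summation_oracle():
    rng = np.random.default_rng(3)
    values = rng.normal(5, 1, (100, 40))
    mask = rng.random((100, 40)) > 0.1
    pm = ProfileMatrix(values=values, mask=mask, region_ids=[f"r{i}" for i in range(100)],
                       offsets=np.arange(40) * 50.0, bin_width=50)
    meta = metaprofile(pm)
    for j in range(40):
        rows = mask[:, j]
        expected = values[rows, j].sum() / rows.sum()
        assert meta["mean"][j] == pytest.approx(expected)
        assert meta["n"][j] == rows.sum()


def test_foldchange_identity_and_pseudocount():
    a = np.array([1.0, 2.0, 0.0])
    ratio, log2r = foldchange_profile(a, a, pseudocount=0.5)
    assert np.allclose(ratio, 1.0) and np.allclose(log2r, 0.0)
    ratio, _ = foldchange_profile(np.zeros(3), np.zeros(3), pseudocount=0.5)
    assert np.allclose(ratio, 1.0)
    with pytest.raises(ValueError):
        foldchange_profile(np.zeros(3), np.zeros(4), pseudocount=0.5)


# ----------------------------------------------------- promoter/body split

def test_promoter_body_uniform_track_equal():
    t = track(np.full(400, 4.0))
    genes = region_df([("chr1", 5000, 15_000, "+", "g0")])
    out = promoter_body_signal(t, genes)
    assert out.loc["g0", "promoter"] == pytest.approx(out.loc["g0", "body"])


def test_promoter_body_ratio_tracks_pause_height(genome_small, kinetics):
    cond = sq.ConditionSpec(label="pol", assay="chip_polII")
    e = sq.expected_signals(genome_small, cond, kinetics)
    both = CoverageTrack(
        data={c: e.tracks["+"].data[c] + e.tracks["-"].data[c]
              for c in e.tracks["+"].data},
        bin_width=kinetics.bin_width,
    )
    genes = pd.DataFrame(
        [(g.chrom, g.start, g.end, g.strand, g.id) for g in genome_small.genes],
        columns=["chrom", "start", "end", "strand", "id"],
    )
    out = promoter_body_signal(both, genes)
    gtab = e.genes
    from scipy.stats import norm as normal

    ratios = []
    for g in genome_small.genes:
        prom = out.loc[g.id, "promoter"]
        k = gtab.loc[g.id, "k_init"]
        amp = kinetics.pause_height * k / kinetics.elongation_rate
        # pause Gaussian (centre +100, sd 150) truncated to the gene: mass
        # inside [TSS, TSS+250]; downstream half of the window carries early
        # zone coverage ~ k; upstream half carries the antisense unit's body
        frac = normal.cdf((250 - kinetics.pause_offset) / kinetics.pause_width) - \
            normal.cdf((0 - kinetics.pause_offset) / kinetics.pause_width)
        pred = (
            amp * kinetics.pause_width * np.sqrt(2 * np.pi) * frac / 500.0
            + 0.5 * k / kinetics.elongation_rate
            + 0.5 * gtab.loc[g.id, "flux_as"] / kinetics.elongation_rate
        )
        ratios.append(prom / pred)
    ratios = np.array(ratios)
    assert np.median(np.abs(ratios - 1.0)) < 0.2


def test_set1_depletion_hits_body_not_promoter(genome_small, kinetics):
    polu = sq.ConditionSpec(label="u", assay="chip_polII")
    pold = sq.ConditionSpec(label="d", assay="chip_polII", s=0.0)
    eu = sq.expected_signals(genome_small, polu, kinetics)
    ed = sq.expected_signals(genome_small, pold, kinetics)
    genes = pd.DataFrame(
        [(g.chrom, g.start, g.end, g.strand, g.id) for g in genome_small.genes
         if g.set1_occupancy > 0.5],
        columns=["chrom", "start", "end", "strand", "id"],
    )
    def combined(e):
        return CoverageTrack(
            data={c: e.tracks["+"].data[c] + e.tracks["-"].data[c]
                  for c in e.tracks["+"].data},
            bin_width=kinetics.bin_width,
        )
    ou = promoter_body_signal(combined(eu), genes)
    od = promoter_body_signal(combined(ed), genes)
    body_change = od["body"] / ou["body"]
    prom_change = od["promoter"] / ou["promoter"]
    assert (body_change < 0.9).mean() > 0.9          # bodies drop
    assert (np.abs(prom_change - 1) < 0.1).all()     # promoters barely move


def test_gene_shorter_than_windows_rejected():
    t = track(np.full(100, 1.0))
    genes = region_df([("chr1", 1000, 1400, "+", "tiny")])
    with pytest.raises(ValueError, match="tiny"):
        promoter_body_signal(t, genes)


# ------------------------------------------------------- attenuation

def make_log2_matrix(rows, ids):
    arr = np.asarray(rows, float)
    return ProfileMatrix(
        values=arr,
        mask=np.ones_like(arr, bool),
        region_ids=ids,
        offsets=np.arange(arr.shape[1]) * 50.0,
        bin_width=50,
    )


def test_attenuation_flat_profile_tss_proximal_tiebreak():
    pm = make_log2_matrix([np.zeros(60)], ["g0"])
    out = attenuation_summary(pm, {"g0": (0.0, 1500.0)})
    assert out.loc["g0", "depth"] == 0.0
    assert out.loc["g0", "position"] == 25.0  # first bin midpoint
    assert bool(out.loc["g0", "in_cgi"])


def test_attenuation_locates_constructed_dip():
    row = np.zeros(60)
    row[16] = -2.0  # dip in bin starting at 800
    pm = make_log2_matrix([row], ["g0"])
    out = attenuation_summary(pm, {"g0": (0.0, 1500.0)})
    assert abs(out.loc["g0", "position"] - 800) <= 25
    assert out.loc["g0", "depth"] == -2.0


def test_attenuation_restricted_to_3kb():
    row = np.zeros(100)
    row[80] = -5.0  # beyond 3 kb: must be ignored
    row[10] = -1.0
    pm = make_log2_matrix([row], ["g0"])
    out = attenuation_summary(pm, {"g0": (0.0, 1500.0)})
    assert out.loc["g0", "depth"] == -1.0


def test_attenuation_epistasis_double_equals_zc3h4_only(genome_small, kinetics, expectations_small):
    """Fold-change profile of double depletion matches ZC3H4-only depletion."""
    genes_bed = sq.pipeline._gene_bed(genome_small)
    mats = {}
    for label in ("UNT", "dZC3H4", "dBOTH"):
        e = expectations_small[label]
        mats[label] = coverage_matrix(
            e.tracks["+"], e.tracks["-"], genes_bed, upstream=0, downstream=3000
        )
    pc = 0.01
    _, l2_z = foldchange_profile(mats["dZC3H4"], mats["UNT"], pc)
    _, l2_b = foldchange_profile(mats["dBOTH"], mats["UNT"], pc)
    zones = {
        g.id: (0.0, float(expectations_small["UNT"].genes.loc[g.id, "zone_len"]))
        for g in genome_small.genes
    }
    az = attenuation_summary(
        ProfileMatrix(l2_z, mats["UNT"].mask, mats["UNT"].region_ids,
                      mats["UNT"].offsets, mats["UNT"].bin_width), zones)
    ab = attenuation_summary(
        ProfileMatrix(l2_b, mats["UNT"].mask, mats["UNT"].region_ids,
                      mats["UNT"].offsets, mats["UNT"].bin_width), zones)
    assert abs(az["depth"].median() - ab["depth"].median()) < 0.1


def test_calibration_commutes_with_metaprofile(genome_small, kinetics):
    """metaprofile(downsampled track) ~ r * metaprofile(track) over seeds."""
    from spikequant.calibration import downsample

    e = sq.expected_signals(genome_small, sq.ConditionSpec(label="u", depth=2e6),
                            kinetics)
    tracks = sq.sample_coverage(e, seed=1, sample_id="c")
    genes_bed = sq.pipeline._gene_bed(genome_small)
    mat = coverage_matrix(tracks["+"], tracks["-"], genes_bed,
                          upstream=0, downstream=2000)
    base = metaprofile(mat)["mean"]
    r = 0.4
    acc = np.zeros_like(base.to_numpy())
    n_seeds = 30
    for seed in range(n_seeds):
        thin = downsample(tracks["+"], r, seed), downsample(tracks["-"], r, seed + 1000)
        m = coverage_matrix(thin[0], thin[1], genes_bed, upstream=0, downstream=2000)
        acc += metaprofile(m)["mean"].to_numpy()
    np.testing.assert_allclose(acc / n_seeds, r * base, rtol=0.05)
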