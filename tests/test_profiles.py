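import numpy as np
import pytest

from metachip.profiles import (
    HalfGeneAnchor,
    PointAnchor,
    ProfileError,
    flank_extents_from_irs,
    halfgene_anchors,
    halfgene_profile,
    point_anchored_profile,
    sliding_mean,
    write_profile_tsv,
)
from metachip.annotation import Feature

from conftest import per_base


# ---------------------------------------------------------------------------
# sliding mean
# ---------------------------------------------------------------------------

def test_sliding_mean_window_one_identity():
    x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
    assert np.array_equal(sliding_mean(x, 1), x)


def test_sliding_mean_edge_shrink():
    got = sliding_mean([1, 2, 3, 4], 3)
    assert np.allclose(got, [1.5, 2.0, 3.0, 3.5])


def test_sliding_mean_constant_unchanged():
    assert np.allclose(sliding_mean([2.0] * 9, 5), 2.0)


def test_sliding_mean_window_too_large():
    with pytest.raises(ProfileError):
        sliding_mean([1.0, 2.0], 5)
    with pytest.raises(ProfileError):
        sliding_mean([1.0, 2.0], 0)


def test_sliding_mean_even_window_oracle():
    x = np.array([1.0, 2.0, 4.0, 8.0])
    got = sliding_mean(x, 2)
    # centered with half_left=0, half_right=1
    expect = [(1 + 2) / 2, (2 + 4) / 2, (4 + 8) / 2, 8.0]
    assert np.allclose(got, expect)


def test_sliding_mean_skips_nan():
    x = np.array([1.0, np.nan, 3.0])
    got = sliding_mean(x, 3)
    assert got[1] == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# point-anchored profiles
# ---------------------------------------------------------------------------

def test_point_profile_uniform_flat(uniform_track):
    t = uniform_track(1.0, {"chr1": 10_000})
    anchors = [PointAnchor("chr1", p) for p in (2000, 5000, 7000)]
    prof = point_anchored_profile(t, anchors, bin=100, span=2000, smooth=400)
    assert np.allclose(prof.mean, 1.0)
    assert np.all(prof.n == 3)


def test_point_profile_identity_smoothing(make_track):
    rng = np.random.default_rng(0)
    t = make_track({"chr1": rng.random(100)})
    prof = point_anchored_profile(
        t, [PointAnchor("chr1", 500)], bin=50, span=400, smooth=50
    )
    expect = [
        np.mean(t.values["chr1"][(500 + off) // 10 : (500 + off + 50) // 10])
        for off in prof.offsets
    ]
    assert np.allclose(prof.mean, expect, atol=1e-12)


def _point_oracle(track, anchors, bin, span):
    """Per-anchor, per-base brute force (no smoothing)."""
    nb = span // bin
    sums = np.zeros(nb)
    counts = np.zeros(nb)
    for a in anchors:
        base = per_base(track, a.chrom)
        for k in range(nb):
            lo = a.pos - span // 2 + k * bin
            hi = lo + bin
            if lo < 0 or hi > len(base):
                continue
            idx = k if a.strand != "-" else nb - 1 - k
            sums[idx] += base[lo:hi].mean()
            counts[idx] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan), counts


@pytest.mark.parametrize("seed", range(5))
def test_point_profile_matches_oracle(seed, make_track):
    rng = np.random.default_rng(seed)
    t = make_track({"chr1": rng.random(1000)})  # 10 kb
    anchors = [
        PointAnchor("chr1", int(rng.integers(0, 10_000)), rng.choice(["+", "-", "."]))
        for _ in range(20)
    ]
    prof = point_anchored_profile(t, anchors, bin=50, span=1000, smooth=50)
    exp_mean, exp_n = _point_oracle(t, anchors, 50, 1000)
    assert np.allclose(prof.n, exp_n)
    both = np.isfinite(prof.mean) & np.isfinite(exp_mean)
    assert np.array_equal(np.isfinite(prof.mean), np.isfinite(exp_mean))
    assert np.allclose(prof.mean[both], exp_mean[both], atol=1e-9)


def test_point_profile_minus_strand_flips(make_track):
    ramp = np.arange(100, dtype=float)
    t = make_track({"chr1": ramp})
    plus = point_anchored_profile(
        t, [PointAnchor("chr1", 500, "+")], bin=10, span=200, smooth=10
    )
    minus = point_anchored_profile(
        t, [PointAnchor("chr1", 500, "-")], bin=10, span=200, smooth=10
    )
    assert np.allclose(plus.mean, minus.mean[::-1])


def test_point_profile_clipped_anchor_partial(uniform_track):
    t = uniform_track(2.0, {"chr1": 1000})
    prof = point_anchored_profile(
        t, [PointAnchor("chr1", 100)], bin=100, span=1000, smooth=100
    )
    # bins left of position 0 are missing; remaining bins exist
    assert np.isnan(prof.mean[: 4]).all()
    assert np.allclose(prof.mean[4:], 2.0)


def test_point_profile_errors(uniform_track):
    t = uniform_track(1.0, {"chr1": 1000})
    with pytest.raises(ProfileError):
        point_anchored_profile(t, [], bin=10, span=100, smooth=10)
    with pytest.raises(ProfileError):
        point_anchored_profile(t, [PointAnchor("chr1", 5)], bin=30, span=100, smooth=10)


# ---------------------------------------------------------------------------
# half-gene profiles
# ---------------------------------------------------------------------------

def test_halfgene_uniform_flat(uniform_track):
    t = uniform_track(1.5, {"chr1": 20_000})
    genes = [
        Feature("g1", "chr1", 2000, 5000, "+", "gene"),
        Feature("g2", "chr1", 8000, 12_000, "-", "gene"),
    ]
    prof = halfgene_profile(
        t, halfgene_anchors(genes), None, bin=50, max_extent=1000, smooth=200
    )
    finite = np.isfinite(prof.mean)
    assert finite.any()
    assert np.allclose(prof.mean[finite], 1.5)


def test_halfgene_strand_mirror_symmetry(make_track):
    rng = np.random.default_rng(5)
    vals = rng.random(400)  # 4 kb
    t_fwd = make_track({"chr1": vals})
    t_rev = make_track({"chr1": vals[::-1].copy()})
    g_fwd = Feature("g", "chr1", 1000, 3000, "+", "gene")
    g_rev = Feature("g", "chr1", 4000 - 3000, 4000 - 1000, "-", "gene")
    p_fwd = halfgene_profile(
        t_fwd, halfgene_anchors([g_fwd]), None, bin=50, max_extent=1000, smooth=50
    )
    p_rev = halfgene_profile(
        t_rev, halfgene_anchors([g_rev]), None, bin=50, max_extent=1000, smooth=50
    )
    assert np.allclose(p_fwd.mean, p_rev.mean, equal_nan=True)


def _halfgene_gene_oracle(track, g: HalfGeneAnchor, bin, max_extent):
    """Per-base per-gene sampled segment vectors (no smoothing)."""
    base = per_base(track, g.chrom)
    d = 1 if g.strand == "+" else -1
    L = g.length
    h5 = min(((L + 1) // 2) // bin, max_extent // bin)
    h3 = min((L // 2) // bin, max_extent // bin)
    v5 = []
    for k in range(h5):
        lo, hi = sorted((g.tss + d * k * bin, g.tss + d * (k + 1) * bin))
        v5.append(base[lo:hi].mean())
    v3 = []
    for k in range(h3):
        lo, hi = sorted((g.tts - d * (k + 1) * bin, g.tts - d * k * bin))
        v3.append(base[lo:hi].mean())
    return np.array(v5), np.array(v3)


def test_halfgene_matches_per_gene_oracle(make_track):
    rng = np.random.default_rng(21)
    nbase = 100_000
    t = make_track({"chr1": rng.random(nbase // 10)})
    genes = []
    pos = 500
    for i in range(30):
        length = int(rng.integers(600, 2400))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Feature(f"g{i}", "chr1", pos, pos + length, strand, "gene"))
        pos += length + int(rng.integers(300, 800))
    anchors = halfgene_anchors(genes)
    m = 1000 // 50
    sums5 = np.zeros(m)
    n5 = np.zeros(m)
    sums3 = np.zeros(m)
    n3 = np.zeros(m)
    for a in anchors:
        v5, v3 = _halfgene_gene_oracle(t, a, 50, 1000)
        sums5[: len(v5)] += v5
        n5[: len(v5)] += 1
        sums3[: len(v3)] += v3
        n3[: len(v3)] += 1
    prof = halfgene_profile(t, anchors, None, bin=50, max_extent=1000, smooth=50)
    seg5 = prof.segment("5half")
    seg3 = prof.segment("3half")
    with np.errstate(invalid="ignore"):
        exp5 = np.where(n5 > 0, sums5 / np.maximum(n5, 1), np.nan)
        exp3 = np.where(n3 > 0, sums3 / np.maximum(n3, 1), np.nan)
    assert np.allclose(seg5.mean, exp5, atol=1e-9, equal_nan=True)
    assert np.array_equal(seg5.n, n5.astype(int))
    # 3half is emitted far->TTS, oracle index counts away from TTS
    assert np.allclose(seg3.mean, exp3[::-1], atol=1e-9, equal_nan=True)
    assert np.array_equal(seg3.n, n3[::-1].astype(int))


def test_halfgene_ramp_rises_toward_tts(make_track):
    # per-bin ramp along each gene: 3' half must increase toward offset 0
    nbins = 12_000
    vals = np.full(nbins, 0.5)
    genes = []
    pos = 1000
    rng = np.random.default_rng(2)
    for i in range(30):
        length = int(rng.integers(1200, 2400)) // 10 * 10
        g = Feature(f"g{i}", "chr1", pos, pos + length, "+", "gene")
        genes.append(g)
        b0, b1 = g.start // 10, g.end // 10
        vals[b0:b1] = 0.5 + np.linspace(0, 1, b1 - b0)
        pos += length + 500
    t = make_track({"chr1": vals})
    prof = halfgene_profile(
        t, halfgene_anchors(genes), None, bin=50, max_extent=600, smooth=100
    )
    seg3 = prof.segment("3half")
    assert np.all(np.diff(seg3.mean) > -1e-9)
    assert seg3.mean[-1] > seg3.mean[0]


def test_halfgene_anchor_count_bookkeeping(make_track):
    t = make_track({"chr1": np.ones(2000)})
    lengths = [600, 1000, 1500, 2600]
    genes = []
    pos = 100
    for i, L in enumerate(lengths):
        genes.append(Feature(f"g{i}", "chr1", pos, pos + L, "+", "gene"))
        pos += L + 300
    prof = halfgene_profile(
        t, halfgene_anchors(genes), None, bin=50, max_extent=1000, smooth=50
    )
    seg5 = prof.segment("5half")
    half5_bins = [min(((L + 1) // 2) // 50, 20) for L in lengths]
    for j, off in enumerate(seg5.offsets):
        assert seg5.n[j] == sum(1 for h in half5_bins if h > j)


def test_halfgene_flanks_limited_to_ir(make_track):
    t = make_track({"chr1": np.ones(1000)})
    g = Feature("g1", "chr1", 3000, 6000, "+", "gene")
    ir_up = Feature("IR:a", "chr1", 2700, 3000, ".", "IR")  # 300 bp
    ir_down = Feature("IR:b", "chr1", 6000, 6200, ".", "IR")  # 200 bp
    flanks = flank_extents_from_irs([g], [ir_up, ir_down])
    assert flanks == {"g1": (300, 200)}
    prof = halfgene_profile(
        t, halfgene_anchors([g]), flanks, bin=50, max_extent=1000, smooth=50
    )
    f5 = prof.segment("5flank")
    f3 = prof.segment("3flank")
    assert int((f5.n > 0).sum()) == 6  # 300 bp / 50
    assert int((f3.n > 0).sum()) == 4  # 200 bp / 50


def test_halfgene_minus_strand_flank_orientation():
    g = Feature("g1", "chr1", 3000, 6000, "-", "gene")
    ir_up = Feature("IR:a", "chr1", 2700, 3000, ".", "IR")
    ir_down = Feature("IR:b", "chr1", 6000, 6200, ".", "IR")
    flanks = flank_extents_from_irs([g], [ir_up, ir_down])
    # for a minus-strand gene the 5' flank is the downstream-coordinate IR
    assert flanks == {"g1": (200, 300)}


def test_halfgene_short_gene_skipped_with_warning(uniform_track):
    t = uniform_track(1.0, {"chr1": 5000})
    genes = [
        Feature("tiny", "chr1", 100, 180, "+", "gene"),
        Feature("ok", "chr1", 1000, 3000, "+", "gene"),
    ]
    with pytest.warns(UserWarning, match="tiny"):
        prof = halfgene_profile(
            t, halfgene_anchors(genes), None, bin=50, max_extent=500, smooth=50
        )
    assert prof.segment("5half").n.max() == 1


def test_halfgene_empty_gene_set_error(uniform_track):
    t = uniform_track(1.0, {"chr1": 5000})
    with pytest.raises(ProfileError):
        halfgene_profile(t, [], None, bin=50, max_extent=500, smooth=50)


def test_profile_tsv_writer(tmp_path, uniform_track):
    t = uniform_track(1.0, {"chr1": 10_000})
    prof = point_anchored_profile(
        t, [PointAnchor("chr1", 5000)], bin=100, span=1000, smooth=100
    )
    p = tmp_path / "prof.tsv"
    write_profile_tsv(prof, p)
    lines = p.read_text().splitlines()
    assert lines[0] == "segment\toffset_bp\tmean\tn"
    assert len(lines) == 11
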