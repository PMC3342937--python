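import random

import numpy as np
import pytest

from metachip.annotation import (
    AnnotationError,
    ChromatinStateSegment,
    Feature,
    GenomeModel,
    ParseError,
    compute_inter_annotation_regions,
    filter_genes_for_profiles,
    load_annotation,
    load_state_segments,
    merge_adjacent_state_segments,
    write_features_bed,
    write_state_segments_bed,
)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def test_gff3_coordinates_converted(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text("chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1\n")
    (feat,) = load_annotation(p, "gff3")
    assert (feat.start, feat.end) == (100, 200)
    assert feat.id == "g1"
    assert feat.category == "gene"


def test_empty_file_gives_empty_list(tmp_path):
    p = tmp_path / "empty.gff3"
    p.write_text("")
    assert load_annotation(p, "gff3") == []


def test_bed_is_native_half_open(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t99\t200\tg1\t0\t-\n")
    (feat,) = load_annotation(p, "bed")
    assert (feat.chrom, feat.start, feat.end, feat.strand) == ("chr1", 99, 200, "-")


def test_malformed_line_names_line_number(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text("chr1\tsrc\tgene\t1\t50\t.\t+\t.\tID=g1\nchr1\tgarbage\n")
    with pytest.raises(ParseError, match="line 2"):
        load_annotation(p, "gff3")


def test_inverted_interval_rejected(tmp_path):
    p = tmp_path / "a.gff3"
    # GFF3 start=200 end=100 -> end <= start after conversion
    p.write_text("chr1\tsrc\tgene\t200\t100\t.\t+\t.\tID=g1\n")
    with pytest.raises(ParseError, match="line 1"):
        load_annotation(p, "gff3")


def test_bed_roundtrip_preserves_category(tmp_path):
    feats = [
        Feature("g1", "chr1", 0, 100, "+", "gene"),
        Feature("t1", "chr1", 200, 300, "-", "TE"),
        Feature("IR:chr1:300-500", "chr1", 300, 500, ".", "IR"),
    ]
    p = tmp_path / "f.bed"
    write_features_bed(feats, p)
    back = load_annotation(p, "bed")
    assert [(f.chrom, f.start, f.end, f.strand, f.category) for f in back] == [
        (f.chrom, f.start, f.end, f.strand, f.category) for f in feats
    ]


# ---------------------------------------------------------------------------
# inter-annotation regions
# ---------------------------------------------------------------------------

def _ir_oracle(features, genome, min_len):
    """Per-base complement oracle."""
    out = []
    for chrom, length in genome.chromosomes:
        covered = np.zeros(length, dtype=bool)
        for f in features:
            if f.chrom == chrom:
                covered[f.start:f.end] = True
        s = None
        for i in range(length + 1):
            free = i < length and not covered[i]
            if free and s is None:
                s = i
            elif not free and s is not None:
                if i - s > min_len:
                    out.append((chrom, s, i))
                s = None
    return out


def test_ir_example_min_len(toy_genome):
    feats = [
        Feature("g1", "chr1", 100, 200, "+", "gene"),
        Feature("g2", "chr1", 400, 500, "+", "gene"),
    ]
    genome = GenomeModel((("chr1", 1000),))
    irs = compute_inter_annotation_regions(feats, genome, min_len=150)
    assert [(f.start, f.end) for f in irs] == [(200, 400), (500, 1000)]
    irs0 = compute_inter_annotation_regions(feats, genome, min_len=0)
    assert [(f.start, f.end) for f in irs0] == [(0, 100), (200, 400), (500, 1000)]


def test_ir_tiling_chromosome_empty():
    genome = GenomeModel((("chr1", 1000),))
    feats = [Feature("g1", "chr1", 0, 600, "+"), Feature("g2", "chr1", 600, 1000, "+")]
    assert compute_inter_annotation_regions(feats, genome) == []


def test_ir_overlapping_features_unioned():
    genome = GenomeModel((("chr1", 1000),))
    feats = [Feature("a", "chr1", 0, 300, "+"), Feature("b", "chr1", 200, 600, "+")]
    irs = compute_inter_annotation_regions(feats, genome, min_len=150)
    assert [(f.start, f.end) for f in irs] == [(600, 1000)]


def test_ir_min_len_is_strict():
    genome = GenomeModel((("chr1", 500),))
    feats = [Feature("a", "chr1", 0, 200, "+"), Feature("b", "chr1", 350, 500, "+")]
    # gap is exactly 150 -> excluded under strict >
    assert compute_inter_annotation_regions(feats, genome, min_len=150) == []
    assert len(compute_inter_annotation_regions(feats, genome, min_len=149)) == 1


@pytest.mark.parametrize("seed", range(5))
def test_ir_matches_per_base_oracle(seed):
    rng = random.Random(seed)
    genome = GenomeModel((("chr1", 5000), ("chr2", 3000)))
    feats = []
    for i in range(rng.randint(0, 25)):
        chrom, length = rng.choice(genome.chromosomes)
        s = rng.randrange(0, length - 10)
        e = rng.randrange(s + 1, min(length, s + 800) + 1)
        feats.append(Feature(f"f{i}", chrom, s, e, "+", "gene"))
    min_len = rng.choice([0, 50, 150])
    got = compute_inter_annotation_regions(feats, genome, min_len)
    assert [(f.chrom, f.start, f.end) for f in got] == _ir_oracle(feats, genome, min_len)


def test_ir_complement_covers_genome_exactly_once():
    rng = random.Random(99)
    genome = GenomeModel((("chr1", 2000),))
    feats = [
        Feature(f"f{i}", "chr1", s := rng.randrange(0, 1900), rng.randrange(s + 1, 2000), "+")
        for i in range(10)
    ]
    irs = compute_inter_annotation_regions(feats, genome, min_len=0)
    cover = np.zeros(2000, dtype=int)
    for f in feats:
        cover[f.start:f.end] = 1  # union, not multiplicity
    for f in irs:
        cover[f.start:f.end] += 1
    assert np.all(cover == 1)


# ---------------------------------------------------------------------------
# chromatin-state merging
# ---------------------------------------------------------------------------

def test_merge_abutting_same_state():
    segs = [
        ChromatinStateSegment("chr1", 0, 100, "CS1"),
        ChromatinStateSegment("chr1", 100, 250, "CS1"),
    ]
    assert merge_adjacent_state_segments(segs) == [
        ChromatinStateSegment("chr1", 0, 250, "CS1")
    ]


def test_merge_different_states_unchanged():
    segs = [
        ChromatinStateSegment("chr1", 0, 100, "CS1"),
        ChromatinStateSegment("chr1", 100, 250, "CS2"),
    ]
    assert merge_adjacent_state_segments(segs) == segs


def test_merge_overlap_rejected():
    segs = [
        ChromatinStateSegment("chr1", 0, 100, "CS1"),
        ChromatinStateSegment("chr1", 50, 250, "CS1"),
    ]
    with pytest.raises(AnnotationError, match="overlap"):
        merge_adjacent_state_segments(segs)


def _merge_oracle(segs):
    """Linear scan over sorted segments."""
    segs = sorted(segs, key=lambda s: (s.chrom, s.start))
    out = []
    for s in segs:
        if (
            out
            and out[-1].chrom == s.chrom
            and out[-1].end == s.start
            and out[-1].state == s.state
        ):
            out[-1] = ChromatinStateSegment(s.chrom, out[-1].start, s.end, s.state)
        else:
            out.append(s)
    return out


@pytest.mark.parametrize("seed", range(5))
def test_merge_matches_linear_scan_oracle(seed):
    rng = random.Random(seed)
    pos = 0
    segs = []
    for _ in range(10):
        width = rng.randrange(10, 100)
        segs.append(
            ChromatinStateSegment("chr1", pos, pos + width, rng.choice(["CS1", "CS2", "CS3", "CS4"]))
        )
        pos += width
    got = merge_adjacent_state_segments(segs)
    assert got == _merge_oracle(segs)
    assert len(got) <= len(segs)
    # idempotence
    assert merge_adjacent_state_segments(got) == got


def test_states_bed_roundtrip(tmp_path):
    segs = [
        ChromatinStateSegment("chr1", 0, 100, "CS1"),
        ChromatinStateSegment("chr1", 100, 250, "CS3"),
    ]
    p = tmp_path / "cs.bed"
    write_state_segments_bed(segs, p)
    assert load_state_segments(p) == segs


# ---------------------------------------------------------------------------
# gene filtering
# ---------------------------------------------------------------------------

def test_filter_short_gene():
    g = Feature("g1", "chr1", 0, 900, "+", "gene")
    kept, reasons = filter_genes_for_profiles([g], [g])
    assert kept == [] and reasons == {"g1": "short"}


def test_filter_organellar():
    g = Feature("g1", "ChrM", 0, 5000, "+", "gene")
    kept, reasons = filter_genes_for_profiles([g], [g])
    assert kept == [] and reasons == {"g1": "organellar"}


def test_filter_overlap_with_te():
    g = Feature("g1", "chr1", 100, 2000, "+", "gene")
    te = Feature("t1", "chr1", 1900, 2500, "+", "TE")
    kept, reasons = filter_genes_for_profiles([g], [g, te])
    assert kept == [] and reasons == {"g1": "overlap"}
    # oracle: pairwise interval intersection
    assert max(g.start, te.start) < min(g.end, te.end)


def test_filter_ir_does_not_count_as_overlap():
    g = Feature("g1", "chr1", 100, 2000, "+", "gene")
    ir = Feature("IR:x", "chr1", 0, 3000, ".", "IR")
    kept, _ = filter_genes_for_profiles([g], [g, ir])
    assert kept == [g]


def test_filter_kept_gene_passes_all_rules():
    g1 = Feature("g1", "chr1", 0, 1500, "+", "gene")
    g2 = Feature("g2", "chr1", 2000, 3600, "-", "gene")
    kept, reasons = filter_genes_for_profiles([g1, g2], [g1, g2])
    assert kept == [g1, g2] and reasons == {}


def test_filter_order_independent():
    rng = random.Random(5)
    feats = []
    for i in range(40):
        s = rng.randrange(0, 50_000)
        feats.append(
            Feature(
                f"f{i}", "chr1", s, s + rng.randrange(500, 3000),
                rng.choice(["+", "-"]),
                rng.choice(["gene", "gene", "TE"]),
            )
        )
    genes = [f for f in feats if f.category == "gene"]
    kept1, _ = filter_genes_for_profiles(genes, feats)
    shuffled = genes[:]
    rng.shuffle(shuffled)
    kept2, _ = filter_genes_for_profiles(shuffled, feats)
    assert {g.id for g in kept1} == {g.id for g in kept2}


def test_genome_model_validation():
    with pytest.raises(AnnotationError):
        GenomeModel((("chr1", 0),))
    with pytest.raises(AnnotationError):
        GenomeModel((("chr1", 100), ("chr1", 200)))
    with pytest.raises(AnnotationError):
        GenomeModel((("chr1", 100),), centromeres={"chr1": (50, 200)})
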