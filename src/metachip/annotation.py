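"""Genomic annotations: features, inter-annotation regions, chromatin states.

All coordinates are 0-based half-open internally.  GFF3 input (1-based
inclusive) is converted on read; BED passes through unchanged.  Emitters
write BED6 with the category or chromatin state in the name column.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

STRANDS = ("+", "-", ".")
CATEGORIES = ("gene", "TE", "other", "IR")
STATES = ("CS1", "CS2", "CS3", "CS4")

#: Chromosome names treated as organellar (excluded from gene profiling).
DEFAULT_ORGANELLAR = frozenset({"ChrM", "ChrC", "mitochondria", "chloroplast"})

#: Default mapping from GFF3 type / BED name tokens to feature categories.
DEFAULT_CATEGORY_MAP: Mapping[str, str] = {
    "gene": "gene",
    "protein_coding_gene": "gene",
    "mRNA": "gene",
    "TE": "TE",
    "other": "other",
    "transposable_element": "TE",
    "transposable_element_gene": "TE",
    "pseudogene": "TE",
    "IR": "IR",
}


class AnnotationError(ValueError):
    """Invalid annotation content."""


class ParseError(AnnotationError):
    """Malformed annotation line; message carries the line number."""


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome coordinate frame plus centromere/heterochromatin intervals.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length)`` pairs; lengths in bp, all > 0.
    centromeres
        Map chromosome name -> ``(start, end)`` half-open interval.
    heterochromatin
        ``(chrom, start, end)`` blocks; may be empty.
    """

    chromosomes: tuple[tuple[str, int], ...]
    centromeres: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    heterochromatin: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise AnnotationError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise AnnotationError(f"chromosome {name} has non-positive length")
        lengths = dict(self.chromosomes)
        for name, (s, e) in self.centromeres.items():
            if name not in lengths:
                raise AnnotationError(f"centromere on unknown chromosome {name}")
            if not (0 <= s < e <= lengths[name]):
                raise AnnotationError(f"centromere interval out of range on {name}")
        for chrom, s, e in self.heterochromatin:
            if chrom not in lengths:
                raise AnnotationError(f"heterochromatin on unknown chromosome {chrom}")
            if not (0 <= s < e <= lengths[chrom]):
                raise AnnotationError(f"heterochromatin interval out of range on {chrom}")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]


@dataclass(frozen=True)
class Feature:
    """One stranded genomic interval with a category."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    category: str = "gene"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise AnnotationError(
                f"feature {self.id}: invalid interval [{self.start},{self.end})"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"feature {self.id}: bad strand {self.strand!r}")
        if self.category not in CATEGORIES:
            raise AnnotationError(f"feature {self.id}: bad category {self.category!r}")
        if self.category == "IR" and self.strand != ".":
            raise AnnotationError(f"IR feature {self.id} must be unstranded")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ChromatinStateSegment:
    """One chromatin-state interval (CS1..CS4), 0-based half-open."""

    chrom: str
    start: int
    end: int
    state: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise AnnotationError(f"invalid state interval [{self.start},{self.end})")
        if self.state not in STATES:
            raise AnnotationError(f"unknown chromatin state {self.state!r}")


def validate_features(features: Iterable[Feature], genome: GenomeModel) -> None:
    """Check every feature lies within its chromosome."""
    lengths = genome.lengths
    for f in features:
        if f.chrom not in lengths:
            raise AnnotationError(f"feature {f.id} on unknown chromosome {f.chrom}")
        if f.end > lengths[f.chrom]:
            raise AnnotationError(
                f"feature {f.id} extends beyond {f.chrom} ({f.end} > {lengths[f.chrom]})"
            )


def _categorize(token: str, category_map: Mapping[str, str] | None) -> str:
    cmap = DEFAULT_CATEGORY_MAP if category_map is None else category_map
    return cmap.get(token, "other")


def _gff3_attr(attrs: str, key: str) -> str | None:
    for part in attrs.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def load_annotation(
    path,
    dialect: str,
    category_map: Mapping[str, str] | None = None,
) -> list[Feature]:
    """Read features from a GFF3 or BED file.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open frame; BED is native.  Categories come from the GFF3
    type column or the BED name column through ``category_map``.
    """
    if dialect not in ("gff3", "bed"):
        raise ValueError(f"unknown dialect {dialect!r}")
    feats: list[Feature] = []
    auto = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("track"):
                continue
            cols = line.split("\t")
            try:
                if dialect == "gff3":
                    if len(cols) < 8:
                        raise ValueError("expected >= 8 tab-separated columns")
                    chrom, _src, ftype, s1, e1, _score, strand, _phase = cols[:8]
                    start, end = int(s1) - 1, int(e1)
                    attrs = cols[8] if len(cols) > 8 else ""
                    fid = _gff3_attr(attrs, "ID")
                    category = _categorize(ftype, category_map)
                else:
                    if len(cols) < 3:
                        raise ValueError("expected >= 3 tab-separated columns")
                    chrom = cols[0]
                    start, end = int(cols[1]), int(cols[2])
                    name = cols[3] if len(cols) > 3 else ""
                    strand = cols[5] if len(cols) > 5 else "."
                    # our own BED emitter writes "category|id" in the name column
                    token, _, rest = name.partition("|")
                    fid = rest or (name or None)
                    category = _categorize(token, category_map)
                if strand not in STRANDS:
                    raise ValueError(f"bad strand {strand!r}")
                if end <= start:
                    raise ValueError(f"end <= start after conversion ({start},{end})")
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if fid is None:
                auto += 1
                fid = f"feat{auto}"
            if category == "IR":
                strand = "."
            feats.append(Feature(fid, chrom, start, end, strand, category))
    return feats


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def compute_inter_annotation_regions(
    features: Sequence[Feature],
    genome: GenomeModel,
    min_len: int = 150,
) -> list[Feature]:
    """Complement of all annotated intervals, keeping spans strictly > min_len."""
    validate_features(features, genome)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
    irs: list[Feature] = []
    for chrom, length in genome.chromosomes:
        pos = 0
        for s, e in _merge_intervals(by_chrom.get(chrom, [])):
            if s - pos > min_len:
                irs.append(Feature(f"IR:{chrom}:{pos}-{s}", chrom, pos, s, ".", "IR"))
            pos = max(pos, e)
        if length - pos > min_len:
            irs.append(Feature(f"IR:{chrom}:{pos}-{length}", chrom, pos, length, ".", "IR"))
    return irs


def merge_adjacent_state_segments(
    segments: Sequence[ChromatinStateSegment],
) -> list[ChromatinStateSegment]:
    """Collapse abutting same-state runs; rejects overlapping segments."""
    ordered = sorted(segments, key=lambda s: (s.chrom, s.start))
    out: list[ChromatinStateSegment] = []
    for seg in ordered:
        if out and out[-1].chrom == seg.chrom:
            if seg.start < out[-1].end:
                raise AnnotationError(
                    f"overlapping segments on {seg.chrom} at {seg.start}"
                )
            if seg.start == out[-1].end and seg.state == out[-1].state:
                out[-1] = ChromatinStateSegment(
                    seg.chrom, out[-1].start, seg.end, seg.state
                )
                continue
        out.append(seg)
    return out


def filter_genes_for_profiles(
    genes: Sequence[Feature],
    all_features: Sequence[Feature],
    min_transcript_len: int = 1000,
    organellar_chroms: frozenset[str] | set[str] = DEFAULT_ORGANELLAR,
) -> tuple[list[Feature], dict[str, str]]:
    """Apply the profiling gene-exclusion rules.

    Removes genes on organellar chromosomes, genes whose interval intersects
    any other non-IR feature (strand-blind, >= 1 bp), and genes shorter than
    ``min_transcript_len``.  Returns the kept genes plus a map
    gene id -> exclusion reason in {"organellar", "overlap", "short"}.
    """
    # per-chromosome sorted endpoint arrays over non-IR features
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for f in all_features:
        if f.category == "IR":
            continue
        starts, ends = by_chrom.setdefault(f.chrom, ([], []))
        starts.append(f.start)
        ends.append(f.end)
    for starts, ends in by_chrom.values():
        starts.sort()
        ends.sort()
    in_universe = {f.id for f in all_features}

    kept: list[Feature] = []
    reasons: dict[str, str] = {}
    for g in genes:
        if g.chrom in organellar_chroms:
            reasons[g.id] = "organellar"
            continue
        starts, ends = by_chrom.get(g.chrom, ([], []))
        n_hit = bisect.bisect_left(starts, g.end) - bisect.bisect_right(ends, g.start)
        if g.id in in_universe:
            n_hit -= 1  # the gene intersects itself
        if n_hit > 0:
            reasons[g.id] = "overlap"
            continue
        if g.length < min_transcript_len:
            reasons[g.id] = "short"
            continue
        kept.append(g)
    return kept, reasons


def write_features_bed(features: Iterable[Feature], path) -> None:
    """BED6 writer; the name column holds ``category|id`` (just the category
    for IR features, matching the IR emitter contract)."""
    with open(path, "w") as fh:
        for f in features:
            name = f.category if f.category == "IR" else f"{f.category}|{f.id}"
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{name}\t0\t{f.strand}\n")


def write_state_segments_bed(segments: Iterable[ChromatinStateSegment], path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.state}\t0\t.\n")


def load_state_segments(path) -> list[ChromatinStateSegment]:
    """Read chromatin-state segments from BED-like TSV (chrom start end state)."""
    segs: list[ChromatinStateSegment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            cols = line.split("\t")
            try:
                if len(cols) < 4:
                    raise ValueError("expected >= 4 columns")
                segs.append(
                    ChromatinStateSegment(cols[0], int(cols[1]), int(cols[2]), cols[3])
                )
            except (ValueError, AnnotationError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return segs


def write_genome_tsv(genome: GenomeModel, path) -> None:
    """Genome emitter: chromosome rows plus centromere/heterochromatin rows."""
    with open(path, "w") as fh:
        fh.write("record\tchrom\tstart\tend\n")
        for name, length in genome.chromosomes:
            fh.write(f"chromosome\t{name}\t0\t{length}\n")
        for name, (s, e) in genome.centromeres.items():
            fh.write(f"centromere\t{name}\t{s}\t{e}\n")
        for chrom, s, e in genome.heterochromatin:
            fh.write(f"heterochromatin\t{chrom}\t{s}\t{e}\n")


def load_genome_tsv(path) -> GenomeModel:
    chroms: list[tuple[str, int]] = []
    cens: dict[str, tuple[int, int]] = {}
    het: list[tuple[str, int, int]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("record"):
            raise ParseError(f"{path}: missing genome TSV header")
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            try:
                rec, chrom, s, e = raw.rstrip("\n").split("\t")
                s, e = int(s), int(e)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if rec == "chromosome":
                chroms.append((chrom, e))
            elif rec == "centromere":
                cens[chrom] = (s, e)
            elif rec == "heterochromatin":
                het.append((chrom, s, e))
            else:
                raise ParseError(f"{path}: line {lineno}: unknown record {rec!r}")
    return GenomeModel(tuple(chroms), cens, tuple(het))
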