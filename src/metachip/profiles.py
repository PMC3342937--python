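"""Anchored aggregate profiles: point-centered and half-gene (TSS/TTS) modes.

Profiles average a density track across many anchors aligned at a common
reference.  Half-gene profiles sample four segments per gene in
transcriptional orientation: 5' flanking inter-annotation region, 5' gene
half (anchored at the TSS), 3' gene half (anchored at the TTS) and 3'
flanking region.  A centered sliding mean with edge shrink smooths the
aggregated series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .annotation import Feature
from .signal_io import SignalTrack, interval_means

SEGMENTS = ("5flank", "5half", "3half", "3flank")


class ProfileError(ValueError):
    pass


@dataclass(frozen=True)
class PointAnchor:
    chrom: str
    pos: int
    strand: str = "."


@dataclass(frozen=True)
class HalfGeneAnchor:
    """TSS/TTS anchor pair; for minus-strand genes tss > tts numerically."""

    id: str
    chrom: str
    tss: int
    tts: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss == self.tts:
            raise ProfileError(f"{self.id}: TSS == TTS")
        if self.strand == "+" and self.tss > self.tts:
            raise ProfileError(f"{self.id}: + strand but TSS > TTS")
        if self.strand == "-" and self.tss < self.tts:
            raise ProfileError(f"{self.id}: - strand but TSS < TTS")

    @property
    def length(self) -> int:
        return abs(self.tts - self.tss)


def halfgene_anchors(genes: Sequence[Feature]) -> list[HalfGeneAnchor]:
    """Build TSS/TTS anchors from stranded gene features."""
    out = []
    for g in genes:
        if g.strand == "-":
            out.append(HalfGeneAnchor(g.id, g.chrom, g.end, g.start, "-"))
        else:
            out.append(HalfGeneAnchor(g.id, g.chrom, g.start, g.end, "+"))
    return out


@dataclass
class AggregateProfile:
    """Aggregated per-bin means with contributing-anchor counts.

    ``offsets`` give each bin's left edge in bp relative to its anchor in
    transcriptional orientation; ``mean`` is NaN where ``n`` is 0.
    """

    bin_width: int
    offsets: np.ndarray
    mean: np.ndarray
    n: np.ndarray
    segment_labels: list[str] | None = None

    def segment(self, label: str) -> "AggregateProfile":
        if self.segment_labels is None:
            raise ProfileError("profile has no segment labels")
        idx = np.array([l == label for l in self.segment_labels])
        return AggregateProfile(
            self.bin_width,
            self.offsets[idx],
            self.mean[idx],
            self.n[idx],
            [label] * int(idx.sum()),
        )


def sliding_mean(series, window: int) -> np.ndarray:
    """Centered moving average with edge shrink; output length == input length.

    NaN entries are ignored within each window (all-NaN windows stay NaN).
    """
    x = np.asarray(series, dtype=float)
    if window < 1:
        raise ProfileError("window must be >= 1")
    if window > 2 * len(x):
        raise ProfileError(f"window {window} larger than 2x series length {len(x)}")
    if window == 1:
        return x.copy()
    half_l = (window - 1) // 2
    half_r = window // 2
    finite = np.isfinite(x)
    filled = np.where(finite, x, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(filled)])
    ccnt = np.concatenate([[0], np.cumsum(finite.astype(np.int64))])
    i = np.arange(len(x))
    lo = np.maximum(i - half_l, 0)
    hi = np.minimum(i + half_r + 1, len(x))
    cnt = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, (csum[hi] - csum[lo]) / np.maximum(cnt, 1), np.nan)
    return out


def _bins_to_window(smooth_bp: int, bin_width: int) -> int:
    return max(1, int(round(smooth_bp / bin_width)))


def point_anchored_profile(
    track: SignalTrack,
    anchors: Sequence[PointAnchor],
    bin: int,
    span: int,
    smooth: int,
) -> AggregateProfile:
    """Average signal in ``span`` bp of ``bin``-bp windows centered on anchors.

    Minus-strand anchors are orientation-flipped.  Anchors whose window runs
    off the chromosome contribute only the bins that exist (clipped, not
    dropped).  ``smooth`` bp of centered sliding mean is applied last.
    """
    if bin <= 0 or span % bin != 0:
        raise ProfileError("span must be a positive multiple of bin")
    if bin > span:
        raise ProfileError("bin larger than span")
    if not anchors:
        raise ProfileError("no anchors")
    nb = span // bin
    offsets = (np.arange(nb) * bin) - span // 2
    sums = np.zeros(nb)
    counts = np.zeros(nb, dtype=np.int64)
    used = 0
    for a in anchors:
        if a.chrom not in track.values:
            raise ProfileError(f"anchor on unknown chromosome {a.chrom}")
        length = track.chrom_lengths[a.chrom]
        left = a.pos + offsets
        right = left + bin
        ok = (left >= 0) & (right <= length)
        if not ok.any():
            continue
        vals = interval_means(track, a.chrom, left[ok], right[ok])
        idx = np.flatnonzero(ok)
        if a.strand == "-":
            idx = nb - 1 - idx
        sums[idx] += vals
        counts[idx] += 1
        used += 1
    if used == 0:
        raise ProfileError("zero usable anchors")
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mean = sliding_mean(mean, _bins_to_window(smooth, bin))
    return AggregateProfile(bin, offsets, mean, counts)


def flank_extents_from_irs(
    genes: Sequence[Feature], irs: Sequence[Feature]
) -> dict[str, tuple[int, int]]:
    """Per-gene (5' flank, 3' flank) lengths from abutting IR features.

    A flank exists only where an IR directly abuts the gene boundary; its
    extent is the IR length.  Orientation follows the gene strand.
    """
    up = {}  # (chrom, end) -> length of IR ending there
    down = {}  # (chrom, start) -> length of IR starting there
    for ir in irs:
        up[(ir.chrom, ir.end)] = ir.length
        down[(ir.chrom, ir.start)] = ir.length
    out: dict[str, tuple[int, int]] = {}
    for g in genes:
        before = up.get((g.chrom, g.start), 0)
        after = down.get((g.chrom, g.end), 0)
        out[g.id] = (after, before) if g.strand == "-" else (before, after)
    return out


def halfgene_profile(
    track: SignalTrack,
    genes: Sequence[HalfGeneAnchor],
    flanks: Mapping[str, tuple[int, int]] | None = None,
    bin: int = 50,
    max_extent: int = 2000,
    smooth: int = 500,
) -> AggregateProfile:
    """Dual-anchored half-gene aggregate profile.

    Each gene's 5' half is anchored at its TSS (offsets >= 0), the 3' half
    at its TTS (offsets < 0); halves are capped at ``max_extent`` bp with
    the midpoint bp assigned to the 5' half for odd lengths.  Flank segments
    sample the abutting inter-annotation regions, up to ``max_extent``.
    Per-bin means are taken over the genes that reach that bin.  Smoothing
    is applied per segment.  Genes shorter than ``2 * bin`` are skipped.
    """
    if not genes:
        raise ProfileError("empty gene set")
    if bin <= 0 or max_extent % bin != 0:
        raise ProfileError("max_extent must be a positive multiple of bin")
    m = max_extent // bin
    sums = {seg: np.zeros(m) for seg in SEGMENTS}
    counts = {seg: np.zeros(m, dtype=np.int64) for seg in SEGMENTS}
    flanks = flanks or {}
    used = 0
    for g in genes:
        L = g.length
        if L < 2 * bin:
            warnings.warn(f"gene {g.id} shorter than 2 bins; skipped", stacklevel=2)
            continue
        if g.chrom not in track.values:
            raise ProfileError(f"gene {g.id} on unknown chromosome {g.chrom}")
        d = 1 if g.strand == "+" else -1
        half5 = min(((L + 1) // 2) // bin, m)  # bins; midpoint bp goes 5'
        half3 = min((L // 2) // bin, m)
        f5_bp, f3_bp = flanks.get(g.id, (0, 0))
        f5 = min(max(f5_bp, 0) // bin, m)
        f3 = min(max(f3_bp, 0) // bin, m)
        clen = track.chrom_lengths[g.chrom]

        def sample(anchor: int, rel_lo: np.ndarray, seg: str, idx: np.ndarray) -> None:
            nonlocal used
            a = anchor + d * rel_lo
            b = anchor + d * (rel_lo + bin)
            lo = np.minimum(a, b)
            hi = np.maximum(a, b)
            ok = (lo >= 0) & (hi <= clen)
            if not ok.any():
                return
            vals = interval_means(track, g.chrom, lo[ok], hi[ok])
            sums[seg][idx[ok]] += vals
            counts[seg][idx[ok]] += 1

        if half5 > 0:
            k = np.arange(half5)
            sample(g.tss, k * bin, "5half", k)
        if half3 > 0:
            k = np.arange(half3)
            sample(g.tts, -(k + 1) * bin, "3half", k)
        if f5 > 0:
            k = np.arange(f5)
            sample(g.tss, -(k + 1) * bin, "5flank", k)
        if f3 > 0:
            k = np.arange(f3)
            sample(g.tts, k * bin, "3flank", k)
        used += 1
    if used == 0:
        raise ProfileError("zero usable genes")

    def seg_mean(seg: str) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(
                counts[seg] > 0, sums[seg] / np.maximum(counts[seg], 1), np.nan
            )

    w = _bins_to_window(smooth, bin)
    # per segment, local index k counts bins away from the anchor; assemble in
    # transcription order: 5flank (far -> TSS), 5half, 3half (far -> TTS), 3flank
    parts_mean: list[np.ndarray] = []
    parts_n: list[np.ndarray] = []
    parts_off: list[np.ndarray] = []
    labels: list[str] = []
    for seg in SEGMENTS:
        mean_k = seg_mean(seg)
        if seg in ("5flank", "3half"):
            ordered = sliding_mean(mean_k[::-1], w)
            n_ordered = counts[seg][::-1]
            off = -(np.arange(m, 0, -1)) * bin
        else:
            ordered = sliding_mean(mean_k, w)
            n_ordered = counts[seg]
            off = np.arange(m) * bin
        parts_mean.append(ordered)
        parts_n.append(n_ordered)
        parts_off.append(off)
        labels.extend([seg] * m)
    return AggregateProfile(
        bin,
        np.concatenate(parts_off),
        np.concatenate(parts_mean),
        np.concatenate(parts_n),
        labels,
    )


def write_profile_tsv(profile: AggregateProfile, path) -> None:
    labels = profile.segment_labels or ["."] * len(profile.offsets)
    with open(path, "w") as fh:
        fh.write("segment\toffset_bp\tmean\tn\n")
        for seg, off, mu, n in zip(labels, profile.offsets, profile.mean, profile.n):
            mu_s = "nan" if not np.isfinite(mu) else format(mu, ".10g")
            fh.write(f"{seg}\t{int(off)}\t{mu_s}\t{int(n)}\n")
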