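"""Fixed-step genomic density tracks: WIG/bedGraph IO, normalization, queries.

A :class:`SignalTrack` holds one value per ``step``-bp window per chromosome
(density semantics: positions absent from the input file are 0, not NaN).
Interval queries are coverage-weighted means, so partial step-windows at
interval ends contribute proportionally to their overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotation import GenomeModel


class SignalIOError(ValueError):
    """Invalid track content or query."""


def n_bins(length: int, step: int) -> int:
    return -(-length // step)  # ceil


@dataclass
class SignalTrack:
    """Per-chromosome fixed-step density vectors.

    ``values[chrom]`` has ``ceil(length/step)`` entries; the last window may
    be shorter than ``step`` when the chromosome length is not a multiple.
    """

    step: int
    values: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]
    library_size: float | None = None
    normalized: bool = False
    _integrals: dict[str, np.ndarray] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise SignalIOError("step must be positive")
        for chrom, vec in self.values.items():
            if chrom not in self.chrom_lengths:
                raise SignalIOError(f"values for unknown chromosome {chrom}")
            expected = n_bins(self.chrom_lengths[chrom], self.step)
            if len(vec) != expected:
                raise SignalIOError(
                    f"{chrom}: expected {expected} bins, got {len(vec)}"
                )
            if np.any(np.asarray(vec) < 0):
                raise SignalIOError(f"{chrom}: negative signal value")

    def _integral(self, chrom: str) -> np.ndarray:
        """Prefix per-base integral: S[j] = sum of base-level signal in bins < j."""
        cached = self._integrals.get(chrom)
        if cached is not None:
            return cached
        vec = self.values[chrom]
        widths = np.full(len(vec), self.step, dtype=float)
        widths[-1] = self.chrom_lengths[chrom] - (len(vec) - 1) * self.step
        csum = np.concatenate([[0.0], np.cumsum(vec * widths)])
        self._integrals[chrom] = csum
        return csum

    def _invalidate(self) -> None:
        self._integrals.clear()


def track_like(genome: GenomeModel, step: int) -> SignalTrack:
    """All-zero track on a genome's grid."""
    lengths = genome.lengths
    values = {c: np.zeros(n_bins(l, step)) for c, l in lengths.items()}
    return SignalTrack(step=step, values=values, chrom_lengths=lengths)


def _base_integral_at(track: SignalTrack, chrom: str, pos: np.ndarray) -> np.ndarray:
    """Integral of the per-base signal over [0, pos) for an array of positions."""
    vec = track.values[chrom]
    csum = track._integral(chrom)
    j = np.minimum(pos // track.step, len(vec))
    rem = pos - j * track.step
    vals = vec[np.minimum(j, len(vec) - 1)]
    return csum[j] + rem * vals


def interval_means(
    track: SignalTrack, chrom: str, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Coverage-weighted mean signal over many [start, end) intervals at once."""
    if chrom not in track.values:
        raise SignalIOError(f"unknown chromosome {chrom}")
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    length = track.chrom_lengths[chrom]
    if np.any(starts < 0) or np.any(ends > length) or np.any(ends <= starts):
        raise SignalIOError(f"interval out of range on {chrom}")
    hi = _base_integral_at(track, chrom, ends)
    lo = _base_integral_at(track, chrom, starts)
    return (hi - lo) / (ends - starts)


def mean_signal(track: SignalTrack, chrom: str, start: int, end: int) -> float:
    """Coverage-weighted mean of the track over [start, end)."""
    return float(interval_means(track, chrom, np.array([start]), np.array([end]))[0])


def normalize_by_library_size(
    track: SignalTrack, mapped_reads: float, scale: float = 1e6
) -> SignalTrack:
    """Scale every value by ``scale / mapped_reads`` (per-million by default)."""
    if track.normalized:
        raise SignalIOError("track is already normalized")
    if mapped_reads <= 0:
        raise SignalIOError("mapped_reads must be positive")
    factor = scale / mapped_reads
    values = {c: v * factor for c, v in track.values.items()}
    return SignalTrack(
        step=track.step,
        values=values,
        chrom_lengths=dict(track.chrom_lengths),
        library_size=float(mapped_reads),
        normalized=True,
    )


def average_replicates(tracks: Sequence[SignalTrack]) -> SignalTrack:
    """Element-wise mean of replicate tracks on identical grids."""
    if not tracks:
        raise SignalIOError("need at least one track")
    first = tracks[0]
    for t in tracks[1:]:
        if t.step != first.step or t.chrom_lengths != first.chrom_lengths:
            raise SignalIOError("mismatched track grids")
        if t.normalized != first.normalized:
            raise SignalIOError("mixing normalized and raw tracks")
    values = {
        c: np.mean([t.values[c] for t in tracks], axis=0) for c in first.values
    }
    return SignalTrack(
        step=first.step,
        values=values,
        chrom_lengths=dict(first.chrom_lengths),
        library_size=None,
        normalized=first.normalized,
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _resample_intervals(
    acc: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    vals: np.ndarray,
    step: int,
) -> None:
    """Accumulate value*overlap per step-bin for arbitrary intervals."""
    b0 = starts // step
    b1 = (ends - 1) // step
    single = b0 == b1
    if np.any(single):
        np.add.at(acc, b0[single], vals[single] * (ends[single] - starts[single]))
    for s, e, v, a, b in zip(
        starts[~single], ends[~single], vals[~single], b0[~single], b1[~single]
    ):
        acc[a] += v * ((a + 1) * step - s)
        acc[b] += v * (e - b * step)
        if b > a + 1:
            acc[a + 1 : b] += v * step


def read_fixed_step_track(path, genome: GenomeModel, step: int = 10) -> SignalTrack:
    """Read a WIG (fixedStep/variableStep) or bedGraph file onto a step grid.

    Values off the declared grid are resampled by coverage-weighted mean with
    missing positions counted as 0.  Unknown chromosomes and negative values
    are errors.
    """
    lengths = genome.lengths
    acc = {c: np.zeros(n_bins(l, step)) for c, l in lengths.items()}
    unknown: set[str] = set()

    mode = "bedgraph"  # until a WIG declaration line is seen
    cur_chrom: str | None = None
    cur_start = 0  # 0-based, for fixedStep
    cur_step = step
    cur_span = 1
    pend_s: list[int] = []
    pend_e: list[int] = []
    pend_v: list[float] = []

    def flush() -> None:
        nonlocal pend_s, pend_e, pend_v
        if cur_chrom is None or cur_chrom in unknown or not pend_s:
            pend_s, pend_e, pend_v = [], [], []
            return
        s = np.asarray(pend_s, dtype=np.int64)
        e = np.asarray(pend_e, dtype=np.int64)
        v = np.asarray(pend_v, dtype=float)
        e = np.minimum(e, lengths[cur_chrom])
        ok = e > s
        _resample_intervals(acc[cur_chrom], s[ok], e[ok], v[ok], step)
        pend_s, pend_e, pend_v = [], [], []

    def parse_decl(line: str) -> dict[str, str]:
        return dict(
            kv.split("=", 1) for kv in line.split()[1:] if "=" in kv
        )

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                flush()
                d = parse_decl(line)
                mode = "fixed"
                cur_chrom = d["chrom"]
                cur_start = int(d["start"]) - 1
                cur_step = int(d.get("step", step))
                cur_span = int(d.get("span", cur_step))
                if cur_chrom not in lengths:
                    unknown.add(cur_chrom)
                continue
            if line.startswith("variableStep"):
                flush()
                d = parse_decl(line)
                mode = "variable"
                cur_chrom = d["chrom"]
                cur_span = int(d.get("span", 1))
                if cur_chrom not in lengths:
                    unknown.add(cur_chrom)
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            try:
                if mode == "fixed":
                    val = float(cols[0])
                    pend_s.append(cur_start)
                    pend_e.append(cur_start + cur_span)
                    pend_v.append(val)
                    cur_start += cur_step
                elif mode == "variable":
                    pos = int(cols[0]) - 1
                    val = float(cols[1])
                    pend_s.append(pos)
                    pend_e.append(pos + cur_span)
                    pend_v.append(val)
                else:  # bedgraph
                    chrom, s, e, val = cols[0], int(cols[1]), int(cols[2]), float(cols[3])
                    if chrom != cur_chrom:
                        flush()
                        cur_chrom = chrom
                        if chrom not in lengths:
                            unknown.add(chrom)
                    pend_s.append(s)
                    pend_e.append(e)
                    pend_v.append(val)
            except (ValueError, IndexError) as exc:
                raise SignalIOError(f"{path}: line {lineno}: {exc}") from exc
            if val < 0:
                raise SignalIOError(f"{path}: line {lineno}: negative value {val}")
    flush()
    if unknown:
        raise SignalIOError(
            f"{path}: unknown chromosomes: {', '.join(sorted(unknown))}"
        )
    # convert accumulated value*overlap into per-bin coverage-weighted means
    for chrom, vec in acc.items():
        widths = np.full(len(vec), step, dtype=float)
        if len(vec):
            widths[-1] = lengths[chrom] - (len(vec) - 1) * step
        vec /= widths
    return SignalTrack(step=step, values=acc, chrom_lengths=dict(lengths))


def write_wig(track: SignalTrack, path, name: str | None = None) -> None:
    """fixedStep WIG writer (full float precision, round-trip safe)."""
    with open(path, "w") as fh:
        if name:
            fh.write(f"track type=wiggle_0 name={name}\n")
        for chrom in track.values:
            vec = track.values[chrom]
            if not len(vec):
                continue
            fh.write(
                f"fixedStep chrom={chrom} start=1 step={track.step} span={track.step}\n"
            )
            fh.write("\n".join(format(v, ".17g") for v in vec))
            fh.write("\n")


def write_bedgraph(track: SignalTrack, path, name: str | None = None) -> None:
    with open(path, "w") as fh:
        if name:
            fh.write(f"track type=bedGraph name={name}\n")
        for chrom, vec in track.values.items():
            length = track.chrom_lengths[chrom]
            for i, v in enumerate(vec):
                s = i * track.step
                e = min(s + track.step, length)
                fh.write(f"{chrom}\t{s}\t{e}\t{format(v, '.17g')}\n")


def write_track_tsv(track: SignalTrack, path) -> None:
    """Per-bin TSV export: chrom, bin_start, value."""
    with open(path, "w") as fh:
        fh.write("chrom\tbin_start\tvalue\n")
        for chrom, vec in track.values.items():
            for i, v in enumerate(vec):
                fh.write(f"{chrom}\t{i * track.step}\t{format(v, '.17g')}\n")
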