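import numpy as np
import pytest

from metachip.annotation import GenomeModel
from metachip.signal_io import SignalTrack, n_bins


@pytest.fixture
def toy_genome() -> GenomeModel:
    return GenomeModel(
        chromosomes=(("chr1", 1000), ("chr2", 800)),
        centromeres={"chr1": (400, 600)},
    )


@pytest.fixture
def make_track():
    """Factory for tracks on arbitrary chromosome lengths."""

    def _make(values: dict[str, np.ndarray], step: int = 10,
              lengths: dict[str, int] | None = None,
              normalized: bool = False) -> SignalTrack:
        if lengths is None:
            lengths = {c: len(v) * step for c, v in values.items()}
        return SignalTrack(
            step=step,
            values={c: np.asarray(v, dtype=float) for c, v in values.items()},
            chrom_lengths=lengths,
            normalized=normalized,
        )

    return _make


@pytest.fixture
def uniform_track(make_track):
    def _make(constant: float, lengths: dict[str, int], step: int = 10):
        values = {
            c: np.full(n_bins(length, step), float(constant))
            for c, length in lengths.items()
        }
        return make_track(values, step=step, lengths=lengths)

    return _make


def per_base(track: SignalTrack, chrom: str) -> np.ndarray:
    """Independent per-base expansion of a step track (test oracle)."""
    length = track.chrom_lengths[chrom]
    return np.repeat(np.asarray(track.values[chrom]), track.step)[:length]
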