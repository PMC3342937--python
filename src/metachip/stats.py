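"""Enrichment statistics: 3' last-kb enrichment, rank correlations,
sliding-window scatter series, region distributions and Welch's t-test."""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .annotation import ChromatinStateSegment, Feature
from .profiles import sliding_mean
from .signal_io import SignalTrack, mean_signal


class StatsError(ValueError):
    pass


def last_kb_enrichment(track: SignalTrack, gene: Feature, k: int = 1000) -> float:
    """Mean signal over the k bp immediately 5' of the TTS, in gene orientation."""
    if gene.length < k:
        raise StatsError(f"gene {gene.id} shorter than {k} bp")
    if gene.strand == "-":
        return mean_signal(track, gene.chrom, gene.start, gene.start + k)
    return mean_signal(track, gene.chrom, gene.end - k, gene.end)


def enrichment_table(
    track: SignalTrack, genes: Sequence[Feature], k: int = 1000
) -> dict[str, float]:
    """Per-gene last-kb enrichment; genes shorter than k are excluded upstream."""
    return {g.id: last_kb_enrichment(track, g, k) for g in genes}


def spearman_correlation(x, y) -> float:
    """Spearman rho: Pearson correlation of tie-averaged ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise StatsError("input lengths differ")
    if len(x) < 3:
        raise StatsError("need at least 3 observations")
    rx = sps.rankdata(x)  # average rank on ties
    ry = sps.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise StatsError("constant input: correlation undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def windowed_scatter(x, y, window: int = 10) -> np.ndarray:
    """Sort pairs by x (stable) and smooth both coordinates.

    Returns an (n, 2) array of centered sliding means with edge shrink; one
    output row per input pair.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if window < 1:
        raise StatsError("window must be >= 1")
    if window > len(x):
        raise StatsError("window larger than number of pairs")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    return np.column_stack([sliding_mean(xs, window), sliding_mean(ys, window)])


def differential_rank_scatter(
    expr_diff: Mapping[str, float],
    enr_diff: Mapping[str, float],
    window: int = 500,
) -> np.ndarray:
    """Rank-space scatter of enrichment change against expression change.

    Both per-gene difference maps (dividing - non-dividing) are converted to
    tie-averaged ranks; genes are ordered by expression-difference rank and
    both rank series smoothed with a centered ``window``-gene sliding mean.
    """
    if set(expr_diff) != set(enr_diff):
        raise StatsError("mismatched gene sets")
    genes = list(expr_diff)
    ex = sps.rankdata([expr_diff[g] for g in genes])
    en = sps.rankdata([enr_diff[g] for g in genes])
    if window < 1 or window > len(genes):
        raise StatsError("window out of range")
    order = np.argsort(ex, kind="stable")
    return np.column_stack(
        [sliding_mean(ex[order], window), sliding_mean(en[order], window)]
    )


@dataclass(frozen=True)
class DistributionSummary:
    """Five-number summary of per-region mean signals for one class."""

    label: str
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    n: int


def distribution_over_regions(
    track: SignalTrack,
    regions: Sequence[Feature | ChromatinStateSegment],
    by: str = "category",
) -> list[DistributionSummary]:
    """Per-class five-number summaries of per-region mean signal.

    ``by`` names the attribute providing the class label ("category" for
    features, "state" for chromatin-state segments).  Quartiles use linear
    interpolation (R type-7).  Empty classes are omitted.
    """
    values: dict[str, list[float]] = {}
    for r in regions:
        label = getattr(r, by)
        values.setdefault(label, []).append(
            mean_signal(track, r.chrom, r.start, r.end)
        )
    out = []
    for label, vals in values.items():
        arr = np.asarray(vals)
        q = np.percentile(arr, [0, 25, 50, 75, 100])  # linear interpolation
        out.append(DistributionSummary(label, *map(float, q), n=len(arr)))
    return out


def welch_t_test(a, b) -> float:
    """Two-sided p-value of Welch's unequal-variance t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each sample needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 1.0
        raise StatsError("both samples degenerate with different means")
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def write_enrichment_tsv(table: Mapping[str, Mapping[str, float]], path) -> None:
    """TSV: gene_id plus one column per track label."""
    labels = list(table)
    genes = sorted({g for col in table.values() for g in col})
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(labels) + "\n")
        for g in genes:
            row = [format(table[l].get(g, float("nan")), ".10g") for l in labels]
            fh.write(g + "\t" + "\t".join(row) + "\n")


def write_scatter_tsv(series: np.ndarray, path, names=("x", "y")) -> None:
    with open(path, "w") as fh:
        fh.write(f"{names[0]}\t{names[1]}\n")
        for xv, yv in series:
            fh.write(f"{format(xv, '.10g')}\t{format(yv, '.10g')}\n")


def write_distribution_tsv(summaries: Sequence[DistributionSummary], path) -> None:
    with open(path, "w") as fh:
        fh.write("class\tmin\tq1\tmedian\tq3\tmax\tn\n")
        for s in summaries:
            fh.write(
                f"{s.label}\t{s.minimum:.10g}\t{s.q1:.10g}\t{s.median:.10g}"
                f"\t{s.q3:.10g}\t{s.maximum:.10g}\t{s.n}\n"
            )


def write_correlation_json(rho: float, n: int, path, p: float | None = None) -> None:
    with open(path, "w") as fh:
        json.dump({"rho": rho, "n": n, "p": p}, fh, indent=2)
        fh.write("\n")
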