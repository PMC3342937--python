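"""FPKM expression tables: replicate filtering, binning, gene-set selection.

The table stores per-gene FPKM keyed by (tissue, replicate).  Per-tissue
means are arithmetic means over that tissue's replicates; a gene counts as
expressed when any library has FPKM > 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

TISSUES = ("dividing", "nondividing")

EXPRESSION_BIN_EDGES = (0.0, 1.0, 5.0, 10.0, 20.0, 30.0)
EXPRESSION_BIN_LABELS = ("0-1", "1-5", "5-10", "10-20", "20-30", ">30")

LENGTH_BIN_EDGES = (1000, 2000, 3000, 4000)
LENGTH_BIN_LABELS = ("<1kb", "1-2kb", "2-3kb", "3-4kb", ">4kb")


class ExpressionError(ValueError):
    pass


@dataclass(frozen=True)
class Verdict:
    keep: bool
    rule: str | None = None  # "i" | "ii" | "iii" when discarded

    def __str__(self) -> str:
        return "keep" if self.keep else f"discard({self.rule})"


def replicate_consistency_filter(fpkm_rep1: float, fpkm_rep2: float) -> Verdict:
    """Three-rule replicate-variation filter, reported with precedence i > ii > iii.

    Discard when (i) the absolute FPKM difference exceeds 1.0, (ii) that
    difference exceeds a third of the smaller (non-zero) value, or (iii)
    exactly one replicate is zero.
    """
    r1, r2 = float(fpkm_rep1), float(fpkm_rep2)
    if r1 < 0 or r2 < 0:
        raise ExpressionError("FPKM values must be >= 0")
    diff = abs(r1 - r2)
    lo = min(r1, r2)
    if diff > 1.0:
        return Verdict(False, "i")
    if lo > 0 and diff / lo > 1.0 / 3.0:
        return Verdict(False, "ii")
    if (r1 == 0) != (r2 == 0):
        return Verdict(False, "iii")
    return Verdict(True)


class ExpressionTable:
    """Per-gene FPKM by (tissue, replicate) with derived means and verdicts."""

    def __init__(
        self, records: Mapping[str, Mapping[tuple[str, int], float]]
    ) -> None:
        self.records: dict[str, dict[tuple[str, int], float]] = {}
        for gene, vals in records.items():
            clean: dict[tuple[str, int], float] = {}
            for (tissue, rep), fpkm in vals.items():
                fpkm = float(fpkm)
                if fpkm < 0:
                    raise ExpressionError(f"{gene}: negative FPKM")
                clean[(str(tissue), int(rep))] = fpkm
            self.records[str(gene)] = clean

    # -- basic access -----------------------------------------------------
    def genes(self) -> list[str]:
        return list(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene: str) -> bool:
        return gene in self.records

    def replicates(self, gene: str, tissue: str) -> list[float]:
        vals = self.records[gene]
        return [v for (t, _r), v in sorted(vals.items()) if t == tissue]

    def tissue_mean(self, gene: str, tissue: str) -> float:
        reps = self.replicates(gene, tissue)
        if not reps:
            raise ExpressionError(f"{gene}: no replicates for tissue {tissue!r}")
        return sum(reps) / len(reps)

    def is_expressed(self, gene: str) -> bool:
        return any(v > 0 for v in self.records[gene].values())

    # -- filtering --------------------------------------------------------
    def verdict(self, gene: str, tissues: Sequence[str] = TISSUES) -> Verdict:
        """Per-gene verdict: discarded if any tissue's replicate pair fails."""
        for tissue in tissues:
            reps = self.replicates(gene, tissue)
            if len(reps) == 2:
                v = replicate_consistency_filter(reps[0], reps[1])
                if not v.keep:
                    return v
        return Verdict(True)

    def kept_genes(self, tissues: Sequence[str] = TISSUES) -> list[str]:
        return [g for g in self.records if self.verdict(g, tissues).keep]

    # -- IO ---------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path) -> "ExpressionTable":
        """Long-format TSV: gene_id, tissue, replicate, fpkm (with header)."""
        records: dict[str, dict[tuple[str, int], float]] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:4] != ["gene_id", "tissue", "replicate", "fpkm"]:
                raise ExpressionError(f"{path}: unexpected header {header!r}")
            for lineno, raw in enumerate(fh, start=2):
                if not raw.strip():
                    continue
                try:
                    gene, tissue, rep, fpkm = raw.rstrip("\n").split("\t")
                    records.setdefault(gene, {})[(tissue, int(rep))] = float(fpkm)
                except ValueError as exc:
                    raise ExpressionError(f"{path}: line {lineno}: {exc}") from exc
        return cls(records)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\ttissue\treplicate\tfpkm\n")
            for gene in self.records:
                for (tissue, rep), fpkm in sorted(self.records[gene].items()):
                    fh.write(f"{gene}\t{tissue}\t{rep}\t{format(fpkm, '.17g')}\n")

    def write_verdicts_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tverdict\n")
            for gene in self.records:
                fh.write(f"{gene}\t{self.verdict(gene)}\n")


def assign_expression_bin(mean_fpkm: float) -> str:
    """Map a positive mean FPKM to its (lo, hi] expression bin label."""
    v = float(mean_fpkm)
    if v <= 0:
        raise ExpressionError("unexpressed gene has no expression bin")
    for hi, label in zip(EXPRESSION_BIN_EDGES[1:], EXPRESSION_BIN_LABELS[:-1]):
        if v <= hi:
            return label
    return EXPRESSION_BIN_LABELS[-1]


def assign_length_bin(gene_length: int) -> str:
    """Map a gene length to its [lo, hi) length bin label."""
    if gene_length <= 0:
        raise ExpressionError("gene length must be positive")
    for hi, label in zip(LENGTH_BIN_EDGES, LENGTH_BIN_LABELS[:-1]):
        if gene_length < hi:
            return label
    return LENGTH_BIN_LABELS[-1]


def select_fold_change_sets(
    expr: ExpressionTable,
    fold: float = 5.0,
    genes: Iterable[str] | None = None,
) -> tuple[set[str], set[str]]:
    """Genes up-regulated >= fold in one tissue versus the other.

    A zero denominator counts as exceeding any fold, so ON/OFF genes fall in
    the appropriate set; genes silent in both tissues fall in neither.
    """
    up_div: set[str] = set()
    up_nondiv: set[str] = set()
    pool = expr.genes() if genes is None else list(genes)
    for g in pool:
        m_div = expr.tissue_mean(g, "dividing")
        m_non = expr.tissue_mean(g, "nondividing")
        if m_div > 0 and m_div >= fold * m_non:
            up_div.add(g)
        if m_non > 0 and m_non >= fold * m_div:
            up_nondiv.add(g)
    return up_div, up_nondiv


def select_on_off_sets(
    expr: ExpressionTable,
    on_thresh: float = 3.0,
    off_thresh: float = 1.0,
    genes: Iterable[str] | None = None,
) -> tuple[set[str], set[str]]:
    """Genes ON (> on_thresh) in one tissue and OFF (< off_thresh) in the other."""
    on_div: set[str] = set()
    on_non: set[str] = set()
    pool = expr.genes() if genes is None else list(genes)
    for g in pool:
        m_div = expr.tissue_mean(g, "dividing")
        m_non = expr.tissue_mean(g, "nondividing")
        if m_div > on_thresh and m_non < off_thresh:
            on_div.add(g)
        if m_non > on_thresh and m_div < off_thresh:
            on_non.add(g)
    return on_div, on_non


@dataclass(frozen=True)
class GeneGroupSummary:
    """Per-group FPKM totals and the dividing/non-dividing ratio."""

    label: str
    dividing_total: float
    nondividing_total: float
    n_genes: int

    @property
    def ratio(self) -> float | None:
        if self.nondividing_total <= 0:
            return None
        return self.dividing_total / self.nondividing_total

    def rendered(self) -> tuple[str, str, str, str]:
        """Totals at one decimal, ratio at two, as in the published table."""
        r = self.ratio
        return (
            self.label,
            f"{self.dividing_total:.1f}",
            f"{self.nondividing_total:.1f}",
            "NA" if r is None else f"{r:.2f}",
        )


def summarize_gene_groups(
    expr: ExpressionTable, groups: Mapping[str, Sequence[str]]
) -> list[GeneGroupSummary]:
    """Totals of per-tissue mean FPKM over each group's member genes."""
    missing = sorted(
        {g for members in groups.values() for g in members if g not in expr}
    )
    if missing:
        raise ExpressionError(f"genes missing from table: {', '.join(missing)}")
    out = []
    for label, members in groups.items():
        div = sum(expr.tissue_mean(g, "dividing") for g in members)
        non = sum(expr.tissue_mean(g, "nondividing") for g in members)
        out.append(GeneGroupSummary(label, div, non, len(members)))
    return out


def write_group_summaries_tsv(summaries: Sequence[GeneGroupSummary], path) -> None:
    with open(path, "w") as fh:
        fh.write("group\tdividing_total\tnondividing_total\tratio\tn_genes\n")
        for s in summaries:
            label, div, non, ratio = s.rendered()
            fh.write(f"{label}\t{div}\t{non}\t{ratio}\t{s.n_genes}\n")
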