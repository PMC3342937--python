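"""Synthetic genomes, annotations, expression tables and density tracks.

The generator produces multi-chromosome genomes with centromeres and
heterochromatic blocks, non-overlapping stranded genes separated by
inter-annotation gaps, TEs biased toward heterochromatin, a two-tissue /
two-replicate FPKM table with a controlled differential fraction, and four
density tracks per tissue:

* H3.3-like — baseline plus a 3'-increasing ramp scaled by log(1+FPKM),
  depleted inside heterochromatin;
* H3.1-like — near-uniform with mild heterochromatin enrichment;
* H3-like  — uniform with a centromeric bump;
* IgG-like — flat background.

Deposition is modelled per base, binned onto the track step, then optionally
perturbed with Poisson sampling noise.  Every output is a pure function of
(config, seed); ground truth is recorded for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .annotation import (
    ChromatinStateSegment,
    Feature,
    GenomeModel,
    merge_adjacent_state_segments,
    write_genome_tsv,
    write_state_segments_bed,
)
from .expression import ExpressionTable, TISSUES
from .signal_io import SignalTrack, n_bins, write_wig

ANTIBODIES = ("H3.3", "H3.1", "H3", "IgG")


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """All simulator knobs; see module docstring for the signal models."""

    # genome
    n_chromosomes: int = 3
    chromosome_length: int = 1_500_000
    centromere_fraction: float = 0.12
    het_blocks_per_chrom: int = 1
    het_block_length: int = 25_000
    # annotation
    n_genes: int = 1000
    gene_length_log_mean: float = 7.4
    gene_length_log_sd: float = 0.45
    min_gene_length: int = 400
    max_gene_length: int = 12_000
    gene_gap_min: int = 200
    gene_gap_max: int = 1200
    n_tes: int = 120
    te_het_bias: float = 0.8
    te_length_min: int = 500
    te_length_max: int = 3000
    n_sites: int = 400
    # expression
    active_fraction: float = 0.7
    fpkm_log_mean: float = 1.5
    fpkm_log_sd: float = 1.2
    low_fpkm_log_mean: float = -1.5
    low_fpkm_log_sd: float = 0.8
    silent_fraction_of_inactive: float = 0.4
    diff_fraction: float = 0.1
    diff_fold_min: float = 5.0
    diff_fold_log_sd: float = 0.4
    replicate_noise_sd: float = 0.005
    # tracks
    step: int = 10
    h33_baseline: float = 1.0
    h33_slope: float = 0.5
    h33_het_depletion: float = 0.5
    h31_baseline: float = 1.0
    h31_het_enrichment: float = 1.05
    h3_baseline: float = 1.0
    h3_centromere_bump: float = 0.5
    igg_level: float = 0.5
    seq_depth: float = 25.0
    poisson_noise: bool = True
    n_track_replicates: int = 2

    def __post_init__(self) -> None:
        if self.n_chromosomes <= 0 or self.chromosome_length <= 0:
            raise SyntheticError("genome dimensions must be positive")
        for name in ("centromere_fraction", "te_het_bias", "active_fraction",
                     "silent_fraction_of_inactive", "diff_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SyntheticError(f"{name} must be in [0, 1]")
        for name in ("h33_het_depletion", "h31_het_enrichment", "seq_depth"):
            if getattr(self, name) <= 0:
                raise SyntheticError(f"{name} must be > 0")
        if self.n_genes < 0 or self.n_tes < 0 or self.n_sites < 0:
            raise SyntheticError("counts must be >= 0")
        if self.step <= 0:
            raise SyntheticError("step must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators."""

    fpkm: dict[str, dict[str, float]] = field(default_factory=dict)
    slope: dict[str, float] = field(default_factory=dict)
    differential: dict[str, str | None] = field(default_factory=dict)
    active: dict[str, bool] = field(default_factory=dict)
    heterochromatin: list[tuple[str, int, int]] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "fpkm": self.fpkm,
            "slope": self.slope,
            "differential": self.differential,
            "active": self.active,
            "heterochromatin": [list(h) for h in self.heterochromatin],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            fpkm=d["fpkm"],
            slope=d["slope"],
            differential=d["differential"],
            active=d["active"],
            heterochromatin=[tuple(h) for h in d["heterochromatin"]],
        )


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stage])


def generate_genome(
    config: SyntheticConfig, seed: int, truth: SyntheticTruth | None = None
) -> tuple[GenomeModel, list[Feature], list[ChromatinStateSegment], SyntheticTruth]:
    """Genome, feature list and merged chromatin-state segmentation.

    Genes are placed without overlap inside euchromatic arms, separated by
    inter-annotation gaps; centromeres and heterochromatin blocks become
    CS3; regions around genes alternate CS1 (active) / CS2 (inactive); the
    remainder is CS4.  Raises when total gene bp exceeds 80% of the genome.
    """
    rng = _rng(seed, 1)
    truth = truth if truth is not None else SyntheticTruth()
    L = config.chromosome_length
    chroms = tuple((f"chr{i + 1}", L) for i in range(config.n_chromosomes))
    cen_len = int(L * config.centromere_fraction)
    centromeres = {}
    het_blocks: list[tuple[str, int, int]] = []
    arm_segments: list[tuple[str, int, int]] = []  # euchromatic, gene-eligible
    for name, _ in chroms:
        cs = (L - cen_len) // 2
        ce = cs + cen_len
        centromeres[name] = (cs, ce)
        # extra heterochromatin blocks in the left arm
        blocks = []
        for b in range(config.het_blocks_per_chrom):
            hi = cs - config.het_block_length
            if hi <= 0:
                break
            hs = int(rng.integers(0, hi))
            blocks.append((hs, hs + config.het_block_length))
        blocks = _disjoint(blocks)
        het_blocks.extend((name, s, e) for s, e in blocks)
        occupied = sorted(blocks + ([(cs, ce)] if cen_len > 0 else []))
        pos = 0
        for s, e in occupied:
            if s > pos:
                arm_segments.append((name, pos, s))
            pos = max(pos, e)
        if pos < L:
            arm_segments.append((name, pos, L))
    genome = GenomeModel(chroms, centromeres, tuple(het_blocks))
    truth.heterochromatin = [
        (n, *centromeres[n]) for n, _ in chroms
    ] + list(het_blocks)

    # gene lengths and placement
    lengths = np.clip(
        rng.lognormal(config.gene_length_log_mean, config.gene_length_log_sd,
                      config.n_genes),
        config.min_gene_length,
        config.max_gene_length,
    ).astype(int)
    if lengths.sum() > 0.8 * sum(l for _, l in chroms):
        raise SyntheticError("total gene bp exceeds 80% of the genome")
    strands = rng.choice(["+", "-"], size=config.n_genes)
    active = rng.random(config.n_genes) < config.active_fraction

    features: list[Feature] = []
    genes: list[Feature] = []
    seg_iter = iter(arm_segments)
    cur = next(seg_iter, None)
    cursor = cur[1] if cur else 0
    for i in range(config.n_genes):
        glen = int(lengths[i])
        placed = False
        while cur is not None:
            gap = int(rng.integers(config.gene_gap_min, config.gene_gap_max + 1))
            start = cursor + gap
            if start + glen + config.gene_gap_min <= cur[2]:
                gid = f"G{i + 1:05d}"
                g = Feature(gid, cur[0], start, start + glen, str(strands[i]), "gene")
                genes.append(g)
                features.append(g)
                truth.active[gid] = bool(active[i])
                cursor = start + glen
                placed = True
                break
            cur = next(seg_iter, None)
            cursor = cur[1] if cur else 0
        if not placed:
            raise SyntheticError(
                f"could not place gene {i + 1}/{config.n_genes}: genome too dense"
            )

    # leftover euchromatic space (after the last placed gene) for arm TEs/sites
    leftover: list[tuple[str, int, int]] = []
    if cur is not None:
        leftover.append((cur[0], cursor, cur[2]))
        leftover.extend(seg_iter)

    het_space = [(n, s, e) for n, (s, e) in centromeres.items()] + list(het_blocks)
    n_het_tes = int(round(config.n_tes * config.te_het_bias))
    te_lengths = rng.integers(
        config.te_length_min, config.te_length_max + 1, size=config.n_tes
    )
    tes = _place_in_segments(
        het_space, te_lengths[:n_het_tes], config.gene_gap_min, rng
    ) + _place_in_segments(
        leftover, te_lengths[n_het_tes:], config.gene_gap_min, rng
    )
    for j, (chrom, s, e) in enumerate(tes):
        strand = str(rng.choice(["+", "-"]))
        features.append(Feature(f"TE{j + 1:04d}", chrom, s, e, strand, "TE"))

    # chromatin states: CS3 over centromere+het, CS1/CS2 around genes, CS4 rest
    pad = config.gene_gap_min // 2
    raw: list[ChromatinStateSegment] = []
    for chrom, s, e in het_space:
        raw.append(ChromatinStateSegment(chrom, s, e, "CS3"))
    for g in genes:
        state = "CS1" if truth.active[g.id] else "CS2"
        raw.append(ChromatinStateSegment(g.chrom, g.start - pad, g.end + pad, state))
    raw.sort(key=lambda x: (x.chrom, x.start))
    filled: list[ChromatinStateSegment] = []
    by_chrom: dict[str, list[ChromatinStateSegment]] = {}
    for seg in raw:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for name, _ in chroms:
        pos = 0
        for seg in by_chrom.get(name, []):
            if seg.start > pos:
                filled.append(ChromatinStateSegment(name, pos, seg.start, "CS4"))
            filled.append(seg)
            pos = seg.end
        if pos < L:
            filled.append(ChromatinStateSegment(name, pos, L, "CS4"))
    segments = merge_adjacent_state_segments(filled)
    return genome, features, segments, truth


def _disjoint(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(blocks):
        if out and s < out[-1][1]:
            continue
        out.append((s, e))
    return out


def _place_in_segments(
    segments: list[tuple[str, int, int]],
    lengths: np.ndarray,
    gap: int,
    rng: np.random.Generator,
) -> list[tuple[str, int, int]]:
    """Place intervals of the given lengths sequentially with fixed gaps.

    Stops silently when space runs out (TE counts are best-effort)."""
    out: list[tuple[str, int, int]] = []
    seg_iter = iter(segments)
    cur = next(seg_iter, None)
    cursor = cur[1] if cur else 0
    for tl in lengths:
        tl = int(tl)
        while cur is not None:
            start = cursor + gap
            if start + tl + gap <= cur[2]:
                out.append((cur[0], start, start + tl))
                cursor = start + tl
                break
            cur = next(seg_iter, None)
            cursor = cur[1] if cur else 0
        if cur is None:
            break
    return out


def generate_sites(
    config: SyntheticConfig,
    genome: GenomeModel,
    features: list[Feature],
    seed: int,
) -> list[tuple[str, int]]:
    """Point sites (TFBS-like) drawn uniformly from annotation-free space."""
    rng = _rng(seed, 4)
    occupied: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        occupied.setdefault(f.chrom, []).append((f.start, f.end))
    free: list[tuple[str, int, int]] = []
    for name, length in genome.chromosomes:
        pos = 0
        for s, e in _disjoint(sorted(occupied.get(name, []))):
            if s > pos:
                free.append((name, pos, s))
            pos = max(pos, e)
        if pos < length:
            free.append((name, pos, length))
    if not free or config.n_sites == 0:
        return []
    widths = np.array([e - s for _, s, e in free], dtype=float)
    idx = rng.choice(len(free), size=config.n_sites, p=widths / widths.sum())
    sites = []
    for i in idx:
        chrom, s, e = free[i]
        sites.append((chrom, int(rng.integers(s, e))))
    return sorted(sites)


def generate_expression(
    config: SyntheticConfig,
    genes: list[Feature],
    truth: SyntheticTruth,
    seed: int,
) -> ExpressionTable:
    """Two-tissue, two-replicate FPKM table with a differential fraction.

    Active genes draw log-normal base FPKM; a configured fraction receive a
    >= ``diff_fold_min`` fold difference between tissues (half up in each
    direction).  Replicates multiply the truth by log-normal noise.
    """
    rng = _rng(seed, 2)
    gene_ids = [g.id for g in genes]
    n = len(gene_ids)
    base = np.empty(n)
    for i, gid in enumerate(gene_ids):
        if truth.active.get(gid, True):
            base[i] = rng.lognormal(config.fpkm_log_mean, config.fpkm_log_sd)
        elif rng.random() < config.silent_fraction_of_inactive:
            base[i] = 0.0
        else:
            base[i] = rng.lognormal(config.low_fpkm_log_mean, config.low_fpkm_log_sd)
    div = base.copy()
    non = base.copy()
    expressed = np.flatnonzero(base > 0)
    n_diff = int(round(config.diff_fraction * n))
    n_diff = min(n_diff, len(expressed))
    diff_idx = rng.choice(expressed, size=n_diff, replace=False)
    for j, i in enumerate(diff_idx):
        fold = config.diff_fold_min * np.exp(
            abs(rng.normal(0.0, config.diff_fold_log_sd))
        )
        if j % 2 == 0:
            div[i] = base[i] * fold
            truth.differential[gene_ids[i]] = "up_dividing"
        else:
            non[i] = base[i] * fold
            truth.differential[gene_ids[i]] = "up_nondividing"
    records: dict[str, dict[tuple[str, int], float]] = {}
    sd = config.replicate_noise_sd
    for i, gid in enumerate(gene_ids):
        truth.fpkm[gid] = {"dividing": float(div[i]), "nondividing": float(non[i])}
        truth.differential.setdefault(gid, None)
        recs = {}
        for tissue, true_val in (("dividing", div[i]), ("nondividing", non[i])):
            for rep in (1, 2):
                noise = np.exp(rng.normal(0.0, sd)) if sd > 0 else 1.0
                recs[(tissue, rep)] = float(true_val * noise)
        records[gid] = recs
    return ExpressionTable(records)


def _expected_density(
    config: SyntheticConfig,
    genome: GenomeModel,
    features: list[Feature],
    truth: SyntheticTruth,
    antibody: str,
    tissue: str,
) -> dict[str, np.ndarray]:
    """Per-base expected deposition for one antibody/tissue."""
    lengths = genome.lengths
    het_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in truth.heterochromatin:
        het_by_chrom.setdefault(chrom, []).append((s, e))
    out: dict[str, np.ndarray] = {}
    for chrom, L in genome.chromosomes:
        if antibody == "H3.3":
            arr = np.full(L, config.h33_baseline)
            for g in features:
                if g.category != "gene" or g.chrom != chrom:
                    continue
                F = truth.fpkm.get(g.id, {}).get(tissue, 0.0)
                if F <= 0:
                    continue
                frac = (np.arange(g.length) + 0.5) / g.length
                if g.strand == "-":
                    frac = frac[::-1]
                arr[g.start:g.end] += config.h33_slope * np.log1p(F) * frac
            for s, e in het_by_chrom.get(chrom, []):
                arr[s:e] *= config.h33_het_depletion
        elif antibody == "H3.1":
            arr = np.full(L, config.h31_baseline)
            for s, e in het_by_chrom.get(chrom, []):
                arr[s:e] *= config.h31_het_enrichment
        elif antibody == "H3":
            arr = np.full(L, config.h3_baseline)
            cen = genome.centromeres.get(chrom)
            if cen:
                arr[cen[0]:cen[1]] += config.h3_centromere_bump
        elif antibody == "IgG":
            arr = np.full(L, config.igg_level)
        else:
            raise SyntheticError(f"unknown antibody {antibody!r}")
        out[chrom] = arr
    return out


def generate_tracks(
    config: SyntheticConfig,
    genome: GenomeModel,
    features: list[Feature],
    truth: SyntheticTruth,
    seed: int,
) -> dict[tuple[str, str, int], SignalTrack]:
    """Unnormalized replicate tracks keyed (antibody, tissue, replicate).

    Per-base expectation is binned to the step grid; Poisson counts at
    ``seq_depth`` emulate sequencing noise (exact expected values when
    ``poisson_noise`` is off).  Library size is the track's total count.
    """
    rng = _rng(seed, 3)
    step = config.step
    tracks: dict[tuple[str, str, int], SignalTrack] = {}
    for tissue in TISSUES:
        for antibody in ANTIBODIES:
            dens = _expected_density(config, genome, features, truth, antibody, tissue)
            binned: dict[str, np.ndarray] = {}
            for chrom, L in genome.chromosomes:
                nb = n_bins(L, step)
                edges = np.arange(nb) * step
                widths = np.minimum(edges + step, L) - edges
                binned[chrom] = np.add.reduceat(dens[chrom], edges) / widths
            for rep in range(1, config.n_track_replicates + 1):
                values: dict[str, np.ndarray] = {}
                for chrom in binned:
                    lam = binned[chrom] * config.seq_depth
                    if config.poisson_noise:
                        values[chrom] = rng.poisson(lam).astype(float)
                    else:
                        values[chrom] = lam.copy()
                lib = float(sum(v.sum() for v in values.values()))
                tracks[(antibody, tissue, rep)] = SignalTrack(
                    step=step,
                    values=values,
                    chrom_lengths=genome.lengths,
                    library_size=lib if lib > 0 else None,
                    normalized=False,
                )
    return tracks


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: GenomeModel
    features: list[Feature]
    segments: list[ChromatinStateSegment]
    expression: ExpressionTable
    truth: SyntheticTruth
    tracks: dict[tuple[str, str, int], SignalTrack]
    sites: list[tuple[str, int]]

    @property
    def genes(self) -> list[Feature]:
        return [f for f in self.features if f.category == "gene"]


def generate_dataset(config: SyntheticConfig, seed: int) -> SyntheticDataset:
    """Run all generators with stage-separated sub-streams of ``seed``."""
    genome, features, segments, truth = generate_genome(config, seed)
    genes = [f for f in features if f.category == "gene"]
    expr = generate_expression(config, genes, truth, seed)
    # record the realised 3' slope coefficient per gene (dividing tissue)
    for g in genes:
        F = truth.fpkm[g.id]["dividing"]
        truth.slope[g.id] = float(config.h33_slope * np.log1p(F))
    tracks = generate_tracks(config, genome, features, truth, seed)
    sites = generate_sites(config, genome, features, seed)
    return SyntheticDataset(config, genome, features, segments, expr, truth,
                            tracks, sites)


# ---------------------------------------------------------------------------
# emitters
# ---------------------------------------------------------------------------

_GFF3_TYPE = {"gene": "gene", "TE": "transposable_element", "other": "other"}


def write_gff3(features: list[Feature], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            if f.category == "IR":
                continue
            ftype = _GFF3_TYPE.get(f.category, "other")
            fh.write(
                f"{f.chrom}\tmetachip\t{ftype}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={f.id}\n"
            )


def write_sites_bed(sites: list[tuple[str, int]], path) -> None:
    with open(path, "w") as fh:
        for i, (chrom, pos) in enumerate(sites, start=1):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\tsite{i}\t0\t.\n")


def emit_dataset(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write the whole dataset as plain-text files; returns name -> path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def reg(key: str, p: Path) -> Path:
        paths[key] = str(p)
        return p

    write_genome_tsv(dataset.genome, reg("genome", out / "genome.tsv"))
    write_gff3(dataset.features, reg("annotation", out / "annotation.gff3"))
    write_state_segments_bed(dataset.segments, reg("states", out / "states.bed"))
    dataset.expression.to_tsv(reg("expression", out / "expression.tsv"))
    dataset.truth.to_json(reg("truth", out / "truth.json"))
    write_sites_bed(dataset.sites, reg("sites", out / "sites.bed"))
    trackdir = out / "tracks"
    trackdir.mkdir(exist_ok=True)
    for (antibody, tissue, rep), track in dataset.tracks.items():
        safe = antibody.replace(".", "")
        p = reg(
            f"track:{antibody}:{tissue}:{rep}",
            trackdir / f"{safe}_{tissue}_rep{rep}.wig",
        )
        write_wig(track, p)
        with open(str(p) + ".libsize", "w") as fh:
            fh.write(f"{int(track.library_size or 0)}\n")
    with open(out / "config.json", "w") as fh:
        json.dump(asdict(dataset.config), fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["config"] = str(out / "config.json")
    return paths
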