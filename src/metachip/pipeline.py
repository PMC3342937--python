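"""End-to-end orchestration: declarative run config, stages, manifest.

Stages can run individually (CLI subcommands) or in sequence through
:func:`run_pipeline`; both paths call the same stage functions, so outputs
are identical.  Every stage writes plain-text TSV/JSON into the configured
output directory and the orchestrated run records a manifest with the
config hash, seeds and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__, annotation as ann, signal_io as sio
from .expression import (
    ExpressionTable,
    assign_expression_bin,
    assign_length_bin,
    select_fold_change_sets,
    select_on_off_sets,
    summarize_gene_groups,
    write_group_summaries_tsv,
)
from .profiles import (
    PointAnchor,
    flank_extents_from_irs,
    halfgene_anchors,
    halfgene_profile,
    point_anchored_profile,
    write_profile_tsv,
)
from .stats import (
    differential_rank_scatter,
    distribution_over_regions,
    enrichment_table,
    spearman_correlation,
    windowed_scatter,
    write_distribution_tsv,
    write_enrichment_tsv,
    write_scatter_tsv,
)

log = logging.getLogger("metachip")

STAGES = (
    "annotate",
    "tracks",
    "profile_centromere",
    "distributions",
    "profile_genes",
    "enrichment",
    "dynamics",
    "summarize",
)


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class Params:
    """Analysis parameters; defaults follow the published protocol."""

    step: int = 10
    normalization_scale: float = 1e6
    ir_min_len: int = 150
    min_gene_len: int = 1000
    gene_bin: int = 50
    gene_max_extent: int = 2000
    gene_smooth: int = 500
    centromere_bin: int = 200_000
    centromere_span: int = 20_000_000
    centromere_smooth: int = 1_000_000
    site_bin: int = 50
    site_span: int = 2000
    site_smooth: int = 200
    last_kb: int = 1000
    fold: float = 5.0
    on_thresh: float = 3.0
    off_thresh: float = 1.0
    scatter_window: int = 10
    rank_window: int = 500


@dataclass
class RunConfig:
    """Declarative pipeline configuration (one YAML file)."""

    outdir: str
    genome: str
    annotation: str
    annotation_dialect: str = "gff3"
    states: str | None = None
    expression: str | None = None
    sites: str | None = None
    # antibody -> tissue -> list of {"path": ..., "library_size": optional}
    tracks: dict[str, dict[str, list[dict[str, Any]]]] = field(default_factory=dict)
    params: Params = field(default_factory=Params)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = Params(**(raw.pop("params", {}) or {}))
        return cls(params=params, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def sha256(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _require(path: str | None, what: str, stage: str) -> str:
    if not path or not os.path.exists(path):
        raise PipelineError(f"stage {stage}: missing input {what}: {path!r}")
    return path


class PipelineContext:
    """Lazy loader/cache for pipeline inputs shared across stages."""

    def __init__(self, config: RunConfig) -> None:
        self.cfg = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self._cache: dict[str, Any] = {}

    # -- inputs -----------------------------------------------------------
    @property
    def genome(self) -> ann.GenomeModel:
        if "genome" not in self._cache:
            path = _require(self.cfg.genome, "genome", "annotate")
            self._cache["genome"] = ann.load_genome_tsv(path)
        return self._cache["genome"]

    @property
    def features(self) -> list[ann.Feature]:
        if "features" not in self._cache:
            path = _require(self.cfg.annotation, "annotation", "annotate")
            feats = ann.load_annotation(path, self.cfg.annotation_dialect)
            ann.validate_features(feats, self.genome)
            self._cache["features"] = feats
        return self._cache["features"]

    @property
    def irs(self) -> list[ann.Feature]:
        if "irs" not in self._cache:
            self._cache["irs"] = ann.compute_inter_annotation_regions(
                self.features, self.genome, self.cfg.params.ir_min_len
            )
        return self._cache["irs"]

    @property
    def kept_genes(self) -> list[ann.Feature]:
        if "kept_genes" not in self._cache:
            genes = [f for f in self.features if f.category == "gene"]
            kept, reasons = ann.filter_genes_for_profiles(
                genes, self.features, self.cfg.params.min_gene_len
            )
            self._cache["kept_genes"] = kept
            self._cache["filter_reasons"] = reasons
        return self._cache["kept_genes"]

    @property
    def expression(self) -> ExpressionTable:
        if "expression" not in self._cache:
            path = _require(self.cfg.expression, "expression table", "profile_genes")
            self._cache["expression"] = ExpressionTable.from_tsv(path)
        return self._cache["expression"]

    def track(self, antibody: str, tissue: str) -> sio.SignalTrack:
        """Normalized replicate-averaged track for one antibody/tissue."""
        key = f"track:{antibody}:{tissue}"
        if key not in self._cache:
            try:
                entries = self.cfg.tracks[antibody][tissue]
            except KeyError as exc:
                raise PipelineError(
                    f"stage tracks: no track configured for {antibody}/{tissue}"
                ) from exc
            reps = []
            for entry in entries:
                path = _require(entry.get("path"), f"{antibody}/{tissue} track",
                                "tracks")
                raw = sio.read_fixed_step_track(path, self.genome,
                                                self.cfg.params.step)
                lib = entry.get("library_size")
                if lib is None:
                    sidecar = path + ".libsize"
                    if os.path.exists(sidecar):
                        lib = float(open(sidecar).read().strip())
                    else:
                        lib = float(sum(v.sum() for v in raw.values.values()))
                reps.append(
                    sio.normalize_by_library_size(
                        raw, lib, self.cfg.params.normalization_scale
                    )
                )
            self._cache[key] = sio.average_replicates(reps)
        return self._cache[key]

    @property
    def antibodies(self) -> list[str]:
        return list(self.cfg.tracks)

    def tissues(self, antibody: str) -> list[str]:
        return list(self.cfg.tracks[antibody])


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_annotate(ctx: PipelineContext) -> list[str]:
    out_ir = ctx.outdir / "irs.bed"
    ann.write_features_bed(ctx.irs, out_ir)
    kept = ctx.kept_genes
    reasons = ctx._cache["filter_reasons"]
    out_filter = ctx.outdir / "gene_filter.tsv"
    with open(out_filter, "w") as fh:
        fh.write("gene_id\tstatus\n")
        for f in ctx.features:
            if f.category != "gene":
                continue
            fh.write(f"{f.id}\t{reasons.get(f.id, 'kept')}\n")
    log.info("annotate: %d features, %d IRs, %d genes kept",
             len(ctx.features), len(ctx.irs), len(kept))
    return [str(out_ir), str(out_filter)]


def stage_tracks(ctx: PipelineContext) -> list[str]:
    out = ctx.outdir / "track_stats.tsv"
    with open(out, "w") as fh:
        fh.write("antibody\ttissue\tn_replicates\tmean_signal\n")
        for antibody in ctx.antibodies:
            for tissue in ctx.tissues(antibody):
                t = ctx.track(antibody, tissue)
                total = sum(v.sum() for v in t.values.values())
                nb = sum(len(v) for v in t.values.values())
                fh.write(
                    f"{antibody}\t{tissue}\t{len(ctx.cfg.tracks[antibody][tissue])}"
                    f"\t{total / nb:.10g}\n"
                )
    return [str(out)]


def stage_profile_centromere(ctx: PipelineContext) -> list[str]:
    p = ctx.cfg.params
    anchors = [
        PointAnchor(chrom, (s + e) // 2, ".")
        for chrom, (s, e) in ctx.genome.centromeres.items()
    ]
    if not anchors:
        raise PipelineError("stage profile_centromere: genome has no centromeres")
    outs = []
    for antibody in ctx.antibodies:
        tissue = ctx.tissues(antibody)[0]
        prof = point_anchored_profile(
            ctx.track(antibody, tissue), anchors,
            bin=p.centromere_bin, span=p.centromere_span, smooth=p.centromere_smooth,
        )
        out = ctx.outdir / f"centromere_{antibody.replace('.', '')}.tsv"
        write_profile_tsv(prof, out)
        outs.append(str(out))
    return outs


def stage_profile_sites(ctx: PipelineContext) -> list[str]:
    p = ctx.cfg.params
    path = _require(ctx.cfg.sites, "sites", "profile_sites")
    sites = ann.load_annotation(path, "bed")
    anchors = [PointAnchor(s.chrom, (s.start + s.end) // 2, s.strand) for s in sites]
    outs = []
    for antibody in ctx.antibodies:
        tissue = ctx.tissues(antibody)[0]
        prof = point_anchored_profile(
            ctx.track(antibody, tissue), anchors,
            bin=p.site_bin, span=p.site_span, smooth=p.site_smooth,
        )
        out = ctx.outdir / f"sites_{antibody.replace('.', '')}.tsv"
        write_profile_tsv(prof, out)
        outs.append(str(out))
    return outs


def stage_distributions(ctx: PipelineContext) -> list[str]:
    outs = []
    states = None
    if ctx.cfg.states:
        states = ann.merge_adjacent_state_segments(
            ann.load_state_segments(_require(ctx.cfg.states, "states",
                                             "distributions"))
        )
    for antibody in ctx.antibodies:
        tissue = ctx.tissues(antibody)[0]
        track = ctx.track(antibody, tissue)
        regions = list(ctx.features) + list(ctx.irs)
        feat_summary = distribution_over_regions(track, regions, by="category")
        out = ctx.outdir / f"distributions_features_{antibody.replace('.', '')}.tsv"
        write_distribution_tsv(sorted(feat_summary, key=lambda s: s.label), out)
        outs.append(str(out))
        if states:
            cs_summary = distribution_over_regions(track, states, by="state")
            out = ctx.outdir / f"distributions_states_{antibody.replace('.', '')}.tsv"
            write_distribution_tsv(sorted(cs_summary, key=lambda s: s.label), out)
            outs.append(str(out))
    return outs


def _gene_profile_for_subset(ctx: PipelineContext, antibody: str, tissue: str,
                             genes: list[ann.Feature]):
    p = ctx.cfg.params
    anchors = halfgene_anchors(genes)
    flanks = flank_extents_from_irs(genes, ctx.irs)
    return halfgene_profile(
        ctx.track(antibody, tissue), anchors, flanks,
        bin=p.gene_bin, max_extent=p.gene_max_extent, smooth=p.gene_smooth,
    )


def _write_binned_profiles(ctx, antibody, tissue, bins: dict[str, list], prefix):
    out = ctx.outdir / f"{prefix}_{antibody.replace('.', '')}.tsv"
    with open(out, "w") as fh:
        fh.write("bin\tsegment\toffset_bp\tmean\tn\n")
        for label in bins:
            genes = bins[label]
            if not genes:
                continue
            prof = _gene_profile_for_subset(ctx, antibody, tissue, genes)
            for seg, off, mu, n in zip(prof.segment_labels, prof.offsets,
                                       prof.mean, prof.n):
                mu_s = "nan" if not np.isfinite(mu) else format(mu, ".10g")
                fh.write(f"{label}\t{seg}\t{int(off)}\t{mu_s}\t{int(n)}\n")
    return str(out)


def stage_profile_genes(ctx: PipelineContext) -> list[str]:
    expr = ctx.expression
    kept = [g for g in ctx.kept_genes if g.id in expr]
    consistent = set(expr.kept_genes())
    expressed = [g for g in kept if expr.is_expressed(g.id)]
    outs = []
    for antibody in ctx.antibodies:
        for tissue in ctx.tissues(antibody):
            expr_bins: dict[str, list] = {}
            for g in expressed:
                mean = (expr.tissue_mean(g.id, "dividing")
                        + expr.tissue_mean(g.id, "nondividing")) / 2
                if mean <= 0:
                    continue
                expr_bins.setdefault(assign_expression_bin(mean), []).append(g)
            outs.append(_write_binned_profiles(
                ctx, antibody, tissue, expr_bins, f"genes_expr_{tissue}"))
            len_bins: dict[str, list] = {}
            for g in kept:
                if g.id in consistent:
                    len_bins.setdefault(assign_length_bin(g.length), []).append(g)
            outs.append(_write_binned_profiles(
                ctx, antibody, tissue, len_bins, f"genes_len_{tissue}"))
    return outs


def stage_enrichment(ctx: PipelineContext) -> list[str]:
    p = ctx.cfg.params
    expr = ctx.expression
    genes = [g for g in ctx.kept_genes
             if g.id in expr and g.length >= p.last_kb
             and expr.is_expressed(g.id)]
    if len(genes) < 3:
        raise PipelineError("stage enrichment: fewer than 3 usable genes")
    outs = []
    tables: dict[str, dict[str, float]] = {}
    correlations = {}
    for antibody in ctx.antibodies:
        for tissue in ctx.tissues(antibody):
            label = f"{antibody}:{tissue}"
            track = ctx.track(antibody, tissue)
            tables[label] = enrichment_table(track, genes, p.last_kb)
            fpkm = [expr.tissue_mean(g.id, tissue) for g in genes]
            enr = [tables[label][g.id] for g in genes]
            try:
                rho = spearman_correlation(fpkm, enr)
            except Exception:
                rho = float("nan")
            correlations[label] = {"rho": rho, "n": len(genes)}
            scatter = windowed_scatter(fpkm, enr, p.scatter_window)
            out = ctx.outdir / (
                f"scatter_{antibody.replace('.', '')}_{tissue}.tsv")
            write_scatter_tsv(scatter, out, names=("fpkm", "enrichment"))
            outs.append(str(out))
    out = ctx.outdir / "enrichment.tsv"
    write_enrichment_tsv(tables, out)
    outs.append(str(out))
    out = ctx.outdir / "correlations.json"
    with open(out, "w") as fh:
        json.dump(correlations, fh, indent=1, sort_keys=True)
        fh.write("\n")
    outs.append(str(out))
    return outs


def stage_dynamics(ctx: PipelineContext) -> list[str]:
    p = ctx.cfg.params
    expr = ctx.expression
    consistent = set(expr.kept_genes())
    kept = [g for g in ctx.kept_genes if g.id in expr and g.id in consistent]
    by_id = {g.id: g for g in kept}
    up_div, up_non = select_fold_change_sets(expr, p.fold, list(by_id))
    on_div, on_non = select_on_off_sets(expr, p.on_thresh, p.off_thresh,
                                        list(by_id))
    outs = []
    sets = {
        "fold_up_dividing": up_div,
        "fold_up_nondividing": up_non,
        "on_div_off_nondiv": on_div,
        "on_nondiv_off_div": on_non,
    }
    out = ctx.outdir / "gene_sets.tsv"
    with open(out, "w") as fh:
        fh.write("set\tgene_id\n")
        for label, ids in sets.items():
            for gid in sorted(ids):
                fh.write(f"{label}\t{gid}\n")
    outs.append(str(out))
    for antibody in ctx.antibodies:
        for label, ids in sets.items():
            genes = [by_id[i] for i in sorted(ids) if i in by_id]
            for tissue in ctx.tissues(antibody):
                if not genes:
                    continue
                prof = _gene_profile_for_subset(ctx, antibody, tissue, genes)
                out = ctx.outdir / (
                    f"dyn_{label}_{antibody.replace('.', '')}_{tissue}.tsv")
                write_profile_tsv(prof, out)
                outs.append(str(out))
    # rank-space modulation scatter over all kept genes long enough
    genes = [g for g in kept if g.length >= p.last_kb]
    if len(genes) >= p.rank_window:
        expr_diff = {
            g.id: expr.tissue_mean(g.id, "dividing")
            - expr.tissue_mean(g.id, "nondividing")
            for g in genes
        }
        for antibody in ctx.antibodies:
            tissues = ctx.tissues(antibody)
            if len(tissues) < 2:
                continue
            t_div = ctx.track(antibody, "dividing")
            t_non = ctx.track(antibody, "nondividing")
            enr_div = enrichment_table(t_div, genes, p.last_kb)
            enr_non = enrichment_table(t_non, genes, p.last_kb)
            enr_diff = {g.id: enr_div[g.id] - enr_non[g.id] for g in genes}
            series = differential_rank_scatter(expr_diff, enr_diff, p.rank_window)
            out = ctx.outdir / f"rank_scatter_{antibody.replace('.', '')}.tsv"
            write_scatter_tsv(series, out, names=("expr_rank", "enr_rank"))
            outs.append(str(out))
    return outs


def stage_summarize(ctx: PipelineContext) -> list[str]:
    p = ctx.cfg.params
    expr = ctx.expression
    consistent = set(expr.kept_genes())
    kept_ids = [g.id for g in ctx.kept_genes
                if g.id in expr and g.id in consistent]
    up_div, up_non = select_fold_change_sets(expr, p.fold, kept_ids)
    groups = {
        "all_kept": kept_ids,
        "fold_up_dividing": sorted(up_div),
        "fold_up_nondividing": sorted(up_non),
    }
    summaries = summarize_gene_groups(expr, groups)
    out = ctx.outdir / "group_summaries.tsv"
    write_group_summaries_tsv(summaries, out)
    return [str(out)]


_STAGE_FUNCS = {
    "annotate": stage_annotate,
    "tracks": stage_tracks,
    "profile_centromere": stage_profile_centromere,
    "distributions": stage_distributions,
    "profile_genes": stage_profile_genes,
    "enrichment": stage_enrichment,
    "dynamics": stage_dynamics,
    "summarize": stage_summarize,
    "profile_sites": stage_profile_sites,
}


def run_stage(config: RunConfig, name: str) -> list[str]:
    ctx = PipelineContext(config)
    return _STAGE_FUNCS[name](ctx)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in order; write and return the run manifest.

    Any stage failure aborts the run with the stage name and the offending
    input in the error message.
    """
    ctx = PipelineContext(config)
    manifest: dict[str, Any] = {
        "config_sha256": config.sha256(),
        "seed": config.seed,
        "version": __version__,
        "stages": [],
    }
    for name in STAGES:
        try:
            outputs = _STAGE_FUNCS[name](ctx)
        except Exception as exc:
            manifest["stages"].append(
                {"name": name, "status": "failed", "error": str(exc)}
            )
            _write_manifest(ctx, manifest)
            raise PipelineError(f"stage {name} failed: {exc}") from exc
        manifest["stages"].append(
            {"name": name, "status": "completed", "outputs": outputs}
        )
        log.info("stage %s completed (%d outputs)", name, len(outputs))
    _write_manifest(ctx, manifest)
    return manifest


def _write_manifest(ctx: PipelineContext, manifest: dict) -> None:
    with open(ctx.outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
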