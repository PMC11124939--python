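"""End-to-end orchestration and the candidate-gene report.

The pipeline chains: simulation (or user-supplied inputs) -> variant
filtering -> the two-statistic association scan -> marker co-segregation
refinement -> RNA-seq differential expression -> genes in the refined region
intersected with DEGs, ranked. Every random draw derives from the single
configured seed, so a re-run writes byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import BulkSegregantScan, BulkScanResults
from .expression import DifferentialExpression, DiffExpressionResults
from .finemap import FineMapError, refine_interval, score_cosegregation
from .intervals import Region, regions_to_frame
from .simdata import (
    SimulationConfig,
    build_bulks,
    make_gene_annotation,
    marker_table_from_population,
    simulate_expression,
    simulate_f2,
    simulate_pool_reads,
)
from .variant_io import filter_informative, window_density, write_variants

__all__ = [
    "read_gff3",
    "write_gff3",
    "genes_in_region",
    "rank_candidates",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "DEFAULT_KEYWORDS",
]

# annotation classes of the usual anthocyanin-pathway suspects; heuristic
DEFAULT_KEYWORDS = (
    "bHLH",
    "MYB",
    "WD",
    "chalcone",
    "anthocyanin",
    "flavon",
    "transcription factor",
    "vacuolar",
)


def write_gff3(annotation: pd.DataFrame, path) -> None:
    """Write gene models as GFF3 (gene features with ID and Note attributes)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.itertuples(index=False):
            note = str(row.annotation).replace(";", "%3B").replace("=", "%3D")
            fh.write(
                f"{row.chrom}\tbulkscan\tgene\t{row.start}\t{row.end}\t.\t+\t.\t"
                f"ID={row.gene_id};Note={note}\n"
            )


def read_gff3(path) -> pd.DataFrame:
    """Read gene features from GFF3 into the annotation table."""
    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True)
    rows = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        note = feat.attributes.get("Note", [""])[0]
        rows.append((feat.id, feat.seqid, feat.start, feat.end, note))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "annotation"])


def genes_in_region(annotation: pd.DataFrame, region: Region, mode: str = "overlap") -> list[str]:
    """Gene ids overlapping (>= 1 bp, default) or contained in ``region``."""
    if mode not in ("overlap", "containment"):
        raise ValueError(f"unknown mode {mode!r}")
    on = annotation["chrom"] == region.chrom
    if mode == "overlap":
        hit = on & (annotation["start"] <= region.end) & (annotation["end"] >= region.start)
    else:
        hit = on & (annotation["start"] >= region.start) & (annotation["end"] <= region.end)
    sub = annotation.loc[hit].sort_values(["start", "end"], kind="mergesort")
    return sub["gene_id"].tolist()


def rank_candidates(
    region_genes: list[str],
    degs: pd.DataFrame,
    annotation: pd.DataFrame,
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS,
) -> pd.DataFrame:
    """Rank region genes: significant DEGs first (by |log2FC| desc, FDR asc),
    then annotation-keyword matches, then position. Deterministic ties."""
    ann = annotation.set_index("gene_id")
    missing = [g for g in region_genes if g not in ann.index]
    if missing:
        raise ValueError(f"region gene(s) absent from annotation: {missing[:5]}")
    if len(degs) and not degs.index.intersection(ann.index).size:
        raise ValueError(
            "gene ids of the expression results do not match the annotation"
        )
    sub = ann.loc[region_genes, ["chrom", "start", "end", "annotation"]].copy()
    sub["in_expression"] = sub.index.isin(degs.index)
    for col, default in (("direction", "ns"), ("log2fc", np.nan), ("fdr", np.nan)):
        sub[col] = degs[col].reindex(sub.index) if col in degs.columns else default
    sub["direction"] = sub["direction"].fillna("ns")
    sub["significant"] = sub["direction"] != "ns"
    low = sub["annotation"].str.lower()
    sub["keyword_hit"] = False
    for kw in keywords:
        sub["keyword_hit"] |= low.str.contains(kw.lower(), regex=False)

    sig = sub["significant"].to_numpy()
    abs_lfc = np.where(sig, np.abs(sub["log2fc"].to_numpy(dtype=float)), 0.0)
    fdr = np.where(sig, sub["fdr"].to_numpy(dtype=float), 0.0)
    order = np.lexsort(
        (
            sub["start"].to_numpy(),
            sub["chrom"].to_numpy(),
            (~sub["keyword_hit"]).to_numpy(),
            fdr,
            -abs_lfc,
            (~sig),
        )
    )
    out = sub.iloc[order].copy()
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out.reset_index().rename(columns={"index": "gene_id"})


@dataclass
class PipelineConfig:
    """Configuration of an end-to-end (simulated) run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # association scan
    method: str = "both"
    k: float = 5.0
    bandwidth_bp: float = 2_000_000.0
    ci_levels: tuple[float, ...] = (0.95, 0.99)
    call_level: float = 0.99
    reps: int = 10_000
    gap_bp: int = 1_000_000
    min_sites: int = 10
    min_depth: int = 10
    # fine mapping
    run_finemap: bool = True
    n_finemap_markers: int = 100
    finemap_model: str = "additive"
    # expression
    run_expression: bool = True
    n_genes: int = 2000
    n_de: int = 100
    de_log2fc: float = 2.0
    causal_log2fc: float = 3.5
    fdr_max: float = 0.01
    lfc_min: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        cfg = cls(simulation=sim, **raw)
        if isinstance(cfg.simulation.qtl_position, list):
            cfg.simulation.qtl_position = tuple(cfg.simulation.qtl_position)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    """Artifacts of one pipeline run."""

    status: str  # "complete" | "partial"
    config: PipelineConfig
    scan: BulkScanResults
    target_region: Region | None
    refined_region: Region | None
    finemap_results: pd.DataFrame | None
    deg_results: DiffExpressionResults | None
    candidates: pd.DataFrame | None
    outdir: Path | None
    notes: list[str]
    summary_text: str = ""
    provenance: dict = field(default_factory=dict)


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Simulate, scan, refine, test expression and rank candidates.

    Stages that cannot run (no markers / no expression requested, or a marker
    screen with no co-segregating marker) are recorded in ``notes`` and the
    run completes with the best region available; status is "partial" when
    the candidate report could not be produced.
    """
    sim = config.simulation
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    notes: list[str] = []

    # --- simulate and scan ------------------------------------------------
    pop = simulate_f2(sim)
    bulks = build_bulks(pop)
    raw_sites = simulate_pool_reads(pop, bulks, sim)
    sites, filter_report = filter_informative(raw_sites, min_depth=config.min_depth)
    windows = window_density(sites, chrom_lengths={c: sim.chrom_length_bp for c in sim.chromosomes()})
    scan = BulkSegregantScan(sites, n_bulk=sim.n_bulk).fit(
        method=config.method,
        k=config.k,
        bandwidth_bp=config.bandwidth_bp,
        ci_levels=config.ci_levels,
        call_level=config.call_level,
        reps=config.reps,
        gap_bp=config.gap_bp,
        min_sites=config.min_sites,
        seed=np.random.SeedSequence([sim.seed, 17]).generate_state(1)[0] % (2**31),
    )
    if out is not None:
        write_variants(raw_sites, out / "variants.vcf",
                       contig_lengths={c: sim.chrom_length_bp for c in sim.chromosomes()})
        write_variants(raw_sites, out / "variants.tsv", format="tsv")
        windows.to_csv(out / "window_density.tsv", sep="\t", index=False)
        scan.to_dir(out / "scan")

    if not scan.intersection:
        notes.append("association scan called no intersection region")
        result = PipelineResult(
            status="partial", config=config, scan=scan, target_region=None,
            refined_region=None, finemap_results=None, deg_results=None,
            candidates=None, outdir=out, notes=notes,
        )
        _finalize(result, filter_report, pop, bulks)
        return result
    # largest intersected region is carried forward
    target = max(scan.intersection, key=lambda r: r.length_bp)

    # --- fine mapping -----------------------------------------------------
    refined = target
    fm_results = None
    if config.run_finemap:
        individuals = np.concatenate(bulks)
        markers = marker_table_from_population(
            pop, individuals, region=target, n_markers=config.n_finemap_markers
        )
        low_cols = [f"f2_{i}" for i in bulks[0]]
        high_cols = [f"f2_{i}" for i in bulks[1]]
        fm_results = score_cosegregation(markers, low_cols, high_cols, model=config.finemap_model)
        try:
            refined = refine_interval(fm_results, target)
        except FineMapError as err:
            notes.append(f"fine mapping fell back to the scan region: {err}")
        if out is not None:
            markers.to_csv(out / "markers.tsv", sep="\t", index=False)
            fm_results.to_csv(out / "cosegregation.tsv", sep="\t", index=False)
    else:
        notes.append("fine mapping skipped by configuration")

    # --- expression and candidates ---------------------------------------
    deg_res = None
    candidates = None
    status = "partial"
    if config.run_expression:
        annotation = make_gene_annotation(sim, n_genes=config.n_genes)
        # the gene nearest the causal locus is the planted causal candidate
        qchrom, qpos = sim.qtl_position
        on_chrom = annotation[annotation["chrom"] == qchrom]
        mid = (on_chrom["start"] + on_chrom["end"]) / 2.0
        causal_gene = on_chrom.loc[(mid - qpos).abs().idxmin(), "gene_id"]
        annotation.loc[
            annotation["gene_id"] == causal_gene, "annotation"
        ] = "MYB family transcription factor"
        matrix, truth = simulate_expression(
            sim,
            region=target,
            n_de=config.n_de,
            log2fc=config.de_log2fc,
            annotation=annotation,
            causal_gene=causal_gene,
            causal_log2fc=config.causal_log2fc,
        )
        deg_res = DifferentialExpression(matrix).fit(
            fdr_max=config.fdr_max, lfc_min=config.lfc_min
        )
        region_genes = genes_in_region(annotation, refined)
        if region_genes:
            candidates = rank_candidates(region_genes, deg_res.table, annotation)
            status = "complete"
        else:
            notes.append("no annotated gene in the refined region")
        if out is not None:
            write_gff3(annotation, out / "annotation.gff3")
            matrix.to_tsv(out / "counts.tsv", out / "groups.tsv")
            truth.to_csv(out / "expression_truth.tsv", sep="\t")
            deg_res.table.to_csv(out / "deg_results.tsv", sep="\t")
            deg_res.replicate_correlation().to_csv(out / "replicate_correlation.tsv", sep="\t")
            if candidates is not None:
                candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
    else:
        notes.append("expression stage skipped by configuration")

    result = PipelineResult(
        status=status, config=config, scan=scan, target_region=target,
        refined_region=refined, finemap_results=fm_results, deg_results=deg_res,
        candidates=candidates, outdir=out, notes=notes,
    )
    _finalize(result, filter_report, pop, bulks)
    return result


def _finalize(result: PipelineResult, filter_report, pop, bulks) -> None:
    """Provenance JSON and the human-readable summary."""
    out = result.outdir
    scan = result.scan
    provenance = {
        "bulkscan_version": __version__,
        "status": result.status,
        "seed": result.config.simulation.seed,
        "config": result.config.to_dict(),
        "filter_report": filter_report.as_dict(),
        "scan_params": scan.params,
        "ed_thresholds": scan.ed_thresholds,
        "regions": {
            "ed": regions_to_frame(scan.regions_ed).to_dict("records"),
            "snp_index": regions_to_frame(scan.regions_delta).to_dict("records"),
            "intersection": regions_to_frame(scan.intersection).to_dict("records"),
        },
        "refined_region": None
        if result.refined_region is None
        else regions_to_frame([result.refined_region]).to_dict("records")[0],
        "notes": result.notes,
    }
    lines = [
        "# bulkscan pipeline summary",
        "",
        f"status: {result.status}",
        f"F2 plants: {pop.n_f2}; bulks: {len(bulks[0])} green + {len(bulks[1])} purple",
        "",
        "## Association scan",
        "```",
        scan.summary(),
        "```",
    ]
    if result.refined_region is not None and result.refined_region.method == "finemap":
        r = result.refined_region
        lines += [
            "",
            "## Fine mapping",
            f"refined region {r.chrom}:{r.start}-{r.end} ({r.length_mb:.2f} Mb) "
            f"from {r.n_sites} co-segregating markers",
        ]
    if result.deg_results is not None:
        lines += ["", "## Differential expression", "```", result.deg_results.summary(), "```"]
    if result.candidates is not None:
        top = result.candidates.head(8)
        lines += [
            "",
            "## Top candidate genes",
            top.to_string(index=False),
        ]
    if result.notes:
        lines += ["", "## Notes"] + [f"- {n}" for n in result.notes]
    summary = "\n".join(lines) + "\n"
    result.summary_text = summary
    result.provenance = provenance
    if out is not None:
        _write_json(provenance, out / "provenance.json")
        (out / "summary.md").write_text(summary)
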