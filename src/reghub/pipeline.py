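"""End-to-end orchestration: consensus -> hubs -> design -> select -> assign.

:func:`run_bundle` drives the whole method on in-memory inputs and is what
the tests and the batch entry points call; :func:`run_all` wraps it with file
I/O, per-stage outputs and a manifest sufficient to re-run bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from . import io as rio
from .assign import (
    ASSIGNMENT_HEADER,
    assign_causal_elements,
    assignments_to_rows,
    flag_de_targets,
)
from .consensus import build_consensus_peaks, filter_loops
from .expression import CountMatrix, build_design, expressed_filter, log_cpm
from .hubs import assign_members, build_anchor_graph, find_hubs, inactive_blocks
from .selection import SelectionParams, stability_run

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and paths for a full run; defaults are the method's own.

    Thresholds: 60% consensus support, >= 2 supporting reads per loop,
    expressed = CPM >= 1 in >= 5 samples, 50 selection runs with 95%
    retention, TSS +/- 2 kb promoters.
    """

    ctcf_peak_dir: str = ""
    atac_peak_dir: str = ""
    loops_path: str = ""
    ld_blocks_path: str = ""
    genes_path: str = ""
    rna_counts_path: str = ""
    atac_counts_path: str = ""
    de_genes_path: Optional[str] = None
    out_dir: str = "reghub_out"

    consensus_threshold: float = 0.6
    min_loop_reads: int = 2
    min_cpm: float = 1.0
    min_expressed_samples: int = 5
    promoter_pad: int = 2000
    anchor_pad: int = 0
    n_runs: int = 50
    retention_fraction: float = 0.95
    base_seed: int = 17

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    ctcf_consensus: object
    atac_consensus: object
    filtered_loops: list
    hubs: list
    inactive_ld_blocks: list
    selection_results: list
    assignments: list
    stage_counts: dict = field(default_factory=dict)


def run_bundle(
    ctcf_peaks_by_sample: dict,
    atac_peaks_by_sample: dict,
    loops: list,
    ld_blocks: list,
    genes: list,
    rna_counts: CountMatrix,
    atac_counts: CountMatrix,
    cfg: PipelineConfig = PipelineConfig(),
    de_gene_ids: Optional[Sequence[str]] = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs and return all intermediates."""
    ctcf_cons = build_consensus_peaks(
        ctcf_peaks_by_sample, cfg.consensus_threshold, group_id="ctcf"
    )
    atac_cons = build_consensus_peaks(
        atac_peaks_by_sample, cfg.consensus_threshold, group_id="atac"
    )
    floops = filter_loops(loops, ctcf_cons, min_reads=cfg.min_loop_reads)
    graph = build_anchor_graph(floops)
    hubs = [
        assign_members(
            h, genes, atac_cons,
            promoter_pad=cfg.promoter_pad, anchor_pad=cfg.anchor_pad,
        )
        for h in find_hubs(graph, ld_blocks)
    ]
    inactive = inactive_blocks(graph, ld_blocks)

    expressed = set(
        expressed_filter(rna_counts, cfg.min_cpm, cfg.min_expressed_samples)
    )
    rna_lcpm = log_cpm(rna_counts)
    atac_lcpm = log_cpm(atac_counts)

    results = []
    gene_counter = 0
    for hub in hubs:
        for g in hub.member_genes:
            if g.gene_id not in expressed:
                logger.info("skipping non-expressed gene %s", g.gene_id)
                continue
            try:
                design = build_design(
                    hub, rna_lcpm, atac_lcpm, g.gene_id, expressed_gene_ids=expressed
                )
            except ValueError as exc:
                logger.warning("no design for %s: %s", g.gene_id, exc)
                continue
            params = SelectionParams(
                n_runs=cfg.n_runs,
                retention_fraction=cfg.retention_fraction,
                base_seed=cfg.base_seed + 1000 * gene_counter,
            )
            results.append(stability_run(design, params))
            gene_counter += 1

    assignments = flag_de_targets(
        assign_causal_elements(
            results, ld_blocks, genes=genes, peak_catalog=atac_cons.intervals
        ),
        de_gene_ids,
    )
    counts = {
        "n_ctcf_consensus": len(ctcf_cons),
        "n_atac_consensus": len(atac_cons),
        "n_loops_in": len(loops),
        "n_loops_kept": len(floops),
        "n_hubs": len(hubs),
        "n_ld_blocks": len(ld_blocks),
        "n_inactive_ld_blocks": len(inactive),
        "n_expressed_genes": len(expressed),
        "n_modeled_genes": len(results),
        "n_assignments": len(assignments),
    }
    return PipelineResult(
        ctcf_consensus=ctcf_cons,
        atac_consensus=atac_cons,
        filtered_loops=floops,
        hubs=hubs,
        inactive_ld_blocks=inactive,
        selection_results=results,
        assignments=assignments,
        stage_counts=counts,
    )


def _read_peak_dir(peak_dir: str) -> dict:
    paths = sorted(Path(peak_dir).glob("*.bed"))
    if not paths:
        raise FileNotFoundError(f"no .bed files in {peak_dir}")
    return {p.stem: rio.read_bed_peaks(p, sample_id=p.stem) for p in paths}


def run_all(cfg: PipelineConfig) -> PipelineResult:
    """File-based full run; writes per-stage outputs and a manifest."""
    for label, path in (
        ("loops", cfg.loops_path),
        ("LD blocks", cfg.ld_blocks_path),
        ("genes", cfg.genes_path),
        ("RNA counts", cfg.rna_counts_path),
        ("ATAC counts", cfg.atac_counts_path),
    ):
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"{label} input missing: {path!r}")

    ctcf = _read_peak_dir(cfg.ctcf_peak_dir)
    atac = _read_peak_dir(cfg.atac_peak_dir)
    loops = rio.read_bedpe_loops(cfg.loops_path)
    ld = rio.read_bed_ld_blocks(cfg.ld_blocks_path)
    genes = rio.read_gene_table(cfg.genes_path)
    rna = rio.read_count_matrix(cfg.rna_counts_path)
    atac_counts = rio.read_count_matrix(cfg.atac_counts_path)
    de_ids = None
    if cfg.de_genes_path:
        de_ids = [l.strip() for l in open(cfg.de_genes_path) if l.strip()]

    result = run_bundle(ctcf, atac, loops, ld, genes, rna, atac_counts, cfg, de_ids)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_outputs(result, cfg, out)
    return result


def write_outputs(result: PipelineResult, cfg: PipelineConfig, out: Path) -> None:
    for cons, name in (
        (result.ctcf_consensus, "ctcf_consensus.bed"),
        (result.atac_consensus, "atac_consensus.bed"),
    ):
        with open(out / name, "w") as fh:
            for iv, support in cons.regions:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{support}\n")

    hubs_json = [
        {
            "hub_id": h.hub_id,
            "seed_blocks": [
                {"lead_snp": b.lead_snp, "interval": str(b.interval)}
                for b in h.seed_blocks
            ],
            "anchor_regions": [str(iv) for iv in h.anchor_regions],
            "member_genes": [g.gene_id for g in h.member_genes],
            "member_peaks": [[pid, str(iv)] for pid, iv in h.member_peaks],
        }
        for h in result.hubs
    ]
    (out / "hubs.json").write_text(json.dumps(hubs_json, indent=2, sort_keys=True))

    sel_rows = []
    for res in result.selection_results:
        for fid, frac in sorted(res.retention_fraction_per_feature.items()):
            sel_rows.append(
                (res.target_gene_id, fid, f"{frac:.3f}",
                 int(fid in res.retained_features))
            )
    rio.write_table(
        sel_rows, out / "selection.tsv",
        header=["target_gene", "feature_id", "retention_fraction", "retained"],
    )
    rio.write_table(
        assignments_to_rows(result.assignments), out / "assignments.tsv",
        header=ASSIGNMENT_HEADER,
    )
    manifest = {
        "package_version": __version__,
        "config": asdict(cfg),
        "stage_counts": result.stage_counts,
        "inactive_ld_blocks": sorted(
            b.lead_snp for b in result.inactive_ld_blocks
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
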