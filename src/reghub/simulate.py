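"""Synthetic multi-omic bundles with planted regulatory structure.

The generator emulates the statistical shape of the real inputs at desk
scale: groups of replicate samples whose peak calls partially drop out, CTCF
loops whose anchors chain each hub into one connected component, risk LD
blocks covering a subset of anchors, and RNA/ATAC count matrices in which a
planted subset of peak accessibilities linearly drives gene expression on the
log2 scale, observed through negative-binomial counting noise.

Geometry: hub ``h`` lives on chromosome ``chr<h+1>``.  Its CTCF anchors are
2-kb regions spaced 100 kb apart, chained by loops (consecutive pairs plus a
closing loop, so one lost edge cannot split the hub).  The active LD block
covers anchor 0 with a 1-kb margin; the planted ATAC peaks sit inside anchor
0 (hence inside the block), decoy ATAC peaks inside the remaining anchors.
Genes have their TSS at anchors 1..A-1 and 10-kb bodies pointing away from
the block.  Decoy loops connect fresh anchor pairs far downstream; inactive
LD blocks sit in empty territory.

Counts: per-sample latent accessibility ``a_ps ~ Normal(mu_p, 1)`` on the
log2 scale; latent log2 expression of gene g is
``baseline_g + sum_planted beta * (a_ps - mu_p) + Normal(0, noise_sd)``;
observed counts are negative-binomial with mean ``2**latent`` and dispersion
``nb_dispersion``; loop read support is ``1 + Poisson(loop_read_mean - 1)``.
Everything is reproducible from the single config seed, which drives named
sub-streams (peaks, loops, counts) so stages can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as rio
from .expression import CountMatrix
from .intervals import Gene, GenomicInterval, LDBlock, Loop, Peak

ANCHOR_WIDTH = 2_000
ANCHOR_SPACING = 100_000
HUB_BASE = 1_000_000
DECOY_BASE = 20_000_000
INACTIVE_BASE = 50_000_000
GENE_BODY = 10_000
ATAC_WIDTH = 400


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic bundle.

    ``planted_links`` are (peak_index, gene_index, beta) triples applied
    within every hub; peak indices refer to the hub's ATAC peaks in coordinate
    order, gene indices to the hub's genes.  ``beta`` is in latent log2 units
    per accessibility SD (accessibility SD is 1 by construction).
    """

    seed: int = 17
    n_samples: int = 16
    n_hubs: int = 2
    anchors_per_hub: int = 4
    genes_per_hub: int = 4
    peaks_per_hub: int = 6
    planted_links: tuple = ((0, 0, 2.0), (1, 1, 2.0))
    peak_dropout_rate: float = 0.1
    loop_read_mean: float = 5.0
    nb_dispersion: float = 0.05
    baseline_log_expression_mean: float = 8.0
    baseline_log_expression_sd: float = 1.0
    noise_sd: float = 0.5
    n_decoy_loops: int = 3
    n_decoy_genes: int = 4
    ld_block_fraction_active: float = 33 / 46
    atac_latent_mean: float = 6.0

    def __post_init__(self) -> None:
        if not (0 <= self.peak_dropout_rate < 1):
            raise ValueError("peak_dropout_rate must be in [0, 1)")
        if self.loop_read_mean < 1:
            raise ValueError("loop_read_mean must be >= 1")
        if self.nb_dispersion <= 0 or self.noise_sd < 0:
            raise ValueError("nb_dispersion must be > 0 and noise_sd >= 0")
        if not (0 < self.ld_block_fraction_active <= 1):
            raise ValueError("ld_block_fraction_active must be in (0, 1]")
        n_planted_peaks = max(3, self.peaks_per_hub // 2)
        for pk, gn, beta in self.planted_links:
            if not (0 <= pk < self.peaks_per_hub and 0 <= gn < self.genes_per_hub):
                raise ValueError(f"planted link ({pk},{gn},{beta}) outside hub bounds")
            if pk >= n_planted_peaks:
                raise ValueError(
                    f"planted peak index {pk} falls outside the LD block "
                    f"(first {n_planted_peaks} peaks sit in the block)"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [f"s{i:02d}" for i in range(self.n_samples)]

    @property
    def n_ld_blocks(self) -> int:
        return int(np.ceil(self.n_hubs / self.ld_block_fraction_active))


@dataclass
class Truth:
    """Ground truth of a simulated bundle."""

    planted_pairs: set  # {(peak_coord_id, gene_id)}
    active_lead_snps: set
    inactive_lead_snps: set
    bundle_seed: int


@dataclass
class SimBundle:
    """In-memory synthetic inputs for a full pipeline run."""

    config: SimConfig
    ctcf_peaks_by_sample: dict
    atac_peaks_by_sample: dict
    loops: list
    ld_blocks: list
    genes: list
    rna_counts: CountMatrix
    atac_counts: CountMatrix
    truth: Truth


def _coord_id(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def _hub_geometry(cfg: SimConfig, h: int):
    """Anchors, ATAC peaks, genes and the active LD block of hub ``h``."""
    chrom = f"chr{h + 1}"
    anchors = [
        GenomicInterval(chrom, HUB_BASE + i * ANCHOR_SPACING,
                        HUB_BASE + i * ANCHOR_SPACING + ANCHOR_WIDTH)
        for i in range(cfg.anchors_per_hub)
    ]
    # ATAC peaks: the first few inside anchor 0 (inside the LD block), the
    # rest distributed across the remaining anchors
    n_in_block = max(3, cfg.peaks_per_hub // 2)
    atac = []
    for k in range(min(n_in_block, cfg.peaks_per_hub)):
        off = 100 + k * (ATAC_WIDTH + 150)
        atac.append(
            GenomicInterval(chrom, anchors[0].start + off,
                            anchors[0].start + off + ATAC_WIDTH)
        )
    for k in range(cfg.peaks_per_hub - len(atac)):
        host = anchors[1 + k % (cfg.anchors_per_hub - 1)]
        off = 300 + (k // (cfg.anchors_per_hub - 1)) * (ATAC_WIDTH + 200)
        atac.append(GenomicInterval(chrom, host.start + off, host.start + off + ATAC_WIDTH))
    atac.sort(key=lambda iv: iv.start)

    genes = []
    for g in range(cfg.genes_per_hub):
        host = anchors[1 + g % (cfg.anchors_per_hub - 1)]
        tss = host.start + 500 + 200 * (g // (cfg.anchors_per_hub - 1))
        genes.append(Gene(f"GENE_h{h}_{g}", GenomicInterval(chrom, tss, tss + GENE_BODY), "+"))

    block = LDBlock(
        GenomicInterval(chrom, anchors[0].start - 1_000, anchors[0].end + 1_000),
        lead_snp=f"rs{1000 + h}",
    )
    return chrom, anchors, atac, genes, block


def simulate(cfg: SimConfig, out_dir: Optional[Path] = None) -> SimBundle:
    """Generate a full synthetic bundle; optionally write it as a file set.

    When ``out_dir`` is given, writes per-sample CTCF/ATAC peak BEDs, a loop
    BEDPE, LD-block BED, gene table, RNA and ATAC count TSVs, and a truth
    table TSV.
    """
    rng_root = np.random.default_rng(cfg.seed)
    rng_peaks, rng_loops, rng_counts = (
        np.random.default_rng(s) for s in rng_root.integers(0, 2**31 - 1, size=3)
    )

    all_anchors: list[GenomicInterval] = []
    all_atac: list[GenomicInterval] = []
    genes: list[Gene] = []
    ld_blocks: list[LDBlock] = []
    loops: list[Loop] = []
    planted_pairs: set[tuple[str, str]] = set()

    def support() -> int:
        return 1 + int(rng_loops.poisson(cfg.loop_read_mean - 1))

    for h in range(cfg.n_hubs):
        chrom, anchors, atac, hub_genes, block = _hub_geometry(cfg, h)
        all_anchors.extend(anchors)
        all_atac.extend(atac)
        genes.extend(hub_genes)
        ld_blocks.append(block)
        # chain + closing loop keeps the hub connected if one edge drops
        pairs = [(i, i + 1) for i in range(len(anchors) - 1)]
        if len(anchors) > 2:
            pairs.append((0, len(anchors) - 1))
        for i, j in pairs:
            loops.append(Loop(anchors[i], anchors[j], read_support=support()))
        for pk, gn, beta in cfg.planted_links:
            planted_pairs.add((_coord_id(atac[pk]), hub_genes[gn].gene_id))

    # decoy loops on fresh anchors far from any hub or LD block
    for d in range(cfg.n_decoy_loops):
        chrom = f"chr{1 + d % cfg.n_hubs}"
        base = DECOY_BASE + d * 5 * ANCHOR_SPACING
        a1 = GenomicInterval(chrom, base, base + ANCHOR_WIDTH)
        a2 = GenomicInterval(chrom, base + ANCHOR_SPACING, base + ANCHOR_SPACING + ANCHOR_WIDTH)
        all_anchors.extend([a1, a2])
        loops.append(Loop(a1, a2, read_support=support()))

    # decoy genes in empty territory (never hub members)
    for d in range(cfg.n_decoy_genes):
        chrom = f"chr{1 + d % cfg.n_hubs}"
        start = INACTIVE_BASE - 5_000_000 + d * 100_000
        genes.append(Gene(f"GENE_decoy_{d}", GenomicInterval(chrom, start, start + GENE_BODY), "+"))

    # inactive LD blocks: no anchors anywhere near
    n_inactive = cfg.n_ld_blocks - cfg.n_hubs
    inactive = []
    for d in range(n_inactive):
        chrom = f"chr{1 + d % cfg.n_hubs}"
        start = INACTIVE_BASE + d * 1_000_000
        blk = LDBlock(GenomicInterval(chrom, start, start + 50_000), lead_snp=f"rs{2000 + d}")
        ld_blocks.append(blk)
        inactive.append(blk)

    ctcf_by_sample = sample_peak_calls(
        all_anchors, cfg.sample_ids, cfg.peak_dropout_rate, rng_peaks
    )
    atac_by_sample = sample_peak_calls(
        all_atac, cfg.sample_ids, cfg.peak_dropout_rate, rng_peaks
    )

    rna_counts, atac_counts = _simulate_counts(cfg, all_atac, genes, rng_counts)

    truth = Truth(
        planted_pairs=planted_pairs,
        active_lead_snps={b.lead_snp for b in ld_blocks[: cfg.n_hubs]},
        inactive_lead_snps={b.lead_snp for b in inactive},
        bundle_seed=cfg.seed,
    )
    bundle = SimBundle(
        config=cfg,
        ctcf_peaks_by_sample=ctcf_by_sample,
        atac_peaks_by_sample=atac_by_sample,
        loops=loops,
        ld_blocks=ld_blocks,
        genes=genes,
        rna_counts=rna_counts,
        atac_counts=atac_counts,
        truth=truth,
    )
    if out_dir is not None:
        write_bundle(bundle, Path(out_dir))
    return bundle


def sample_peak_calls(
    true_peaks: Sequence[GenomicInterval],
    sample_ids: Sequence[str],
    dropout_rate: float,
    rng: np.random.Generator,
) -> dict[str, list[Peak]]:
    """Per-sample peak calls: each true peak is dropped independently per sample."""
    out: dict[str, list[Peak]] = {}
    for sid in sample_ids:
        keep = rng.random(len(true_peaks)) >= dropout_rate
        out[sid] = [Peak(iv, sample_id=sid) for iv, k in zip(true_peaks, keep) if k]
    return out


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson: Var = mean + dispersion * mean^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _simulate_counts(cfg: SimConfig, atac_peaks, genes, rng):
    n = cfg.n_samples
    n_peaks = len(atac_peaks)
    mu_p = rng.normal(cfg.atac_latent_mean, 1.0, size=n_peaks)
    a_centered = rng.normal(0.0, 1.0, size=(n_peaks, n))  # a_ps - mu_p
    atac_latent = mu_p[:, None] + a_centered

    peak_index = {_coord_id(iv): k for k, iv in enumerate(atac_peaks)}
    effects = {}  # gene_id -> list of (peak row, beta)
    for h in range(cfg.n_hubs):
        _, _, atac_h, genes_h, _ = _hub_geometry(cfg, h)
        for pk, gn, beta in cfg.planted_links:
            effects.setdefault(genes_h[gn].gene_id, []).append(
                (peak_index[_coord_id(atac_h[pk])], beta)
            )

    baselines = rng.normal(
        cfg.baseline_log_expression_mean, cfg.baseline_log_expression_sd, size=len(genes)
    )
    rna_latent = np.empty((len(genes), n))
    for gi, g in enumerate(genes):
        lat = baselines[gi] + rng.normal(0.0, cfg.noise_sd, size=n)
        for row, beta in effects.get(g.gene_id, []):
            lat = lat + beta * a_centered[row]
        rna_latent[gi] = lat

    atac_counts = _nb_draw(rng, 2.0**atac_latent, cfg.nb_dispersion)
    rna_counts = _nb_draw(rng, 2.0**rna_latent, cfg.nb_dispersion)

    return (
        CountMatrix(
            feature_ids=[g.gene_id for g in genes],
            sample_ids=cfg.sample_ids,
            counts=rna_counts,
        ),
        CountMatrix(
            feature_ids=[_coord_id(iv) for iv in atac_peaks],
            sample_ids=cfg.sample_ids,
            counts=atac_counts,
        ),
    )


def write_bundle(bundle: SimBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for kind, by_sample in (
        ("ctcf", bundle.ctcf_peaks_by_sample),
        ("atac", bundle.atac_peaks_by_sample),
    ):
        d = out_dir / f"{kind}_peaks"
        d.mkdir(exist_ok=True)
        for sid, peaks in by_sample.items():
            rio.write_bed_peaks(peaks, d / f"{sid}.bed")
    rio.write_bedpe_loops(bundle.loops, out_dir / "loops.bedpe")
    rio.write_bed_ld_blocks(bundle.ld_blocks, out_dir / "ld_blocks.bed")
    rio.write_gene_table(bundle.genes, out_dir / "genes.tsv")
    rio.write_count_matrix(bundle.rna_counts, out_dir / "rna_counts.tsv")
    rio.write_count_matrix(bundle.atac_counts, out_dir / "atac_counts.tsv")
    rows = sorted(bundle.truth.planted_pairs)
    rio.write_table(rows, out_dir / "truth_pairs.tsv", header=["element", "target_gene"])
    rio.write_table(
        [(s, "active") for s in sorted(bundle.truth.active_lead_snps)]
        + [(s, "inactive") for s in sorted(bundle.truth.inactive_lead_snps)],
        out_dir / "truth_ld_blocks.tsv",
        header=["lead_snp", "status"],
    )


def truth_compare(assignments, truth: Truth) -> dict:
    """Sensitivity and false-discovery fraction of emitted (element, target) pairs.

    A planted pair is recovered when some assignment's element interval
    overlaps the planted peak and targets the planted gene.  Sensitivity is
    over planted pairs in active LD blocks (all planted pairs, by
    construction); the false-discovery fraction is the share of emitted pairs
    matching no planted pair.
    """
    from .expression import parse_coord_id
    from .intervals import overlaps as iv_overlaps

    planted = []
    for coord, gene_id in truth.planted_pairs:
        planted.append((parse_coord_id(coord), gene_id))

    emitted = {(a.element_interval, a.target_gene_id) for a in assignments}
    recovered = set()
    n_false = 0
    for iv, gid in emitted:
        hit = False
        for k, (piv, pgid) in enumerate(planted):
            if gid == pgid and iv_overlaps(iv, piv):
                recovered.add(k)
                hit = True
        if not hit:
            n_false += 1
    sensitivity = len(recovered) / len(planted) if planted else float("nan")
    fdf = n_false / len(emitted) if emitted else 0.0
    return {"sensitivity": sensitivity, "false_discovery_fraction": fdf,
            "n_emitted": len(emitted), "n_planted": len(planted)}
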