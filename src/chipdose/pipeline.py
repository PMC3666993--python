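"""End-to-end orchestration: simulate or load inputs, then run every stage.

Stage order: read processing -> peak calling (with control subtraction) ->
concordance -> E-box analysis -> motif analysis.  Each stage writes its
tables under the output directory; reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import concordance as conc
from . import ebox_analysis as ebox
from . import motif_analysis as motifs
from .genome_io import Genome, GenomicInterval, RunConfig, write_bed, write_bedgraph, write_table
from .peak_calling import NBGCModel, RankedPeakSet, call_peaks, fdr_curve, fit_background, subtract_control
from .read_processing import (
    MappedRead,
    build_coverage,
    deduplicate,
    exclude_chromosomes,
)
from .synthetic_data import GroundTruth, SyntheticConfig, simulate_genome, simulate_reads

logger = logging.getLogger(__name__)


@dataclass
class SampleResult:
    name: str
    coverage: object
    model: NBGCModel
    peaks: RankedPeakSet
    reads: list


@dataclass
class PipelineResult:
    genome: Genome
    truth: GroundTruth | None
    samples: dict[str, SampleResult]
    control_peaks: RankedPeakSet
    overlap: conc.OverlapGrid
    correlation: float
    ebox_bins: dict[str, pd.DataFrame]
    motif_tables: dict[str, pd.DataFrame]


def process_sample(
    reads: list[MappedRead],
    genome: Genome,
    config: RunConfig,
    p_threshold: float,
    sample: str,
) -> SampleResult:
    reads = exclude_chromosomes(deduplicate(reads), config.exclude_chroms)
    coverage = build_coverage(reads, genome, config.extension_length)
    model = fit_background(
        coverage, genome, config.gc_window, config.gc_bin_width
    )
    peaks = call_peaks(
        coverage, model, p_threshold, config.merge_distance, sample=sample
    )
    return SampleResult(sample, coverage, model, peaks, reads)


def run_pipeline(
    config: RunConfig,
    outdir: str | Path,
    syn_config: SyntheticConfig | None = None,
    n_motifs: int = 3,
) -> PipelineResult:
    """Run the full synthetic-mode analysis and write per-stage outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if syn_config is None:
        syn_config = SyntheticConfig(seed=config.seed)
    logger.info("simulating genome and reads (seed=%d)", syn_config.seed)
    genome, truth = simulate_genome(syn_config)
    reads = {
        s: simulate_reads(genome, truth, syn_config, s)
        for s in ("endogenous", "overexpressed", "control")
    }

    samples: dict[str, SampleResult] = {}
    for name in ("endogenous", "overexpressed"):
        samples[name] = process_sample(
            reads[name], genome, config, config.peak_p_threshold, name
        )
    ctrl = process_sample(
        reads["control"], genome, config, config.control_p_threshold, "control"
    )
    for name, s in samples.items():
        s.peaks = subtract_control(s.peaks, ctrl.peaks)
        write_bed(s.peaks.peaks, outdir / f"peaks_{name}.bed")
        write_bedgraph(s.coverage.depth, outdir / f"coverage_{name}.bedgraph")
        write_table(
            fdr_curve(s.coverage, s.model, [1e-3, 1e-5, 1e-8]),
            outdir / f"fdr_{name}.tsv",
        )
    write_bed(ctrl.peaks.peaks, outdir / "peaks_control.bed")

    # concordance
    nmin = min(len(samples["endogenous"].peaks), len(samples["overexpressed"].peaks))
    bw = min(config.rank_bin_width, max(nmin // 4, 1))
    grid = conc.overlap_grid(
        samples["endogenous"].peaks, samples["overexpressed"].peaks, bin_width=bw
    )
    grid.fraction.to_csv(outdir / "overlap_grid.tsv", sep="\t")
    heights = conc.matched_heights(
        samples["endogenous"].peaks,
        samples["overexpressed"].peaks,
        samples["endogenous"].coverage,
        samples["overexpressed"].coverage,
    )
    correlation = conc.asinh_pearson(heights["h1"], heights["h2"])

    # E-box analysis
    sites = ebox.scan_eboxes(
        genome, exclude=ctrl.peaks.peaks, exclude_chroms=config.exclude_chroms
    )
    ebox_bins: dict[str, pd.DataFrame] = {}
    for name, s in samples.items():
        ranked = ebox.rank_eboxes(sites, s.coverage, s.model)
        table = ebox.variant_distribution_by_bin(ranked)
        table.to_csv(outdir / f"ebox_bins_{name}.tsv", sep="\t", index=False)
        ebox_bins[name] = table

    # motif analysis on top peaks of each sample
    motif_tables: dict[str, pd.DataFrame] = {}
    for name, s in samples.items():
        fg = foreground_windows(s.peaks, genome, top_n=min(500, len(s.peaks)))
        bg = motifs.sample_background(genome, fg, seed=config.seed)
        found = motifs.discover_motifs(fg, bg, k_range=(6, 6), n_motifs=n_motifs)
        table = motifs.motif_table(found)
        table.to_csv(outdir / f"motifs_{name}.tsv", sep="\t", index=False)
        motifs.write_meme(
            {f"motif_{i + 1}": r.pwm for i, r in enumerate(found)},
            outdir / f"motifs_{name}.meme",
        )
        motif_tables[name] = table

    return PipelineResult(
        genome=genome,
        truth=truth,
        samples=samples,
        control_peaks=ctrl.peaks,
        overlap=grid,
        correlation=correlation,
        ebox_bins=ebox_bins,
        motif_tables=motif_tables,
    )


def foreground_windows(
    peaks: RankedPeakSet, genome: Genome, top_n: int, half_width: int = 50
) -> motifs.SequenceSet:
    """Summit-centered windows (width 2*half_width + 1) of the top peaks."""
    windows = []
    seqs = []
    for p in peaks.top(top_n):
        chrom_len = len(genome.sequences[p.interval.chrom])
        lo = p.summit - half_width
        hi = p.summit + half_width + 1
        if lo < 0 or hi > chrom_len:
            continue
        windows.append(GenomicInterval(p.interval.chrom, lo, hi))
        seqs.append(genome.sequences[p.interval.chrom][lo:hi])
    return motifs.SequenceSet("foreground", windows, seqs)
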