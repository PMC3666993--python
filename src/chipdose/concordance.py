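"""Comparing two ranked peak sets.

The cross-sample statistic is deliberately non-parametric: for rank
cutoffs x and y, the fraction of the top-x peaks of one sample overlapping
(>= 1 base) the top-y peaks of the other, normalized by the smaller set.
Matched-locus peak heights are compared by Pearson correlation after an
asinh transform, and the height-ratio distribution is computed after
sub-sampling both read sets to a common depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peak_calling import Peak, RankedPeakSet
from .read_processing import MappedRead, build_coverage, subsample_reads


@dataclass
class OverlapGrid:
    """Overlap fractions over a grid of rank-cutoff pairs."""

    cutoffs_x: np.ndarray
    cutoffs_y: np.ndarray
    fraction: pd.DataFrame  # index = x cutoffs, columns = y cutoffs

    def at(self, x: int, y: int) -> float:
        return float(self.fraction.loc[x, y])


def _sorted_intervals(peaks: list[Peak]):
    """Per-chromosome coordinate-sorted (starts, ends, ranks) arrays."""
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(
            (p.interval.start, p.interval.end, p.rank)
        )
    out = {}
    for chrom, triples in by_chrom.items():
        triples.sort()
        arr = np.asarray(triples, dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
    return out


def min_overlapping_rank(queries: list[Peak], subjects: list[Peak]) -> np.ndarray:
    """For each query peak, the minimal rank among overlapping subject peaks
    (0 when none overlaps).  Subject peaks within a set are disjoint."""
    idx = _sorted_intervals(subjects)
    out = np.zeros(len(queries), dtype=np.int64)
    for i, q in enumerate(queries):
        got = idx.get(q.interval.chrom)
        if got is None:
            continue
        starts, ends, ranks = got
        lo = int(np.searchsorted(ends, q.interval.start, side="right"))
        hi = int(np.searchsorted(starts, q.interval.end, side="left"))
        if hi > lo:
            out[i] = int(ranks[lo:hi].min())
    return out


def overlap_fraction(top_x: list[Peak], top_y: list[Peak]) -> float:
    """Fraction of the smaller peak list overlapping the other.

    Each peak counts once regardless of how many partners it overlaps; the
    denominator is the size of the smaller list, so the fraction is <= 1.
    """
    if not top_x or not top_y:
        raise ValueError("overlap_fraction requires two non-empty peak lists")
    small, large = (top_x, top_y) if len(top_x) <= len(top_y) else (top_y, top_x)
    hits = min_overlapping_rank(small, large)
    return float((hits > 0).sum() / len(small))


def overlap_grid(
    set1: RankedPeakSet,
    set2: RankedPeakSet,
    bin_width: int = 5000,
    max_rank: int | None = None,
) -> OverlapGrid:
    """Overlap fraction at every rank-cutoff pair (multiples of bin_width).

    A grid cell (x, y) holds the fraction of the top-x peaks of set1
    overlapping the top-y peaks of set2, divided by min(x, y).  When
    ``max_rank`` exceeds the available peaks, the grid is truncated.
    """
    n1, n2 = len(set1), len(set2)
    if min(n1, n2) < bin_width:
        raise ValueError("both peak sets must contain at least bin_width peaks")
    top = max_rank if max_rank is not None else max(n1, n2)
    cutoffs1 = np.arange(bin_width, min(top, n1) + 1, bin_width)
    cutoffs2 = np.arange(bin_width, min(top, n2) + 1, bin_width)
    # rank in set2 of the best partner of each set1 peak, and vice versa
    best2 = min_overlapping_rank(set1.peaks, set2.peaks)
    best1 = min_overlapping_rank(set2.peaks, set1.peaks)
    frac = pd.DataFrame(index=cutoffs1, columns=cutoffs2, dtype=float)
    for x in cutoffs1:
        for y in cutoffs2:
            if x <= y:
                hits = int(((best2[:x] > 0) & (best2[:x] <= y)).sum())
            else:
                hits = int(((best1[:y] > 0) & (best1[:y] <= x)).sum())
            frac.loc[x, y] = hits / min(x, y)
    return OverlapGrid(cutoffs1, cutoffs2, frac)


def asinh_pearson(heights1, heights2) -> float:
    """Pearson correlation of asinh-transformed matched peak heights."""
    x = np.arcsinh(np.asarray(heights1, dtype=float))
    y = np.arcsinh(np.asarray(heights2, dtype=float))
    if len(x) != len(y):
        raise ValueError("height vectors must have equal length")
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def matched_heights(
    set1: RankedPeakSet,
    set2: RankedPeakSet,
    coverage1,
    coverage2,
) -> pd.DataFrame:
    """Heights of both samples at the union of peak summits.

    A locus missing from one sample's peak list still gets that sample's
    coverage depth at the other sample's summit, so both vectors are defined
    everywhere.
    """
    only2 = min_overlapping_rank(set2.peaks, set1.peaks) == 0
    loci = list(set1.peaks) + [p for p, keep in zip(set2.peaks, only2) if keep]
    rows = [
        {
            "chrom": p.interval.chrom,
            "summit": p.summit,
            "h1": coverage1.depth_at(p.interval.chrom, p.summit),
            "h2": coverage2.depth_at(p.interval.chrom, p.summit),
        }
        for p in loci
    ]
    return pd.DataFrame(rows)


def height_ratio_distribution(
    set1: RankedPeakSet,
    set2: RankedPeakSet,
    reads1: list[MappedRead],
    reads2: list[MappedRead],
    genome,
    extension_length: int,
    seed: int = 0,
    quantiles=(0.1, 0.25, 0.5, 0.75, 0.9),
) -> pd.DataFrame:
    """Quantiles of log2 height ratios at shared loci after equalizing reads.

    Both read sets are sub-sampled to the common minimum, coverage is
    rebuilt, and log2((h2 + 1) / (h1 + 1)) is summarized at every shared
    peak locus.
    """
    n = min(len(reads1), len(reads2))
    sub1 = subsample_reads(reads1, n, seed)
    sub2 = subsample_reads(reads2, n, seed + 1)
    cov1 = build_coverage(sub1, genome, extension_length)
    cov2 = build_coverage(sub2, genome, extension_length)
    best2 = min_overlapping_rank(set1.peaks, set2.peaks)
    shared = [p for p, b in zip(set1.peaks, best2) if b > 0]
    if not shared:
        raise ValueError("no shared loci between the two peak sets")
    ratios = []
    for p in shared:
        h1 = cov1.depth_at(p.interval.chrom, p.summit)
        h2 = cov2.depth_at(p.interval.chrom, p.summit)
        ratios.append(np.log2((h2 + 1.0) / (h1 + 1.0)))
    ratios = np.asarray(ratios)
    return pd.DataFrame(
        {
            "quantile": list(quantiles),
            "log2_ratio": [float(np.quantile(ratios, q)) for q in quantiles],
            "n_loci": len(ratios),
        }
    )


def plot_overlap_grid(grid: OverlapGrid, path) -> None:
    """Render the rank-overlap matrix as a heatmap (upper-triangular style)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    data = grid.fraction.to_numpy(dtype=float)
    im = ax.imshow(data, vmin=0, vmax=1, cmap="viridis", origin="upper")
    ax.set_xticks(range(len(grid.cutoffs_y)))
    ax.set_xticklabels([f"{c//1000}K" if c >= 1000 else c for c in grid.cutoffs_y],
                       rotation=90, fontsize=7)
    ax.set_yticks(range(len(grid.cutoffs_x)))
    ax.set_yticklabels([f"{c//1000}K" if c >= 1000 else c for c in grid.cutoffs_x],
                       fontsize=7)
    ax.set_xlabel("top-y peaks (sample 2)")
    ax.set_ylabel("top-x peaks (sample 1)")
    fig.colorbar(im, ax=ax, label="overlap fraction")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
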