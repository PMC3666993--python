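"""Genome-wide E-box (CANNTG) occupancy analyses.

The CANNTG pattern class is reverse-complement symmetric, so a single
forward-strand scan finds every E-box exactly once.  Variants are named by
their internal dinucleotide, canonicalized so a variant and its reverse
complement form one class (CACCTG and CAGGTG are both "CC").  Sites are
ranked by the NB tail p-value of their read coverage, binned by rank for
variant-composition tables, and coverage CCDFs are computed over consensus
(RRCAGSTG) sites and over accessibility-stratified CAGCTG sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import Genome, GenomicInterval
from .peak_calling import NBGCModel, nb_tail
from .read_processing import CoverageTrack, build_coverage, subsample_reads

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_variant(nn: str) -> str:
    """Canonical class of an internal dinucleotide: the lexicographically
    smaller of NN and the NN its reverse-complement E-box carries."""
    rc = revcomp(nn)
    return min(nn, rc)


def matches_pattern(seq: str, pattern: str) -> bool:
    if len(seq) != len(pattern):
        return False
    return all(b in IUPAC.get(p, "") for b, p in zip(seq, pattern))


@dataclass(frozen=True, slots=True)
class EBoxSite:
    """One forward-strand CANNTG occurrence with its static annotations."""

    chrom: str
    start: int               # 0-based start of the 6-base E-box
    sequence: str            # the CANNTG hexamer as written on the forward strand
    variant: str             # canonical internal dinucleotide class
    flank5: str              # up to 6 bases of upstream sequence
    flank3: str              # up to 6 bases of downstream sequence
    mappable: bool           # uniquely mappable within +/- 200 bases

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.start + 6)


def scan_eboxes(
    genome: Genome,
    exclude: list | None = None,
    exclude_chroms: tuple[str, ...] = (),
    mappability_window: int = 200,
) -> list[EBoxSite]:
    """All forward-strand CANNTG matches, minus excluded regions.

    ``exclude`` is a list of intervals (control peaks); E-boxes overlapping
    any of them, or on an excluded chromosome, are dropped.  Each site's
    mappable flag requires unique mappability over the E-box +/- the
    mappability window.
    """
    excl_by_chrom: dict[str, np.ndarray] = {}
    if exclude:
        tmp: dict[str, list[tuple[int, int]]] = {}
        for item in exclude:
            iv = getattr(item, "interval", item)
            tmp.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, spans in tmp.items():
            arr = np.asarray(sorted(spans), dtype=np.int64)
            excl_by_chrom[chrom] = arr
    sites: list[EBoxSite] = []
    for chrom, seq in genome.sequences.items():
        if chrom in exclude_chroms:
            continue
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        n = len(arr)
        if n < 6:
            continue
        hit = (
            (arr[: n - 5] == ord("C"))
            & (arr[1 : n - 4] == ord("A"))
            & (arr[4 : n - 1] == ord("T"))
            & (arr[5:] == ord("G"))
        )
        positions = np.flatnonzero(hit)
        spans = excl_by_chrom.get(chrom)
        mask = genome.mappability_mask[chrom] if genome.mappability_mask else None
        for s in positions:
            s = int(s)
            if spans is not None:
                i = int(np.searchsorted(spans[:, 1], s, side="right"))
                if i < len(spans) and spans[i, 0] < s + 6:
                    continue
            hexamer = seq[s : s + 6]
            if "N" in hexamer:
                continue
            lo = max(0, s - mappability_window)
            hi = min(n, s + 6 + mappability_window)
            mappable = bool(mask[lo:hi].all()) if mask is not None else True
            sites.append(
                EBoxSite(
                    chrom=chrom,
                    start=s,
                    sequence=hexamer,
                    variant=canonical_variant(hexamer[2:4]),
                    flank5=seq[max(0, s - 6) : s],
                    flank3=seq[s + 6 : s + 12],
                    mappable=mappable,
                )
            )
    return sites


def sites_frame(sites: list[EBoxSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "start": [s.start for s in sites],
            "sequence": [s.sequence for s in sites],
            "variant": [s.variant for s in sites],
            "mappable": [s.mappable for s in sites],
        }
    )


def site_coverage(sites: list[EBoxSite], coverage: CoverageTrack) -> np.ndarray:
    """Max depth over the 6 bases of each site (peak-height semantics)."""
    out = np.zeros(len(sites), dtype=np.int64)
    for i, s in enumerate(sites):
        d = coverage.depth[s.chrom]
        out[i] = int(d[s.start : s.start + 6].max())
    return out


def rank_eboxes(
    sites: list[EBoxSite], coverage: CoverageTrack, model: NBGCModel
) -> pd.DataFrame:
    """Rank sites by the NB tail p-value of their coverage.

    Returns the site table with coverage, p_value and 1-based rank columns,
    sorted ascending by p-value with ties broken by descending coverage then
    coordinate.
    """
    df = sites_frame(sites)
    cov = site_coverage(sites, coverage)
    pvals = np.ones(len(sites))
    for i, s in enumerate(sites):
        bins = model.window_bins[s.chrom]
        widx = min(s.start // model.window_size, len(bins) - 1)
        b = int(bins[widx])
        pvals[i] = nb_tail(int(cov[i]), float(model.mu[b]), float(model.r[b]))
    df["coverage"] = cov
    df["p_value"] = pvals
    df = df.sort_values(
        ["p_value", "coverage", "chrom", "start"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def variant_distribution_by_bin(
    ranked: pd.DataFrame, bin_edges=(1000, 10_000, 100_000)
) -> pd.DataFrame:
    """Per-rank-bin E-box variant proportions plus a genome-background row.

    Bins are (0, e1], (e1, e2], ... up to all sites; the background row is
    the variant distribution over every site.  Proportions sum to 1 per row.
    """
    variants = sorted(ranked["variant"].unique())
    edges = [e for e in bin_edges if e < len(ranked)] + [len(ranked)]
    rows = []
    lo = 0
    for e in edges:
        part = ranked.iloc[lo:e]
        label = f"top_{e}" if lo == 0 else f"{lo + 1}-{e}"
        props = part["variant"].value_counts(normalize=True)
        rows.append({"bin": label, **{v: float(props.get(v, 0.0)) for v in variants}})
        lo = e
    props = ranked["variant"].value_counts(normalize=True)
    rows.append(
        {"bin": "background", **{v: float(props.get(v, 0.0)) for v in variants}}
    )
    return pd.DataFrame(rows)


def _pattern_match_flags(
    sites: list[EBoxSite], pattern: str = "RRCAGSTG"
) -> np.ndarray:
    """True where the site, with flanks, matches the consensus on either strand."""
    rc_pattern = revcomp(pattern)
    flags = np.zeros(len(sites), dtype=bool)
    for i, s in enumerate(sites):
        fwd = s.flank5[-2:] + s.sequence if len(s.flank5) >= 2 else ""
        rev = s.sequence + s.flank3[:2] if len(s.flank3) >= 2 else ""
        flags[i] = (len(fwd) == 8 and matches_pattern(fwd, pattern)) or (
            len(rev) == 8 and matches_pattern(rev, rc_pattern)
        )
    return flags


def _ccdf(cov: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    return np.array([(cov > t).mean() if len(cov) else 0.0 for t in thresholds])


def _log2_grid(max_cov: int) -> np.ndarray:
    """Thresholds 2**k, k = 0, 1, ... (the log2-coverage axis points)."""
    top = max(int(np.ceil(np.log2(max(max_cov, 2)))), 1)
    return 2 ** np.arange(0, top + 1)


def coverage_ccdf(
    sites: list[EBoxSite],
    genome: Genome,
    reads_by_sample: dict[str, list],
    extension_length: int = 200,
    pattern: str = "RRCAGSTG",
    seed: int = 0,
) -> pd.DataFrame:
    """Coverage CCDF over consensus-pattern sites vs all other E-boxes.

    Reads of each sample are sub-sampled to the common minimum before
    computing depth, so samples are directly comparable; only sites uniquely
    mappable within the +/-200-base window enter.  Returns long-format rows
    (sample, site_class, threshold, ccdf) with P(coverage > threshold).
    """
    usable = [s for s in sites if s.mappable]
    flags = _pattern_match_flags(usable, pattern)
    if not flags.any():
        raise ValueError(f"pattern {pattern} matches no mappable E-box")
    n = min(len(r) for r in reads_by_sample.values())
    rows = []
    depths = {}
    for k, (sample, reads) in enumerate(sorted(reads_by_sample.items())):
        sub = subsample_reads(reads, n, seed + k)
        cov = build_coverage(sub, genome, extension_length)
        depths[sample] = site_coverage(usable, cov)
    grid = _log2_grid(int(max(d.max() for d in depths.values())) if depths else 2)
    for sample, depth in depths.items():
        for cls, sel in (("consensus", flags), ("other", ~flags)):
            cc = _ccdf(depth[sel], grid)
            for t, v in zip(grid, cc):
                rows.append(
                    {"sample": sample, "site_class": cls,
                     "threshold": int(t), "ccdf": float(v)}
                )
    return pd.DataFrame(rows)


def assign_accessibility(
    sites: list[EBoxSite], scores: pd.DataFrame
) -> pd.DataFrame:
    """Join accessibility scores to CAGCTG sites and assign classes.

    Classes follow half-open score intervals (0,1] low, (1,2] moderate,
    (2,inf) high.  Sites without a score are labeled unknown and excluded
    from stratified analyses (the count is logged).
    """
    lookup = {
        (r["chrom"], int(r["start"])): float(r["score"])
        for _, r in scores.iterrows()
    }
    rows = []
    missing = 0
    for s in sites:
        if s.sequence != "CAGCTG":
            continue
        score = lookup.get((s.chrom, s.start))
        if score is None:
            cls = "unknown"
            missing += 1
        elif score <= 1.0:
            cls = "low"
        elif score <= 2.0:
            cls = "moderate"
        else:
            cls = "high"
        rows.append(
            {"chrom": s.chrom, "start": s.start, "score": score,
             "access_class": cls, "mappable": s.mappable}
        )
    if missing:
        logger.info("accessibility: %d CAGCTG sites without a score (excluded)", missing)
    return pd.DataFrame(rows)


def accessibility_ccdf(
    sites: list[EBoxSite],
    scores: pd.DataFrame,
    genome: Genome,
    reads_by_sample: dict[str, list],
    extension_length: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Accessibility-stratified coverage CCDF over CAGCTG E-boxes.

    Long-format rows (sample, access_class, threshold, ccdf) for the three
    accessibility classes, computed after equal-count read sub-sampling.
    """
    assigned = assign_accessibility(sites, scores)
    assigned = assigned[(assigned["access_class"] != "unknown") & assigned["mappable"]]
    by_key = {(s.chrom, s.start): i for i, s in enumerate(sites)}
    n = min(len(r) for r in reads_by_sample.values())
    idx = assigned.apply(lambda r: by_key[(r["chrom"], int(r["start"]))], axis=1)
    rows = []
    depths = {}
    for k, (sample, reads) in enumerate(sorted(reads_by_sample.items())):
        sub = subsample_reads(reads, n, seed + k)
        cov = build_coverage(sub, genome, extension_length)
        depths[sample] = site_coverage(sites, cov)[idx.to_numpy()]
    grid = _log2_grid(int(max(d.max() for d in depths.values())) if depths else 2)
    for sample, depth in depths.items():
        for cls in ("low", "moderate", "high"):
            sel = (assigned["access_class"] == cls).to_numpy()
            cc = _ccdf(depth[sel], grid)
            for t, v in zip(grid, cc):
                rows.append(
                    {"sample": sample, "access_class": cls,
                     "threshold": int(t), "ccdf": float(v)}
                )
    return pd.DataFrame(rows)
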