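"""From mapped reads to coverage: deduplication, directional extension, pileup.

ChIP fragments are longer than the sequenced read, so each read is extended
in its sequencing orientation to the nominal fragment length (200 bases by
default) before computing per-base depth.  Exact-duplicate reads are removed
first to damp PCR amplification artifacts, and reads on excluded chromosomes
are dropped before any statistics are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import Genome, GenomicInterval


@dataclass(frozen=True, slots=True)
class MappedRead:
    """A uniquely mapped sequencing read: a stranded interval plus sample label."""

    interval: GenomicInterval
    sample: str = ""


@dataclass
class CoverageTrack:
    """Per-chromosome integer depth profiles built from extended reads."""

    depth: dict[str, np.ndarray]
    total_reads_used: int
    extension_length: int

    def total_mass(self) -> int:
        return int(sum(int(d.sum()) for d in self.depth.values()))

    def depth_at(self, chrom: str, pos: int) -> int:
        return int(self.depth[chrom][pos])

    def max_depth(self, interval: GenomicInterval) -> int:
        d = self.depth[interval.chrom]
        return int(d[interval.start : interval.end].max())


def deduplicate(reads: list[MappedRead]) -> list[MappedRead]:
    """Keep at most one read per (chrom, start, end, strand), first occurrence wins."""
    seen: set[tuple[str, int, int, str]] = set()
    out: list[MappedRead] = []
    for r in reads:
        key = (r.interval.chrom, r.interval.start, r.interval.end, r.interval.strand)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def exclude_chromosomes(reads: list[MappedRead], names) -> list[MappedRead]:
    names = set(names)
    return [r for r in reads if r.interval.chrom not in names]


def extend_read(
    read: MappedRead, total_length: int, chrom_length: int | None = None
) -> GenomicInterval:
    """Extend a read in its sequencing orientation to ``total_length`` bases.

    Plus-strand reads grow rightward from their start, minus-strand reads
    grow leftward from their end; the result is clipped to chromosome bounds.
    Reads already at least ``total_length`` long are returned unchanged.
    """
    iv = read.interval
    if iv.strand not in ("+", "-"):
        raise ValueError("cannot extend an unstranded read")
    if total_length <= 0:
        raise ValueError("total_length must be positive")
    if len(iv) >= total_length:
        return iv
    if iv.strand == "+":
        start, end = iv.start, iv.start + total_length
    else:
        start, end = iv.end - total_length, iv.end
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(iv.chrom, start, end, iv.strand)


def build_coverage(
    reads: list[MappedRead], genome: Genome, total_length: int
) -> CoverageTrack:
    """Per-base depth of directionally extended reads, via difference arrays.

    depth[i] counts the extended reads covering base i; the total depth mass
    equals the sum of clipped extended-read lengths.
    """
    lengths = genome.chrom_lengths
    diffs = {c: np.zeros(n + 1, dtype=np.int64) for c, n in lengths.items()}
    # group read endpoints per chromosome, then one add.at per chromosome
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in lengths}
    for r in reads:
        if r.interval.chrom not in lengths:
            raise KeyError(f"read on unknown chromosome {r.interval.chrom}")
        ext = extend_read(r, total_length, lengths[r.interval.chrom])
        by_chrom[ext.chrom].append((ext.start, min(ext.end, lengths[ext.chrom])))
    for chrom, pairs in by_chrom.items():
        if not pairs:
            continue
        arr = np.asarray(pairs, dtype=np.int64)
        np.add.at(diffs[chrom], arr[:, 0], 1)
        np.add.at(diffs[chrom], arr[:, 1], -1)
    depth = {c: np.cumsum(d[:-1]).astype(np.int32) for c, d in diffs.items()}
    return CoverageTrack(
        depth=depth, total_reads_used=len(reads), extension_length=total_length
    )


def subsample_reads(reads: list[MappedRead], n: int, seed: int) -> list[MappedRead]:
    """Draw exactly n reads uniformly without replacement; deterministic given seed."""
    if n > len(reads):
        raise ValueError(f"cannot subsample {n} from {len(reads)} reads")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=n, replace=False)
    return [reads[i] for i in idx]
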