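"""Genomic coordinate types and readers/writers for the formats the pipeline touches.

All coordinates are 0-based, half-open (BED convention) throughout the
package; any 1-based display is a formatting concern of the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A strand-aware half-open interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Genome:
    """Chromosome sequences plus optional TSS annotations and a mappability mask.

    ``sequences`` maps chromosome name to an uppercase DNA string over
    {A,C,G,T,N}.  ``mappability_mask`` holds, per chromosome, a boolean vector
    (True = uniquely mappable) of the same length as the sequence; when loaded
    from soft-masked FASTA, lowercase positions are recorded as non-mappable.
    """

    sequences: dict[str, str]
    tss: list[GenomicInterval] | None = None
    mappability_mask: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.mappability_mask is not None:
            for chrom, mask in self.mappability_mask.items():
                if chrom not in self.sequences:
                    raise ValueError(f"mask for unknown chromosome {chrom}")
                if len(mask) != len(self.sequences[chrom]):
                    raise ValueError(
                        f"mappability mask length mismatch on {chrom}"
                    )

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def fetch(self, interval: GenomicInterval) -> str:
        seq = self.sequences.get(interval.chrom)
        if seq is None:
            raise KeyError(f"unknown chromosome {interval.chrom}")
        return seq[interval.start : interval.end]

    def is_mappable(self, interval: GenomicInterval) -> bool:
        """True when every base of the interval is uniquely mappable."""
        if self.mappability_mask is None:
            return True
        mask = self.mappability_mask[interval.chrom]
        lo = max(0, interval.start)
        hi = min(len(mask), interval.end)
        return bool(mask[lo:hi].all())


@dataclass
class RunConfig:
    """Pipeline-wide knobs shared by the stages.

    ``extension_length`` is the fragment length reads are extended to before
    pileup; ``exclude_chroms`` names chromosomes dropped at ingestion (the
    sex chromosomes, for mouse data); ``gc_window``/``gc_bin_width`` control
    the GC-conditioned background model; ``rank_bin_width`` is the rank-bin
    granularity used in concordance and rank-stratified analyses.
    """

    extension_length: int = 200
    exclude_chroms: tuple[str, ...] = ("chrX", "chrY")
    gc_window: int = 500
    gc_bin_width: float = 0.05
    peak_p_threshold: float = 1e-5
    control_p_threshold: float = 1e-3
    merge_distance: int = 200
    rank_bin_width: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extension_length <= 0:
            raise ValueError("extension_length must be positive")
        if self.rank_bin_width <= 0:
            raise ValueError("rank_bin_width must be positive")


def read_bed(path: str | Path, stranded: bool = False) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals, preserving file order.

    With ``stranded=True`` a sixth column is required and parsed; otherwise
    the strand column is used when present and '.' assumed when absent.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = "."
            if len(fields) >= 6:
                strand = fields[5]
            elif stranded:
                raise ValueError(f"{path}:{lineno}: strand column required")
            try:
                intervals.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(items: Iterable, path: str | Path) -> None:
    """Write intervals or peaks as BED.

    Plain intervals are written as BED6 (name '.', score 0).  Objects with
    ``height``/``p_value``/``rank`` attributes (peaks) are written as BED6+2
    with score = height and two extra columns for p-value (6 significant
    digits) and rank.
    """
    with open(path, "w") as fh:
        for item in items:
            iv = getattr(item, "interval", item)
            if hasattr(item, "p_value"):
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{item.rank}\t"
                    f"{item.height}\t{iv.strand}\t{item.p_value:.6g}\t{item.rank}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_fasta(path: str | Path) -> Genome:
    """Load a (possibly soft-masked) FASTA as a Genome.

    Sequences are uppercased; lowercase (soft-masked) positions become
    non-mappable in the mappability mask.  'N' bases are retained and are
    excluded from GC computations downstream.
    """
    sequences: dict[str, str] = {}
    masks: dict[str, np.ndarray] = {}
    any_masked = False
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate sequence name {record.id} in {path}")
        raw = str(record.seq)
        arr = np.frombuffer(raw.encode("ascii"), dtype=np.uint8)
        lower = (arr >= ord("a")) & (arr <= ord("z"))
        masks[record.id] = ~lower
        any_masked = any_masked or bool(lower.any())
        sequences[record.id] = raw.upper()
    return Genome(sequences=sequences, mappability_mask=masks)


def write_fasta(genome: Genome, path: str | Path) -> None:
    """Write genome sequences as FASTA, soft-masking non-mappable positions."""
    records = []
    for chrom, seq in genome.sequences.items():
        if genome.mappability_mask is not None:
            mask = genome.mappability_mask[chrom]
            chars = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
            lower_off = ord("a") - ord("A")
            chars[~mask] += lower_off
            seq = chars.tobytes().decode("ascii")
        records.append(SeqRecord(Seq(seq), id=chrom, description=""))
    SeqIO.write(records, str(path), "fasta")


def write_bedgraph(depth_by_chrom: dict[str, np.ndarray], path: str | Path) -> None:
    """Write per-base depth vectors as bedGraph (runs of equal depth)."""
    with open(path, "w") as fh:
        for chrom, depth in depth_by_chrom.items():
            if len(depth) == 0:
                continue
            change = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(depth)]))
            for s, e in zip(starts, ends):
                v = int(depth[s])
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


def write_table(df, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
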