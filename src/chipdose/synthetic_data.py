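"""Synthetic genomes, binding sites and ChIP read sets with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, at desk scale: a small multi-chromosome genome whose GC fraction
varies smoothly along each chromosome; true binding sites with graded
affinities, each planted on a CANNTG E-box whose variant (and flanking
consensus) is coupled to affinity; chromatin-accessibility classes for
CAGCTG E-boxes that multiply site occupancy; two ChIP samples sharing the
same sites, one with a configurable fold-higher foreground read mass
(default 4x, an "overexpressed" factor dose); background reads drawn per
window from a GC-conditioned negative binomial; a control sample of pure
background plus a few shared artifact spikes; and duplicated repeat tracts
marked non-mappable.

Everything is deterministic given the seed, and a :class:`GroundTruth`
records what was planted so recovery can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import Genome, GenomicInterval, write_bed, write_fasta
from .peak_calling import window_gc_fractions
from .read_processing import MappedRead

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
ACCESS_CLASSES = ("low", "moderate", "high")


def default_background_nb(
    gc_bin_width: float = 0.05,
    base_mu: float = 25.0,
    gc_slope: float = 30.0,
    dispersion: float = 5.0,
) -> dict[float, tuple[float, float]]:
    """Reads-per-window NB (mean, dispersion) per GC bin, increasing with GC.

    GC-rich regions attract more nonspecific ChIP background, which is the
    bias the GC-conditioned model exists to absorb.
    """
    out = {}
    edges = np.arange(0.0, 1.0, gc_bin_width)
    for left in edges:
        center = left + gc_bin_width / 2
        mu = float(np.clip(base_mu + gc_slope * (center - 0.45), 4.0, 80.0))
        out[round(float(left), 6)] = (mu, dispersion)
    return out


@dataclass
class SyntheticConfig:
    """Study conditions for the two-sample simulation.

    ``n_foreground_reads`` is the expected immunoprecipitated (site-derived)
    read mass of the baseline ("endogenous") sample; the "overexpressed"
    sample receives ``dose_factor`` times that mass over the same sites.
    Background parameters are reads-per-window NB laws keyed by GC bin.
    """

    n_chroms: int = 3
    chrom_length: int = 2_000_000
    gc_mean: float = 0.45
    gc_amplitude: float = 0.10
    gc_period: int = 400_000
    n_true_sites: int = 5000
    affinity_sigma: float = 1.0
    dose_factor: float = 4.0
    background_nb: dict[float, tuple[float, float]] = field(
        default_factory=default_background_nb
    )
    gc_bin_width: float = 0.05
    window_size: int = 500
    fragment_length: int = 200
    read_length: int = 36
    n_foreground_reads: int = 150_000
    n_control_artifacts: int = 5
    artifact_reads: int = 400
    accessibility_mixture: tuple[float, float, float] = (0.55, 0.25, 0.20)
    accessibility_bound_mixture: tuple[float, float, float] = (0.05, 0.25, 0.70)
    accessibility_effect: tuple[float, float, float] = (0.3, 1.0, 2.5)
    pref_variant_floor: float = 0.05
    pref_variant_slope: float = 0.90
    n_repeat_tracts: int = 4
    repeat_length: int = 5000
    min_site_spacing: int = 1000
    edge_margin: int = 2000
    n_tss: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dose_factor <= 0:
            raise ValueError("dose_factor must be positive")
        for mu, r in self.background_nb.values():
            if mu <= 0 or r <= 0:
                raise ValueError("background NB means and dispersions must be positive")
        if abs(sum(self.accessibility_mixture) - 1.0) > 1e-9:
            raise ValueError("accessibility mixture proportions must sum to 1")

    def background_params(self, gc: float) -> tuple[float, float]:
        edges = sorted(self.background_nb)
        idx = int(np.searchsorted(edges, gc, side="right")) - 1
        idx = min(max(idx, 0), len(edges) - 1)
        return self.background_nb[edges[idx]]


@dataclass
class GroundTruth:
    """What the generator planted: the oracle for recovery tests."""

    sites: pd.DataFrame           # chrom, start (of E-box), summit, affinity, variant, consensus, access_class
    artifacts: pd.DataFrame       # chrom, summit
    accessibility_scores: pd.DataFrame  # chrom, start, score, access_class (all CAGCTG E-boxes)
    read_origins: dict[str, np.ndarray] = field(default_factory=dict)


def _draw_sequence(rng: np.random.Generator, length: int, gc: np.ndarray) -> np.ndarray:
    """Per-position base draw at the local GC fraction; returns uint8 ASCII."""
    u = rng.random(length)
    which = rng.integers(0, 2, length)
    # 0:A 1:C 2:G 3:T ; GC positions pick C/G, AT positions pick A/T
    codes = np.where(u < gc, 1 + which, 3 * which)  # C(1)/G(2) vs A(0)/T(3)
    return _BASES[codes]


def _lognormal_score_for_class(rng: np.random.Generator, cls: int) -> float:
    """Latent accessibility score consistent with a class, via the truncated
    standard log-normal whose thresholds sit at 1 and 2."""
    f1 = stats.norm.cdf(0.0)            # P(score <= 1)
    f2 = stats.norm.cdf(math.log(2.0))  # P(score <= 2)
    lo, hi = [(1e-6, f1), (f1, f2), (f2, 1 - 1e-9)][cls]
    u = rng.uniform(lo, hi)
    return float(math.exp(stats.norm.ppf(u)))


def simulate_genome(config: SyntheticConfig) -> tuple[Genome, GroundTruth]:
    rng = np.random.default_rng(config.seed)
    sequences: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    chroms = [f"syn{i + 1}" for i in range(config.n_chroms)]
    for ci, chrom in enumerate(chroms):
        pos = np.arange(config.chrom_length)
        phase = rng.uniform(0, 2 * math.pi)
        gc = config.gc_mean + config.gc_amplitude * np.sin(
            2 * math.pi * pos / config.gc_period + phase
        )
        sequences[chrom] = _draw_sequence(rng, config.chrom_length, gc)
        masks[chrom] = np.ones(config.chrom_length, dtype=bool)

    # repeat tracts: duplicated sequence, both copies non-mappable
    for _ in range(config.n_repeat_tracts):
        src_c, dst_c = rng.choice(chroms, 2)
        L = config.repeat_length
        s1 = int(rng.integers(config.edge_margin, config.chrom_length - L - config.edge_margin))
        s2 = int(rng.integers(config.edge_margin, config.chrom_length - L - config.edge_margin))
        if src_c == dst_c and abs(s1 - s2) < L:
            continue
        sequences[dst_c][s2 : s2 + L] = sequences[src_c][s1 : s1 + L]
        masks[src_c][s1 : s1 + L] = False
        masks[dst_c][s2 : s2 + L] = False

    # true binding sites: spaced positions, affinity-coupled E-box planting
    n = config.n_true_sites
    per_chrom = np.full(config.n_chroms, n // config.n_chroms)
    per_chrom[: n % config.n_chroms] += 1
    site_rows = []
    internal_other = [
        d for d in ("AA AC AG AT CA CG CT GA GT TA TC TG TT".split())
    ]  # every NN except GC and GG (the planted preferred classes)
    for ci, chrom in enumerate(chroms):
        k = int(per_chrom[ci])
        usable = config.chrom_length - 2 * config.edge_margin
        spacing = usable // k
        if spacing <= config.min_site_spacing:
            raise ValueError("requested sites exceed placeable positions")
        offsets = rng.integers(0, spacing - 12, k)
        starts = config.edge_margin + np.arange(k) * spacing + offsets
        for s in starts:
            s = int(s)
            if not masks[chrom][s - 2 : s + 8].all():
                s = s + config.repeat_length  # hop past a repeat tract
            site_rows.append((chrom, s))
    affinity = rng.lognormal(mean=0.0, sigma=config.affinity_sigma, size=len(site_rows))
    qq = stats.rankdata(affinity) / (len(affinity) + 1)

    purine = np.frombuffer(b"AG", dtype=np.uint8)
    rows = []
    for i, (chrom, s) in enumerate(site_rows):
        seq = sequences[chrom]
        # cubic in the affinity quantile: motif quality rises steeply among
        # the strongest (peak-callable) sites rather than saturating early
        p_pref = config.pref_variant_floor + config.pref_variant_slope * qq[i] ** 3
        preferred = rng.random() < p_pref
        if preferred:
            s_base = b"C" if rng.random() < 0.5 else b"G"
            word = (
                purine[rng.integers(0, 2)].tobytes()
                + purine[rng.integers(0, 2)].tobytes()
                + b"CAG" + s_base + b"TG"
            )
            seq[s - 2 : s + 6] = np.frombuffer(word, dtype=np.uint8)
            nn = "CAG" + s_base.decode() + "TG"
            consensus = True
        else:
            nn = internal_other[rng.integers(0, len(internal_other))]
            word = b"CA" + nn.encode() + b"TG"
            seq[s : s + 6] = np.frombuffer(word, dtype=np.uint8)
            nn = word.decode()
            consensus = False
        rows.append(
            {
                "chrom": chrom,
                "start": s,
                "summit": s + 3,
                "affinity": affinity[i],
                "variant": nn,
                "consensus": consensus,
                "access_class": "",
            }
        )
    sites = pd.DataFrame(rows)

    # accessibility: latent log-normal score per CAGCTG E-box (thresholds 1, 2).
    # Bound E-boxes draw their class from a mixture skewed toward open
    # chromatin: accessibility is a determinant of occupancy, so accessible
    # classes are enriched among bound sites and the read-mass multiplier
    # below compounds the coupling.
    mix_bg = np.asarray(config.accessibility_mixture)
    mix_bound = np.asarray(config.accessibility_bound_mixture)
    acc_rows = []
    planted_cagctg = {}
    for idx, row in sites.iterrows():
        if row["variant"] == "CAGCTG":
            planted_cagctg[(row["chrom"], int(row["start"]))] = idx
    for chrom in chroms:
        seq_b = sequences[chrom].tobytes()
        off = 0
        while True:
            j = seq_b.find(b"CAGCTG", off)
            if j < 0:
                break
            bound = (chrom, j) in planted_cagctg
            cls = int(rng.choice(3, p=mix_bound if bound else mix_bg))
            score = _lognormal_score_for_class(rng, cls)
            acc_rows.append(
                {"chrom": chrom, "start": j, "score": score,
                 "access_class": ACCESS_CLASSES[cls]}
            )
            off = j + 1
    accessibility = pd.DataFrame(acc_rows)

    # couple occupancy to accessibility for CAGCTG-planted sites
    effect = dict(zip(ACCESS_CLASSES, config.accessibility_effect))
    acc_lookup = {
        (r["chrom"], int(r["start"])): r["access_class"]
        for _, r in accessibility.iterrows()
    }
    for idx in planted_cagctg.values():
        key = (sites.at[idx, "chrom"], int(sites.at[idx, "start"]))
        cls = acc_lookup.get(key)
        if cls is not None:
            sites.at[idx, "access_class"] = cls
            sites.at[idx, "affinity"] = sites.at[idx, "affinity"] * effect[cls]

    # control artifact positions, away from true sites
    art_rows = []
    taken = set(zip(sites["chrom"], sites["start"] // 2000))
    while len(art_rows) < config.n_control_artifacts:
        chrom = chroms[int(rng.integers(0, config.n_chroms))]
        p = int(rng.integers(config.edge_margin, config.chrom_length - config.edge_margin))
        if (chrom, p // 2000) in taken:
            continue
        art_rows.append({"chrom": chrom, "summit": p})
    artifacts = pd.DataFrame(art_rows)

    # synthetic TSS annotations (used for TSS-distance-matched background sampling)
    tss = []
    for _ in range(config.n_tss):
        chrom = chroms[int(rng.integers(0, config.n_chroms))]
        p = int(rng.integers(0, config.chrom_length - 1))
        tss.append(GenomicInterval(chrom, p, p + 1, "+" if rng.random() < 0.5 else "-"))

    genome = Genome(
        sequences={c: sequences[c].tobytes().decode("ascii") for c in chroms},
        tss=tss,
        mappability_mask=masks,
    )
    truth = GroundTruth(sites=sites, artifacts=artifacts, accessibility_scores=accessibility)
    return genome, truth


def _site_reads(
    rng: np.random.Generator,
    chrom: str,
    summit: int,
    count: int,
    config: SyntheticConfig,
    chrom_len: int,
    sample: str,
) -> list[MappedRead]:
    """Strand-split reads whose extension to fragment_length covers the summit."""
    out = []
    L, rl = config.fragment_length, config.read_length
    d = rng.integers(0, L, count)
    fwd = rng.random(count) < 0.5
    for k in range(count):
        if fwd[k]:
            start = max(0, summit - int(d[k]))
            iv = GenomicInterval(chrom, start, min(start + rl, chrom_len), "+")
        else:
            end = min(chrom_len, summit + int(d[k]) + 1)
            iv = GenomicInterval(chrom, max(0, end - rl), end, "-")
        out.append(MappedRead(iv, sample))
    return out


def simulate_reads(
    genome: Genome,
    truth: GroundTruth,
    config: SyntheticConfig,
    sample: str,
    seed: int | None = None,
) -> list[MappedRead]:
    """Reads for one sample: "endogenous", "overexpressed", or "control*".

    Foreground counts per site are multinomial with weights proportional to
    affinity (which already folds in the accessibility effect), scaled by
    ``dose_factor`` for the overexpressed sample.  Background counts per
    tiling window follow the window's GC bin NB law.  Control samples carry
    background plus artifact spikes at positions shared across replicates.
    """
    is_control = sample.startswith("control")
    if not is_control and sample not in ("endogenous", "overexpressed"):
        raise ValueError(f"unknown sample label {sample!r}")
    if seed is None:
        seed = config.seed + {"endogenous": 1, "overexpressed": 2}.get(sample, 3)
    rng = np.random.default_rng(seed)
    lengths = genome.chrom_lengths
    reads: list[MappedRead] = []
    origins: list[str] = []

    if not is_control:
        mass = config.n_foreground_reads * (
            config.dose_factor if sample == "overexpressed" else 1.0
        )
        w = truth.sites["affinity"].to_numpy()
        counts = rng.multinomial(int(round(mass)), w / w.sum())
        for (_, row), c in zip(truth.sites.iterrows(), counts):
            if c == 0:
                continue
            rs = _site_reads(
                rng, row["chrom"], int(row["summit"]), int(c), config,
                lengths[row["chrom"]], sample,
            )
            reads.extend(rs)
            origins.extend(["foreground"] * len(rs))

    # GC-conditioned background, per tiling window
    gc = window_gc_fractions(genome, config.window_size)
    rl = config.read_length
    for chrom, fracs in gc.items():
        clen = lengths[chrom]
        for w_idx, f in enumerate(fracs):
            mu, r = config.background_params(float(f))
            n_bg = int(rng.negative_binomial(r, r / (r + mu)))
            if n_bg == 0:
                continue
            w_start = w_idx * config.window_size
            w_end = min(w_start + config.window_size, clen)
            pos5 = rng.integers(w_start, w_end, n_bg)
            fwd = rng.random(n_bg) < 0.5
            for k in range(n_bg):
                x = int(pos5[k])
                if fwd[k]:
                    iv = GenomicInterval(chrom, x, min(x + rl, clen), "+")
                else:
                    end = min(x + 1, clen)
                    iv = GenomicInterval(chrom, max(0, end - rl), end, "-")
                reads.append(MappedRead(iv, sample))
                origins.append("background")

    if is_control:
        for _, row in truth.artifacts.iterrows():
            rs = _site_reads(
                rng, row["chrom"], int(row["summit"]), config.artifact_reads,
                config, lengths[row["chrom"]], sample,
            )
            reads.extend(rs)
            origins.extend(["artifact"] * len(rs))

    truth.read_origins[sample] = np.asarray(origins)
    return reads


def write_fixture(
    genome: Genome,
    truth: GroundTruth,
    reads_by_sample: dict[str, list[MappedRead]],
    outdir: str | Path,
) -> None:
    """Write FASTA + per-sample BED + truth tables, reloadable by genome_io."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(genome, outdir / "genome.fa")
    if genome.tss:
        write_bed(genome.tss, outdir / "tss.bed")
    for sample, reads in reads_by_sample.items():
        write_bed([r.interval for r in reads], outdir / f"{sample}.bed")
    truth.sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    truth.artifacts.to_csv(outdir / "truth_artifacts.tsv", sep="\t", index=False)
    truth.accessibility_scores.to_csv(
        outdir / "accessibility_scores.tsv", sep="\t", index=False
    )
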