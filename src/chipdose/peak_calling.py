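"""GC-conditioned negative-binomial background model and peak calling.

Background read depth varies systematically with local GC content, so the
genome is tiled into fixed windows, each window is assigned a GC bin, and a
negative binomial is fitted per bin to the depth observed at window
midpoints.  Sampling depth at midpoints (rather than summing reads per
window) makes the estimate an exact binomial thinning of the window's read
count when the window is at least twice the fragment length, which leaves
the NB dispersion parameter unchanged and puts the fitted law directly on
the per-base depth scale that peak significance is computed on.

Bound-site reads contaminate the upper tail of the per-bin counts, and at
realistic site densities that contamination can reach a third of windows,
so the per-bin fit is robust by construction: a truncated maximum-
likelihood fit on the lower 60% of counts (immune to any upper-tail
contamination) acts as a reference, and only when the observed tail mass
beyond that reference is consistent with a clean sample does the fit
switch to the more efficient trimmed-moment estimator with model-implied
truncation correction (see ``_fit_nb_robust``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome_io import Genome, GenomicInterval
from .read_processing import CoverageTrack

_TINY_P = 5e-324  # smallest positive subnormal double; floor for underflowed tails


def nb_tail(observed: int, mu: float, r: float) -> float:
    """P(X >= observed) for X ~ NB(mean mu, dispersion r); r = inf means Poisson."""
    if observed <= 0:
        return 1.0
    if math.isinf(r):
        p = stats.poisson.sf(observed - 1, mu)
    else:
        p = stats.nbinom.sf(observed - 1, r, r / (r + mu))
    return max(float(p), _TINY_P)


def _nb_isf(alpha: float, mu: float, r: float) -> int:
    """Smallest integer c with P(X >= c) <= alpha."""
    if math.isinf(r):
        k = int(stats.poisson.isf(alpha, mu))
    else:
        k = int(stats.nbinom.isf(alpha, r, r / (r + mu)))
    # isf returns smallest k with sf(k) <= alpha, i.e. P(X >= k+1) <= alpha
    c = k + 1
    while c > 0 and nb_tail(c - 1, mu, r) <= alpha:
        c -= 1
    return c


def _moments_to_nb(mean: float, var: float) -> tuple[float, float]:
    if var <= mean:
        return mean, math.inf
    return mean, mean * mean / (var - mean)


def _fit_nb_trimmed(counts: np.ndarray, trim: float = 0.05, iters: int = 30):
    """Method-of-moments NB fit on a top-trimmed sample, corrected for truncation.

    The top ``trim`` fraction of counts is discarded, then the fit iterates
    to self-consistency: compute the mean/variance the current model would
    show after the same trimming (with a fractional atom at the cut, so the
    discrete boundary mass matches the empirical quantile exactly) and
    rescale the raw trimmed moments accordingly.
    """
    n = len(counts)
    keep = int(math.ceil(n * (1.0 - trim)))
    y = np.sort(counts)[:keep]
    mt, vt = float(y.mean()), float(y.var())
    if mt <= 0:
        return 0.0, math.inf
    if vt == 0.0:  # degenerate (constant) counts: no truncation to correct
        return mt, math.inf
    mu, r = _moments_to_nb(mt, vt)
    for _ in range(iters):
        dist = (
            stats.poisson(mu)
            if math.isinf(r)
            else stats.nbinom(r, r / (r + mu))
        )
        q = int(dist.ppf(1.0 - trim)) + 2
        ks = np.arange(0, max(q, 2) + 1)
        pm = dist.pmf(ks)
        cum = np.cumsum(pm)
        target = 1.0 - trim
        j = int(np.searchsorted(cum, target))
        w = pm.copy()
        if j < len(ks):
            w[j] = target - (cum[j - 1] if j > 0 else 0.0)
            w[j + 1 :] = 0.0
        w = np.maximum(w, 0.0)
        tot = w.sum()
        if tot <= 0:
            break
        w /= tot
        em = float((ks * w).sum())
        ev = float(((ks - em) ** 2 * w).sum())
        if em <= 0 or ev <= 0:
            break
        new_mu = mu * mt / em
        model_full_var = mu + (0.0 if math.isinf(r) else mu * mu / r)
        full_var = vt * model_full_var / ev
        new_mu, new_r = _moments_to_nb(new_mu, full_var)
        done = abs(new_mu - mu) < 1e-10 * max(mu, 1.0)
        mu, r = new_mu, new_r
        if done:
            break
    return mu, r


def _fit_nb_truncated_mle(
    counts: np.ndarray, keep_q: float = 0.6, K: float | None = None
):
    """NB fit by maximum likelihood on counts at or below a cut,
    conditioning on the truncation.

    The cut is the ``keep_q`` empirical quantile unless an explicit ``K``
    is given.  Because everything above the cut is ignored entirely (not
    modeled as a censored tail), upper-tail contamination by bound-site
    reads cannot pull the fit.  Returns None when the kept counts carry too
    little resolution or the optimizer runs into its bounds.
    """
    from scipy.optimize import minimize
    from scipy.special import gammaln

    if K is None:
        K = float(np.quantile(counts, keep_q))
    kept = counts[counts <= K]
    vals, cnts = np.unique(kept, return_counts=True)
    if len(vals) < 3 or K < 4:
        return None
    m0 = float(kept.mean())
    v0 = float(kept.var()) + 1e-6
    mu0 = max(m0, 0.1)
    r0 = 10.0 if v0 <= m0 else min(max(m0 * m0 / (v0 - m0), 0.3), 500.0)

    def nll(theta):
        mu = math.exp(min(max(theta[0], -5.0), 8.0))
        r = math.exp(min(max(theta[1], -1.5), 7.0))
        p = r / (r + mu)
        logpmf = (
            gammaln(vals + r) - gammaln(r) - gammaln(vals + 1)
            + r * math.log(p) + vals * np.log1p(-p)
        )
        cdf = stats.nbinom.cdf(K, r, p)
        return -(cnts * (logpmf - math.log(max(cdf, 1e-300)))).sum()

    res = minimize(
        nll,
        np.log([mu0, r0]),
        method="Nelder-Mead",
        options=dict(xatol=1e-5, fatol=1e-7, maxiter=1500),
    )
    mu = math.exp(min(max(res.x[0], -5.0), 8.0))
    r = math.exp(min(max(res.x[1], -1.5), 7.0))
    if r > 900.0:  # hit the dispersion bound: effectively unidentified
        return None
    return float(mu), float(r)


def _fit_nb_robust(counts: np.ndarray, trim: float = 0.05):
    """Background NB fit that tolerates heavy upper-tail signal contamination.

    A truncated-MLE fit on the lower 60% of counts serves as a
    contamination-proof reference; if the fraction of counts beyond that
    reference's 2% tail point is consistent with a clean sample, the
    efficient trimmed-moment fit (``trim``) is used.  A first alarm may be
    a false positive caused by sampling noise in the reference itself, so
    the reference is refit once with the cut moved up to the alarm
    threshold (keeping ~95% of clean data) and the tail re-tested; only a
    persistent excess keeps the robust reference.
    """
    ref = _fit_nb_truncated_mle(counts)
    if ref is None:
        return _fit_nb_trimmed(counts, trim=0.35)

    def flagged_frac(mu, r):
        return float((counts >= _nb_isf(0.02, mu, r)).mean())

    if flagged_frac(*ref) <= 0.04:
        return _fit_nb_trimmed(counts, trim=trim)
    c = _nb_isf(0.02, *ref)
    ref2 = _fit_nb_truncated_mle(counts, K=float(c - 1)) or ref
    if flagged_frac(*ref2) <= 0.04:
        return _fit_nb_trimmed(counts, trim=trim)
    return ref


@dataclass
class NBGCModel:
    """Per-GC-bin negative binomial background law for read depth.

    ``mu``/``r`` are on the per-base depth scale (depth at a window
    midpoint); ``window_mu`` rescales to reads per window.  ``window_bins``
    maps each tiling window of each chromosome to its GC bin so that peak
    calling can look up the local background law without re-reading the
    genome.  Bins with fewer than ``min_windows`` observations inherit the
    nearest fitted bin.
    """

    gc_bin_edges: np.ndarray
    mu: np.ndarray          # depth-scale NB mean per bin
    r: np.ndarray           # NB dispersion per bin (inf = Poisson)
    n_windows: np.ndarray   # windows observed per bin
    window_size: int
    extension_length: int
    window_bins: dict[str, np.ndarray]
    window_gc: dict[str, np.ndarray]
    total_reads: int

    @property
    def window_mu(self) -> np.ndarray:
        """NB mean on the reads-per-window scale."""
        return self.mu * (self.window_size / self.extension_length)

    def bin_of_gc(self, gc: float) -> int:
        if not (0.0 <= gc <= 1.0):
            raise ValueError(f"GC fraction {gc} outside [0, 1]")
        idx = int(np.searchsorted(self.gc_bin_edges, gc, side="right")) - 1
        return min(max(idx, 0), len(self.mu) - 1)

    def tail_pvalue(self, gc: float, observed: int) -> float:
        b = self.bin_of_gc(gc)
        return nb_tail(observed, float(self.mu[b]), float(self.r[b]))

    def depth_thresholds(self, alpha: float) -> np.ndarray:
        """Per-bin minimal depth whose tail probability is <= alpha."""
        return np.array(
            [_nb_isf(alpha, float(m), float(rr)) for m, rr in zip(self.mu, self.r)],
            dtype=np.int64,
        )

    def null_genome_fraction(self, alpha: float) -> float:
        """Model-expected fraction of the genome at depth with tail <= alpha."""
        c = self.depth_thresholds(alpha)
        total = int(self.n_windows.sum())
        if total == 0:
            return 0.0
        frac = 0.0
        for b in range(len(self.mu)):
            if self.n_windows[b] == 0:
                continue
            frac += (self.n_windows[b] / total) * nb_tail(
                int(c[b]), float(self.mu[b]), float(self.r[b])
            )
        return frac


@dataclass(frozen=True, slots=True)
class Peak:
    interval: GenomicInterval
    summit: int
    height: int
    p_value: float
    rank: int = 0


@dataclass
class RankedPeakSet:
    """Peaks of one sample, sorted by ascending p-value.

    Ties are broken by descending height, then chromosome and coordinate, so
    ranks are deterministic.
    """

    sample: str
    peaks: list[Peak]
    total_reads: int
    p_threshold: float

    def __len__(self) -> int:
        return len(self.peaks)

    def top(self, n: int) -> list[Peak]:
        return self.peaks[:n]


def _rank_peaks(sample, peaks, total_reads, p_threshold) -> RankedPeakSet:
    order = sorted(
        peaks,
        key=lambda p: (p.p_value, -p.height, p.interval.chrom, p.interval.start),
    )
    ranked = [
        Peak(p.interval, p.summit, p.height, p.p_value, rank=i + 1)
        for i, p in enumerate(order)
    ]
    return RankedPeakSet(sample, ranked, total_reads, p_threshold)


def window_gc_fractions(genome: Genome, window_size: int) -> dict[str, np.ndarray]:
    """GC fraction per non-overlapping tiling window; N bases are excluded.

    Windows that are entirely N get the genome-wide mean GC so they fall in
    a central (well-populated) bin rather than an arbitrary one.
    """
    out: dict[str, np.ndarray] = {}
    gc_sum = 0.0
    acgt_sum = 0
    raw: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, seq in genome.sequences.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        is_n = arr == ord("N")
        nwin = max(1, math.ceil(len(arr) / window_size))
        gc_counts = np.zeros(nwin)
        base_counts = np.zeros(nwin)
        widx = np.arange(len(arr)) // window_size
        np.add.at(gc_counts, widx, is_gc)
        np.add.at(base_counts, widx, ~is_n)
        raw[chrom] = (gc_counts, base_counts)
        gc_sum += gc_counts.sum()
        acgt_sum += base_counts.sum()
    mean_gc = gc_sum / max(acgt_sum, 1)
    for chrom, (gc_counts, base_counts) in raw.items():
        frac = np.full(len(gc_counts), mean_gc)
        ok = base_counts > 0
        frac[ok] = gc_counts[ok] / base_counts[ok]
        out[chrom] = frac
    return out


def fit_background(
    coverage: CoverageTrack,
    genome: Genome,
    window_size: int = 500,
    gc_bin_width: float = 0.05,
    trim: float = 0.05,
    min_windows: int = 100,
) -> NBGCModel:
    """Fit the per-GC-bin NB background law from midpoint depths.

    Windows whose GC bin holds fewer than ``min_windows`` windows inherit
    the parameters of the nearest fitted bin.  Raises if no bin can be
    fitted at all.
    """
    if window_size < 2 * coverage.extension_length:
        raise ValueError(
            "window_size must be at least twice the extension length so the "
            "midpoint depth is a clean thinning of the window's read count"
        )
    gc = window_gc_fractions(genome, window_size)
    edges = np.arange(0.0, 1.0 + gc_bin_width, gc_bin_width)
    nbins = len(edges) - 1
    window_bins: dict[str, np.ndarray] = {}
    counts_per_bin: list[list[np.ndarray]] = [[] for _ in range(nbins)]
    for chrom, frac in gc.items():
        bins = np.clip(
            np.searchsorted(edges, frac, side="right") - 1, 0, nbins - 1
        ).astype(np.int32)
        window_bins[chrom] = bins
        depth = coverage.depth[chrom]
        mids = np.minimum(
            np.arange(len(bins)) * window_size + window_size // 2, len(depth) - 1
        )
        md = depth[mids]
        for b in range(nbins):
            sel = md[bins == b]
            if len(sel):
                counts_per_bin[b].append(sel)
    mu = np.full(nbins, np.nan)
    r = np.full(nbins, np.nan)
    nw = np.zeros(nbins, dtype=np.int64)
    for b in range(nbins):
        if counts_per_bin[b]:
            c = np.concatenate(counts_per_bin[b])
            nw[b] = len(c)
            if len(c) >= min_windows:
                mu[b], r[b] = _fit_nb_robust(c.astype(np.float64), trim=trim)
    fitted = np.flatnonzero(~np.isnan(mu) & (mu > 0))
    if len(fitted) == 0:
        raise ValueError("no GC bin has enough windows to fit a background model")
    for b in range(nbins):
        if np.isnan(mu[b]) or mu[b] <= 0:
            nearest = fitted[np.argmin(np.abs(fitted - b))]
            mu[b], r[b] = mu[nearest], r[nearest]
    return NBGCModel(
        gc_bin_edges=edges,
        mu=mu,
        r=r,
        n_windows=nw,
        window_size=window_size,
        extension_length=coverage.extension_length,
        window_bins=window_bins,
        window_gc=gc,
        total_reads=coverage.total_reads_used,
    )


def nb_tail_pvalue(model: NBGCModel, gc: float, observed: int) -> float:
    """Tail probability P(depth >= observed) under the GC bin's NB law."""
    return model.tail_pvalue(gc, observed)


def call_peaks(
    coverage: CoverageTrack,
    model: NBGCModel,
    p_threshold: float,
    merge_distance: int = 200,
    sample: str = "",
) -> RankedPeakSet:
    """Call peaks as maximal significant runs of depth, merged at fragment scale.

    A base is significant when its depth meets the local GC bin's depth
    threshold for ``p_threshold``; runs closer than ``merge_distance`` are
    merged; each region reports the summit (leftmost maximum), its height,
    and the NB tail p-value of that height in the summit's GC bin.
    """
    thresholds = model.depth_thresholds(p_threshold)
    peaks: list[Peak] = []
    for chrom, depth in coverage.depth.items():
        if chrom not in model.window_bins or len(depth) == 0:
            continue
        bins = model.window_bins[chrom]
        base_thr = thresholds[bins][
            np.minimum(np.arange(len(depth)) // model.window_size, len(bins) - 1)
        ]
        sig = depth >= base_thr
        if not sig.any():
            continue
        padded = np.concatenate(([False], sig, [False]))
        d = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)
        # merge runs separated by < merge_distance
        merged: list[list[int]] = []
        for s, e in zip(run_starts, run_ends):
            if merged and s - merged[-1][1] < merge_distance:
                merged[-1][1] = e
            else:
                merged.append([int(s), int(e)])
        for s, e in merged:
            region = depth[s:e]
            summit_off = int(np.argmax(region))
            summit = s + summit_off
            height = int(region[summit_off])
            widx = min(summit // model.window_size, len(bins) - 1)
            b = int(bins[widx])
            p = nb_tail(height, float(model.mu[b]), float(model.r[b]))
            peaks.append(
                Peak(GenomicInterval(chrom, s, e), summit, height, p)
            )
    return _rank_peaks(sample, peaks, coverage.total_reads_used, p_threshold)


def subtract_control(
    peaks: RankedPeakSet, control_peaks: RankedPeakSet
) -> RankedPeakSet:
    """Drop peaks overlapping (>= 1 base) any control peak; recompute ranks."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for cp in control_peaks.peaks:
        by_chrom.setdefault(cp.interval.chrom, []).append(
            (cp.interval.start, cp.interval.end)
        )
    sorted_ctrl = {
        c: (np.array(sorted(v))[:, 0], np.array(sorted(v))[:, 1])
        for c, v in by_chrom.items()
    }
    kept = []
    for p in peaks.peaks:
        ctrl = sorted_ctrl.get(p.interval.chrom)
        if ctrl is None:
            kept.append(p)
            continue
        starts, ends = ctrl
        # control peaks are disjoint; first control with end > peak.start
        i = int(np.searchsorted(ends, p.interval.start, side="right"))
        if i < len(starts) and starts[i] < p.interval.end:
            continue
        kept.append(p)
    return _rank_peaks(peaks.sample, kept, peaks.total_reads, peaks.p_threshold)


def fdr_curve(coverage: CoverageTrack, model: NBGCModel, p_grid) -> "pd.DataFrame":
    """Empirical FDR: model-expected vs observed genome fraction per p cutoff.

    observed_fraction is the fraction of bases whose depth meets the local
    significance threshold; null_fraction is the fraction the fitted model
    itself expects; fdr = null/observed, capped at 1, NaN when nothing is
    observed.
    """
    import pandas as pd

    rows = []
    genome_size = sum(len(d) for d in coverage.depth.values())
    for alpha in p_grid:
        thresholds = model.depth_thresholds(alpha)
        observed = 0
        for chrom, depth in coverage.depth.items():
            bins = model.window_bins[chrom]
            base_thr = thresholds[bins][
                np.minimum(
                    np.arange(len(depth)) // model.window_size, len(bins) - 1
                )
            ]
            observed += int((depth >= base_thr).sum())
        obs_frac = observed / genome_size
        null_frac = model.null_genome_fraction(alpha)
        fdr = min(null_frac / obs_frac, 1.0) if obs_frac > 0 else float("nan")
        rows.append(
            {
                "p_cutoff": alpha,
                "observed_fraction": obs_frac,
                "null_fraction": null_frac,
                "fdr": fdr,
            }
        )
    return pd.DataFrame(rows)
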