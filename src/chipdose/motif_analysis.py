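"""Discriminative de-novo motif discovery with EM refinement.

Foreground windows are taken around peak summits; background windows are
random genomic regions matched on GC content and log-scaled distance to the
nearest TSS.  Discovery enumerates k-mer seeds (counting presence per
sequence on either strand), scores each by a two-proportion z-statistic of
foreground vs background presence, greedily degenerates seed positions over
a small IUPAC subset when that sharpens the discrimination, masks accepted
motifs, and repeats.  Each accepted seed is refined to a position weight
matrix by ZOOPS ("zero or one occurrence per sequence") EM over the
foreground, with a Dirichlet pseudocount prior; the EM objective (data
log-likelihood plus log-prior) is non-decreasing at every iteration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import Genome, GenomicInterval
from .ebox_analysis import IUPAC, matches_pattern, revcomp

logger = logging.getLogger(__name__)

_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i

_DEGENERATE_TRY = {
    "A": ["R", "W", "M", "N"],
    "C": ["Y", "S", "M", "N"],
    "G": ["R", "S", "K", "N"],
    "T": ["Y", "W", "K", "N"],
}


def encode(seqs: list[str]) -> np.ndarray:
    """Sequences (equal length) as an (n, width) uint8 array; non-ACGT -> 4."""
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _CODE[arr].reshape(len(seqs), -1)


@dataclass
class SequenceSet:
    """Fixed-width windows playing the foreground or background role."""

    role: str
    windows: list[GenomicInterval]
    sequences: list[str]

    def __post_init__(self) -> None:
        widths = {len(s) for s in self.sequences}
        if len(widths) > 1:
            raise ValueError("all windows in a SequenceSet must share one width")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def width(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


@dataclass
class PWM:
    """Position weight matrix over {A,C,G,T} with its estimation context."""

    probabilities: np.ndarray          # (width, 4), columns sum to 1
    background_frequencies: np.ndarray  # (4,)
    pseudocount: float = 0.25
    converged: bool = True
    gamma: float = float("nan")        # fitted per-sequence occurrence prior
    log_likelihood_path: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if (p <= 0).any():
            raise ValueError("PWM entries must be strictly positive")
        self.probabilities = p

    @property
    def width(self) -> int:
        return self.probabilities.shape[0]

    def consensus(self) -> str:
        """IUPAC consensus: bases holding >= 2x the uniform share per column."""
        letters = []
        inv = {frozenset(v): k for k, v in IUPAC.items()}
        for col in self.probabilities:
            strong = frozenset("ACGT"[b] for b in np.flatnonzero(col >= 0.5))
            if not strong:
                strong = frozenset(
                    "ACGT"[b] for b in np.flatnonzero(col >= 0.25)
                )
            letters.append(inv.get(strong, "N"))
        return "".join(letters)


@dataclass
class MotifResult:
    consensus: str
    pwm: PWM
    z_score: float
    ratio: float
    fg_frac: float
    bg_frac: float


def pwm_from_word(word: str, background: np.ndarray, strong: float = 0.85) -> PWM:
    """Seed PWM: the word's allowed bases share ``strong`` probability mass."""
    probs = np.zeros((len(word), 4))
    for i, letter in enumerate(word):
        allowed = [("ACGT").index(b) for b in IUPAC[letter]]
        if len(allowed) == 4:
            probs[i] = 0.25
        else:
            probs[i, :] = (1.0 - strong) / (4 - len(allowed))
            probs[i, allowed] = strong / len(allowed)
    return PWM(probs, background)


def base_composition(sequences: list[str]) -> np.ndarray:
    codes = encode(sequences)
    counts = np.bincount(codes[codes < 4].ravel(), minlength=4).astype(float)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# background sampling


def _tss_distance(genome: Genome, chrom: str, center: int) -> float:
    if not genome.tss:
        return float("inf")
    best = math.inf
    for t in genome.tss:
        if t.chrom == chrom:
            best = min(best, abs(center - t.start))
    return best


def _tss_bin(dist: float, edges: np.ndarray) -> int:
    return int(np.searchsorted(edges, math.log10(1.0 + dist), side="right"))


def sample_background(
    genome: Genome,
    foreground: SequenceSet,
    n_per_fg: int = 1,
    gc_tolerance: float = 0.02,
    tss_bins: int = 10,
    seed: int = 0,
    max_tries: int = 2000,
) -> SequenceSet:
    """Random genomic windows matched to the foreground on GC and TSS distance.

    For every foreground window, ``n_per_fg`` background windows are drawn
    with |GC difference| <= gc_tolerance and the same log10-scaled
    TSS-distance bin, never overlapping any foreground window.  If the GC
    constraint cannot be met within ``max_tries`` draws it is relaxed for
    that window (logged).
    """
    rng = np.random.default_rng(seed)
    width = foreground.width
    chroms = list(genome.sequences)
    lengths = genome.chrom_lengths
    # precompute TSS positions per chromosome for fast distance queries
    tss_pos = {c: np.array(sorted(
        t.start for t in (genome.tss or []) if t.chrom == c
    )) for c in chroms}

    def tss_dist(chrom: str, center: int) -> float:
        pos = tss_pos.get(chrom)
        if pos is None or len(pos) == 0:
            return float("inf")
        i = int(np.searchsorted(pos, center))
        cands = []
        if i < len(pos):
            cands.append(abs(int(pos[i]) - center))
        if i > 0:
            cands.append(abs(int(pos[i - 1]) - center))
        return float(min(cands))

    fg_gc = []
    fg_dist = []
    for iv, s in zip(foreground.windows, foreground.sequences):
        counts = np.bincount(encode([s])[0], minlength=5)
        acgt = counts[:4].sum()
        fg_gc.append((counts[1] + counts[2]) / max(acgt, 1))
        fg_dist.append(math.log10(1.0 + tss_dist(iv.chrom, (iv.start + iv.end) // 2)))
    finite = [d for d in fg_dist if math.isfinite(d)]
    if finite and tss_bins > 1:
        edges = np.quantile(finite, np.linspace(0, 1, tss_bins + 1)[1:-1])
    else:
        edges = np.array([])
    fg_bins = [int(np.searchsorted(edges, d, side="right")) for d in fg_dist]

    fg_spans: dict[str, list[tuple[int, int]]] = {}
    for iv in foreground.windows:
        fg_spans.setdefault(iv.chrom, []).append((iv.start, iv.end))
    fg_arr = {
        c: np.asarray(sorted(v), dtype=np.int64) for c, v in fg_spans.items()
    }

    def overlaps_fg(chrom: str, start: int, end: int) -> bool:
        spans = fg_arr.get(chrom)
        if spans is None:
            return False
        i = int(np.searchsorted(spans[:, 1], start, side="right"))
        return i < len(spans) and spans[i, 0] < end

    out_windows: list[GenomicInterval] = []
    out_seqs: list[str] = []
    relaxed = 0
    for gc_target, want_bin in zip(fg_gc, fg_bins):
        for _ in range(n_per_fg):
            chosen = None
            fallback = None
            for attempt in range(max_tries):
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                start = int(rng.integers(0, lengths[chrom] - width))
                if overlaps_fg(chrom, start, start + width):
                    continue
                s = genome.sequences[chrom][start : start + width]
                codes = _CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
                acgt = (codes < 4).sum()
                if acgt < width:
                    continue
                gc = ((codes == 1) | (codes == 2)).sum() / width
                d = math.log10(1.0 + tss_dist(chrom, start + width // 2))
                if int(np.searchsorted(edges, d, side="right")) != want_bin:
                    continue
                fallback = (chrom, start, s)
                if abs(gc - gc_target) <= gc_tolerance:
                    chosen = (chrom, start, s)
                    break
            if chosen is None:
                chosen = fallback
                relaxed += 1
            if chosen is None:
                raise RuntimeError("could not place a background window at all")
            chrom, start, s = chosen
            out_windows.append(GenomicInterval(chrom, start, start + width))
            out_seqs.append(s)
    if relaxed:
        logger.warning(
            "background sampling: GC constraint relaxed for %d windows", relaxed
        )
    return SequenceSet("background", out_windows, out_seqs)


# ---------------------------------------------------------------------------
# discovery


def _presence_exact(codes: np.ndarray, codes_rc: np.ndarray, k: int) -> np.ndarray:
    """Per-word presence counts over sequences for all 4**k words (either strand).

    Returns an int array of length 4**k: the number of sequences containing
    each word at least once on the forward or reverse strand.
    """
    n, width = codes.shape
    nwords = 4**k
    mult = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    counts = np.zeros(nwords, dtype=np.int64)
    for i in range(n):
        ids: list[np.ndarray] = []
        for strandcodes in (codes, codes_rc):
            row = strandcodes[i].astype(np.int64)
            if width < k:
                continue
            win = np.lib.stride_tricks.sliding_window_view(row, k)
            valid = (win < 4).all(axis=1)
            if valid.any():
                ids.append((win[valid] * mult).sum(axis=1))
        if ids:
            uniq = np.unique(np.concatenate(ids))
            counts[uniq] += 1
    return counts


def _word_presence(codes: np.ndarray, word: str) -> np.ndarray:
    """Boolean per-sequence presence of a degenerate word on either strand."""
    out = np.zeros(len(codes), dtype=bool)
    for w in (word, revcomp(word)):
        k = len(w)
        allowed = np.zeros((k, 5), dtype=bool)
        for j, letter in enumerate(w):
            for b in IUPAC[letter]:
                allowed[j, "ACGT".index(b)] = True
        win = np.lib.stride_tricks.sliding_window_view(codes, k, axis=1)
        hit = allowed[np.arange(k)[None, None, :], win].all(axis=2).any(axis=1)
        out |= hit
    return out


def two_proportion_z(fg_hits: int, nf: int, bg_hits: int, nb: int) -> float:
    """z = (pf - pb) / sqrt(p(1-p)(1/nf + 1/nb)) with pooled p."""
    pf, pb = fg_hits / nf, bg_hits / nb
    pool = (fg_hits + bg_hits) / (nf + nb)
    denom = math.sqrt(max(pool * (1 - pool), 1e-12) * (1 / nf + 1 / nb))
    return (pf - pb) / denom


def _id_to_word(wid: int, k: int) -> str:
    letters = []
    for _ in range(k):
        letters.append("ACGT"[wid % 4])
        wid //= 4
    return "".join(reversed(letters))


def _mask_word(seqs: list[str], word: str) -> list[str]:
    """Replace occurrences of word (either strand) with N."""
    out = []
    pats = {word, revcomp(word)}
    k = len(word)
    for s in seqs:
        chars = list(s)
        for j in range(len(s) - k + 1):
            sub = s[j : j + k]
            if any(matches_pattern(sub, p) for p in pats):
                chars[j : j + k] = ["N"] * k
        out.append("".join(chars))
    return out


def discover_motifs(
    fg: SequenceSet,
    bg: SequenceSet,
    k_range=(6, 8),
    n_motifs: int = 5,
    n_seed_candidates: int = 30,
    min_abs_z: float = 3.0,
    em_kwargs: dict | None = None,
) -> list[MotifResult]:
    """Greedy discriminative discovery of up to ``n_motifs`` motifs.

    Seeds are the exact k-mers (k in ``k_range``) with the largest |z|;
    each is greedily degenerated position-by-position while |z| improves,
    then refined by ZOOPS EM on the foreground.  After accepting a motif its
    matches are masked (replaced by N) in both sets before the next round.
    Discovery stops when no word reaches ``min_abs_z``.
    """
    ks = list(range(k_range[0], k_range[1] + 1)) if isinstance(k_range, tuple) else list(k_range)
    if max(ks) > fg.width or max(ks) > bg.width:
        raise ValueError("k_range exceeds window width")
    if not len(fg) or not len(bg):
        raise ValueError("foreground and background must be non-empty")
    fg_seqs, bg_seqs = list(fg.sequences), list(bg.sequences)
    background = base_composition(bg_seqs)
    results: list[MotifResult] = []
    nf, nb = len(fg_seqs), len(bg_seqs)
    for _ in range(n_motifs):
        fg_codes, bg_codes = encode(fg_seqs), encode(bg_seqs)
        fg_rc = np.where(fg_codes[:, ::-1] < 4, 3 - fg_codes[:, ::-1].astype(np.int16), 4).astype(np.uint8)
        bg_rc = np.where(bg_codes[:, ::-1] < 4, 3 - bg_codes[:, ::-1].astype(np.int16), 4).astype(np.uint8)
        best_word, best_z = None, 0.0
        for k in ks:
            cf = _presence_exact(fg_codes, fg_rc, k)
            cb = _presence_exact(bg_codes, bg_rc, k)
            occur = np.flatnonzero((cf + cb) > 0)
            if not len(occur):
                continue
            pf, pb = cf[occur] / nf, cb[occur] / nb
            pool = (cf[occur] + cb[occur]) / (nf + nb)
            z = (pf - pb) / np.sqrt(
                np.maximum(pool * (1 - pool), 1e-12) * (1 / nf + 1 / nb)
            )
            order = np.argsort(-np.abs(z))[:n_seed_candidates]
            j = order[0]
            if abs(z[j]) > abs(best_z):
                best_word, best_z = _id_to_word(int(occur[j]), k), float(z[j])
        if best_word is None or abs(best_z) < min_abs_z:
            break
        # greedy degeneration while |z| improves
        word, z_cur = best_word, best_z
        improved = True
        while improved:
            improved = False
            for pos in range(len(word)):
                if word[pos] not in _DEGENERATE_TRY:
                    continue
                for repl in _DEGENERATE_TRY[word[pos]]:
                    cand = word[:pos] + repl + word[pos + 1 :]
                    fh = int(_word_presence(fg_codes, cand).sum())
                    bh = int(_word_presence(bg_codes, cand).sum())
                    zc = two_proportion_z(fh, nf, bh, nb)
                    if abs(zc) > abs(z_cur) + 1e-9:
                        word, z_cur = cand, zc
                        improved = True
        fg_hits = int(_word_presence(fg_codes, word).sum())
        bg_hits = int(_word_presence(bg_codes, word).sum())
        fg_frac, bg_frac = fg_hits / nf, bg_hits / nb
        ratio = fg_frac / bg_frac if bg_frac > 0 else float("inf")
        pwm = em_refine(
            word,
            SequenceSet(fg.role, fg.windows, fg_seqs),
            background=background,
            **(em_kwargs or {}),
        )
        results.append(
            MotifResult(
                consensus=word,
                pwm=pwm,
                z_score=z_cur,
                ratio=ratio,
                fg_frac=fg_frac,
                bg_frac=bg_frac,
            )
        )
        fg_seqs = _mask_word(fg_seqs, word)
        bg_seqs = _mask_word(bg_seqs, word)
    return results


# ---------------------------------------------------------------------------
# EM refinement (ZOOPS)


def em_refine(
    seed_word: str,
    fg: SequenceSet,
    background: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-4,
    pseudocount: float = 0.25,
) -> PWM:
    """ZOOPS EM refinement of a seed word into a PWM on the foreground set.

    The generative model: with probability gamma a sequence carries exactly
    one motif occurrence at a uniformly chosen offset and strand, the rest
    of the sequence drawn from the background composition; with probability
    1 - gamma the whole sequence is background.  The M-step uses a Dirichlet
    (pseudocount) prior on PWM columns; the tracked objective is the data
    log-likelihood plus the log-prior and is non-decreasing by construction.
    """
    if background is None:
        background = base_composition(fg.sequences)
    codes = encode(fg.sequences)
    n, width = codes.shape
    k = len(seed_word)
    if k > width:
        raise ValueError("seed word longer than windows")
    pwm = pwm_from_word(seed_word, background).probabilities
    if not _word_presence(codes, seed_word).any():
        return PWM(pwm, background, pseudocount, converged=False, gamma=0.0)
    noff = width - k + 1
    win = np.lib.stride_tricks.sliding_window_view(codes, k, axis=1)  # (n, noff, k)
    valid = (win < 4).all(axis=2)
    win_safe = np.minimum(win, 3)
    logbg = np.log(background)
    # background log-prob of each window placement (to divide out)
    win_bg = logbg[win_safe].sum(axis=2)
    seq_bg = np.where(codes < 4, logbg[np.minimum(codes, 3)], 0.0).sum(axis=1)
    gamma = 0.5
    ll_path = []
    converged = False
    for it in range(max_iter):
        logpwm = np.log(pwm)
        logpwm_rc = np.log(pwm[::-1, ::-1])  # reverse-complement PWM
        s_fwd = logpwm[np.arange(k)[None, None, :], win_safe].sum(axis=2)
        s_rev = logpwm_rc[np.arange(k)[None, None, :], win_safe].sum(axis=2)
        with np.errstate(invalid="ignore"):
            lr_f = np.where(valid, s_fwd - win_bg, -np.inf)
            lr_r = np.where(valid, s_rev - win_bg, -np.inf)
        # joint log-weights of (occurrence at offset j, strand)
        prior_occ = gamma / (2 * noff) if gamma > 0 else 0.0
        log_prior_occ = math.log(prior_occ) if prior_occ > 0 else -np.inf
        lw = np.concatenate(
            [
                lr_f + log_prior_occ,
                lr_r + log_prior_occ,
                np.full((n, 1), math.log(max(1 - gamma, 1e-300))),
            ],
            axis=1,
        )
        m = lw.max(axis=1, keepdims=True)
        w = np.exp(lw - m)
        tot = w.sum(axis=1, keepdims=True)
        post = w / tot
        # objective: sum_i [log sum + seq_bg_i] + Dirichlet log-prior
        ll = float((np.log(tot[:, 0]) + m[:, 0] + seq_bg).sum())
        ll += float(pseudocount * np.log(pwm).sum())
        ll_path.append(ll)
        post_f, post_r = post[:, :noff], post[:, noff : 2 * noff]
        post_0 = post[:, -1]
        # M-step: PWM counts
        counts = np.full((k, 4), pseudocount)
        for b in range(4):
            is_b = win_safe == b
            counts[:, b] += (post_f[:, :, None] * is_b).sum(axis=(0, 1))
            # reverse strand: position l of motif reads complement of window
            # base at k-1-l
            is_b_rc = win_safe[:, :, ::-1] == (3 - b)
            counts[:, b] += (post_r[:, :, None] * is_b_rc).sum(axis=(0, 1))
        new_pwm = counts / counts.sum(axis=1, keepdims=True)
        gamma = float(np.clip(1.0 - post_0.mean(), 1e-6, 1 - 1e-6))
        delta = float(np.abs(new_pwm - pwm).max())
        pwm = new_pwm
        if delta < tol:
            converged = True
            break
    return PWM(
        pwm,
        background,
        pseudocount,
        converged=converged,
        gamma=gamma,
        log_likelihood_path=np.asarray(ll_path),
    )


# ---------------------------------------------------------------------------
# scoring


def pwm_score(pwm: PWM, window: str) -> float:
    """Best log2-odds of the PWM over all offsets and both strands.

    Placements containing a non-ACGT base are skipped; NaN when no valid
    placement exists.
    """
    k = pwm.width
    if len(window) < k:
        raise ValueError("window shorter than PWM width")
    codes = _CODE[np.frombuffer(window.encode(), dtype=np.uint8)]
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win < 4).all(axis=1)
    if not valid.any():
        return float("nan")
    safe = np.minimum(win[valid], 3)
    logodds = np.log2(pwm.probabilities / pwm.background_frequencies)
    logodds_rc = logodds[::-1, ::-1]
    s_f = logodds[np.arange(k)[None, :], safe].sum(axis=1)
    s_r = logodds_rc[np.arange(k)[None, :], safe].sum(axis=1)
    return float(max(s_f.max(), s_r.max()))


def avg_pwm_by_rank(
    peaks,
    pwm: PWM,
    genome: Genome,
    bin_width: int = 5000,
    floor_score: float = -10.0,
) -> pd.DataFrame:
    """Mean best-E-box PWM score per peak-rank bin.

    Each peak contributes the maximum PWM score among E-boxes inside its
    interval (scored with enough flanking sequence for every PWM offset);
    peaks with no E-box contribute ``floor_score``.
    """
    pad = pwm.width  # flank so a w-wide PWM can slide across each E-box
    scores = np.full(len(peaks.peaks), floor_score)
    for i, p in enumerate(peaks.peaks):
        seq = genome.sequences[p.interval.chrom]
        region = seq[p.interval.start : p.interval.end]
        best = None
        j = 0
        while True:
            j = region.find("CA", j)
            if j < 0 or j + 6 > len(region):
                break
            if region[j + 4 : j + 6] == "TG":
                gstart = p.interval.start + j
                lo = max(0, gstart - pad)
                hi = min(len(seq), gstart + 6 + pad)
                s = pwm_score(pwm, seq[lo:hi])
                if not math.isnan(s) and (best is None or s > best):
                    best = s
            j += 1
        if best is not None:
            scores[i] = best
    ranks = np.array([p.rank for p in peaks.peaks])
    bins = (ranks - 1) // bin_width
    rows = []
    for b in sorted(set(bins)):
        sel = bins == b
        rows.append(
            {
                "rank_bin_start": int(b * bin_width + 1),
                "rank_bin_end": int(min((b + 1) * bin_width, ranks.max())),
                "mean_score": float(scores[sel].mean()),
                "n_peaks": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def motif_table(results: list[MotifResult]) -> pd.DataFrame:
    """Summary table: consensus, z (signed: + enriched, - depleted), ratio,
    fg_frac, bg_frac."""
    return pd.DataFrame(
        [
            {
                "consensus": r.consensus,
                "z_score": r.z_score,
                "ratio": r.ratio,
                "fg_frac": r.fg_frac,
                "bg_frac": r.bg_frac,
            }
            for r in results
        ]
    )


def write_meme(pwms: dict[str, PWM], path) -> None:
    """Write PWMs in MEME minimal text format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        first = next(iter(pwms.values()), None)
        if first is not None:
            bg = first.background_frequencies
            fh.write(
                "Background letter frequencies\n"
                f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n"
            )
        for name, pwm in pwms.items():
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width}\n"
            )
            for row in pwm.probabilities:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")
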