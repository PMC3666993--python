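# Methods

This note documents the statistical models, the synthetic data generator,
and the numerical choices behind `chipdose`, in the package's own words.

## Read processing

Reads are mapped intervals (BED6). Exact duplicates — identical
(chromosome, start, end, strand) — are removed once per sample to damp PCR
amplification; the key is the full mapped span rather than the 5' position
alone, which is the closest interval-level proxy for "duplicate sequence".
Each read is then extended in its sequencing orientation to the nominal
fragment length (default 200 bases, matching typical ChIP fragment
selection) and per-base depth is accumulated with difference arrays.
Extension clips at chromosome boundaries rather than dropping reads, so
total depth mass always equals the sum of clipped extended lengths — an
invariant the tests enforce on arbitrary inputs. Chromosome exclusion (for
real mouse data, chrX/chrY) happens at ingestion, before any statistics.
Cross-sample comparisons that depend on read depth (height ratios, E-box
coverage CCDFs) first sub-sample all read sets to the common minimum,
uniformly without replacement, seeded.

## GC-conditioned negative-binomial background

ChIP background depth is overdispersed and co-varies with GC content, so
the genome is tiled into non-overlapping windows (default 500 bases; N
bases are excluded from the GC fraction, and all-N windows inherit the
genome-mean GC so they land in a well-populated bin). Windows are grouped
into GC bins of width 0.05 and a negative binomial NB(mu_g, r_g) is fitted
per bin.

**What is fitted.** The per-bin observable is the depth at each window's
midpoint. When the window is at least twice the fragment length, the reads
that can cover the midpoint all originate in that window, and each of the
window's reads covers it with probability L/W independently — midpoint
depth is then an exact binomial thinning of the window's read count.
Thinning preserves the NB dispersion r and scales the mean by L/W, so the
fitted law (i) recovers the reads-per-window parameters by a pure mean
rescaling and (ii) lives directly on the per-base depth scale on which peak
significance is evaluated. Depth at off-midpoint positions mixes
contributions from two adjacent windows and is slightly lighter-tailed
than the midpoint law, which makes genome-wide p-values mildly
conservative; the null-calibration tests bound this effect.

**Robustness to signal.** At realistic site densities a third of windows
can carry bound-site reads, so a naive moment fit is badly inflated. The
per-bin fit therefore proceeds in two paths:

1. a *reference* fit by truncated maximum likelihood on counts at or below
   the 60% empirical quantile, conditioning on the cut. Everything above
   the cut is ignored outright (not modeled as a censored tail), so no
   amount of upper-tail contamination can pull this fit;
2. if the fraction of counts beyond the reference's 2% tail point is
   consistent with a clean sample (<= 4%), the data are treated as
   uncontaminated and refitted with the efficient estimator: method of
   moments on the top-5%-trimmed sample, iterated to self-consistency
   against the model-implied trimmed moments. The model-implied trimming
   places a fractional atom at the discrete cut so that the trimmed mass
   matches the empirical quantile exactly — without this, ties at the cut
   bias the dispersion by tens of percent. A first alarm can be a false
   positive of the reference's own sampling noise, so the reference is
   refit once with the cut moved up to the alarm threshold and the tail
   re-tested; only a persistent excess keeps the robust reference.

On pure background this recovers the generator's per-bin mean within ~2-4%
and dispersion within ~10-15% at 2,000+ windows per bin; under heavy
contamination the mean stays within ~10-15% and the dispersion within
~25%, always erring conservative. Degenerate inputs (constant counts,
variance <= mean) fall back to Poisson, encoded as r = infinity. Bins with
fewer than 100 windows inherit the nearest fitted bin.

**Peaks.** A base is significant at level alpha when its depth reaches the
smallest count whose NB tail in the local window's GC bin is <= alpha.
Maximal significant runs closer than 200 bases (one fragment) are merged;
each region reports its summit (leftmost maximum), height (summit depth)
and the NB tail p-value of the height — pairing p-value thresholds with
"read cutoff" heights. Peaks are ranked by ascending p-value, ties broken
by descending height, then coordinate, so ranks are deterministic. Control
peaks are called from the pooled control reads at p = 1e-3 and any sample
peak overlapping one by >= 1 base is removed, with ranks recomputed.

**Empirical FDR.** For each p cutoff, the observed fraction of the genome
at significant depth is compared with the fraction the fitted model itself
expects (summed over GC bins at the same integer thresholds); their ratio
null/observed, capped at 1, is the FDR and is reported as NaN when nothing
is observed. On a desk-scale genome the expectation at stringent cutoffs
(p <= 1e-6 on 6 Mb) is below one base, so calibration statements are only
meaningful where the null expects a measurable number of bases; the tests
apply the 2-fold band where the expectation is >= 20 bases and a 10x
envelope on raw counts below that.

## Concordance of two ranked peak sets

No parametric null captures the between-system variation of two ChIP
samples, so comparison is rank-based: for cutoffs x, y on the two ranked
lists, the fraction of the top-x peaks of one sample overlapping (>= 1
base) the top-y of the other, divided by min(x, y). When y < x the
numerator is counted over the smaller list, keeping the fraction <= 1. The
grid is computed efficiently by precomputing, for each peak, the minimal
rank of any overlapping partner. Matched-locus heights for the asinh-
Pearson correlation are taken at the union of peak summits, with a locus
missing from one sample still read from that sample's coverage (not zero).
Height-ratio distributions equalize read counts by sub-sampling first and
summarize log2((h2+1)/(h1+1)) quantiles with a pseudo-count of 1.

## E-box analyses

CANNTG is reverse-complement symmetric as a pattern class, so one forward
scan finds each physical site exactly once (verified against a both-strand
scan). Variants are canonicalized by internal dinucleotide — a variant and
its reverse complement (CACCTG/CAGGTG) form one class. Site coverage is
the maximum depth over the 6 bases (peak-height semantics); site p-values
reuse the sample's peak-calling background model via the local GC bin.
Rank bins follow the top-1K / 1001-10K / ... scheme with a genome-
background row. Consensus (RRCAGSTG) matching applies on either strand —
a forward-text CASCTGYY match is the consensus read on the reverse strand.
Coverage CCDFs P(depth > t) are evaluated on log2-spaced thresholds t =
1, 2, 4, ... shared across samples, after equal-count sub-sampling, and
only for sites uniquely mappable over the E-box +/- 200 bases.
Accessibility classes follow half-open score intervals (0,1], (1,2],
(2,inf); sites without a score are labeled unknown, logged, and excluded.

## Discriminative motif discovery and EM refinement

Foreground windows are peak summits +/- 50 bases; background windows are
random genomic windows matched per foreground window on GC (tolerance
0.02, relaxed with a logged warning after bounded retries) and on the
log10-scaled distance-to-TSS decile, never overlapping a foreground
window. Discovery enumerates all exact k-mers (k in the requested range)
by integer encoding, counts presence per sequence on either strand, and
scores each word with a two-proportion z-statistic (pooled variance),
whose sign marks enrichment vs depletion. The best seed is greedily
degenerated position-by-position over {R, Y, S, W, K, M, N} while |z|
improves, accepted, refined, masked out of both sets (matches replaced by
N), and the search repeats up to n_motifs times or until no word reaches
|z| >= 3.

EM refinement uses the ZOOPS model: with probability gamma a sequence
carries exactly one motif occurrence at a uniform offset and strand over a
background of the set's base composition. The M-step uses a Dirichlet
pseudocount prior (0.25 per base per column), and the tracked objective —
data log-likelihood plus log-prior — is non-decreasing at every iteration
by the standard MAP-EM argument; the tests assert this on every run.
Convergence is declared when the largest PWM entry change drops below 1e-4
(at most 100 iterations; non-convergence returns the current PWM flagged).
A seed with no foreground occurrence returns the seed-derived PWM flagged,
with gamma 0. PWM scores are best-over-offsets-and-strands log2 odds
against background frequencies; placements containing non-ACGT bases are
skipped, and a window with no valid placement scores NaN. The average-PWM-
by-rank curve assigns each peak the maximum score among E-boxes inside its
interval (each E-box scored with enough flanking sequence for every PWM
offset); peaks without an E-box contribute a floor score of -10, roughly a
background-level log-odds, so they drag the bin mean down rather than
being silently dropped.

The discriminative score is a two-proportion z-test rather than a
regression: it has the same sign convention and presence/absence semantics
as the fg.frac/bg.frac statistics it accompanies, and it is exactly
testable by hand.

## The synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
desk scale, with full ground truth:

- **Genome**: 3 chromosomes x 2 Mb by default; per-base GC probability
  follows a sinusoid (mean 0.45, amplitude 0.10, period 400 kb, random
  phase per chromosome), giving smooth spatial GC variation across ~6 GC
  bins. A few 5 kb tracts are duplicated elsewhere and both copies marked
  non-mappable (the repeat/mappability proxy). Synthetic TSS positions
  support the TSS-matched background sampling.
- **Sites**: 5,000 true sites, spaced at least ~1 kb apart, with
  log-normal affinities (sigma = 1). Each site is planted on an E-box whose
  quality couples to affinity: with probability 0.05 + 0.90 q^3 (q the
  affinity quantile) the site gets the full consensus RRCAGSTG (internal
  GC or CC class); otherwise a random non-preferred CANNTG. The cubic makes
  motif quality rise steeply among the strongest sites — the ones that
  become callable peaks — so the motif-score-vs-rank relation is visible in
  the called range rather than saturating below it.
- **Accessibility**: every CAGCTG E-box gets a latent log-normal score
  thresholded at 1 and 2 into low/moderate/high. Accessibility couples to
  occupancy twice, as in chromatin reality: bound E-boxes draw their class
  from a mixture skewed toward open chromatin (0.05/0.25/0.70 vs
  0.55/0.25/0.20 for unbound), and the class multiplies the site's
  occupancy weight (0.3x / 1x / 2.5x).
- **Reads**: foreground counts per site are multinomial with weights
  proportional to (accessibility-adjusted) affinity; the baseline sample
  carries 150,000 foreground reads and the overexpressed sample
  dose_factor = 4 times that, over the same sites. Reads are strand-split
  (forward 5' of the summit, reverse 3') at uniform offsets within one
  fragment length, so extension re-creates the summit. Background reads
  are drawn per window from the window's GC bin NB law (default mean
  25 + 30 (gc - 0.45) reads per 500-base window, dispersion r = 5 — a
  realistic ChIP overdispersion that also keeps r identifiable from
  thinned midpoint counts at this scale) and placed uniformly. Control
  samples contain background only, plus a handful of 400-read artifact
  spikes at positions shared across control replicates. Totals are roughly
  0.4 M (baseline) and 0.9 M (overexpressed) reads.

Everything is deterministic given the seed, and the ground truth records
site positions, affinities, planted variants, accessibility classes and
scores, artifact positions, and per-read origin labels.

**What the generator does not model** — and hence what passing tests do
not show about real data: sequencing errors and base qualities, mapping
ambiguity beyond the binary mask, PCR duplicates, fragment-length
variation, chromatin-state covariates beyond the single accessibility
score, inter-replicate biological variability, and the genome-scale rank
depth of real data (rank analyses here use bins of hundreds, not 5,000).
The real study's headline percentages depend on its deposited sequencing
data and the mm9 genome; this package demonstrates the *properties* of the
method (calibration, recovery, dose response, preference detection) on
conditions it fully controls.

## Problem sizes and determinism

Default analyses run on the 6 Mb / ~1.3 M read fixture in tens of seconds;
the test suite builds one such fixture per session and reuses it. The
pure-background calibration uses the same genome scale with foreground
mass zero. Motif experiments use 500 + 500 windows of width 101. All
randomness flows through explicit integer seeds (numpy Generator); rerun
outputs are byte-identical.

## Known limitations

- Depth p-values at off-midpoint bases are mildly conservative (see
  above); the FDR table quantifies the effect rather than hiding it.
- Under weak, dense contamination the background mean can absorb a few
  percent of signal mass — indistinguishable from background by counts
  alone — so the weakest sites are priced into the null; this is the
  conservative direction.
- The overlap grid is exact but O(cells x peaks-per-lookup); at genome
  scale (110 K peaks, 22 x 22 cells) it remains inexpensive because
  partner ranks are precomputed once.
- Greedy degenerate search explores single-position refinements only; a
  motif whose information is spread across correlated positions could be
  found as an exact seed but refined suboptimally. EM refinement mitigates
  this in PWM space.
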