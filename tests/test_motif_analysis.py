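"""PWMs, discriminative discovery, ZOOPS EM, scoring, background sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chipdose.ebox_analysis import revcomp
from chipdose.motif_analysis import (
    PWM,
    SequenceSet,
    base_composition,
    discover_motifs,
    em_refine,
    motif_table,
    pwm_from_word,
    pwm_score,
    sample_background,
    two_proportion_z,
    write_meme,
)

UNIFORM = np.full(4, 0.25)


def rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestPWM:
    def test_columns_must_normalize(self):
        with pytest.raises(ValueError):
            PWM(np.array([[0.5, 0.5, 0.1, 0.1]]), UNIFORM)

    def test_entries_must_be_positive(self):
        with pytest.raises(ValueError):
            PWM(np.array([[1.0, 0.0, 0.0, 0.0]]), UNIFORM)

    def test_seed_word_pwm_prefers_its_letters(self):
        pwm = pwm_from_word("CAGS", UNIFORM)
        assert pwm.probabilities[0, 1] > 0.8          # C
        assert pwm.probabilities[3, 1] == pytest.approx(0.425)  # S splits C/G
        assert pwm.probabilities[3, 2] == pytest.approx(0.425)


class TestScore:
    def test_background_pwm_scores_zero_everywhere(self):
        pwm = PWM(np.tile(UNIFORM, (4, 1)), UNIFORM)
        assert pwm_score(pwm, "ACGTACGT") == pytest.approx(0.0, abs=1e-12)

    def test_delta_pwm_matches_hand_computation(self):
        strong = 0.85
        pwm = pwm_from_word("CAGCTG", UNIFORM)
        expected = 6 * math.log2(strong / 0.25)
        assert pwm_score(pwm, "TTCAGCTGTT") == pytest.approx(expected, rel=1e-12)

    def test_strand_symmetry(self, rng):
        pwm = PWM(
            np.random.default_rng(1).dirichlet(np.ones(4) * 2, size=6), UNIFORM
        )
        for _ in range(20):
            w = rand_seq(rng, 15)
            assert pwm_score(pwm, w) == pytest.approx(
                pwm_score(pwm, revcomp(w)), rel=1e-9
            )

    def test_ambiguous_bases_skip_placements(self):
        pwm = pwm_from_word("CAGC", UNIFORM)
        assert not math.isnan(pwm_score(pwm, "NNCAGCNN"))
        assert math.isnan(pwm_score(pwm, "NNNNN"))

    def test_window_shorter_than_pwm_rejected(self):
        with pytest.raises(ValueError):
            pwm_score(pwm_from_word("CAGCTG", UNIFORM), "CAG")


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_score_strand_symmetry_property(seed):
    rng = np.random.default_rng(seed)
    pwm = PWM(rng.dirichlet(np.ones(4), size=5), UNIFORM)
    w = rand_seq(rng, 12)
    assert pwm_score(pwm, w) == pytest.approx(pwm_score(pwm, revcomp(w)), rel=1e-9)


class TestDiscovery:
    def test_z_statistic_matches_hand_formula(self):
        z = two_proportion_z(15, 20, 5, 20)
        pf, pb, p = 0.75, 0.25, 0.5
        expected = (pf - pb) / math.sqrt(p * (1 - p) * (1 / 20 + 1 / 20))
        assert z == pytest.approx(expected, rel=1e-12)
        assert two_proportion_z(2, 20, 10, 20) < 0  # depletion flips the sign

    def test_planted_word_recovered_with_exact_fractions(self, rng):
        fg_seqs, bg_seqs = [], []
        for i in range(100):
            s = rand_seq(rng, 60)
            if i < 80:
                j = rng.integers(0, 54)
                s = s[:j] + "CAGCTG" + s[j + 6 :]
            fg_seqs.append(s)
        for i in range(100):
            s = rand_seq(rng, 60)
            while "CAGCTG" in s or "CAGCTG" in revcomp(s):
                s = rand_seq(rng, 60)
            if i < 10:
                j = rng.integers(0, 54)
                s = s[:j] + "CAGCTG" + s[j + 6 :]
            bg_seqs.append(s)
        fg = SequenceSet("foreground", [], fg_seqs)
        bg = SequenceSet("background", [], bg_seqs)
        (top, *_rest) = discover_motifs(fg, bg, k_range=(6, 6), n_motifs=1)
        # CAGCTG is palindromic, so presence counts are exact
        assert top.fg_frac >= 0.8
        assert top.bg_frac == pytest.approx(0.1, abs=0.02)
        assert top.ratio == pytest.approx(top.fg_frac / top.bg_frac, rel=1e-9)
        from chipdose.ebox_analysis import matches_pattern
        # the (possibly degenerate) consensus must cover the planted word
        assert matches_pattern("CAGCTG", top.consensus) or matches_pattern(
            revcomp("CAGCTG"), top.consensus
        )

    def test_identical_sets_yield_no_motifs(self, rng):
        seqs = [rand_seq(rng, 40) for _ in range(50)]
        fg = SequenceSet("foreground", [], seqs)
        bg = SequenceSet("background", [], list(seqs))
        assert discover_motifs(fg, bg, k_range=(6, 6), n_motifs=2) == []

    def test_overlong_words_rejected(self, rng):
        fg = SequenceSet("foreground", [], [rand_seq(rng, 10)])
        bg = SequenceSet("background", [], [rand_seq(rng, 10)])
        with pytest.raises(ValueError):
            discover_motifs(fg, bg, k_range=(12, 12))


class TestEmRefine:
    def test_planted_exact_occurrences_dominate_columns(self, rng):
        seqs = []
        for _ in range(150):
            s = rand_seq(rng, 50)
            j = rng.integers(0, 44)
            seqs.append(s[:j] + "CAGCTG" + s[j + 6 :])
        pwm = em_refine("CAGCTG", SequenceSet("foreground", [], seqs),
                        background=UNIFORM)
        probs = pwm.probabilities
        rc = probs[::-1, ::-1]
        aligned = probs if probs[0, 1] > rc[0, 1] else rc
        for pos, base in enumerate("CAGCTG"):
            assert aligned[pos, "ACGT".index(base)] >= 0.9

    def test_loglikelihood_monotone_every_iteration(self, rng):
        seqs = [rand_seq(rng, 40) for _ in range(60)]
        for i in range(30):
            j = rng.integers(0, 34)
            seqs[i] = seqs[i][:j] + "CACGTG" + seqs[i][j + 6 :]
        pwm = em_refine("CACGTG", SequenceSet("fg", [], seqs), background=UNIFORM)
        ll = pwm.log_likelihood_path
        assert len(ll) >= 2
        assert (np.diff(ll) >= -1e-7).all()

    def test_seed_without_occurrences_returns_flagged_seed_pwm(self, rng):
        seqs = [("AT" * 20) for _ in range(10)]
        pwm = em_refine("CCCCCC", SequenceSet("fg", [], seqs), background=UNIFORM)
        assert not pwm.converged
        assert pwm.gamma == 0.0

    def test_columns_stay_normalized_after_refinement(self, rng):
        seqs = [rand_seq(rng, 30) for _ in range(40)]
        pwm = em_refine("ACGTAC", SequenceSet("fg", [], seqs), background=UNIFORM,
                        max_iter=15)
        assert np.allclose(pwm.probabilities.sum(axis=1), 1.0, atol=1e-9)
        assert (pwm.probabilities > 0).all()


class TestBackgroundSampling:
    def test_gc_and_tss_matching(self, small_config):
        from chipdose.synthetic_data import simulate_genome

        genome, _ = simulate_genome(small_config)
        rng = np.random.default_rng(2)
        windows, seqs = [], []
        from chipdose.genome_io import GenomicInterval

        for _ in range(40):
            c = "syn1"
            s = int(rng.integers(0, len(genome.sequences[c]) - 101))
            windows.append(GenomicInterval(c, s, s + 101))
            seqs.append(genome.sequences[c][s : s + 101])
        fg = SequenceSet("foreground", windows, seqs)
        bg = sample_background(genome, fg, n_per_fg=1, gc_tolerance=0.05, seed=4)
        assert len(bg) == len(fg)
        gc = lambda s: (s.count("G") + s.count("C")) / len(s)
        mean_fg = np.mean([gc(s) for s in fg.sequences])
        mean_bg = np.mean([gc(s) for s in bg.sequences])
        assert abs(mean_fg - mean_bg) < 0.05
        for w in bg.windows:
            for q in fg.windows:
                assert not w.overlaps(q)


def test_motif_table_roundtrip(tmp_path, rng):
    from chipdose.motif_analysis import MotifResult

    pwm = pwm_from_word("CAGCTG", UNIFORM)
    results = [
        MotifResult("CAGCTG", pwm, 12.5, 2.0, 0.5, 0.25),
        MotifResult("RRCAGSTG", pwm_from_word("RRCAGSTG", UNIFORM), -3.0, 0.5,
                    0.1, 0.2),
    ]
    table = motif_table(results)
    assert table.iloc[0]["ratio"] == pytest.approx(
        table.iloc[0]["fg_frac"] / table.iloc[0]["bg_frac"]
    )
    assert table.iloc[1]["z_score"] < 0
    path = tmp_path / "motifs.tsv"
    table.to_csv(path, sep="\t", index=False)
    import pandas as pd

    back = pd.read_csv(path, sep="\t")
    assert back["consensus"].tolist() == ["CAGCTG", "RRCAGSTG"]
    assert back["z_score"].to_numpy() == pytest.approx(table["z_score"].to_numpy())
    meme = tmp_path / "motifs.meme"
    write_meme({"m1": pwm}, meme)
    text = meme.read_text()
    assert "MEME version 4" in text and "w= 6" in text
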