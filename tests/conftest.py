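"""Shared fixtures: one full-scale two-sample simulation per session, plus a
small fast configuration for pipeline-level tests."""

from __future__ import annotations

import numpy as np
import pytest

from chipdose.peak_calling import call_peaks, fit_background
from chipdose.read_processing import build_coverage
from chipdose.synthetic_data import SyntheticConfig, simulate_genome, simulate_reads

STD_SEED = 11


class TwoSampleFixture:
    """Default-condition simulation with everything downstream precomputed."""

    def __init__(self, config: SyntheticConfig):
        self.config = config
        self.genome, self.truth = simulate_genome(config)
        self.reads = {
            s: simulate_reads(self.genome, self.truth, config, s)
            for s in ("endogenous", "overexpressed", "control")
        }
        self.coverage = {
            s: build_coverage(r, self.genome, config.fragment_length)
            for s, r in self.reads.items()
        }
        self.models = {
            s: fit_background(self.coverage[s], self.genome, config.window_size,
                              config.gc_bin_width)
            for s in self.coverage
        }
        self.peaks = {
            s: call_peaks(
                self.coverage[s],
                self.models[s],
                1e-3 if s == "control" else 1e-5,
                sample=s,
            )
            for s in self.coverage
        }


@pytest.fixture(scope="session")
def std_fixture() -> TwoSampleFixture:
    """The standard study conditions: 3 x 2 Mb, 5,000 shared sites, dose 4x."""
    return TwoSampleFixture(SyntheticConfig(seed=STD_SEED))


@pytest.fixture(scope="session")
def background_only():
    """Pure-background simulation (no foreground reads) for calibration tests."""
    cfg = SyntheticConfig(
        seed=42, n_true_sites=10, n_foreground_reads=0, n_repeat_tracts=0
    )
    genome, truth = simulate_genome(cfg)
    reads = simulate_reads(genome, truth, cfg, "endogenous")
    coverage = build_coverage(reads, genome, cfg.fragment_length)
    model = fit_background(coverage, genome, cfg.window_size, cfg.gc_bin_width)
    return cfg, genome, coverage, model


@pytest.fixture
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_chroms=2,
        chrom_length=300_000,
        n_true_sites=150,
        n_foreground_reads=8_000,
        n_tss=60,
        n_repeat_tracts=1,
        repeat_length=2_000,
        seed=5,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
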