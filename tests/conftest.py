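"""Shared fixtures: a small, fast synthetic study used across test modules.

The small configuration shrinks the genome and cell population but keeps
every probability parameter at its default, so per-fragment behaviour is
identical to the full-scale study; tests that assert the full-scale
phenomena live in the acceptance suite.
"""

import logging

import numpy as np
import pandas as pd
import pytest

from rebivalent.intervals import FragmentSet, IntervalSet
from rebivalent.peaks import PeakCallConfig, call_islands, filter_peaks
from rebivalent.simulate import (PLAN_IGG_IGG, PLAN_K4K27, PLAN_K27K4,
                                 PLAN_TOTAL_K4, PLAN_TOTAL_K27,
                                 SimulatorConfig, build_truth,
                                 simulate_sample)

logging.getLogger("rebivalent").setLevel(logging.ERROR)

SMALL_REGION_COUNTS = {"K4_ONLY": 12, "K27_ONLY": 12, "BIVALENT": 16,
                       "ALLELIC_HET": 8, "CELLULAR_HET": 8}


def small_config(seed=11, **overrides) -> SimulatorConfig:
    kwargs = dict(seed=seed, n_chrom=1, chrom_length=1_000_000,
                  n_cells=400, depth=50_000,
                  region_counts=dict(SMALL_REGION_COUNTS))
    kwargs.update(overrides)
    return SimulatorConfig(**kwargs)


@pytest.fixture(scope="session")
def sim_config() -> SimulatorConfig:
    return small_config()


@pytest.fixture(scope="session")
def truth(sim_config):
    return build_truth(sim_config)


@pytest.fixture(scope="session")
def samples(sim_config, truth):
    """One sample per canonical plan on the shared small truth."""
    plans = {"k4_total": PLAN_TOTAL_K4, "k27_total": PLAN_TOTAL_K27,
             "k4k27": PLAN_K4K27, "k27k4": PLAN_K27K4,
             "igg_igg": PLAN_IGG_IGG}
    return {name: simulate_sample(truth, sim_config, plan, seed=100 + i)
            for i, (name, plan) in enumerate(plans.items())}


@pytest.fixture(scope="session")
def peaksets(sim_config, samples):
    config = PeakCallConfig()
    sizes = sim_config.chrom_sizes
    igg = samples["igg_igg"]
    return {name: filter_peaks(call_islands(fr, igg, config, sizes), config)
            for name, fr in samples.items() if name != "igg_igg"}


def random_interval_set(rng, n, n_chroms=2, span=10_000,
                        max_width=500) -> IntervalSet:
    chroms = [f"chr{rng.integers(1, n_chroms + 1)}" for _ in range(n)]
    starts = rng.integers(0, span, n)
    widths = rng.integers(1, max_width, n)
    return IntervalSet(pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": starts + widths}))


def brute_force_overlaps(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """Quadratic any-overlap oracle."""
    out = np.zeros(len(a), dtype=bool)
    for i, ra in enumerate(a.df.itertuples(index=False)):
        for rb in b.df.itertuples(index=False):
            if (ra.chrom == rb.chrom and ra.start < rb.end
                    and rb.start < ra.end):
                out[i] = True
                break
    return out


def brute_force_intersect(a: IntervalSet, b: IntervalSet) -> set:
    segs = set()
    for ra in a.df.itertuples(index=False):
        for rb in b.df.itertuples(index=False):
            if ra.chrom == rb.chrom:
                lo, hi = max(ra.start, rb.start), min(ra.end, rb.end)
                if lo < hi:
                    segs.add((ra.chrom, lo, hi))
    return segs


def brute_force_count(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    out = np.zeros(len(a), dtype=int)
    for i, ra in enumerate(a.df.itertuples(index=False)):
        for rb in b.df.itertuples(index=False):
            if (ra.chrom == rb.chrom and ra.start < rb.end
                    and rb.start < ra.end):
                out[i] += 1
    return out


def make_fragments(tuples, sample_id="s") -> FragmentSet:
    return FragmentSet(pd.DataFrame(tuples,
                                    columns=["chrom", "start", "end"]),
                       sample_id=sample_id)
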