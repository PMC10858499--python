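"""Enrichment and QC metrics: log2 CPM/bp, FRiP, profiles, downsampling.

CPM/bp corrects a region's fragment count for both library depth (counts
per million) and region width (per base pair), making enrichment values
comparable across samples and across regions of different size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import FragmentSet, IntervalSet, subsample

DEFAULT_LOG_FLOOR = 2.0 ** -10


def cpm_per_bp(frags: FragmentSet, regions: IntervalSet) -> np.ndarray:
    """Per region: (overlapping fragments / library size * 1e6) / width."""
    counts = regions.count_overlaps(frags)
    widths = (regions.df["end"] - regions.df["start"]).to_numpy()
    lib = max(frags.library_size, 1)
    return counts / lib * 1e6 / widths


def log2_cpm_per_bp(frags: FragmentSet, regions: IntervalSet,
                    floor: float = DEFAULT_LOG_FLOOR) -> np.ndarray:
    """log2 of CPM/bp with a floor so empty regions stay finite.

    With the default floor (2^-10) an empty region scores exactly -10.
    """
    return np.log2(np.maximum(cpm_per_bp(frags, regions), floor))


def enrichment_matrix(samples: Mapping[str, FragmentSet],
                      regions: IntervalSet,
                      floor: float = DEFAULT_LOG_FLOOR) -> pd.DataFrame:
    """Regions x samples matrix of log2 CPM/bp values."""
    data = {sid: log2_cpm_per_bp(fr, regions, floor)
            for sid, fr in samples.items()}
    idx = [f"{r.chrom}:{r.start}-{r.end}"
           for r in regions.df.itertuples(index=False)]
    return pd.DataFrame(data, index=idx)


@dataclass
class FripRow:
    sample_id: str
    reads_in_peaks: int
    library_size: int
    frip: float


def frip(frags: FragmentSet, peaks: IntervalSet) -> FripRow:
    """Fraction of the library's fragments overlapping >= 1 peak.

    Each fragment is counted at most once however many peaks it touches,
    which keeps the score bounded in [0, 1].
    """
    n = int(frags.overlaps_any(peaks).sum()) if len(peaks) else 0
    lib = frags.library_size
    return FripRow(frags.sample_id, n, lib, n / lib if lib else 0.0)


def frip_report(samples: Mapping[str, FragmentSet],
                peaks: IntervalSet) -> pd.DataFrame:
    rows = [frip(fr, peaks) for fr in samples.values()]
    return pd.DataFrame([r.__dict__ for r in rows])


def profile_matrix(frags: FragmentSet, regions: IntervalSet,
                   flank: int = 5000, n_bins: int = 100,
                   mask_percentile: float = 99.0) -> dict:
    """Relative-distribution matrix around region centers.

    Each region is re-centered and extended to ±``flank``; the window is
    split into ``n_bins`` equal bins; per-bin mean CPM/bp is computed from
    fragment midpoints.  Values above the ``mask_percentile`` of all bins
    are capped, then the whole matrix is scaled to [0, 1] by its maximum.
    The equal-weight column means form the average profile.
    """
    if len(regions) == 0:
        raise ValueError("no regions to profile")
    bin_w = 2 * flank / n_bins
    mids_by_chrom = {
        chrom: np.sort(((sub["start"] + sub["end"]) // 2).to_numpy())
        for chrom, sub in frags.df.groupby("chrom", sort=False)}
    lib = max(frags.library_size, 1)
    mat = np.zeros((len(regions), n_bins))
    for i, row in enumerate(regions.df.itertuples(index=False)):
        center = (row.start + row.end) // 2
        mids = mids_by_chrom.get(row.chrom)
        if mids is None:
            continue
        edges = center - flank + bin_w * np.arange(n_bins + 1)
        counts = np.diff(np.searchsorted(mids, edges))
        mat[i] = counts / lib * 1e6 / bin_w
    cap = np.percentile(mat, mask_percentile)
    masked = np.minimum(mat, cap)
    peak = masked.max()
    scaled = masked / peak if peak > 0 else masked
    return {"matrix": scaled, "profile": scaled.mean(axis=0),
            "cap": float(cap), "n_bins": n_bins, "flank": flank}


def downsampling_curve(samples: Mapping[str, FragmentSet],
                       fractions: Sequence[float], seed: int,
                       pipeline: Callable[[Mapping[str, FragmentSet]], dict]
                       ) -> pd.DataFrame:
    """Re-run an analysis closure on seeded subsamples of every library.

    ``pipeline`` maps sample_id -> FragmentSet to a dict of counts (e.g.
    number of peaks / bivalent regions); one row per fraction is returned,
    sorted ascending.
    """
    rows = []
    for k, frac in enumerate(sorted(fractions)):
        sub = {sid: subsample(fr, frac, seed + k)
               for sid, fr in samples.items()}
        rec = {"fraction": frac,
               "n_reads": int(sum(fr.library_size for fr in sub.values()))}
        rec.update(pipeline(sub))
        rows.append(rec)
    return pd.DataFrame(rows)
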