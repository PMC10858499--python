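"""Reciprocal-reChIP bivalency calling, confidence classes and promoters.

A region is called bivalent only when it has peak support in *both*
sequential-ChIP orientations (H3K4me3→H3K27me3 and H3K27me3→H3K4me3).
Each reciprocal-bivalent peak is then stratified by overlap with total
single-ChIP peak sets into four confidence classes:

* ``HC``  — overlaps a peak in both total H3K4me3 and total H3K27me3,
* ``K4B`` — overlaps only total H3K4me3 (K4-biased),
* ``K27B``— overlaps only total H3K27me3 (K27-biased),
* ``LC``  — overlaps neither (low confidence).

The classes are exhaustive and mutually exclusive; the tallies always
partition the bivalent set.  Promoters (TSS ± 1.5 kb) inherit the
highest-priority class among their overlapping peaks (HC > K4B > K27B >
LC).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .peaks import PeakSet

CLASSES = ("HC", "K4B", "K27B", "LC")
_CLASS_PRIORITY = {c: i for i, c in enumerate(CLASSES)}


@dataclass
class InSilicoComparison:
    """Accounting for the in-silico overlap strategy vs reciprocal reChIP.

    ``fp_rate_percent`` is the share of putative in-silico bivalent regions
    not validated by peaks in both reChIP orientations — the apparent
    bivalency attributable to allelic/cellular heterogeneity (or noise).
    Undefined (None) when there are no in-silico regions.
    """

    n_insilico: int
    n_validated: int
    n_unvalidated: int
    fp_rate_percent: float | None
    n_k4k27: int = 0
    n_k27k4: int = 0
    n_shared: int = 0
    class_tallies: dict | None = None

    def __post_init__(self) -> None:
        assert self.n_unvalidated == self.n_insilico - self.n_validated
        if self.class_tallies is not None and self.n_shared:
            assert sum(self.class_tallies.values()) == self.n_shared

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ReciprocalResult:
    bivalent: IntervalSet
    n_k4k27: int
    n_k27k4: int
    n_shared: int


def _as_interval_set(obj) -> IntervalSet:
    if isinstance(obj, PeakSet):
        return obj.intervals()
    return obj


def consensus_peaks(replicate_peaksets: Sequence) -> IntervalSet:
    """Commonly enriched regions across replicates.

    With a single replicate this is the identity; with more, the pairwise
    overlap segments are folded left across replicates and merged.
    """
    sets = [_as_interval_set(p) for p in replicate_peaksets]
    if not sets:
        raise ValueError("need at least one replicate peak set")
    acc = sets[0]
    for nxt in sets[1:]:
        acc = acc.intersect(nxt)
    return acc.merge()


def reciprocal_bivalent(k4k27: IntervalSet,
                        k27k4: IntervalSet) -> ReciprocalResult:
    """Peaks supported by >= 1 bp overlap in BOTH reChIP orientations.

    A shared region is represented by the K4-K27 peak interval carrying the
    supporting overlap (one anchor side has to be chosen; the choice is
    recorded here so counts are auditable).  ``n_shared`` counts K4-K27
    peaks with at least one supporting K27-K4 overlap.
    """
    k4k27 = _as_interval_set(k4k27)
    k27k4 = _as_interval_set(k27k4)
    supported = k4k27.overlaps_any(k27k4)
    shared = IntervalSet(k4k27.df[supported])
    return ReciprocalResult(bivalent=shared, n_k4k27=len(k4k27),
                            n_k27k4=len(k27k4), n_shared=len(shared))


class ClassifiedPeakSet:
    """Bivalent peaks with confidence classes and total-ChIP overlap flags."""

    def __init__(self, df: pd.DataFrame):
        # class is derivable from the flags; enforce the invariant
        expect = np.where(
            df["overlaps_total_k4"] & df["overlaps_total_k27"], "HC",
            np.where(df["overlaps_total_k4"], "K4B",
                     np.where(df["overlaps_total_k27"], "K27B", "LC")))
        if len(df) and not (df["class"].to_numpy() == expect).all():
            raise ValueError("class labels inconsistent with overlap flags")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def intervals(self) -> IntervalSet:
        return IntervalSet(self.df[["chrom", "start", "end"]])

    def tallies(self) -> dict[str, int]:
        counts = self.df["class"].value_counts()
        return {c: int(counts.get(c, 0)) for c in CLASSES}

    def subset(self, cls: str) -> IntervalSet:
        return IntervalSet(self.df[self.df["class"] == cls]
                           [["chrom", "start", "end"]])

    def write_bed(self, path) -> None:
        out = self.df.copy()
        out["name"] = out["class"]
        out.to_csv(path, sep="\t", header=False, index=False,
                   columns=["chrom", "start", "end", "name"])


def classify_peaks(bivalent: IntervalSet, total_k4: IntervalSet,
                   total_k27: IntervalSet) -> ClassifiedPeakSet:
    """Stratify reciprocal-bivalent peaks by total-ChIP peak overlap.

    Every peak receives exactly one class and the four tallies always sum
    to the number of bivalent peaks (asserted).
    """
    bivalent = _as_interval_set(bivalent)
    df = bivalent.df[["chrom", "start", "end"]].copy()
    f4 = bivalent.overlaps_any(_as_interval_set(total_k4))
    f27 = bivalent.overlaps_any(_as_interval_set(total_k27))
    df["overlaps_total_k4"] = f4
    df["overlaps_total_k27"] = f27
    df["class"] = np.where(f4 & f27, "HC",
                           np.where(f4, "K4B", np.where(f27, "K27B", "LC")))
    out = ClassifiedPeakSet(df)
    assert sum(out.tallies().values()) == len(out)  # classes partition the set
    return out


def in_silico_comparison(total_k4: IntervalSet, total_k27: IntervalSet,
                         bivalent: IntervalSet,
                         reciprocal: ReciprocalResult | None = None,
                         class_tallies: Mapping[str, int] | None = None,
                         ) -> InSilicoComparison:
    """Putative bivalency by total-peak overlap, validated against reChIP.

    The in-silico set is the merged intersection of the two total peak
    sets; a member is validated when it overlaps a reciprocal-bivalent
    region.  The false-positive rate (percent, 1 decimal) is undefined when
    the in-silico set is empty.
    """
    insilico = _as_interval_set(total_k4).intersect(
        _as_interval_set(total_k27)).merge()
    n_insilico = len(insilico)
    n_validated = int(insilico.overlaps_any(_as_interval_set(bivalent)).sum()) \
        if n_insilico else 0
    n_unvalidated = n_insilico - n_validated
    fp = round(100.0 * n_unvalidated / n_insilico, 1) if n_insilico else None
    return InSilicoComparison(
        n_insilico=n_insilico, n_validated=n_validated,
        n_unvalidated=n_unvalidated, fp_rate_percent=fp,
        n_k4k27=reciprocal.n_k4k27 if reciprocal else 0,
        n_k27k4=reciprocal.n_k27k4 if reciprocal else 0,
        n_shared=reciprocal.n_shared if reciprocal else 0,
        class_tallies=dict(class_tallies) if class_tallies else None)


def promoter_windows(tss: IntervalSet, half_width: int = 1500,
                     chrom_sizes: Mapping[str, int] | None = None
                     ) -> IntervalSet:
    """Symmetric promoter windows (TSS ± ``half_width``), clipped to bounds.

    The TSS base is the interval start for ``+``/``.`` genes and ``end - 1``
    for ``-`` strand genes.
    """
    df = tss.df.copy()
    strand = df["strand"] if "strand" in df.columns else pd.Series(
        ".", index=df.index)
    pos = np.where(strand == "-", df["end"].to_numpy() - 1,
                   df["start"].to_numpy())
    start = np.maximum(pos - half_width, 0)
    end = pos + half_width
    if chrom_sizes is not None:
        limits = df["chrom"].map(chrom_sizes).to_numpy()
        end = np.minimum(end, limits)
    out = df[["chrom"]].copy()
    out["start"], out["end"] = start, end
    for col in ("name", "strand"):
        if col in df.columns:
            out[col] = df[col]
    return IntervalSet(out)


def classify_promoters(promoters: IntervalSet,
                       classified: ClassifiedPeakSet) -> pd.DataFrame:
    """Assign each promoter the highest-priority class among its peaks.

    One record per gene (promoters must already be gene-deduplicated);
    promoters overlapping no bivalent peak get class ``none``.  The
    assignment depends only on which peaks overlap, never on peak input
    order.
    """
    pdf = promoters.df
    out = pdf[["chrom", "start", "end"]].copy()
    out["gene"] = pdf["name"].astype(str) if "name" in pdf.columns else [
        f"gene_{i}" for i in range(len(pdf))]
    prom_set = IntervalSet(out[["chrom", "start", "end"]])
    cdf = classified.df
    best = np.full(len(pdf), "none", dtype=object)
    for cls in CLASSES:  # CLASSES is already in priority order
        sub = cdf[cdf["class"] == cls]
        if not len(sub):
            continue
        hits = prom_set.overlaps_any(IntervalSet(sub[["chrom", "start", "end"]]))
        best[hits & (best == "none")] = cls
    out["class"] = best
    out["peaks"] = _contributing_peaks(out, cdf)
    return out.reset_index(drop=True)


def _contributing_peaks(promoters: pd.DataFrame, cdf: pd.DataFrame) -> list[str]:
    """Comma-joined ids (class:chrom:start-end) of peaks per promoter,
    sorted by genomic position so the output is order-independent."""
    csort = cdf.sort_values(["chrom", "start", "end"], kind="mergesort")
    labels = np.array([f"{c}:{ch}:{s}-{e}" for c, ch, s, e in
                       zip(csort["class"], csort["chrom"],
                           csort["start"], csort["end"])], dtype=object)
    result = []
    for prow in promoters.itertuples(index=False):
        mask = ((csort["chrom"] == prow.chrom)
                & (csort["start"] < prow.end)
                & (csort["end"] > prow.start)).to_numpy()
        result.append(",".join(labels[mask]))
    return result


def compare_promoter_sets(a: pd.DataFrame, b: pd.DataFrame) -> dict:
    """Gene-level overlap between two promoter classifications.

    Only genes that received a bivalency class (not ``none``) count.  The
    shared percentage is reported relative to set ``b`` (integer percent).
    """
    genes_a = set(a.loc[a["class"] != "none", "gene"])
    genes_b = set(b.loc[b["class"] != "none", "gene"])
    shared = genes_a & genes_b
    pct = int(round(100 * len(shared) / len(genes_b))) if genes_b else None
    return {"n_a": len(genes_a), "n_b": len(genes_b),
            "n_shared": len(shared),
            "n_unique_a": len(genes_a - genes_b),
            "n_unique_b": len(genes_b - genes_a),
            "pct_of_b_shared": pct}


def annotate_features(peaks: IntervalSet,
                      features: Mapping[str, IntervalSet],
                      classes: Sequence[str] | None = None) -> pd.DataFrame:
    """Overlap flags (>= 1 bp) of each peak against named feature sets.

    Returns the peak frame with one boolean column per feature; if
    ``classes`` (one label per peak) is given, per-class tallies can be
    derived with a groupby on the returned frame.
    """
    peaks = _as_interval_set(peaks)
    out = peaks.df[["chrom", "start", "end"]].copy()
    for name, feat in features.items():
        out[name] = peaks.overlaps_any(_as_interval_set(feat))
    if classes is not None:
        out["class"] = list(classes)
    return out


def feature_tallies(annotated: pd.DataFrame,
                    feature_names: Sequence[str]) -> pd.DataFrame:
    """Per-class counts of peaks overlapping each feature."""
    if "class" not in annotated.columns:
        raise ValueError("annotated frame lacks a 'class' column")
    return annotated.groupby("class")[list(feature_names)].sum().astype(int)
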