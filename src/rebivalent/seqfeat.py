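"""GC and CpG sequence metrics with width/GC-matched random controls.

Bivalent regions in mammalian genomes sit overwhelmingly at CpG-island
promoters, so their GC fraction and CpG-dinucleotide frequency exceed
those of random genomic regions.  To show this fairly, the control regions
must match the query set in width (exactly, as a multiset) and in GC
content (by nearest-neighbour matching), otherwise width- or
composition-driven artefacts dominate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalSet
from .peaks import bh_adjust


def fetch_sequences(intervals: IntervalSet, fasta_path: str) -> list[str]:
    """Region sequences from a (plain or bgzipped) FASTA via pyfaidx."""
    from pyfaidx import Fasta
    fa = Fasta(fasta_path, sequence_always_upper=True)
    return [str(fa[row.chrom][row.start:row.end])
            for row in intervals.df.itertuples(index=False)]


def gc_metrics(seqs: Sequence[str]) -> pd.DataFrame:
    """Per-sequence GC fraction and CpG dinucleotide frequency.

    GC fraction is (#C + #G) / (length - #N): ambiguous bases are excluded
    from numerator and denominator.  CpG frequency is the count of "CG"
    dinucleotides over the number of dinucleotide positions (length - 1).
    Case-insensitive; both metrics stay within [0, 1].
    """
    rows = []
    for s in seqs:
        u = s.upper()
        n = len(u)
        n_ambig = u.count("N")
        gc = u.count("G") + u.count("C")
        denom = n - n_ambig
        cpg_positions = n - 1
        rows.append((gc / denom if denom else 0.0,
                     u.count("CG") / cpg_positions if cpg_positions else 0.0))
    return pd.DataFrame(rows, columns=["gc_fraction", "cpg_freq"])


@dataclass
class RandomRegionSet:
    regions: IntervalSet
    matching_report: dict


def matched_random_regions(query: IntervalSet,
                           chrom_sizes: Mapping[str, int],
                           fasta_path: str, seed: int,
                           n_candidates_per_query: int = 20,
                           exclude: IntervalSet | None = None
                           ) -> RandomRegionSet:
    """Random control regions matched on width (exactly) and GC (nearest).

    For each query interval, ``n_candidates_per_query`` same-width
    candidate regions are drawn uniformly over the genome avoiding the
    query set (and an optional blacklist); the candidate nearest in GC
    fraction, without replacement, is selected.  Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    avoid = query if exclude is None else IntervalSet(
        pd.concat([query.df[["chrom", "start", "end"]],
                   exclude.df[["chrom", "start", "end"]]], ignore_index=True))
    avoid = avoid.merge()
    chroms = sorted(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    cprob = lengths / lengths.sum()

    widths = (query.df["end"] - query.df["start"]).to_numpy()
    cand_rows = []
    for qi, w in enumerate(widths):
        found = 0
        tries = 0
        max_tries = n_candidates_per_query * 50
        while found < n_candidates_per_query:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    "could not draw enough candidate regions; increase "
                    "n_candidates_per_query or relax the exclusion set")
            ci = rng.choice(len(chroms), p=cprob)
            chrom = chroms[ci]
            if chrom_sizes[chrom] <= w:
                continue
            start = int(rng.integers(0, chrom_sizes[chrom] - w))
            cand = IntervalSet(pd.DataFrame(
                {"chrom": [chrom], "start": [start], "end": [start + w]}))
            if cand.overlaps_any(avoid)[0]:
                continue
            cand_rows.append((qi, chrom, start, start + int(w)))
            found += 1
    cand = pd.DataFrame(cand_rows, columns=["query_idx", "chrom", "start", "end"])

    q_gc = gc_metrics(fetch_sequences(query, fasta_path))["gc_fraction"].to_numpy()
    c_gc = gc_metrics(fetch_sequences(
        IntervalSet(cand[["chrom", "start", "end"]]), fasta_path)
    )["gc_fraction"].to_numpy()

    chosen = []
    used = np.zeros(len(cand), dtype=bool)
    for qi in range(len(widths)):
        pool = np.flatnonzero((cand["query_idx"] == qi).to_numpy() & ~used)
        best = pool[np.argmin(np.abs(c_gc[pool] - q_gc[qi]))]
        used[best] = True
        chosen.append(best)
    matched = IntervalSet(cand.iloc[chosen][["chrom", "start", "end"]])
    report = {
        "n": len(widths),
        "mean_abs_gc_diff": float(np.mean(np.abs(c_gc[chosen] - q_gc))),
        "width_multiset_preserved": sorted(widths.tolist()) == sorted(
            (matched.df["end"] - matched.df["start"]).tolist()),
    }
    return RandomRegionSet(matched, report)


def compare_classes(metrics_by_class: Mapping[str, np.ndarray],
                    control: np.ndarray) -> pd.DataFrame:
    """Pairwise two-sided t-tests of every class against control and each
    other, Benjamini–Hochberg adjusted."""
    names = list(metrics_by_class) + ["control"]
    values = {**{k: np.asarray(v, dtype=float)
                 for k, v in metrics_by_class.items()},
              "control": np.asarray(control, dtype=float)}
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            t, p = stats.ttest_ind(values[a], values[b], equal_var=False)
            rows.append((a, b, float(t), float(p),
                         float(values[a].mean() - values[b].mean())))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "t", "p",
                                     "mean_diff"])
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# Synthetic genome sequence (for testing sequence metrics end-to-end)
# ---------------------------------------------------------------------------

def synthetic_genome(chrom_sizes: Mapping[str, int], seed: int,
                     gc_background: float = 0.42,
                     cpg_regions: IntervalSet | None = None,
                     gc_enriched: float = 0.65) -> dict[str, str]:
    """Random genome sequence, optionally CpG/GC-enriched inside regions.

    Synthetic stand-in for a reference assembly: background bases are drawn
    i.i.d. at ``gc_background`` GC; inside ``cpg_regions`` the GC fraction
    rises to ``gc_enriched`` with an explicit excess of CG dinucleotides.
    """
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    for chrom in sorted(chrom_sizes):
        n = chrom_sizes[chrom]
        p_gc = gc_background
        probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
        seq = rng.choice(np.array(list("ACGT")), size=n, p=probs)
        if cpg_regions is not None:
            sub = cpg_regions.df[cpg_regions.df["chrom"] == chrom]
            for row in sub.itertuples(index=False):
                w = row.end - row.start
                p = gc_enriched
                block = rng.choice(np.array(list("ACGT")), size=w,
                                   p=[(1 - p) / 2, p / 2, p / 2, (1 - p) / 2])
                # plant CG dinucleotides at ~8% of positions
                n_cpg = int(0.08 * w)
                pos = rng.choice(w - 1, size=n_cpg, replace=False)
                block[pos] = "C"
                block[pos + 1] = "G"
                seq[row.start:row.end] = block
        genome[chrom] = "".join(seq)
    return genome


def write_fasta(genome: Mapping[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            s = genome[chrom]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")
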