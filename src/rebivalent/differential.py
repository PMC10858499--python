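"""Differential bivalency between conditions.

Normalization and testing follow the standard count-based differential
binding recipe: library-size offsets corrected by trimmed-mean-of-M-values
(TMM) factors computed on 10 kb genome bins, then a per-region
negative-binomial two-group comparison with moment-based dispersion shrunk
toward the common value, tested by a 1-df likelihood-ratio chi-square and
Benjamini–Hochberg corrected.  A region only counts as differentially
bivalent when it is significant *with the same sign* in both reChIP
orientations — the two-orientation rule is the scientific core of the
differential analysis.

The test is an equivalent-in-spirit NB likelihood-ratio test, not a
re-implementation of any specific quasi-likelihood package; its acceptance
rests on type-I calibration, power and sign-recovery properties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .intervals import FragmentSet, IntervalSet, coverage
from .peaks import bh_adjust


@dataclass
class DiffConfig:
    """Differential-test parameters.

    The trim constants (30% of M-values, 5% of A-values per tail) are the
    classical TMM defaults; ``prior_weight`` is the number of
    pseudo-observations pulling each region's moment dispersion toward the
    common dispersion.  A region is significant at |log2FC| > 1 and
    FDR < 0.05.
    """

    trim_m: float = 0.30
    trim_a: float = 0.05
    prior_weight: float = 20.0
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05

    def validate(self) -> None:
        for name in ("trim_m", "trim_a"):
            v = getattr(self, name)
            if not 0 <= v < 0.5:
                raise ValueError(f"{name}={v} outside [0, 0.5)")
        if self.lfc_threshold <= 0 or self.fdr_threshold <= 0:
            raise ValueError("thresholds must be > 0")


@dataclass
class CountMatrix:
    """Regions x samples integer counts with library sizes and conditions."""

    counts: pd.DataFrame          # rows: region id; columns: sample ids
    library_sizes: pd.Series      # per sample
    conditions: pd.Series         # per sample
    regions: IntervalSet | None = None

    def validate_for_test(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        tallies = self.conditions.value_counts()
        if len(tallies) != 2:
            raise ValueError("exactly two conditions are required")
        if (tallies < 2).any():
            raise ValueError(
                "each condition needs >= 2 samples (dispersion is "
                "unidentifiable otherwise)")


def bin_genome_counts(samples: Mapping[str, FragmentSet],
                      chrom_sizes: Mapping[str, int],
                      bin_width: int = 10_000,
                      conditions: Mapping[str, str] | None = None,
                      drop_empty: bool = True) -> CountMatrix:
    """Midpoint-assigned fragment counts per genome bin per sample.

    Column sums equal the library sizes before empty rows (bins with zero
    counts in every sample) are dropped.
    """
    cols = {}
    for sid, frags in samples.items():
        cov = coverage(frags, bin_width, chrom_sizes)
        cols[sid] = np.concatenate([cov.data[c] for c in sorted(chrom_sizes)])
    index = [f"{c}:{i * bin_width}"
             for c in sorted(chrom_sizes)
             for i in range(int(np.ceil(chrom_sizes[c] / bin_width)))]
    df = pd.DataFrame(cols, index=index).astype(np.int64)
    lib = pd.Series({sid: fr.library_size for sid, fr in samples.items()})
    if drop_empty:
        df = df[df.sum(axis=1) > 0]
    cond = pd.Series(conditions) if conditions is not None else pd.Series(
        "NA", index=df.columns)
    return CountMatrix(df, lib, cond)


def region_counts(samples: Mapping[str, FragmentSet], regions: IntervalSet,
                  conditions: Mapping[str, str] | None = None) -> CountMatrix:
    """Fragments overlapping (>= 1 bp) each consensus region, per sample."""
    cols = {sid: regions.count_overlaps(fr) for sid, fr in samples.items()}
    idx = [f"{r.chrom}:{r.start}-{r.end}"
           for r in regions.df.itertuples(index=False)]
    df = pd.DataFrame(cols, index=idx).astype(np.int64)
    lib = pd.Series({sid: fr.library_size for sid, fr in samples.items()})
    cond = pd.Series(conditions) if conditions is not None else pd.Series(
        "NA", index=df.columns)
    return CountMatrix(df, lib, cond, regions=regions)


def tmm_factors(bins: CountMatrix, config: DiffConfig | None = None
                ) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    The reference sample is the one whose upper-quartile count proportion
    is closest to the mean upper quartile.  For each sample, M (log2 count
    proportion ratio vs reference) and A (average log2 proportion) are
    computed over bins positive in both; the most extreme ``trim_m`` of M
    and ``trim_a`` of A are discarded from each tail, and the factor is two
    to the precision-weighted mean of the surviving M-values.  Factors are
    rescaled to geometric mean 1.
    """
    config = config or DiffConfig()
    config.validate()
    counts = bins.counts
    if counts.shape[1] < 2:
        raise ValueError("TMM needs >= 2 samples")
    lib = bins.library_sizes[counts.columns].to_numpy(dtype=float)
    mat = counts.to_numpy(dtype=float)
    prop = mat / lib
    with np.errstate(divide="ignore", invalid="ignore"):
        f75 = np.array([np.quantile(prop[:, j][mat[:, j] >= 0], 0.75)
                        for j in range(mat.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref:
            continue
        both = (mat[:, j] > 0) & (mat[:, ref] > 0)
        if both.sum() == 0:
            raise ValueError("no bins positive in both sample and reference")
        x, r = mat[both, j], mat[both, ref]
        nx, nr = lib[j], lib[ref]
        m = np.log2((x / nx) / (r / nr))
        a = 0.5 * np.log2((x / nx) * (r / nr))
        w = (nx - x) / (nx * x) + (nr - r) / (nr * r)  # asymptotic var of M
        lo_m, hi_m = np.quantile(m, [config.trim_m, 1 - config.trim_m])
        lo_a, hi_a = np.quantile(a, [config.trim_a, 1 - config.trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.sum() == 0:
            raise ValueError("no bins survive TMM trimming")
        factors[j] = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# Negative-binomial two-group test
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Summed NB log-likelihood per region (rows), dispersion alpha."""
    a = alpha[:, None]
    mu = np.maximum(mu, 1e-12)
    inv = 1.0 / a
    ll = (gammaln(y + inv) - gammaln(inv) - gammaln(y + 1)
          + y * np.log(a * mu / (1 + a * mu)) - inv * np.log1p(a * mu))
    return ll.sum(axis=1)


def _fit_q(y: np.ndarray, s: np.ndarray, alpha: np.ndarray,
           n_iter: int = 50) -> np.ndarray:
    """Per-region MLE of the rate q with means mu_j = q * s_j.

    Solves sum_j (y_j - q s_j) / (1 + alpha q s_j) = 0, which is monotone
    decreasing in q, by damped Newton with a positivity safeguard.
    """
    q = np.maximum(y.sum(axis=1) / s.sum(), 1e-12)
    a = alpha[:, None]
    for _ in range(n_iter):
        mu = q[:, None] * s
        denom = 1 + a * mu
        f = ((y - mu) / denom).sum(axis=1)
        # d/dq [(y - q s)/(1 + a q s)] = -s (1 + a y) / (1 + a q s)^2
        fp = -((s * (1 + a * y)) / denom ** 2).sum(axis=1)
        step = f / np.where(fp != 0, fp, -1.0)
        q_new = q - step
        q = np.where(q_new > 0, q_new, q / 2)
    return q


def _moment_dispersion(norm: np.ndarray, groups: Sequence[np.ndarray]
                       ) -> np.ndarray:
    """Method-of-moments NB dispersion per region from normalized counts."""
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    for g in groups:
        sub = norm[:, g]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += (v - m) * len(g)
        den += (m ** 2) * len(g)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    return np.clip(alpha, 0.0, 50.0)


def nb_test(counts: CountMatrix, factors: pd.Series,
            config: DiffConfig | None = None,
            contrast: tuple[str, str] | None = None) -> pd.DataFrame:
    """Per-region NB likelihood-ratio test between two conditions.

    Effective library sizes (library size x TMM factor) enter as offsets.
    Each region's dispersion is the moment estimate shrunk toward the
    common (count-weighted mean) dispersion with ``prior_weight``
    pseudo-observations.  ``contrast=(B, A)`` reports log2FC of B over A
    with pseudocount 0.5 on offset-normalized means.
    """
    config = config or DiffConfig()
    config.validate()
    counts.validate_for_test()
    cols = list(counts.counts.columns)
    cond = counts.conditions[cols]
    levels = list(pd.unique(cond))
    if contrast is None:
        contrast = (levels[1], levels[0])
    cond_b, cond_a = contrast
    idx_a = np.flatnonzero((cond == cond_a).to_numpy())
    idx_b = np.flatnonzero((cond == cond_b).to_numpy())
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each contrasted condition needs >= 2 samples")

    y = counts.counts.to_numpy(dtype=float)
    eff = (counts.library_sizes[cols].to_numpy(dtype=float)
           * factors[cols].to_numpy(dtype=float))
    s = eff / eff.mean()  # relative offsets; q is then on mean-library scale

    norm = y / s
    alpha_mom = _moment_dispersion(norm, [idx_a, idx_b])
    n_obs = y.shape[1]
    weights = y.sum(axis=1)
    common = (np.average(alpha_mom, weights=np.maximum(weights, 1))
              if len(alpha_mom) else 0.0)
    alpha = ((n_obs * alpha_mom + config.prior_weight * common)
             / (n_obs + config.prior_weight))
    alpha = np.clip(alpha, 1e-8, 50.0)

    q0 = _fit_q(y, s, alpha)
    qa = _fit_q(y[:, idx_a], s[idx_a], alpha)
    qb = _fit_q(y[:, idx_b], s[idx_b], alpha)

    ll0 = _nb_loglik(y, q0[:, None] * s, alpha)
    ll1 = (_nb_loglik(y[:, idx_a], qa[:, None] * s[idx_a], alpha)
           + _nb_loglik(y[:, idx_b], qb[:, None] * s[idx_b], alpha))
    dev = np.maximum(2 * (ll1 - ll0), 0.0)
    p = stats.chi2.sf(dev, df=1)
    fdr = bh_adjust(p)
    log2fc = np.log2((qb + 0.5) / (qa + 0.5))
    sig = (np.abs(log2fc) > config.lfc_threshold) & (fdr < config.fdr_threshold)

    return pd.DataFrame({
        "log2fc": log2fc, "dispersion": alpha, "p": p, "fdr": fdr,
        "significant": sig,
    }, index=counts.counts.index)


def call_differential_bivalency(res_k4k27: pd.DataFrame,
                                res_k27k4: pd.DataFrame,
                                regions: IntervalSet | None = None,
                                promoters: pd.DataFrame | None = None,
                                prior_genes: Sequence[str] | None = None
                                ) -> dict:
    """Regions significant with concordant sign in BOTH reChIP orientations.

    The two result frames must be indexed over the same consensus regions.
    Promoter calls (optional) are promoters overlapping >= 1 differential
    region; with a ``prior_genes`` list the promoter calls are split into
    previously-known and novel.
    """
    if not res_k4k27.index.equals(res_k27k4.index):
        raise ValueError("orientation results must share one region index")
    both = (res_k4k27["significant"] & res_k27k4["significant"]
            & (np.sign(res_k4k27["log2fc"]) == np.sign(res_k27k4["log2fc"])))
    both = both.to_numpy()
    direction = np.sign(res_k4k27["log2fc"].to_numpy())
    n_lost = int((both & (direction < 0)).sum())
    n_gained = int((both & (direction > 0)).sum())
    out = {
        "n_differential": int(both.sum()),
        "n_lost": n_lost,
        "n_gained": n_gained,
        "differential_index": list(res_k4k27.index[both]),
    }
    if regions is not None and promoters is not None:
        diff_regions = IntervalSet(regions.df[both])
        prom_set = IntervalSet(promoters[["chrom", "start", "end"]])
        hit = prom_set.overlaps_any(diff_regions)
        genes = promoters.loc[hit, "gene"].tolist()
        out["n_promoters"] = len(genes)
        out["promoter_genes"] = genes
        if prior_genes is not None:
            prior = set(prior_genes)
            out["n_known"] = sum(g in prior for g in genes)
            out["n_novel"] = sum(g not in prior for g in genes)
    return out
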