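"""Generative simulator of sequential chromatin immunoprecipitation.

The model is a population of cells whose nucleosomes (on a fixed spacing
grid, diploid) carry H3K4me3 and/or H3K27me3 according to the state of the
region they fall in:

* ``K4_ONLY`` / ``K27_ONLY``: the designated mark with probability ``m``.
* ``BIVALENT``: both marks, each independently with probability ``m`` —
  marks co-occur on the same fragment.
* ``ALLELIC_HET``: allele 0 carries H3K4me3 (prob ``m``), allele 1 carries
  H3K27me3 (prob ``m``) — never both on one fragment.
* ``CELLULAR_HET``: a fraction ``f`` of cells carries H3K4me3, the rest
  H3K27me3 — again never both on one fragment.
* everywhere else each mark appears independently with background
  probability ``epsilon``.

Fragments then pass one or two antibody-capture rounds: a fragment carrying
the antibody's target mark is captured with probability ``e``, otherwise
with the nonspecific probability ``b`` (IgG always captures at ``b``).
Between rounds a captured fragment survives elution with probability
``eta``; in the second round a fragment may additionally be retained with
the mark-independent carry-over probability ``c``.  Both histone tails
travel with the fragment, which is exactly what makes the two-round
protocol specific for true bivalency and blind to allelic or cellular
heterogeneity.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import FragmentSet, IntervalSet, write_chrom_sizes

logger = logging.getLogger(__name__)

STATES = ("K4_ONLY", "K27_ONLY", "BIVALENT", "ALLELIC_HET", "CELLULAR_HET")

#: antibody targets
K4, K27, IGG = "K4", "K27", "IGG"
_VALID_TARGETS = {K4, K27, IGG}

#: canonical single- and two-round plans
PLAN_TOTAL_K4 = (K4,)
PLAN_TOTAL_K27 = (K27,)
PLAN_K4K27 = (K4, K27)
PLAN_K27K4 = (K27, K4)
PLAN_IGG_IGG = (IGG, IGG)


class SimulationError(RuntimeError):
    pass


class CapacityError(SimulationError):
    """The genome is too small to place the requested regions."""


class EmptyPoolError(SimulationError):
    """Every fragment was lost at some immunoprecipitation stage."""

    def __init__(self, stage: str):
        super().__init__(f"no fragments survived the {stage} stage")
        self.stage = stage


def _default_region_counts() -> dict[str, int]:
    return {"K4_ONLY": 60, "K27_ONLY": 60, "BIVALENT": 80,
            "ALLELIC_HET": 40, "CELLULAR_HET": 40}


@dataclass
class SimulatorConfig:
    """Study conditions for the synthetic sequential-ChIP experiment.

    Defaults describe a two-chromosome 10 Mb genome of 2,000 diploid cells
    with 280 marked regions; antibody efficiency ``capture_specific`` and
    background ``capture_nonspecific`` are chosen so that the qualitative
    behaviour of the experimental controls holds (strong reciprocal reChIP
    enrichment only at truly bivalent regions, IgG–IgG background FRiP well
    below 0.1).
    """

    n_chrom: int = 2
    chrom_length: int = 5_000_000
    nucleosome_spacing: int = 200
    fragment_length: int = 147
    n_cells: int = 2_000
    ploidy: int = 2
    region_counts: dict[str, int] = field(default_factory=_default_region_counts)
    region_width_range: tuple[int, int] = (600, 2_000)
    het_fraction: float = 0.5
    mark_prob: float = 0.8
    background_mark_prob: float = 0.001
    capture_specific: float = 0.3
    capture_nonspecific: float = 0.003
    elution_efficiency: float = 0.8
    carryover: float = 0.002
    depth: int = 500_000
    seed: int = 0
    mode: str = "WT"
    dko_dependent_fraction: float = 0.1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        probs = {
            "het_fraction": self.het_fraction,
            "mark_prob": self.mark_prob,
            "background_mark_prob": self.background_mark_prob,
            "capture_specific": self.capture_specific,
            "capture_nonspecific": self.capture_nonspecific,
            "elution_efficiency": self.elution_efficiency,
            "carryover": self.carryover,
            "dko_dependent_fraction": self.dko_dependent_fraction,
        }
        for k, v in probs.items():
            if not 0 <= v <= 1:
                raise ValueError(f"{k}={v} outside [0, 1]")
        if self.capture_specific <= self.capture_nonspecific:
            raise ValueError(
                "capture_specific must exceed capture_nonspecific, "
                "otherwise there is no signal to simulate")
        if self.region_width_range[0] < self.nucleosome_spacing:
            raise ValueError("region widths must be >= nucleosome_spacing")
        if self.region_width_range[0] > self.region_width_range[1]:
            raise ValueError("region_width_range must be (low, high)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.ploidy != 2:
            raise ValueError("only diploid simulations are supported")
        if self.mode not in {"WT", "TAZ", "DKO"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        unknown = set(self.region_counts) - set(STATES)
        if unknown:
            raise ValueError(f"unknown region states: {unknown}")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chrom)}

    @property
    def genome_length(self) -> int:
        return self.n_chrom * self.chrom_length

    def to_dict(self) -> dict:
        d = asdict(self)
        d["region_width_range"] = list(self.region_width_range)
        return d


@dataclass
class TruthMap:
    """Ground-truth region states for a synthetic genome.

    Regions are non-overlapping and sorted; every base not listed has state
    ``NONE``.
    """

    regions: pd.DataFrame  # chrom, start, end, state, dko_dependent
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        self.regions = self.regions.reset_index(drop=True)

    def by_state(self, *states: str) -> IntervalSet:
        sub = self.regions[self.regions["state"].isin(states)]
        return IntervalSet(sub[["chrom", "start", "end"]])

    def dko_dependent(self) -> IntervalSet:
        sub = self.regions[self.regions["dko_dependent"]]
        return IntervalSet(sub[["chrom", "start", "end"]])

    def to_interval_set(self) -> IntervalSet:
        df = self.regions.rename(columns={"state": "name"})
        return IntervalSet(df[["chrom", "start", "end", "name"]])

    def write_bed(self, path: str | Path) -> None:
        out = self.regions.copy()
        out["dko_dependent"] = out["dko_dependent"].astype(int)
        out.to_csv(path, sep="\t", header=False, index=False,
                   columns=["chrom", "start", "end", "state", "dko_dependent"])

    @classmethod
    def read_bed(cls, path: str | Path,
                 chrom_sizes: dict[str, int]) -> "TruthMap":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "state",
                                "dko_dependent"])
        df["dko_dependent"] = df["dko_dependent"].astype(bool)
        return cls(df, chrom_sizes)


def validate_plan(plan: Sequence[str]) -> tuple[str, ...]:
    plan = tuple(plan)
    if len(plan) not in (1, 2):
        raise ValueError("an antibody plan has one or two rounds")
    for t in plan:
        if t not in _VALID_TARGETS:
            raise ValueError(f"unknown antibody target {t!r}")
    return plan


def plan_name(plan: Sequence[str]) -> str:
    names = {K4: "k4", K27: "k27", IGG: "igg"}
    return "".join(names[t] for t in validate_plan(plan)) if len(plan) == 2 \
        else names[plan[0]] + "_total"


# ---------------------------------------------------------------------------
# Truth construction
# ---------------------------------------------------------------------------

def build_truth(config: SimulatorConfig) -> TruthMap:
    """Place the configured regions uniformly at random, without overlap.

    Regions keep >= 2 fragment lengths of clearance from each other.  A
    seeded subset of BIVALENT regions (``dko_dependent_fraction``) is
    flagged ``dko_dependent``; the flag is drawn for every mode so that WT
    and DKO studies generated from the same seed share one truth map, and
    only DKO-mode sampling acts on it.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    states = [s for s in STATES for _ in range(config.region_counts.get(s, 0))]
    rng.shuffle(states)
    chroms = list(config.chrom_sizes)
    gap = 2 * config.fragment_length
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    max_tries = 200
    for state in states:
        width = int(rng.integers(config.region_width_range[0],
                                 config.region_width_range[1] + 1))
        for attempt in range(max_tries):
            chrom = chroms[int(rng.integers(len(chroms)))]
            limit = config.chrom_sizes[chrom] - width - gap
            if limit <= gap:
                continue
            start = int(rng.integers(gap, limit))
            end = start + width
            ok = all(start - gap >= pe or end + gap <= ps
                     for ps, pe in placed[chrom])
            if ok:
                placed[chrom].append((start, end))
                rows.append((chrom, start, end, state))
                break
        else:
            raise CapacityError(
                f"could not place a {state} region of width {width} after "
                f"{max_tries} attempts; genome too small for region_counts")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    df["dko_dependent"] = False
    biv_idx = df.index[df["state"] == "BIVALENT"].to_numpy()
    n_dep = int(round(config.dko_dependent_fraction * len(biv_idx)))
    if n_dep:
        dep = rng.choice(biv_idx, size=n_dep, replace=False)
        df.loc[dep, "dko_dependent"] = True
    return TruthMap(df, dict(config.chrom_sizes))


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _mark_probs_for_groups(state: str, config: SimulatorConfig,
                           dko_dependent: bool) -> list[tuple[int, float, float]]:
    """Per homogeneous group of (cell, allele) trials at one nucleosome:
    (n_trials, P(K4 on fragment), P(K27 on fragment))."""
    n_alleles = config.n_cells * config.ploidy
    m = config.mark_prob
    eps = config.background_mark_prob
    if config.mode == "DKO" and dko_dependent:
        state = "NONE"
    if state == "NONE":
        return [(n_alleles, eps, eps)]
    if state == "K4_ONLY":
        return [(n_alleles, m, 0.0)]
    if state == "K27_ONLY":
        return [(n_alleles, 0.0, m)]
    if state == "BIVALENT":
        return [(n_alleles, m, m)]
    if state == "ALLELIC_HET":
        return [(config.n_cells, m, 0.0), (config.n_cells, 0.0, m)]
    if state == "CELLULAR_HET":
        n_k4_cells = int(config.het_fraction * config.n_cells)
        return [(n_k4_cells * config.ploidy, m, 0.0),
                ((config.n_cells - n_k4_cells) * config.ploidy, 0.0, m)]
    raise ValueError(f"unknown state {state!r}")


def _capture_probs(plan_round: str, config: SimulatorConfig) -> np.ndarray:
    """Capture probability for the 4 mark categories (none, K4, K27, both)."""
    e, b = config.capture_specific, config.capture_nonspecific
    if plan_round == IGG:
        return np.array([b, b, b, b])
    if plan_round == K4:
        return np.array([b, e, b, e])
    return np.array([b, b, e, e])  # K27


def simulate_sample(truth: TruthMap, config: SimulatorConfig,
                    plan: Sequence[str], seed: int | None = None) -> FragmentSet:
    """Draw one sample's fragments through the immunoprecipitation plan.

    Returns at most ``config.depth`` fragments (a seeded subsample without
    replacement); if fewer survive, all survivors are returned with a
    logged warning.  Raises :class:`EmptyPoolError` when a stage empties
    the pool.
    """
    plan = validate_plan(plan)
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    m = config
    half = m.fragment_length // 2
    taz = m.mode == "TAZ"

    all_chroms, all_centers, all_counts = [], [], []
    r1_total = eluted_total = 0

    for chrom, size in truth.chrom_sizes.items():
        n_pos = size // m.nucleosome_spacing
        centers = (np.arange(n_pos) * m.nucleosome_spacing
                   + m.nucleosome_spacing // 2)
        regions = truth.regions[truth.regions["chrom"] == chrom]
        # group nucleosome positions by (state, dko flag); default NONE
        pos_group = np.zeros(n_pos, dtype=np.int64)  # 0 => NONE
        group_specs: list[tuple[str, bool]] = [("NONE", False)]
        for row in regions.itertuples(index=False):
            lo = np.searchsorted(centers, row.start, side="left")
            hi = np.searchsorted(centers, row.end, side="left")
            if hi > lo:
                group_specs.append((row.state, bool(row.dko_dependent)))
                pos_group[lo:hi] = len(group_specs) - 1

        survived = np.zeros(n_pos, dtype=np.int64)
        for gi, (state, dko_dep) in enumerate(group_specs):
            idx = np.flatnonzero(pos_group == gi)
            if len(idx) == 0:
                continue
            for n_trials, p4, p27 in _mark_probs_for_groups(state, m, dko_dep):
                if n_trials == 0:
                    continue
                if taz:
                    p27 = 0.0
                pvals = np.array([(1 - p4) * (1 - p27), p4 * (1 - p27),
                                  (1 - p4) * p27, p4 * p27])
                cat = rng.multinomial(n_trials, pvals, size=len(idx))
                p1 = _capture_probs(plan[0], m)
                r1 = rng.binomial(cat, p1)
                r1_total += int(r1.sum())
                if len(plan) == 1:
                    survived[idx] += r1.sum(axis=1)
                    continue
                kept = rng.binomial(r1, m.elution_efficiency)
                eluted_total += int(kept.sum())
                p2 = _capture_probs(plan[1], m)
                p2 = 1.0 - (1.0 - p2) * (1.0 - m.carryover)
                r2 = rng.binomial(kept, p2)
                survived[idx] += r2.sum(axis=1)

        nz = np.flatnonzero(survived)
        all_chroms.append(np.repeat(np.array([chrom], dtype=object),
                                    survived[nz].sum()))
        all_centers.append(np.repeat(centers[nz], survived[nz]))
        all_counts.append(int(survived[nz].sum()))

    n_surv = int(sum(all_counts))
    if n_surv == 0:
        if r1_total == 0:
            raise EmptyPoolError("first immunoprecipitation")
        if len(plan) == 2 and eluted_total == 0:
            raise EmptyPoolError("elution")
        raise EmptyPoolError("second immunoprecipitation")

    chrom_arr = np.concatenate(all_chroms)
    center_arr = np.concatenate(all_centers)
    if n_surv > m.depth:
        pick = np.sort(rng.choice(n_surv, size=m.depth, replace=False))
        chrom_arr, center_arr = chrom_arr[pick], center_arr[pick]
    else:
        logger.warning(
            "plan %s: only %d fragments survived (< depth %d); emitting all",
            "-".join(plan), n_surv, m.depth)
    starts = np.maximum(center_arr - half, 0)
    df = pd.DataFrame({"chrom": chrom_arr, "start": starts,
                       "end": starts + m.fragment_length})
    df = df.sort_values(["chrom", "start"], kind="mergesort")
    return FragmentSet(df, sample_id="-".join(plan))


# ---------------------------------------------------------------------------
# Whole-study generation
# ---------------------------------------------------------------------------

_STUDY_PLANS = {
    "k4_total": PLAN_TOTAL_K4,
    "k27_total": PLAN_TOTAL_K27,
    "k4k27": PLAN_K4K27,
    "k27k4": PLAN_K27K4,
}


def sample_seed(base_seed: int, sample_id: str) -> int:
    """Deterministic per-sample seed: base seed + CRC32 of the sample id."""
    return (int(base_seed) + zlib.crc32(sample_id.encode())) % (2 ** 31)


def make_study(config: SimulatorConfig, replicates: int, outdir: str | Path,
               overwrite: bool = False) -> pd.DataFrame:
    """Generate a full synthetic study on disk.

    Per replicate: total H3K4me3, total H3K27me3, and both reChIP
    orientations; plus one shared IgG–IgG control (9 fragment files for two
    replicates).  Also writes the truth BED, chromosome sizes, a config echo
    (YAML) and the tab-separated sample sheet, and returns the sheet.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{outdir} exists and is not empty; pass overwrite=True")
    outdir.mkdir(parents=True, exist_ok=True)

    truth = build_truth(config)
    truth.write_bed(outdir / "truth.bed")
    write_chrom_sizes(config.chrom_sizes, outdir / "chrom.sizes")

    import yaml
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    condition = config.mode
    rows = []
    for rep in range(1, replicates + 1):
        for role, plan in _STUDY_PLANS.items():
            sid = f"{condition}_rep{rep}_{role}"
            seed = sample_seed(config.seed, sid)
            frags = simulate_sample(truth, config, plan, seed=seed)
            path = outdir / f"{sid}.bed"
            frags.df.to_csv(path, sep="\t", header=False, index=False,
                            columns=["chrom", "start", "end"])
            rows.append((sid, role, condition, rep, str(path), seed))
    sid = f"{condition}_igg_igg"
    seed = sample_seed(config.seed, sid)
    frags = simulate_sample(truth, config, PLAN_IGG_IGG, seed=seed)
    path = outdir / f"{sid}.bed"
    frags.df.to_csv(path, sep="\t", header=False, index=False,
                    columns=["chrom", "start", "end"])
    rows.append((sid, "igg_igg", condition, 1, str(path), seed))

    sheet = pd.DataFrame(rows, columns=["sample_id", "role", "condition",
                                        "replicate", "path", "seed"])
    sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    return sheet


def dko_config(config: SimulatorConfig) -> SimulatorConfig:
    """The matched double-knockout condition for a WT configuration."""
    return replace(config, mode="DKO")
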