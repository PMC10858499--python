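"""End-to-end orchestration: sample sheet in, bivalency report out.

The pipeline mirrors the standard sequential-ChIP analysis: call islands
per sample against the IgG–IgG control, intersect replicates into
consensus peak sets per role, intersect the two reChIP orientations into
reciprocal-bivalent regions, stratify them against the total single-ChIP
consensus sets, assign promoter classes, compute QC (FRiP, in-silico
comparison), and — when the sheet carries two conditions — run the
differential bivalency test in both orientations.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import bivalency, differential, quantify
from .intervals import (FragmentSet, IntervalSet, read_chrom_sizes,
                        read_fragments, read_tss)
from .peaks import PeakCallConfig, PeakSet, call_islands, filter_peaks
from .simulate import SimulatorConfig

logger = logging.getLogger(__name__)

RECHIP_ROLES = ("k4k27", "k27k4")
TOTAL_ROLES = ("k4_total", "k27_total")
CONTROL_ROLES = ("igg_igg", "input")
KNOWN_ROLES = RECHIP_ROLES + TOTAL_ROLES + CONTROL_ROLES


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Nested configuration for the whole pipeline; YAML round-trippable."""

    seed: int = 0
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    peaks: PeakCallConfig = field(default_factory=PeakCallConfig)
    diff: differential.DiffConfig = field(default_factory=differential.DiffConfig)
    paths: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"seed": self.seed,
                "simulator": self.simulator.to_dict(),
                "peaks": self.peaks.__dict__.copy(),
                "diff": self.diff.__dict__.copy(),
                "paths": dict(self.paths)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {"seed", "simulator", "peaks", "diff", "paths"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim = dict(d.get("simulator", {}))
        if "region_width_range" in sim:
            sim["region_width_range"] = tuple(sim["region_width_range"])
        if "region_counts" in sim:
            sim["region_counts"] = dict(sim["region_counts"])
        return cls(seed=int(d.get("seed", 0)),
                   simulator=SimulatorConfig(**sim),
                   peaks=PeakCallConfig(**d.get("peaks", {})),
                   diff=differential.DiffConfig(**d.get("diff", {})),
                   paths=dict(d.get("paths", {})))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    required = {"sample_id", "role", "path"}
    missing = required - set(sheet.columns)
    if missing:
        raise PipelineError("sample-sheet", f"missing columns: {sorted(missing)}")
    bad = set(sheet["role"]) - set(KNOWN_ROLES)
    if bad:
        raise PipelineError("sample-sheet", f"unknown roles: {sorted(bad)}")
    if "condition" not in sheet.columns:
        sheet["condition"] = "NA"
    return sheet


def _load_fragments(sheet: pd.DataFrame) -> dict[str, FragmentSet]:
    return {row.sample_id: read_fragments(row.path, sample_id=row.sample_id)
            for row in sheet.itertuples(index=False)}


def run_all(config: PipelineConfig, sample_sheet: str | Path | pd.DataFrame,
            chrom_sizes: Mapping[str, int] | str | Path,
            tss_path: str | Path | None = None,
            blacklist: IntervalSet | None = None,
            out_json: str | Path | None = None) -> dict:
    """Execute the full bivalency pipeline from a sample sheet.

    Requires both reChIP orientations and an IgG–IgG control; totals are
    optional (without them the classification stage is skipped).  Returns
    the summary dict (also written to ``out_json`` when given) containing
    every tally the classification and comparison stages define.
    """
    sheet = sample_sheet if isinstance(sample_sheet, pd.DataFrame) \
        else read_sample_sheet(sample_sheet)
    if not isinstance(chrom_sizes, Mapping):
        chrom_sizes = read_chrom_sizes(chrom_sizes)

    roles_present = set(sheet["role"])
    for role in RECHIP_ROLES:
        if role not in roles_present:
            raise PipelineError("inputs", f"missing required role {role!r}")
    if "igg_igg" not in roles_present:
        raise PipelineError("inputs", "missing required role 'igg_igg'")

    logger.info("pipeline config %s, %d samples", config.digest(), len(sheet))
    frags = _load_fragments(sheet)
    conditions = sorted(sheet["condition"].unique())
    summary: dict = {"config_digest": config.digest(), "seed": config.seed,
                     "conditions": conditions}

    def condition_analysis(sub: pd.DataFrame, label: str) -> dict:
        igg_rows = sub[sub["role"] == "igg_igg"]
        if not len(igg_rows):
            raise PipelineError("peaks", f"no IgG–IgG control for {label}")
        control = frags[igg_rows.iloc[0].sample_id]

        peaksets: dict[str, list[PeakSet]] = {}
        for role in RECHIP_ROLES + TOTAL_ROLES:
            rows = sub[sub["role"] == role]
            called = []
            for row in rows.itertuples(index=False):
                pk = call_islands(frags[row.sample_id], control,
                                  config.peaks, dict(chrom_sizes))
                called.append(filter_peaks(pk, config.peaks, blacklist))
            if called:
                peaksets[role] = called

        consensus = {role: bivalency.consensus_peaks(ps)
                     for role, ps in peaksets.items()}
        rec = bivalency.reciprocal_bivalent(consensus["k4k27"],
                                            consensus["k27k4"])
        res = {"n_k4k27": rec.n_k4k27, "n_k27k4": rec.n_k27k4,
               "n_shared": rec.n_shared}

        classified = None
        if "k4_total" in consensus and "k27_total" in consensus:
            classified = bivalency.classify_peaks(
                rec.bivalent, consensus["k4_total"], consensus["k27_total"])
            res["class_tallies"] = classified.tallies()
            comp = bivalency.in_silico_comparison(
                consensus["k4_total"], consensus["k27_total"], rec.bivalent,
                reciprocal=rec, class_tallies=classified.tallies())
            res["in_silico"] = comp.to_dict()

        # QC: FRiP of every sample over the reciprocal-bivalent regions
        sample_ids = sub["sample_id"].tolist()
        res["frip"] = {
            sid: quantify.frip(frags[sid], rec.bivalent).frip
            for sid in sample_ids}

        if tss_path is not None and classified is not None:
            tss = read_tss(tss_path)
            windows = bivalency.promoter_windows(tss, chrom_sizes=chrom_sizes)
            proms = bivalency.classify_promoters(windows, classified)
            res["promoter_tallies"] = (
                proms[proms["class"] != "none"]["class"]
                .value_counts().to_dict())
            res["n_bivalent_promoters"] = int((proms["class"] != "none").sum())
            res["_promoters"] = proms
        res["_consensus"] = consensus
        res["_reciprocal"] = rec
        return res

    per_condition = {}
    for label in conditions:
        sub = sheet[sheet["condition"] == label]
        if not set(RECHIP_ROLES) <= set(sub["role"]):
            continue
        per_condition[label] = condition_analysis(sub, label)
    if not per_condition:
        # single shared condition column or igg shared across conditions:
        per_condition["all"] = condition_analysis(sheet, "all")
    summary["per_condition"] = {
        k: {kk: vv for kk, vv in v.items() if not kk.startswith("_")}
        for k, v in per_condition.items()}

    # differential bivalency when exactly two conditions are testable
    testable = [c for c in per_condition if c != "all"]
    if len(testable) == 2:
        a, b = testable
        try:
            summary["differential"] = _differential_stage(
                sheet, frags, per_condition, a, b, config, chrom_sizes)
        except ValueError as exc:
            raise PipelineError("differential", str(exc)) from exc

    if out_json is not None:
        with open(out_json, "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
    return summary


def _differential_stage(sheet: pd.DataFrame, frags, per_condition,
                        cond_a: str, cond_b: str, config: PipelineConfig,
                        chrom_sizes: Mapping[str, int]) -> dict:
    """Two-orientation differential test between cond_b and cond_a."""
    out: dict = {"contrast": f"{cond_b}:{cond_a}"}
    results = {}
    region_union = None
    for role in RECHIP_ROLES:
        rows = sheet[(sheet["role"] == role)
                     & sheet["condition"].isin([cond_a, cond_b])]
        samples = {r.sample_id: frags[r.sample_id]
                   for r in rows.itertuples(index=False)}
        conditions = {r.sample_id: r.condition
                      for r in rows.itertuples(index=False)}
        # consensus regions: union of both conditions' reciprocal peaks
        union_df = pd.concat(
            [per_condition[c]["_reciprocal"].bivalent.df[
                ["chrom", "start", "end"]] for c in (cond_a, cond_b)],
            ignore_index=True)
        regions = IntervalSet(union_df).merge()
        region_union = regions
        counts = differential.region_counts(samples, regions, conditions)
        bins = differential.bin_genome_counts(samples, chrom_sizes,
                                              conditions=conditions)
        factors = differential.tmm_factors(bins, config.diff)
        results[role] = differential.nb_test(
            counts, factors, config.diff, contrast=(cond_b, cond_a))
    promoters = per_condition[cond_a].get("_promoters")
    calls = differential.call_differential_bivalency(
        results["k4k27"], results["k27k4"], regions=region_union,
        promoters=promoters)
    calls.pop("differential_index", None)
    calls.pop("promoter_genes", None)
    out.update(calls)
    return out
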