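"""End-to-end orchestration: ingest -> select -> series -> profile -> flag.

The pipeline reproduces the full analysis on any pair of inputs
(structure library + activity table): per-compound hit-rate profiling,
the quantile selection cascade, single-cut series extraction over the
selected compounds, series parameter profiling with rank fusion, and
the interference census. Every intermediate is written to the output
directory as delimited text or JSON; with identical inputs and
configuration, reruns are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

from . import activity as act
from . import interference as intf
from .chem import canonicalize_library, read_smiles_file, write_smiles_file
from .fragmentation import SizeRestrictions
from .mms import MMS, build_mms, find_mmps, remove_redundant, write_mms_json
from .profiling import MMSProfile, profile_mms, rank_series

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "PipelineError", "run", "size_histogram"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    structures: str
    activity: str
    output_dir: str
    pains: str | None = None
    aggregators: str | None = None
    thresholds: act.SelectionThresholds | None = None  # None = derive from data
    bulk_hit_rate_upper: float = 0.01
    rule_set: str = "recap"
    restrictions: SizeRestrictions = field(default_factory=SizeRestrictions)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "structures": self.structures,
            "activity": self.activity,
            "output_dir": self.output_dir,
            "pains": self.pains,
            "aggregators": self.aggregators,
            "thresholds": dataclasses.asdict(self.thresholds) if self.thresholds else None,
            "bulk_hit_rate_upper": self.bulk_hit_rate_upper,
            "rule_set": self.rule_set,
            "restrictions": dataclasses.asdict(self.restrictions),
            "seed": self.seed,
            "log_level": self.log_level,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if d.get("thresholds"):
            d["thresholds"] = act.SelectionThresholds(**d["thresholds"])
        if d.get("restrictions"):
            d["restrictions"] = SizeRestrictions(**d["restrictions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass(frozen=True)
class RunReport:
    n_compounds_in: int
    n_parse_failures: int
    n_compounds_profiled: int
    n_compounds_selected: int
    thresholds: dict[str, float]
    n_mmps: int
    n_mms_raw: int
    n_mms: int
    n_mms_compounds: int
    mms_size_histogram: dict[int, int]
    parameter_summaries: dict[str, dict[str, float] | None]
    flag_census: dict[str, int]
    confirmatory_consistency: float | None

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["mms_size_histogram"] = {str(k): v for k, v in sorted(self.mms_size_histogram.items())}
        return d

    def to_text(self) -> str:
        lines = [
            "analog-series promiscuity analysis - run report",
            f"compounds read:            {self.n_compounds_in} ({self.n_parse_failures} parse failures)",
            f"compounds with activity:   {self.n_compounds_profiled}",
            f"high-hit-rate selection:   {self.n_compounds_selected}",
            "thresholds:                "
            + ", ".join(f"{k}={v:.6g}" for k, v in sorted(self.thresholds.items())),
            f"matched molecular pairs:   {self.n_mmps}",
            f"series before/after dedup: {self.n_mms_raw}/{self.n_mms}",
            f"unique series compounds:   {self.n_mms_compounds}",
            "series size histogram:     "
            + ", ".join(f"{k}:{v}" for k, v in sorted(self.mms_size_histogram.items())),
        ]
        for name, summary in sorted(self.parameter_summaries.items()):
            if summary is None:
                lines.append(f"{name:<26} undefined for all series")
            else:
                lines.append(
                    f"{name:<26} median={summary['median']:.4f} "
                    f"q1={summary['q1']:.4f} q3={summary['q3']:.4f}"
                )
        lines.append(
            "interference census:       "
            + ", ".join(f"{k}={v}" for k, v in sorted(self.flag_census.items()))
        )
        if self.confirmatory_consistency is not None:
            lines.append(
                f"confirmatory consistency:  {self.confirmatory_consistency:.4f}"
            )
        return "\n".join(lines) + "\n"


def size_histogram(series: Sequence[MMS]) -> dict[int, int]:
    """Exact member-count histogram of a series collection."""
    hist: dict[int, int] = {}
    for s in series:
        hist[s.size] = hist.get(s.size, 0) + 1
    return dict(sorted(hist.items()))


def _summary_or_none(values: list[float]) -> dict[str, float] | None:
    if not values:
        return None
    return act.summarize_distribution(values).as_dict()


def run(config: PipelineConfig) -> RunReport:
    """Execute all stages and write intermediates to ``output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()

    def _stage(name: str):
        logger.info("stage %-12s t=%.1fs", name, time.monotonic() - t0)

    try:
        _stage("ingest")
        molecules, failures = canonicalize_library(
            (smiles, mid) for smiles, mid in read_smiles_file(config.structures)
        )
        write_smiles_file(out / "library.smi", molecules)
        records = act.read_activity_table(config.activity)
        matrix = act.ingest_records(records)
    except Exception as exc:
        raise PipelineError("ingest", exc) from exc

    try:
        _stage("select")
        profiles = act.compound_profiles(matrix)
        act.profiles_to_frame(profiles).to_csv(out / "compound_profiles.tsv", sep="\t", index=False)
        selected, thresholds, stage_summaries = act.selection_cascade(
            profiles, config.thresholds, bulk_hit_rate_upper=config.bulk_hit_rate_upper
        )
        consistency = None
        if any(p.n_tested_confirmatory > 0 for p in profiles):
            consistency = act.confirmatory_consistency(matrix, selected)
        with open(out / "selection.json", "w") as fh:
            json.dump(
                {
                    "selected": sorted(selected),
                    "thresholds": dataclasses.asdict(thresholds),
                    "stage_hit_rate_summaries": [s.as_dict() for s in stage_summaries],
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
    except Exception as exc:
        raise PipelineError("select", exc) from exc

    try:
        _stage("series")
        selected_mols = sorted(
            (m for m in molecules if m.id in selected), key=lambda m: m.id
        )
        mmps = find_mmps(selected_mols, config.rule_set, config.restrictions)
        raw_series = build_mms(mmps)
        series = remove_redundant(raw_series)
        write_mms_json(out / "mms.json", series)
    except Exception as exc:
        raise PipelineError("series", exc) from exc

    try:
        _stage("characterize")
        series_profiles: list[MMSProfile] = [profile_mms(s, matrix) for s in series]
        ranked = rank_series(series_profiles) if series_profiles else []
        _write_profile_table(out / "mms_profiles.tsv", series_profiles, ranked)
    except Exception as exc:
        raise PipelineError("characterize", exc) from exc

    try:
        _stage("flag")
        catalog = intf.load_pains(config.pains) if config.pains else None
        aggregators = (
            intf.load_aggregators(config.aggregators) if config.aggregators else frozenset()
        )
        member_ids = {m for s in series for m in s.members}
        flags = intf.flag_library(
            [m for m in molecules if m.id in member_ids], catalog, aggregators
        )
        flag_census = intf.census(series, flags)
        _write_flag_table(out / "interference_flags.tsv", flags)
    except Exception as exc:
        raise PipelineError("flag", exc) from exc

    _stage("report")
    report = RunReport(
        n_compounds_in=len(molecules) + len(failures),
        n_parse_failures=len(failures),
        n_compounds_profiled=len(profiles),
        n_compounds_selected=len(selected),
        thresholds=dataclasses.asdict(thresholds),
        n_mmps=len(mmps),
        n_mms_raw=len(raw_series),
        n_mms=len(series),
        n_mms_compounds=len(member_ids),
        mms_size_histogram=size_histogram(series),
        parameter_summaries={
            "assay_overlap": _summary_or_none([p.overlap for p in series_profiles]),
            "mms_hit_rate": _summary_or_none([p.hr for p in series_profiles]),
            "inconsistent_fraction": _summary_or_none(
                [p.inconsistent for p in series_profiles if p.inconsistent is not None]
            ),
            "target_hit_rate": _summary_or_none(
                [p.target_hr for p in series_profiles if p.target_hr is not None]
            ),
        },
        flag_census={
            "with_aggregator": flag_census.n_mms_with_aggregator,
            "with_pains": flag_census.n_mms_with_pains,
            "with_both": flag_census.n_mms_with_both,
            "clean": flag_census.n_mms_clean,
        },
        confirmatory_consistency=consistency,
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    (out / "report.txt").write_text(report.to_text())
    return report


def _write_profile_table(
    path: Path, profiles: Sequence[MMSProfile], ranked: Sequence
) -> None:
    by_key = {
        (r.mms.core, tuple(sorted(r.mms.members))): (r.fused_score, i + 1)
        for i, r in enumerate(ranked)
    }
    with open(path, "w") as fh:
        fh.write(
            "core\tmembers\tn_union_assays\thr\toverlap\tinconsistent\ttarget_hr"
            "\tfused_score\tfused_rank\n"
        )
        rows = sorted(
            profiles, key=lambda p: by_key[(p.mms.core, tuple(sorted(p.mms.members)))][1]
        )
        for p in rows:
            score, rank = by_key[(p.mms.core, tuple(sorted(p.mms.members)))]
            fh.write(
                f"{p.mms.core}\t{';'.join(p.mms.sorted_members())}\t{p.n_union_assays}"
                f"\t{p.hr:.6f}\t{p.overlap:.6f}"
                f"\t{'' if p.inconsistent is None else f'{p.inconsistent:.6f}'}"
                f"\t{'' if p.target_hr is None else f'{p.target_hr:.6f}'}"
                f"\t{score:.4f}\t{rank}\n"
            )


def _write_flag_table(path: Path, flags: dict[str, intf.InterferenceFlags]) -> None:
    with open(path, "w") as fh:
        fh.write("compound_id\tpains_families\tis_aggregator\n")
        for cid in sorted(flags):
            f = flags[cid]
            fh.write(f"{cid}\t{';'.join(f.pains_families)}\t{str(f.is_aggregator).lower()}\n")
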