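"""Compound-level activity profiles and the hit-rate selection cascade.

This module ingests compound-assay outcome records (the shape of a
PubChem BioAssay export: compound id, assay id, active/inactive call,
primary or confirmatory stage, optional target annotation), computes
per-compound assay frequencies and hit rates, and applies a
quantile-based cascade that isolates the extensively tested, highly
active subpopulation:

1. keep compounds tested in *more than* the lower-quartile number of
   primary assays;
2. within those, take the subpopulation with hit rate at or above a
   fixed "bulk" upper bound (default 1.0%, the upper edge of the bulk of
   a typical screening hit-rate distribution);
3. set the high-hit-rate threshold to the *median* hit rate of that
   subpopulation and keep compounds strictly above it.

Inconclusive outcomes are retained in the matrix but excluded from both
the numerator and denominator of every hit rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ActivityRecord",
    "ActivityMatrix",
    "CompoundProfile",
    "DistributionSummary",
    "SelectionThresholds",
    "StageError",
    "ingest_records",
    "read_activity_table",
    "write_activity_table",
    "compound_profiles",
    "summarize_distribution",
    "selection_cascade",
    "confirmatory_consistency",
]

OUTCOMES = ("active", "inactive", "inconclusive")
STAGES = ("primary", "confirmatory")


@dataclass(frozen=True, slots=True)
class ActivityRecord:
    compound_id: str
    assay_id: str
    outcome: str
    stage: str
    target_id: str | None = None

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome token: {self.outcome!r}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage token: {self.stage!r}")


@dataclass(frozen=True, slots=True)
class CompoundProfile:
    """Per-compound assay counts; ``hit_rate`` is over primary assays only."""

    compound_id: str
    n_tested_primary: int
    n_active_primary: int
    n_tested_confirmatory: int
    n_active_confirmatory: int

    @property
    def hit_rate(self) -> float | None:
        if self.n_tested_primary == 0:
            return None
        return self.n_active_primary / self.n_tested_primary


@dataclass(frozen=True, slots=True)
class DistributionSummary:
    """Tukey boxplot statistics: whiskers at the most extreme data points
    within 1.5 x IQR of the box."""

    lower_whisker: float
    q1: float
    median: float
    q3: float
    upper_whisker: float

    def as_dict(self) -> dict[str, float]:
        return {
            "lower_whisker": self.lower_whisker,
            "q1": self.q1,
            "median": self.median,
            "q3": self.q3,
            "upper_whisker": self.upper_whisker,
        }


@dataclass(frozen=True, slots=True)
class SelectionThresholds:
    """Thresholds of the selection cascade.

    ``min_assays_exclusive`` — keep compounds tested in strictly more
    primary assays than this; ``bulk_hit_rate_upper`` — inclusive lower
    bound of the above-bulk subpopulation; ``high_hit_rate_exclusive`` —
    keep compounds with hit rate strictly greater than this.
    """

    min_assays_exclusive: float
    bulk_hit_rate_upper: float
    high_hit_rate_exclusive: float

    def __post_init__(self) -> None:
        if self.bulk_hit_rate_upper <= 0 or self.high_hit_rate_exclusive <= 0:
            raise ValueError("hit-rate thresholds must be positive")
        if self.bulk_hit_rate_upper > self.high_hit_rate_exclusive:
            raise ValueError("bulk_hit_rate_upper must not exceed high_hit_rate_exclusive")


class StageError(ValueError):
    """A cascade stage produced an empty subpopulation."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"selection stage {stage!r}: {message}")


_OUTCOME_RANK = {"active": 2, "inactive": 1, "inconclusive": 0}


class ActivityMatrix:
    """Sparse compound x assay outcome store, resolved per stage.

    Duplicate records for the same (compound, assay, stage) are resolved
    as: active if any record is active, else inactive if any is
    inactive, else inconclusive. Tested/active sets expose only definite
    (active or inactive) outcomes.
    """

    def __init__(self) -> None:
        self._resolved: dict[tuple[str, str, str], str] = {}
        self._compound_ids: set[str] = set()
        self._tested: dict[str, dict[str, set[str]]] = {s: {} for s in STAGES}
        self._active: dict[str, dict[str, set[str]]] = {s: {} for s in STAGES}
        self._assay_target: dict[str, str | None] = {}
        self._assay_stages: dict[str, set[str]] = {}

    # -- construction ----------------------------------------------------
    def add(self, rec: ActivityRecord) -> None:
        key = (rec.compound_id, rec.assay_id, rec.stage)
        prev = self._resolved.get(key)
        if prev is None or _OUTCOME_RANK[rec.outcome] > _OUTCOME_RANK[prev]:
            self._resolved[key] = rec.outcome
        self._compound_ids.add(rec.compound_id)
        tgt = rec.target_id or None
        if tgt is not None:
            self._assay_target[rec.assay_id] = tgt
        else:
            self._assay_target.setdefault(rec.assay_id, None)
        self._assay_stages.setdefault(rec.assay_id, set()).add(rec.stage)

    def _freeze(self) -> None:
        for (cid, aid, stage), outcome in self._resolved.items():
            if outcome == "inconclusive":
                continue
            self._tested[stage].setdefault(cid, set()).add(aid)
            if outcome == "active":
                self._active[stage].setdefault(cid, set()).add(aid)

    # -- queries ----------------------------------------------------------
    def __len__(self) -> int:
        return len(self._resolved)

    def compounds(self) -> list[str]:
        return sorted(self._compound_ids)

    def assays(self) -> list[str]:
        return sorted(self._assay_target)

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._compound_ids

    def tested_assays(self, compound_id: str, stage: str = "primary") -> frozenset[str]:
        return frozenset(self._tested[stage].get(compound_id, ()))

    def active_assays(self, compound_id: str, stage: str = "primary") -> frozenset[str]:
        return frozenset(self._active[stage].get(compound_id, ()))

    def outcome(self, compound_id: str, assay_id: str, stage: str = "primary") -> str | None:
        return self._resolved.get((compound_id, assay_id, stage))

    def target_of(self, assay_id: str) -> str | None:
        return self._assay_target.get(assay_id)

    def annotated_assays(self) -> list[str]:
        return sorted(a for a, t in self._assay_target.items() if t is not None)


def ingest_records(records: Iterable[ActivityRecord]) -> ActivityMatrix:
    """Build an :class:`ActivityMatrix` from a stream of records."""
    matrix = ActivityMatrix()
    n = 0
    for rec in records:
        if not rec.compound_id or not rec.assay_id:
            raise ValueError("compound_id and assay_id must be nonempty")
        matrix.add(rec)
        n += 1
    matrix._freeze()
    return matrix


# -- delimited text I/O ---------------------------------------------------

ACTIVITY_COLUMNS = ["compound_id", "assay_id", "outcome", "stage", "target_id"]


def read_activity_table(path: str | Path) -> list[ActivityRecord]:
    """Read the tab-delimited activity format (header required).

    Columns: compound_id, assay_id, outcome, stage, target_id (empty =
    unannotated). Malformed rows raise with their line number.
    """
    records: list[ActivityRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(ACTIVITY_COLUMNS)] != ACTIVITY_COLUMNS:
            raise ValueError(f"unexpected header in {path}: {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: malformed row: {line!r}")
            cid, aid, outcome, stage = parts[:4]
            target = parts[4] if len(parts) > 4 and parts[4] else None
            try:
                records.append(ActivityRecord(cid, aid, outcome, stage, target))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_activity_table(path: str | Path, records: Sequence[ActivityRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ACTIVITY_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.compound_id}\t{r.assay_id}\t{r.outcome}\t{r.stage}\t{r.target_id or ''}\n"
            )


# -- profiles and statistics ------------------------------------------------


def compound_profiles(matrix: ActivityMatrix) -> list[CompoundProfile]:
    """Per-compound counts over primary and confirmatory stages."""
    if len(matrix) == 0:
        raise ValueError("empty activity matrix")
    profiles = []
    for cid in matrix.compounds():
        profiles.append(
            CompoundProfile(
                compound_id=cid,
                n_tested_primary=len(matrix.tested_assays(cid, "primary")),
                n_active_primary=len(matrix.active_assays(cid, "primary")),
                n_tested_confirmatory=len(matrix.tested_assays(cid, "confirmatory")),
                n_active_confirmatory=len(matrix.active_assays(cid, "confirmatory")),
            )
        )
    return profiles


def summarize_distribution(values: Sequence[float]) -> DistributionSummary:
    """Tukey boxplot summary with linear-interpolation quartiles.

    Whiskers are the most extreme observed values within 1.5 x IQR of
    the box edges (so for tight distributions they equal min/max).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("summarize_distribution requires at least one value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    # whiskers clip to the box edge when no data point lies beyond it
    # inside the fence (interpolated quartiles need not be data points)
    lo = min(float(arr[arr >= lo_fence].min()), float(q1))
    hi = max(float(arr[arr <= hi_fence].max()), float(q3))
    return DistributionSummary(
        lower_whisker=lo,
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        upper_whisker=hi,
    )


def selection_cascade(
    profiles: Sequence[CompoundProfile],
    thresholds: SelectionThresholds | None = None,
    *,
    bulk_hit_rate_upper: float = 0.01,
) -> tuple[set[str], SelectionThresholds, list[DistributionSummary]]:
    """Select the extensively tested, high-hit-rate compound subset.

    With ``thresholds=None`` the cutoffs are derived from the data:
    the assay-frequency lower quartile (strictly exceeded), the fixed
    ``bulk_hit_rate_upper`` (inclusive), and the median hit rate of the
    above-bulk subpopulation (strictly exceeded). Returns the surviving
    compound ids, the thresholds used, and the hit-rate distribution
    summaries of the three successive subpopulations.

    Note the strictness conventions: a compound tested in exactly
    ``min_assays_exclusive`` assays is dropped; hit rate exactly equal
    to ``bulk_hit_rate_upper`` is kept in the above-bulk subpopulation;
    hit rate exactly equal to ``high_hit_rate_exclusive`` is dropped
    from the final set.
    """
    usable = [p for p in profiles if p.n_tested_primary > 0]
    if not usable:
        raise StageError("frequency", "no compound has primary assay data")

    tested = np.array([p.n_tested_primary for p in usable], dtype=float)
    if thresholds is None:
        min_assays = float(np.percentile(tested, 25))
        bulk_upper = bulk_hit_rate_upper
    else:
        min_assays = thresholds.min_assays_exclusive
        bulk_upper = thresholds.bulk_hit_rate_upper

    stage1 = [p for p in usable if p.n_tested_primary > min_assays]
    if not stage1:
        raise StageError("frequency", f"no compound tested in more than {min_assays} assays")
    summaries = [summarize_distribution([p.hit_rate for p in stage1])]

    stage2 = [p for p in stage1 if p.hit_rate >= bulk_upper]
    if not stage2:
        raise StageError("bulk", f"no compound with hit rate >= {bulk_upper}")
    summaries.append(summarize_distribution([p.hit_rate for p in stage2]))

    if thresholds is None:
        high = float(np.median([p.hit_rate for p in stage2]))
        thresholds = SelectionThresholds(
            min_assays_exclusive=min_assays,
            bulk_hit_rate_upper=bulk_upper,
            high_hit_rate_exclusive=high,
        )
    high = thresholds.high_hit_rate_exclusive

    final = [p for p in stage1 if p.hit_rate > high]
    if not final:
        raise StageError("high", f"no compound with hit rate > {high}")
    summaries.append(summarize_distribution([p.hit_rate for p in final]))

    return {p.compound_id for p in final}, thresholds, summaries


def confirmatory_consistency(matrix: ActivityMatrix, ids: Iterable[str]) -> float:
    """Fraction of ``ids`` with at least one confirmatory-stage active."""
    id_list = list(ids)
    if not id_list:
        raise ValueError("empty compound id set")
    n_confirmed = sum(1 for cid in id_list if len(matrix.active_assays(cid, "confirmatory")) > 0)
    return n_confirmed / len(id_list)


def profiles_to_frame(profiles: Sequence[CompoundProfile]) -> pd.DataFrame:
    """Tabular view of compound profiles (for reports and exports)."""
    return pd.DataFrame(
        {
            "compound_id": [p.compound_id for p in profiles],
            "n_tested_primary": [p.n_tested_primary for p in profiles],
            "n_active_primary": [p.n_active_primary for p in profiles],
            "hit_rate": [p.hit_rate for p in profiles],
            "n_tested_confirmatory": [p.n_tested_confirmatory for p in profiles],
            "n_active_confirmatory": [p.n_active_confirmatory for p in profiles],
        }
    )
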