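"""Series-level promiscuity parameters and rank-fusion prioritization.

Three parameters characterize an analog series against a compound-assay
activity matrix, all computed over primary assays only:

* **series hit rate** — active assays over the assay *union* (assays in
  which at least one member was tested; an assay is active when at
  least one member was active in it);
* **assay overlap** — shared assays (tested by *every* member, the
  intersection) over the union; a confidence measure for comparing
  members;
* **inconsistent fraction** — the proportion of shared assays in which
  some members were active and others inactive.

High overlap and hit rate with few inconsistent assays mark a series
whose activity signal is coherent across analogs. Series are ranked on
the three criteria (descending hit rate and overlap, ascending
inconsistency) and fused by the unweighted mean of ranks (Borda-style).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .activity import ActivityMatrix
from .mms import MMS

__all__ = [
    "MemberStats",
    "MMSProfile",
    "RankedMMS",
    "profile_mms",
    "target_hit_rate",
    "rank_series",
]


@dataclass(frozen=True, slots=True)
class MemberStats:
    n_tested: int
    n_active: int

    @property
    def hit_rate(self) -> float:
        return self.n_active / self.n_tested if self.n_tested else 0.0


@dataclass(frozen=True, slots=True)
class MMSProfile:
    """Assay-statistics profile of one analog series.

    ``inconsistent`` and ``target_hr`` are ``None`` when undefined
    (empty assay intersection; no target-annotated assay touched).
    """

    mms: MMS
    n_union_assays: int
    n_union_active: int
    n_shared_assays: int
    hr: float
    overlap: float
    inconsistent: float | None
    target_hr: float | None
    per_member: Mapping[str, MemberStats]


@dataclass(frozen=True, slots=True)
class RankedMMS:
    mms: MMS
    rank_hr: float
    rank_overlap: float
    rank_inconsistent: float
    fused_score: float


def _member_sets(
    mms: MMS, matrix: ActivityMatrix
) -> tuple[dict[str, frozenset[str]], dict[str, frozenset[str]]]:
    tested: dict[str, frozenset[str]] = {}
    active: dict[str, frozenset[str]] = {}
    for member in mms.sorted_members():
        if member not in matrix:
            raise KeyError(f"series member {member!r} absent from activity matrix")
        t = matrix.tested_assays(member, "primary")
        if not t:
            raise ValueError(f"series member {member!r} has no primary assay data")
        tested[member] = t
        active[member] = matrix.active_assays(member, "primary")
    return tested, active


def profile_mms(mms: MMS, matrix: ActivityMatrix) -> MMSProfile:
    """Compute hit rate, assay overlap and inconsistency for a series.

    Only definite primary outcomes count: an assay belongs to a
    member's tested set when the member was called active or inactive
    in it. In a shared assay every member therefore has a definite
    call, and the assay is inconsistent exactly when both calls occur.
    """
    tested, active = _member_sets(mms, matrix)

    union: set[str] = set().union(*tested.values())
    shared: set[str] = frozenset.intersection(*tested.values())
    union_active: set[str] = set().union(*active.values())

    n_union = len(union)
    n_shared = len(shared)
    inconsistent: float | None = None
    if n_shared:
        n_inconsistent = 0
        for assay in shared:
            n_act = sum(1 for m in active.values() if assay in m)
            if 0 < n_act < len(tested):
                n_inconsistent += 1
        inconsistent = n_inconsistent / n_shared

    return MMSProfile(
        mms=mms,
        n_union_assays=n_union,
        n_union_active=len(union_active),
        n_shared_assays=n_shared,
        hr=len(union_active) / n_union,
        overlap=n_shared / n_union,
        inconsistent=inconsistent,
        target_hr=target_hit_rate(mms, matrix),
        per_member={
            m: MemberStats(n_tested=len(tested[m]), n_active=len(active[m]))
            for m in mms.sorted_members()
        },
    )


def target_hit_rate(mms: MMS, matrix: ActivityMatrix) -> float | None:
    """Series hit rate over annotated targets instead of assays.

    Restricted to target-annotated primary assays: a target counts as
    tested when any member was tested in any of its assays, and as
    active when any member was active in any of them. ``None`` when the
    series touches no annotated assay.
    """
    tested, active = _member_sets(mms, matrix)
    tested_targets: set[str] = set()
    active_targets: set[str] = set()
    for member in tested:
        for assay in tested[member]:
            target = matrix.target_of(assay)
            if target is None:
                continue
            tested_targets.add(target)
            if assay in active[member]:
                active_targets.add(target)
    if not tested_targets:
        return None
    return len(active_targets) / len(tested_targets)


def rank_series(profiles: Sequence[MMSProfile]) -> list[RankedMMS]:
    """Prioritize series by rank fusion over the three parameters.

    Ranks run from 1 (best) per criterion with ties averaged: hit rate
    and overlap descending, inconsistency ascending. A series with an
    undefined inconsistent fraction ranks last on that criterion (no
    shared assays means no evidence of consistency). The fused score is
    the mean of the three ranks; output is sorted ascending by fused
    score with the core string as tie-break.
    """
    if not profiles:
        raise ValueError("rank_series requires at least one profile")
    hr = np.array([p.hr for p in profiles])
    overlap = np.array([p.overlap for p in profiles])
    inconsistent = np.array(
        [p.inconsistent if p.inconsistent is not None else np.inf for p in profiles]
    )
    rank_hr = rankdata(-hr, method="average")
    rank_ov = rankdata(-overlap, method="average")
    rank_inc = rankdata(inconsistent, method="average")
    fused = (rank_hr + rank_ov + rank_inc) / 3.0
    ranked = [
        RankedMMS(
            mms=p.mms,
            rank_hr=float(rank_hr[i]),
            rank_overlap=float(rank_ov[i]),
            rank_inconsistent=float(rank_inc[i]),
            fused_score=float(fused[i]),
        )
        for i, p in enumerate(profiles)
    ]
    ranked.sort(key=lambda r: (r.fused_score, r.mms.core, sorted(r.mms.members)))
    return ranked
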