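"""Affinity-purification interactome analysis.

Implements the standard AP-MS triage for tagged-bait pulldowns with untagged
controls:

1. reliability filtering — a prey is kept only if it is seen in the
   intersection (or, optionally, union) of the tagged biological replicates
   and in none of the control runs;
2. descending emPAI ranking of the reliable preys, with competition ("1224")
   rank numbers for ties;
3. cross-bait membership classification — a prey detected with baits of two
   or more complexes is called *shared*, a prey detected only with baits of a
   single complex is *specific* to it, and a prey detected with no bait is
   *unassigned*.

The classification formalises exclusivity logic used to separate two
partially overlapping chromatin-remodeling complexes (SWI/SNF-type and
RSC-type) that share a common core but carry complex-specific subunits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TapRun:
    """One purification run: bait, replicate index, prey -> peptide count."""

    bait_id: str
    replicate: int
    observations: Mapping[str, int]
    is_control: bool = False

    def preys(self) -> frozenset[str]:
        return frozenset(self.observations)


@dataclass
class EmpaiRanking:
    run_id: str
    #: list of (rank, protein_id, empai), emPAI non-increasing
    entries: list[tuple[int, str, float]] = field(default_factory=list)

    def proteins(self) -> list[str]:
        return [p for _, p, _ in self.entries]


@dataclass(frozen=True)
class MembershipCall:
    protein_id: str
    label: str  # "shared" | "specific:<complex>" | "unassigned"
    #: per-bait detection flags backing the call
    support: Mapping[str, bool]


def filter_reliable_preys(
    tagged_replicates: list[set[str]],
    control_runs: list[set[str]],
    mode: str = "intersection",
) -> set[str]:
    """Replicate-consistent preys minus everything seen in any control.

    ``mode="intersection"`` keeps preys present in every tagged replicate
    (the triplicate-intersection rule); ``mode="union"`` keeps preys present
    in at least one replicate. Control subtraction removes the union of all
    control runs in either mode.
    """
    if not tagged_replicates:
        raise ValueError("at least one tagged replicate is required")
    if not control_runs:
        raise ValueError("at least one control run is required")
    if mode == "intersection":
        kept = set.intersection(*map(set, tagged_replicates))
    elif mode == "union":
        kept = set.union(*map(set, tagged_replicates))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return kept - set.union(*map(set, control_runs))


def rank_preys(scores: Mapping[str, float], run_id: str = "") -> EmpaiRanking:
    """Order preys by descending emPAI; ties share a competition rank.

    Equal scores get equal rank numbers and the next distinct score resumes
    at its 1-based list position (1-2-2-4), with protein id as a
    deterministic secondary sort key.
    """
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    entries: list[tuple[int, str, float]] = []
    rank = 0
    prev: float | None = None
    for pos, (pid, s) in enumerate(ordered, start=1):
        if prev is None or s != prev:
            rank = pos
            prev = s
        entries.append((rank, pid, s))
    return EmpaiRanking(run_id, entries)


def classify_membership(
    detections: Mapping[str, set[str]] | pd.DataFrame,
    bait_complexes: Mapping[str, str | set[str]],
    require_all_baits: bool = False,
) -> list[MembershipCall]:
    """Label preys shared / specific / unassigned from per-bait reliable sets.

    Parameters
    ----------
    detections
        Either a mapping bait id -> reliable prey set, or a boolean DataFrame
        with baits as rows and preys as columns.
    bait_complexes
        Bait id -> complex name (or set of names).  Baits mapped to more than
        one complex cannot discriminate specificity and are excluded from the
        exclusivity test.
    require_all_baits
        If True a "specific" call needs detection with *every* bait of the
        complex; the default needs at least one (and still zero detections
        with any other complex's baits).
    """
    if isinstance(detections, pd.DataFrame):
        detections = {b: set(detections.columns[detections.loc[b].astype(bool)])
                      for b in detections.index}
    unknown = set(detections) - set(bait_complexes)
    if unknown:
        raise ValueError(f"baits with no complex assignment: {sorted(unknown)}")

    def complexes_of(bait: str) -> set[str]:
        c = bait_complexes[bait]
        return {c} if isinstance(c, str) else set(c)

    informative = [b for b in detections if len(complexes_of(b)) == 1]
    all_complexes = {next(iter(complexes_of(b))) for b in informative}
    if len(all_complexes) < 2:
        raise ValueError("need informative baits from at least two complexes")

    preys = sorted(set().union(*detections.values()))
    calls = []
    for prey in preys:
        support = {b: prey in detections[b] for b in detections}
        hit_cx = {next(iter(complexes_of(b))) for b in informative if support[b]}
        if len(hit_cx) >= 2:
            label = "shared"
        elif len(hit_cx) == 1:
            cx = next(iter(hit_cx))
            cx_baits = [b for b in informative if complexes_of(b) == {cx}]
            ok = all(support[b] for b in cx_baits) if require_all_baits else True
            label = f"specific:{cx}" if ok else "unassigned"
        else:
            label = "unassigned"
        calls.append(MembershipCall(prey, label, support))
    return calls


def co_purification_report(
    rankings: Mapping[str, EmpaiRanking],
    absent_marker: float = np.nan,
) -> pd.DataFrame:
    """Prey-by-bait emPAI matrix; undetected cells carry the absent marker."""
    if not rankings:
        raise ValueError("at least one ranking is required")
    preys = sorted({p for r in rankings.values() for p in r.proteins()})
    table = pd.DataFrame(absent_marker, index=preys, columns=list(rankings), dtype=float)
    for bait, ranking in rankings.items():
        for _, pid, score in ranking.entries:
            table.loc[pid, bait] = score
    table.index.name = "prey"
    return table


def runs_to_replicate_sets(runs: Iterable[TapRun], bait_id: str) -> tuple[list[set[str]], list[set[str]]]:
    """Split a run collection into tagged replicate prey sets and control sets."""
    tagged = [set(r.observations) for r in runs if not r.is_control and r.bait_id == bait_id]
    controls = [set(r.observations) for r in runs if r.is_control]
    return tagged, controls


def runs_from_table(table: pd.DataFrame) -> list[TapRun]:
    """Build TapRun objects from a long-format observation table.

    Expected columns: bait, replicate, is_control, protein, peptides_observed.
    """
    runs = []
    for (bait, rep, ctrl), grp in table.groupby(["bait", "replicate", "is_control"], sort=True):
        obs = dict(zip(grp["protein"], grp["peptides_observed"].astype(int)))
        runs.append(TapRun(str(bait), int(rep), obs, bool(ctrl)))
    return runs
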