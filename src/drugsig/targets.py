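"""Per-drug top protein targets, consensus target rankings across drug sets,
and overlap of target lists with gold-standard protein sets.

The top-target list of a drug is simply its interaction signature sorted by
descending score (no score floor by default).  A consensus target ranking
across a drug set orders proteins by how many of the drugs' top lists they
appear on, then by mean position, mirroring how a shared mechanism surfaces
across related drugs.  Overlap with an independently curated gold standard is
quantified three ways: relative frequency of intersections within five rank
bins of the top-100 window, cumulative overlap percentage of the gold
standard recovered up to a cutoff, and the Jaccard coefficient between the
top-cutoff set and the gold standard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .interaction import InteractionMatrix

logger = logging.getLogger(__name__)

RANK_BINS = ((0, 20), (20, 40), (40, 60), (60, 80), (80, 100))
DEFAULT_CUTOFFS = (20, 40, 60, 80, 100)


@dataclass
class TargetList:
    """One drug's proteins ordered by descending interaction score."""

    compound_id: str
    entries: list[tuple[str, float]]

    def __len__(self) -> int:
        return len(self.entries)

    def top(self, cutoff: int) -> list[str]:
        return [pid for pid, _ in self.entries[:cutoff]]


def top_targets(
    matrix: InteractionMatrix,
    compound_id: str,
    n: int = 100,
    score_floor: float | None = None,
) -> TargetList:
    """The drug's n strongest predicted protein interactions.

    Ties on score break by ascending protein_id.  ``score_floor`` optionally
    drops proteins below a minimum score (off by default).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    signature = matrix.signature(compound_id)
    pairs = sorted(
        zip(matrix.protein_ids, signature.tolist()), key=lambda t: (-t[1], t[0])
    )
    if score_floor is not None:
        pairs = [(pid, s) for pid, s in pairs if s >= score_floor]
    return TargetList(compound_id=compound_id, entries=pairs[:n])


@dataclass(frozen=True)
class ConsensusTargetRow:
    """A protein's aggregate standing across several drugs' top-target lists.

    ``average_rank`` is the mean 0-based position on the lists where the
    protein appears; ``average_score`` is its mean interaction score on those
    same lists.
    """

    protein_id: str
    consensus_score: int
    average_rank: float
    average_score: float


def consensus_targets(
    matrix: InteractionMatrix, drug_set: Iterable[str], n: int = 100
) -> list[ConsensusTargetRow]:
    """Order proteins by frequency of appearance across the drugs' top-n lists.

    Ties: ascending average rank, then protein_id.
    """
    drugs = list(dict.fromkeys(drug_set))
    if not drugs:
        raise ValueError("drug set is empty")
    counts: dict[str, int] = {}
    rank_sums: dict[str, float] = {}
    score_sums: dict[str, float] = {}
    for drug in drugs:
        for pos, (pid, score) in enumerate(top_targets(matrix, drug, n=n).entries):
            counts[pid] = counts.get(pid, 0) + 1
            rank_sums[pid] = rank_sums.get(pid, 0.0) + pos
            score_sums[pid] = score_sums.get(pid, 0.0) + score
    ordered = sorted(
        counts, key=lambda pid: (-counts[pid], rank_sums[pid] / counts[pid], pid)
    )
    return [
        ConsensusTargetRow(
            protein_id=pid,
            consensus_score=counts[pid],
            average_rank=rank_sums[pid] / counts[pid],
            average_score=score_sums[pid] / counts[pid],
        )
        for pid in ordered
    ]


def read_gold_standard(path: str | Path) -> list[str]:
    """One protein_id per line; ``#`` comments and blank lines ignored;
    duplicates collapsed preserving first occurrence."""
    ids: list[str] = []
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry and entry not in seen:
            seen.add(entry)
            ids.append(entry)
    return ids


def bin_relative_frequency(
    targets: TargetList, gold: Iterable[str]
) -> np.ndarray:
    """Relative frequency of target/gold intersections within five rank bins
    (positions 1-20, 21-40, 41-60, 61-80, 81-100).

    Counts are normalized by the total number of intersections; with no
    intersections an all-zero vector is returned (and logged).
    """
    gold_set = set(gold)
    counts = np.zeros(len(RANK_BINS))
    for pos, (pid, _) in enumerate(targets.entries[: RANK_BINS[-1][1]]):
        if pid in gold_set:
            counts[pos // 20] += 1
    total = counts.sum()
    if total == 0:
        logger.warning(
            "no intersection between target list of %s and the gold standard",
            targets.compound_id,
        )
        return counts
    return counts / total


def overlap_percentage(targets: TargetList, gold: Iterable[str], cutoff: int) -> float:
    """Percent of the gold standard recovered within the top-cutoff targets."""
    gold_set = set(gold)
    if not gold_set:
        raise ValueError("gold standard is empty")
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    return 100.0 * len(set(targets.top(cutoff)) & gold_set) / len(gold_set)


def jaccard_coefficient(targets: TargetList, gold: Iterable[str], cutoff: int) -> float:
    """|A ∩ B| / |A ∪ B| with A the top-cutoff target set and B the gold standard."""
    a = set(targets.top(cutoff))
    b = set(gold)
    if not a and not b:
        raise ValueError("both the target set and the gold standard are empty")
    return len(a & b) / len(a | b)


@dataclass
class OverlapResult:
    """Rank-binned and cumulative overlap of a target list with a gold standard."""

    bin_relative_freq: np.ndarray
    overlap_percent_at: dict[int, float]
    jaccard_at: dict[int, float]
    total_intersections: int

    def to_dict(self) -> dict:
        return {
            "bin_relative_freq": [float(v) for v in self.bin_relative_freq],
            "overlap_percent_at": {str(k): v for k, v in self.overlap_percent_at.items()},
            "jaccard_at": {str(k): v for k, v in self.jaccard_at.items()},
            "total_intersections": self.total_intersections,
        }


def overlap_analysis(
    targets: TargetList,
    gold: Iterable[str],
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
) -> OverlapResult:
    gold_list = list(gold)
    freqs = bin_relative_frequency(targets, gold_list)
    total = len(set(targets.top(RANK_BINS[-1][1])) & set(gold_list))
    return OverlapResult(
        bin_relative_freq=freqs,
        overlap_percent_at={k: overlap_percentage(targets, gold_list, k) for k in cutoffs},
        jaccard_at={k: jaccard_coefficient(targets, gold_list, k) for k in cutoffs},
        total_intersections=total,
    )


def write_target_list(targets: TargetList, path: str | Path) -> None:
    rows = [
        {"position": pos, "protein_id": pid, "score": f"{score:.6f}"}
        for pos, (pid, score) in enumerate(targets.entries)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_target_list(path: str | Path, compound_id: str = "") -> TargetList:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    df = df.sort_values("position")
    return TargetList(
        compound_id=compound_id,
        entries=[(str(p), float(s)) for p, s in zip(df.protein_id, df.score)],
    )
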