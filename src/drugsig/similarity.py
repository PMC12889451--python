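"""All-against-all cosine-distance similarity rankings between drugs.

Two drugs with similar proteome-wide interaction signatures are predicted to
have similar therapeutic effects; each drug therefore gets a ranked list of
every other drug, ascending by the cosine distance between their signatures.
Positions are 0-based.

A signature that is identically zero has no direction, so cosine distance is
undefined; such drugs are assigned distance 1.0 to every other drug (and
every other drug sees them at distance 1.0), which keeps all lists the same
length while sorting uninformative compounds last.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .interaction import InteractionMatrix

logger = logging.getLogger(__name__)


def cosine_distance(sig_a: np.ndarray, sig_b: np.ndarray) -> float:
    """1 - cos(a, b).  Both vectors must be the same length and nonzero."""
    a = np.asarray(sig_a, dtype=float)
    b = np.asarray(sig_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"signature length mismatch: {a.shape} vs {b.shape}")
    norm_a = np.linalg.norm(a)
    norm_b = np.linalg.norm(b)
    if norm_a == 0.0 or norm_b == 0.0:
        raise ValueError("cosine distance undefined for an all-zero signature")
    return float(1.0 - np.dot(a, b) / (norm_a * norm_b))


@dataclass
class SimilarityRanking:
    """One drug's neighbours, ascending by distance; the query is excluded."""

    query_id: str
    entries: list[tuple[str, float]]

    def __len__(self) -> int:
        return len(self.entries)

    def top(self, k: int) -> list[str]:
        """Compound ids at positions 0 .. k-1."""
        return [cid for cid, _ in self.entries[:k]]

    def position_of(self, compound_id: str) -> int:
        """0-based position of a compound in this list."""
        for pos, (cid, _) in enumerate(self.entries):
            if cid == compound_id:
                return pos
        raise KeyError(f"{compound_id!r} not in ranking of {self.query_id!r}")

    def distance_to(self, compound_id: str) -> float:
        return self.entries[self.position_of(compound_id)][1]


def _distance_row(matrix: InteractionMatrix, i: int, norms: np.ndarray) -> np.ndarray:
    """Cosine distances from compound i to all compounds, zero rows -> 1.0."""
    scores = matrix.scores
    if norms[i] == 0.0:
        dist = np.ones(scores.shape[0])
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            cos = scores @ scores[i] / (norms * norms[i])
        dist = 1.0 - cos
        dist[norms == 0.0] = 1.0
        # guard tiny negative values from floating-point round-off
        np.clip(dist, 0.0, None, out=dist)
    dist[i] = 0.0
    return dist


def _rank_from_distances(
    matrix: InteractionMatrix, i: int, dist: np.ndarray
) -> SimilarityRanking:
    ids = matrix.compound_ids
    others = [(dist[j], ids[j]) for j in range(len(ids)) if j != i]
    others.sort()  # ascending distance, ties by ascending compound_id
    return SimilarityRanking(
        query_id=ids[i], entries=[(cid, float(d)) for d, cid in others]
    )


def rank_neighbors(matrix: InteractionMatrix, query_id: str) -> SimilarityRanking:
    """Rank all other compounds by ascending cosine distance to the query.

    Distance ties are broken by ascending compound_id for reproducibility.
    """
    try:
        i = matrix.compound_ids.index(query_id)
    except ValueError:
        raise KeyError(f"unknown query_id: {query_id!r}") from None
    norms = np.linalg.norm(matrix.scores, axis=1)
    if norms[i] == 0.0:
        logger.warning(
            "compound %s has an all-zero interaction signature; "
            "assigned distance 1.0 to every other compound",
            query_id,
        )
    return _rank_from_distances(matrix, i, _distance_row(matrix, i, norms))


def all_rankings(matrix: InteractionMatrix) -> dict[str, SimilarityRanking]:
    """One similarity ranking per compound (requires at least two compounds)."""
    if matrix.n_compounds < 2:
        raise ValueError("all-against-all ranking needs at least 2 compounds")
    norms = np.linalg.norm(matrix.scores, axis=1)
    n_zero = int((norms == 0.0).sum())
    if n_zero:
        logger.warning(
            "%d compounds have all-zero interaction signatures; "
            "they are sorted last at distance 1.0",
            n_zero,
        )
    rankings: dict[str, SimilarityRanking] = {}
    for i, cid in enumerate(matrix.compound_ids):
        rankings[cid] = _rank_from_distances(matrix, i, _distance_row(matrix, i, norms))
    return rankings


def write_rankings(rankings: dict[str, SimilarityRanking], path: str | Path) -> None:
    """TSV with columns query_id, position, compound_id, distance."""
    rows = [
        {
            "query_id": r.query_id,
            "position": pos,
            "compound_id": cid,
            "distance": f"{d:.6f}",
        }
        for r in rankings.values()
        for pos, (cid, d) in enumerate(r.entries)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_rankings(path: str | Path) -> dict[str, SimilarityRanking]:
    df = pd.read_csv(path, sep="\t", dtype={"query_id": str, "compound_id": str})
    rankings: dict[str, SimilarityRanking] = {}
    for query_id, group in df.groupby("query_id", sort=False):
        group = group.sort_values("position")
        rankings[str(query_id)] = SimilarityRanking(
            query_id=str(query_id),
            entries=[(str(c), float(d)) for c, d in zip(group.compound_id, group.distance)],
        )
    return rankings
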