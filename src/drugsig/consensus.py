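"""Consensus drug prediction for an indication, with binomial tail probabilities.

A candidate's consensus score counts how many similarity lists of the
indication's approved drugs place it within the top-``cutoff`` window.  Under
a null of random rankings, each of the ``n_assoc`` lists independently puts a
given candidate in its top-``cutoff`` with probability
``cutoff / (library_size - 1)`` (a list ranks every compound but its own
query), so the attached probability is the binomial upper tail
P(X >= consensus_score).

Two control drug sets accompany the predictions: a bottom-of-list control
that first removes structurally trivial molecules (fewer than ``min_heavy``
non-hydrogen atoms), and a seeded random draw from a reference drug's
similarity list.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .libraries import CompoundLibrary, heavy_atom_count
from .similarity import SimilarityRanking


def binomial_probability(
    count: int, n_assoc: int, cutoff: int, library_size: int
) -> float:
    """Upper tail P(X >= count), X ~ Binomial(n_assoc, cutoff / (library_size - 1)).

    The per-trial success probability is the chance that a random similarity
    list — which contains every library compound except its own query, hence
    ``library_size - 1`` entries — places a given candidate within the
    top-``cutoff`` window.
    """
    if not 0 <= count <= n_assoc:
        raise ValueError(f"count must satisfy 0 <= count <= n_assoc, got {count}/{n_assoc}")
    if not 1 <= cutoff < library_size:
        raise ValueError(f"cutoff must satisfy 1 <= cutoff < library_size, got {cutoff}")
    p = cutoff / (library_size - 1)
    if count == 0:
        return 1.0
    return float(binom.sf(count - 1, n_assoc, p))


@dataclass(frozen=True)
class ConsensusPrediction:
    """One row of a consensus prediction table.

    ``average_rank`` is the mean 0-based position over the lists that
    contribute to ``consensus_score``; ``probability`` is the binomial upper
    tail (None when probabilities were not requested).
    """

    drug_rank: int
    compound_id: str
    consensus_score: int
    average_rank: float
    probability: float | None


def consensus_predict(
    rankings: Mapping[str, SimilarityRanking],
    associated_drugs: Iterable[str],
    cutoff: int = 10,
    probabilities: bool = True,
) -> list[ConsensusPrediction]:
    """Count candidate appearances in the top-``cutoff`` windows of the
    indication's drug similarity lists.

    Candidates are every compound (including other associated drugs) found in
    at least one window.  Ordering: descending consensus score, then
    ascending average rank, then ascending compound_id.
    """
    assoc = list(dict.fromkeys(associated_drugs))
    if not assoc:
        raise ValueError("associated drug set is empty")
    missing = [d for d in assoc if d not in rankings]
    if missing:
        raise KeyError(f"associated drugs without similarity rankings: {missing}")

    counts: dict[str, int] = {}
    position_sums: dict[str, int] = {}
    for drug in assoc:
        for pos, (cid, _) in enumerate(rankings[drug].entries[:cutoff]):
            counts[cid] = counts.get(cid, 0) + 1
            position_sums[cid] = position_sums.get(cid, 0) + pos

    ordered = sorted(
        counts,
        key=lambda cid: (-counts[cid], position_sums[cid] / counts[cid], cid),
    )
    probs: dict[str, float] = {}
    if probabilities and ordered:
        library_size = len(rankings[assoc[0]].entries) + 1
        p = cutoff / (library_size - 1)
        unique_counts = np.unique([counts[c] for c in ordered])
        tail = binom.sf(unique_counts - 1, len(assoc), p)
        tail_by_count = dict(zip(unique_counts.tolist(), tail.tolist()))
        probs = {cid: tail_by_count[counts[cid]] for cid in ordered}

    return [
        ConsensusPrediction(
            drug_rank=rank,
            compound_id=cid,
            consensus_score=counts[cid],
            average_rank=position_sums[cid] / counts[cid],
            probability=probs.get(cid) if probabilities else None,
        )
        for rank, cid in enumerate(ordered, start=1)
    ]


def write_predictions(predictions: Sequence[ConsensusPrediction], path: str | Path) -> None:
    rows = [
        {
            "drug_rank": p.drug_rank,
            "compound_id": p.compound_id,
            "consensus_score": p.consensus_score,
            "average_rank": f"{p.average_rank:.4g}",
            "probability": "" if p.probability is None else f"{p.probability:.3g}",
        }
        for p in predictions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def bottom_filtered_control(
    rankings: Mapping[str, SimilarityRanking],
    associated_drugs: Iterable[str],
    compounds: CompoundLibrary,
    window: int = 10,
    min_heavy: int = 4,
) -> list[ConsensusPrediction]:
    """Control candidates from the bottoms of the similarity lists.

    Each associated drug's list is first purged of structurally simplistic
    molecules (fewer than ``min_heavy`` heavy atoms; compounds without a
    parseable structure are retained), then the bottom ``window`` entries are
    counted.  Candidates are ordered by descending count; ties go to the
    *worse* (larger) average original position first, then compound_id.
    """
    assoc = list(dict.fromkeys(associated_drugs))
    if not assoc:
        raise ValueError("associated drug set is empty")

    def passes_filter(cid: str) -> bool:
        if cid not in compounds:
            return True
        smiles = compounds[cid].smiles
        if not smiles:
            return True
        try:
            return heavy_atom_count(smiles) >= min_heavy
        except ValueError:
            return True

    counts: dict[str, int] = {}
    position_sums: dict[str, int] = {}
    for drug in assoc:
        if drug not in rankings:
            raise KeyError(f"associated drug without similarity ranking: {drug!r}")
        filtered = [
            (pos, cid)
            for pos, (cid, _) in enumerate(rankings[drug].entries)
            if passes_filter(cid)
        ]
        if len(filtered) < window:
            raise ValueError(
                f"bottom window of {window} unsatisfiable for {drug!r}: only "
                f"{len(filtered)} entries survive the heavy-atom filter"
            )
        for pos, cid in filtered[-window:]:
            counts[cid] = counts.get(cid, 0) + 1
            position_sums[cid] = position_sums.get(cid, 0) + pos

    ordered = sorted(
        counts,
        key=lambda cid: (-counts[cid], -position_sums[cid] / counts[cid], cid),
    )
    return [
        ConsensusPrediction(
            drug_rank=rank,
            compound_id=cid,
            consensus_score=counts[cid],
            average_rank=position_sums[cid] / counts[cid],
            probability=None,
        )
        for rank, cid in enumerate(ordered, start=1)
    ]


def random_control(
    reference_ranking: SimilarityRanking, n_drugs: int, seed: int
) -> list[str]:
    """Seeded draw of ``n_drugs`` distinct positions from a reference drug's
    similarity list; returns the compounds in sampled order."""
    n = len(reference_ranking.entries)
    if n_drugs > n:
        raise ValueError(f"cannot draw {n_drugs} drugs from a list of {n}")
    rng = np.random.default_rng(seed)
    positions = rng.choice(n, size=n_drugs, replace=False)
    return [reference_ranking.entries[int(p)][0] for p in positions]


def backsolve_indication_size(
    printed_probabilities: Mapping[int, float],
    cutoff: int = 10,
    library_size: int = 2449,
    max_n: int = 200,
) -> list[int]:
    """Indication sizes whose binomial upper tails match a published table.

    Scans n = 2 .. ``max_n`` and returns every n for which
    ``binomial_probability(count, n, cutoff, library_size)`` agrees with each
    printed probability to 3 significant figures.  Used to recover an
    indication's drug count when a paper prints the probability column but
    not the indication size.
    """

    def sig3(x: float) -> float:
        return float(f"{x:.3g}")

    matches = []
    for n in range(2, max_n + 1):
        if max(printed_probabilities) > n:
            continue
        if all(
            sig3(binomial_probability(count, n, cutoff, library_size)) == sig3(target)
            for count, target in printed_probabilities.items()
        ):
            matches.append(n)
    return matches
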