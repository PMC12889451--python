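"""Leave-one-out benchmarking of drug similarity rankings against a known
drug-indication mapping.

Four metrics, each evaluated at a set of top-k cutoffs:

* **IA** (indication accuracy): percentage of an indication's drugs whose
  similarity list recovers at least one other drug of the same indication
  within the top k.  **AIA** averages IA over every indication mapped to at
  least two drugs.
* **nIA** (new indication accuracy): percentage of the indication's drugs
  that, when withheld, are recovered within the top k of the consensus
  prediction list built from the remaining drugs.  **nAIA** is its average.
* **NDCG**: standard binary-relevance discounted cumulative gain of the other
  indicated drugs in a similarity list, normalized by the ideal ranking, then
  averaged over the indication's drugs.
* **nNDCG**: the consensus-list analogue — each withheld drug contributes
  gain 1/log2(p+2) at its 0-based consensus position p (zero beyond the
  cutoff), normalized by the ideal where all withheld drugs sit on top.

Two chance baselines accompany the metrics: an empirical control that
permutes each compound's signature across proteins and re-runs the whole
pipeline (averaged over seeded replicates), and the analytic hypergeometric
probability that a random ranking recovers at least one partner drug within
the cutoff.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .consensus import consensus_predict
from .interaction import InteractionMatrix
from .libraries import IndicationMapping
from .similarity import SimilarityRanking, all_rankings

METRICS = ("IA", "nIA", "NDCG", "nNDCG")


def _eligible_drugs(
    rankings: Mapping[str, SimilarityRanking],
    mapping: IndicationMapping,
    indication_id: str,
) -> list[str]:
    drugs = [d for d in mapping.drugs_for(indication_id) if d in rankings]
    if len(drugs) < 2:
        raise ValueError(
            f"indication {indication_id!r} has {len(drugs)} drugs with rankings; "
            "metrics need at least 2"
        )
    return drugs


def eligible_indications(
    rankings: Mapping[str, SimilarityRanking], mapping: IndicationMapping
) -> list[str]:
    """Indications mapped to at least two drugs that have similarity rankings."""
    out = []
    for ind in mapping.indication_ids:
        if sum(d in rankings for d in mapping.drugs_for(ind)) >= 2:
            out.append(ind)
    return out


def indication_accuracy(
    rankings: Mapping[str, SimilarityRanking],
    mapping: IndicationMapping,
    indication_id: str,
    k: int,
) -> float:
    """Percent of the indication's drugs whose top-k similarity window
    contains at least one other drug of the indication."""
    drugs = _eligible_drugs(rankings, mapping, indication_id)
    partners = set(drugs)
    hits = 0
    for d in drugs:
        window = rankings[d].top(k)
        if any(c in partners and c != d for c in window):
            hits += 1
    return 100.0 * hits / len(drugs)


def average_indication_accuracy(
    rankings: Mapping[str, SimilarityRanking],
    mapping: IndicationMapping,
    k: int,
) -> float:
    """Unweighted mean IA over every eligible indication."""
    inds = eligible_indications(rankings, mapping)
    if not inds:
        raise ValueError("no indication is mapped to at least two ranked drugs")
    return float(
        np.mean([indication_accuracy(rankings, mapping, ind, k) for ind in inds])
    )


def leave_one_out_consensus(
    rankings: Mapping[str, SimilarityRanking],
    drugs: Sequence[str],
    cutoff: int = 10,
) -> dict[str, list[str]]:
    """For each drug, the ordered consensus list built from the *other* drugs."""
    out: dict[str, list[str]] = {}
    for withheld in drugs:
        remaining = [d for d in drugs if d != withheld]
        preds = consensus_predict(rankings, remaining, cutoff=cutoff, probabilities=False)
        out[withheld] = [p.compound_id for p in preds]
    return out


def new_indication_accuracy(
    rankings: Mapping[str, SimilarityRanking],
    mapping: IndicationMapping,
    indication_id: str,
    k: int,
    cutoff: int = 10,
) -> float:
    """Percent of withheld drugs recovered within the top k of the consensus
    list built from the indication's remaining drugs."""
    drugs = _eligible_drugs(rankings, mapping, indication_id)
    loo = leave_one_out_consensus(rankings, drugs, cutoff=cutoff)
    hits = sum(1 for d in drugs if d in loo[d][:k])
    return 100.0 * hits / len(drugs)


def ndcg_at_k(ranking: SimilarityRanking, relevant: set[str], k: int) -> float:
    """Binary-relevance NDCG of a similarity list at cutoff k.

    Gain 1/log2(i+1) at 1-based position i.  The ideal ranking places *all*
    relevant items at the top regardless of k, so the normalizer is constant
    in k and the metric is monotone non-decreasing in the cutoff (the usual
    min(k, |relevant|) truncation of the ideal breaks monotonicity).
    """
    if not relevant:
        raise ValueError("relevant set is empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    dcg = sum(
        1.0 / math.log2(pos + 2)
        for pos, (cid, _) in enumerate(ranking.entries[:k])
        if cid in relevant
    )
    idcg = sum(1.0 / math.log2(i + 1) for i in range(1, len(relevant) + 1))
    return dcg / idcg


def _indication_ndcg(
    rankings: Mapping[str, SimilarityRanking], drugs: Sequence[str], k: int
) -> float:
    values = []
    for d in drugs:
        relevant = set(drugs) - {d}
        values.append(ndcg_at_k(rankings[d], relevant, k))
    return float(np.mean(values))


def new_ndcg_at_k(
    loo_consensus: Mapping[str, Sequence[str]],
    k: int,
) -> float:
    """Consensus-list NDCG over leave-one-out withheld drugs.

    ``loo_consensus`` maps each withheld drug to the ordered consensus list
    built from the indication's remaining drugs.  A withheld drug is
    recovered when its 0-based consensus position p is below k.  The
    recovered drugs are pooled into one virtual ranking: positions are
    sorted ascending and a position already occupied is bumped to the next
    free slot (two drugs cannot share one rank), so the i-th recovered drug
    sits at effective position e_i = max(p_i, e_{i-1} + 1) and earns gain
    1/log2(e_i + 2).  Normalization is by the ideal where all m withheld
    drugs occupy the top m slots, which pins the metric to [0, 1] and to
    exactly 1.0 when every withheld drug is recovered first.
    """
    if not loo_consensus:
        raise ValueError("no leave-one-out consensus lists supplied")
    recovered: list[int] = []
    for withheld, consensus in loo_consensus.items():
        consensus = list(consensus)
        if withheld in consensus[:k]:
            recovered.append(consensus.index(withheld))
    recovered.sort()
    dcg = 0.0
    slot = -1
    for p in recovered:
        slot = max(p, slot + 1)
        dcg += 1.0 / math.log2(slot + 2)
    m = len(loo_consensus)
    idcg = sum(1.0 / math.log2(i + 1) for i in range(1, m + 1))
    return dcg / idcg


def hypergeometric_expected_ia(N: int, n: int, k: int) -> float:
    """Chance that a random ranking of the other N-1 drugs places at least one
    of the indication's n-1 partners within the top k, as a percent.

    100 * [1 - C(N-n, k) / C(N-1, k)], with C(a, b) = 0 when a < b.
    """
    if not 2 <= n <= N:
        raise ValueError(f"need 2 <= n <= N, got n={n}, N={N}")
    if not 1 <= k <= N - 1:
        raise ValueError(f"need 1 <= k <= N-1, got k={k}")
    numer = math.comb(N - n, k) if N - n >= k else 0
    return 100.0 * (1.0 - numer / math.comb(N - 1, k))


@dataclass
class BenchmarkReport:
    """Per-indication and averaged benchmark metrics, with optional controls.

    ``per_indication[ind][metric][k]`` and ``averages[metric][k]`` hold the
    observed values; ``controls[tag][metric][k]`` holds a baseline of the
    same averaged shape (tags: ``random_matrix``, ``hypergeometric``).
    """

    cutoffs: list[int]
    per_indication: dict[str, dict[str, dict[int, float]]]
    averages: dict[str, dict[int, float]]
    controls: dict[str, dict[str, dict[int, float]]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def _stringify(d):
            if isinstance(d, dict):
                return {str(k): _stringify(v) for k, v in d.items()}
            return d

        payload = {
            "cutoffs": self.cutoffs,
            "per_indication": _stringify(self.per_indication),
            "averages": _stringify(self.averages),
            "controls": _stringify(self.controls),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def run_benchmark(
    rankings: Mapping[str, SimilarityRanking],
    mapping: IndicationMapping,
    cutoffs: Sequence[int],
    consensus_cutoff: int = 10,
    metrics: Sequence[str] = METRICS,
) -> BenchmarkReport:
    """All requested metrics for every eligible indication, plus their means.

    Averaged metric names follow the field's convention: the mean of IA is
    AIA, of nIA is nAIA; NDCG and nNDCG keep their names.
    """
    inds = eligible_indications(rankings, mapping)
    if not inds:
        raise ValueError("no indication is mapped to at least two ranked drugs")
    per_indication: dict[str, dict[str, dict[int, float]]] = {}
    for ind in inds:
        drugs = _eligible_drugs(rankings, mapping, ind)
        values: dict[str, dict[int, float]] = {m: {} for m in metrics}
        loo = (
            leave_one_out_consensus(rankings, drugs, cutoff=consensus_cutoff)
            if ("nIA" in metrics or "nNDCG" in metrics)
            else {}
        )
        for k in cutoffs:
            if "IA" in metrics:
                values["IA"][k] = indication_accuracy(rankings, mapping, ind, k)
            if "nIA" in metrics:
                hits = sum(1 for d in drugs if d in loo[d][:k])
                values["nIA"][k] = 100.0 * hits / len(drugs)
            if "NDCG" in metrics:
                values["NDCG"][k] = _indication_ndcg(rankings, drugs, k)
            if "nNDCG" in metrics:
                values["nNDCG"][k] = new_ndcg_at_k(loo, k)
        per_indication[ind] = values

    avg_name = {"IA": "AIA", "nIA": "nAIA", "NDCG": "NDCG", "nNDCG": "nNDCG"}
    averages = {
        avg_name[m]: {
            k: float(np.mean([per_indication[ind][m][k] for ind in inds]))
            for k in cutoffs
        }
        for m in metrics
    }
    return BenchmarkReport(
        cutoffs=list(cutoffs), per_indication=per_indication, averages=averages
    )


def hypergeometric_control(
    rankings: Mapping[str, SimilarityRanking],
    mapping: IndicationMapping,
    cutoffs: Sequence[int],
) -> dict[str, dict[str, dict[int, float]]]:
    """Analytic IA baseline per eligible indication, plus the AIA mean.

    Returns ``{"per_indication": {ind: {k: percent}}, "averages": {"AIA": {k: percent}}}``.
    """
    inds = eligible_indications(rankings, mapping)
    if not inds:
        raise ValueError("no indication is mapped to at least two ranked drugs")
    any_ranking = next(iter(rankings.values()))
    N = len(any_ranking.entries) + 1
    per_ind = {
        ind: {
            k: hypergeometric_expected_ia(
                N, sum(d in rankings for d in mapping.drugs_for(ind)), k
            )
            for k in cutoffs
        }
        for ind in inds
    }
    averages = {
        "AIA": {k: float(np.mean([per_ind[ind][k] for ind in inds])) for k in cutoffs}
    }
    return {"per_indication": per_ind, "averages": averages}


@dataclass
class RandomMatrixControl:
    """Mean metrics over replicates of a row-permuted interaction matrix.

    Each replicate independently permutes every compound's signature across
    proteins (destroying protein identity while preserving the score
    distribution of each drug), rebuilds all similarity rankings, and
    recomputes the benchmark.  Standard errors are over replicates.
    """

    n_reps: int
    averages: dict[str, dict[int, float]]
    averages_stderr: dict[str, dict[int, float]]
    per_indication: dict[str, dict[str, dict[int, float]]]
    per_indication_stderr: dict[str, dict[str, dict[int, float]]]


def random_matrix_control(
    matrix: InteractionMatrix,
    mapping: IndicationMapping,
    cutoffs: Sequence[int],
    n_reps: int = 100,
    seed: int = 0,
    consensus_cutoff: int = 10,
    metrics: Sequence[str] = METRICS,
) -> RandomMatrixControl:
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    avg_reps: dict[str, dict[int, list[float]]] = {}
    ind_reps: dict[str, dict[str, dict[int, list[float]]]] = {}
    for stream in streams:
        rng = np.random.default_rng(stream)
        permuted = InteractionMatrix(
            compound_ids=list(matrix.compound_ids),
            protein_ids=list(matrix.protein_ids),
            scores=rng.permuted(matrix.scores, axis=1),
        )
        rankings = all_rankings(permuted)
        report = run_benchmark(
            rankings, mapping, cutoffs, consensus_cutoff=consensus_cutoff, metrics=metrics
        )
        for m, by_k in report.averages.items():
            for k, v in by_k.items():
                avg_reps.setdefault(m, {}).setdefault(k, []).append(v)
        for ind, by_metric in report.per_indication.items():
            for m, by_k in by_metric.items():
                for k, v in by_k.items():
                    ind_reps.setdefault(ind, {}).setdefault(m, {}).setdefault(k, []).append(v)

    def _mean(d):
        return {
            outer: {k: float(np.mean(vals)) for k, vals in by_k.items()}
            for outer, by_k in d.items()
        }

    def _stderr(d):
        return {
            outer: {
                k: float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
                for k, vals in by_k.items()
            }
            for outer, by_k in d.items()
        }

    return RandomMatrixControl(
        n_reps=n_reps,
        averages=_mean(avg_reps),
        averages_stderr=_stderr(avg_reps),
        per_indication={ind: _mean(v) for ind, v in ind_reps.items()},
        per_indication_stderr={ind: _stderr(v) for ind, v in ind_reps.items()},
    )
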