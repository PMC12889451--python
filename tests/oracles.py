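"""Independent brute-force recomputations used as oracles.

Everything here is written against the plainest possible definitions —
nested loops, python sums, explicit sorts — deliberately sharing no code
path with the package implementations it checks.
"""

from __future__ import annotations

import math


def brute_cosine(a, b):
    dot = sum(x * y for x, y in zip(a, b))
    na = math.sqrt(sum(x * x for x in a))
    nb = math.sqrt(sum(y * y for y in b))
    if na == 0.0 or nb == 0.0:
        return 1.0  # convention for uninformative signatures
    return 1.0 - dot / (na * nb)


def brute_rank_neighbors(compound_ids, rows, query_id):
    """Ordered (compound_id, distance) list for one query, ascending distance
    then compound_id; all-zero signatures at distance 1.0."""
    qi = compound_ids.index(query_id)
    q = rows[qi]
    q_zero = all(v == 0.0 for v in q)
    pairs = []
    for j, cid in enumerate(compound_ids):
        if cid == query_id:
            continue
        other_zero = all(v == 0.0 for v in rows[j])
        d = 1.0 if (q_zero or other_zero) else max(0.0, brute_cosine(q, rows[j]))
        pairs.append((d, cid))
    pairs.sort()
    return [(cid, d) for d, cid in pairs]


def brute_score_cell(compound_bits, templates):
    """Max over (confidence, ligand_bits) templates of confidence * Dice."""
    best = 0.0
    for confidence, bits in templates:
        denom = len(compound_bits) + len(bits)
        dice = 0.0 if denom == 0 else 2.0 * len(set(compound_bits) & set(bits)) / denom
        best = max(best, confidence * dice)
    return best


def brute_consensus(rank_lists, associated, cutoff):
    """Recount candidate appearances over top-cutoff windows.

    ``rank_lists`` maps drug -> ordered list of compound ids.  Returns the
    ordered list of (compound_id, count, average_rank).
    """
    appearances = {}
    for drug in associated:
        window = rank_lists[drug][:cutoff]
        for pos, cid in enumerate(window):
            appearances.setdefault(cid, []).append(pos)
    rows = [
        (cid, len(ps), sum(ps) / len(ps)) for cid, ps in appearances.items()
    ]
    rows.sort(key=lambda r: (-r[1], r[2], r[0]))
    return rows


def brute_top_targets(protein_ids, signature, n):
    pairs = [(pid, float(s)) for pid, s in zip(protein_ids, signature)]
    pairs.sort(key=lambda t: (-t[1], t[0]))
    return pairs[:n]


def brute_consensus_targets(protein_ids, rows_by_drug, n):
    """rows_by_drug maps drug -> signature list (aligned with protein_ids).
    Returns ordered (protein_id, count, avg_rank, avg_score)."""
    stats = {}
    for drug, signature in rows_by_drug.items():
        top = brute_top_targets(protein_ids, signature, n)
        for pos, (pid, score) in enumerate(top):
            stats.setdefault(pid, []).append((pos, score))
    rows = []
    for pid, hits in stats.items():
        count = len(hits)
        avg_rank = sum(p for p, _ in hits) / count
        avg_score = sum(s for _, s in hits) / count
        rows.append((pid, count, avg_rank, avg_score))
    rows.sort(key=lambda r: (-r[1], r[2], r[0]))
    return rows
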