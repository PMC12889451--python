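"""Compound x proteome interaction scoring.

Each protein is scored against a compound through its pocket templates: the
interaction score is the maximum over templates of

    confidence * Dice(compound fingerprint, template-ligand fingerprint)

so that a perfectly confident pocket whose known ligand is chemically
identical to the compound scores 1.0, and a protein with no pocket evidence
scores 0.0.  A compound's row of the resulting matrix is its interaction
signature.  A ``dice_only`` variant that ignores pocket confidence is
available through ``score_form``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .libraries import (
    CompoundLibrary,
    Fingerprint,
    PocketLibrary,
    PocketTemplate,
    dice_similarity,
)

ScoreForm = Literal["product", "dice_only"]


def _template_score(
    compound_fp: Fingerprint, template: PocketTemplate, score_form: ScoreForm
) -> float:
    dice = dice_similarity(compound_fp, template.ligand_fingerprint)
    if score_form == "product":
        return template.confidence * dice
    if score_form == "dice_only":
        return dice
    raise ValueError(f"unknown score_form: {score_form!r}")


def score_interaction(
    compound_fp: Fingerprint,
    templates: Sequence[PocketTemplate],
    score_form: ScoreForm = "product",
) -> float:
    """Best pocket-weighted chemical similarity over a protein's templates.

    Returns 0.0 for an empty template list (no pocket evidence).  All
    templates must belong to one protein.
    """
    if not templates:
        return 0.0
    protein_ids = {t.protein_id for t in templates}
    if len(protein_ids) > 1:
        raise ValueError(f"templates span multiple proteins: {sorted(protein_ids)}")
    return max(_template_score(compound_fp, t, score_form) for t in templates)


@dataclass
class InteractionMatrix:
    """Dense compound x protein score matrix with identifier axes.

    ``scores[i, j]`` is the interaction score of compound ``compound_ids[i]``
    with protein ``protein_ids[j]``; row *i* is that compound's interaction
    signature.
    """

    compound_ids: list[str]
    protein_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.compound_ids), len(self.protein_ids)):
            raise ValueError(
                f"score matrix shape {self.scores.shape} does not match "
                f"{len(self.compound_ids)} compounds x {len(self.protein_ids)} proteins"
            )
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError("duplicate compound_ids")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValueError("duplicate protein_ids")
        if self.scores.size and (self.scores.min() < 0.0 or self.scores.max() > 1.0):
            raise ValueError("interaction scores must lie in [0, 1]")
        self._row_index = {c: i for i, c in enumerate(self.compound_ids)}
        self._col_index = {p: j for j, p in enumerate(self.protein_ids)}

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def signature(self, compound_id: str) -> np.ndarray:
        """One compound's interaction signature (a view of its matrix row)."""
        try:
            return self.scores[self._row_index[compound_id]]
        except KeyError:
            raise KeyError(f"unknown compound_id: {compound_id!r}") from None

    def score(self, compound_id: str, protein_id: str) -> float:
        try:
            j = self._col_index[protein_id]
        except KeyError:
            raise KeyError(f"unknown protein_id: {protein_id!r}") from None
        return float(self.signature(compound_id)[j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.compound_ids, columns=self.protein_ids)

    def write_tsv(self, path: str | Path) -> None:
        """Tab-delimited text: first row protein ids, first column compound ids,
        cells with 6 fractional digits."""
        df = self.to_frame()
        df.index.name = "compound_id"
        df.to_csv(path, sep="\t", float_format="%.6f", lineterminator="\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "InteractionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            compound_ids=[str(c) for c in df.index],
            protein_ids=[str(p) for p in df.columns],
            scores=df.to_numpy(dtype=float),
        )


def build_matrix(
    compounds: CompoundLibrary,
    pockets: PocketLibrary,
    score_form: ScoreForm = "product",
) -> InteractionMatrix:
    """Score every usable compound against every protein in the pocket library."""
    usable = compounds.usable_records()
    protein_ids = pockets.protein_ids
    if not usable:
        raise ValueError("no usable compounds (every record lacks a fingerprint)")
    if not protein_ids:
        raise ValueError("pocket library contains no proteins")
    scores = np.zeros((len(usable), len(protein_ids)))
    for j, pid in enumerate(protein_ids):
        templates = pockets.templates_for(pid)
        for i, rec in enumerate(usable):
            scores[i, j] = score_interaction(rec.fingerprint, templates, score_form)
    return InteractionMatrix(
        compound_ids=[r.compound_id for r in usable],
        protein_ids=list(protein_ids),
        scores=scores,
    )


class TopLigandTrace(NamedTuple):
    """Provenance of one matrix cell: the template attaining the maximum."""

    template_id: str
    confidence: float
    dice: float
    score: float


def trace_top_ligand(
    compound_id: str,
    protein_id: str,
    compounds: CompoundLibrary,
    pockets: PocketLibrary,
    score_form: ScoreForm = "product",
) -> TopLigandTrace:
    """Which template ligand drives a compound-protein score.

    Ties on the score are broken toward the lexicographically smallest
    template_id.  Raises on unknown identifiers and on zero scores (no
    contributing template).
    """
    if compound_id not in compounds:
        raise KeyError(f"unknown compound_id: {compound_id!r}")
    rec = compounds[compound_id]
    if not rec.usable:
        raise ValueError(f"compound {compound_id!r} has no usable fingerprint")
    templates = pockets.templates_for(protein_id)
    if protein_id not in pockets.protein_ids:
        raise KeyError(f"unknown protein_id: {protein_id!r}")
    best: TopLigandTrace | None = None
    for t in sorted(templates, key=lambda t: t.template_id):
        score = _template_score(rec.fingerprint, t, score_form)
        if best is None or score > best.score:
            best = TopLigandTrace(
                template_id=t.template_id,
                confidence=t.confidence,
                dice=dice_similarity(rec.fingerprint, t.ligand_fingerprint),
                score=score,
            )
    if best is None or best.score <= 0.0:
        raise ValueError(
            f"no template contributes a positive score for "
            f"({compound_id}, {protein_id})"
        )
    return best
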