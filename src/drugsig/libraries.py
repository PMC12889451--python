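"""Input libraries: compounds, binding-pocket templates, and indication mappings.

A compound is represented by an ECFP4 (Morgan radius-2) fingerprint, either
computed from its SMILES with RDKit or supplied directly as a hex-encoded bit
set.  A protein is represented by one or more pocket templates: the known
ligand of a predicted binding site, fingerprinted the same way, together with
the confidence of the site prediction.  An indication mapping links indication
identifiers to the compounds approved (or otherwise associated) for them.

All readers consume plain UTF-8 tab-separated files with a header row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit import RDLogger

logger = logging.getLogger(__name__)

# RDKit prints parse errors to stderr by default; we log them ourselves.
RDLogger.DisableLog("rdApp.error")

DEFAULT_N_BITS = 2048


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-width chemical fingerprint stored as the set of on-bit indices.

    ``bits`` holds 0-based indices into a bit vector of width ``n_bits``.
    Hex serialization treats the bit set as an integer with bit *i* at
    numeric weight ``2**i``, zero-padded to ``n_bits / 4`` hex digits.
    """

    bits: frozenset[int]
    n_bits: int = DEFAULT_N_BITS

    def __post_init__(self) -> None:
        if self.n_bits <= 0 or self.n_bits % 4 != 0:
            raise ValueError(f"n_bits must be a positive multiple of 4, got {self.n_bits}")
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.n_bits):
            raise ValueError("bit index out of range for fingerprint width")

    def __len__(self) -> int:
        return len(self.bits)

    def to_hex(self) -> str:
        value = 0
        for b in self.bits:
            value |= 1 << b
        return format(value, f"0{self.n_bits // 4}x")

    @classmethod
    def from_hex(cls, hex_string: str, n_bits: int | None = None) -> "Fingerprint":
        width = 4 * len(hex_string) if n_bits is None else n_bits
        value = int(hex_string, 16)
        bits = frozenset(i for i in range(value.bit_length()) if value >> i & 1)
        return cls(bits=bits, n_bits=width)


def compute_fingerprint(smiles: str, n_bits: int = DEFAULT_N_BITS) -> Fingerprint:
    """ECFP4 fingerprint (Morgan, radius 2 = diameter 4) hashed to ``n_bits``.

    Deterministic for a given SMILES and invariant under re-canonicalization
    of the same molecule.  Raises ``ValueError`` on unparsable SMILES.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(bits=frozenset(bv.GetOnBits()), n_bits=n_bits)


def dice_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """Sørensen–Dice coefficient 2|A∩B| / (|A|+|B|) between two bit sets.

    Defined as 0.0 when both sets are empty (an unusable molecule should
    never look similar to anything).
    """
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint width mismatch: {a.n_bits} vs {b.n_bits}")
    denom = len(a.bits) + len(b.bits)
    if denom == 0:
        return 0.0
    return 2.0 * len(a.bits & b.bits) / denom


def heavy_atom_count(smiles: str) -> int:
    """Number of non-hydrogen atoms in the molecule."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return mol.GetNumHeavyAtoms()


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    name: str
    smiles: str | None = None
    fingerprint: Fingerprint | None = None

    @property
    def usable(self) -> bool:
        """Whether the compound can participate in scoring."""
        return self.fingerprint is not None and len(self.fingerprint) > 0


class CompoundLibrary:
    """An ordered collection of compounds with unique identifiers."""

    def __init__(self, records: Iterable[CompoundRecord]):
        self._records: list[CompoundRecord] = list(records)
        self._by_id: dict[str, CompoundRecord] = {}
        for rec in self._records:
            if rec.compound_id in self._by_id:
                raise ValueError(f"duplicate compound_id: {rec.compound_id!r}")
            self._by_id[rec.compound_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self._records)

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._by_id

    def __getitem__(self, compound_id: str) -> CompoundRecord:
        return self._by_id[compound_id]

    @property
    def ids(self) -> list[str]:
        return [r.compound_id for r in self._records]

    def usable_records(self) -> list[CompoundRecord]:
        return [r for r in self._records if r.usable]


@dataclass(frozen=True)
class PocketTemplate:
    """A template ligand of one predicted binding pocket of a protein.

    ``confidence`` is the unitless binding-site prediction score in [0, 1].
    """

    protein_id: str
    template_id: str
    ligand_fingerprint: Fingerprint
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(
                f"confidence must be in [0, 1], got {self.confidence} "
                f"for ({self.protein_id}, {self.template_id})"
            )


class PocketLibrary:
    """Pocket templates grouped by protein, preserving first-seen protein order."""

    def __init__(self, templates: Iterable[PocketTemplate]):
        self._by_protein: dict[str, list[PocketTemplate]] = {}
        seen: set[tuple[str, str]] = set()
        for tpl in templates:
            key = (tpl.protein_id, tpl.template_id)
            if key in seen:
                raise ValueError(f"duplicate (protein_id, template_id): {key}")
            seen.add(key)
            self._by_protein.setdefault(tpl.protein_id, []).append(tpl)

    def __len__(self) -> int:
        return len(self._by_protein)

    @property
    def protein_ids(self) -> list[str]:
        return list(self._by_protein)

    def templates_for(self, protein_id: str) -> list[PocketTemplate]:
        """All templates of one protein; empty list for an unknown protein."""
        return list(self._by_protein.get(protein_id, ()))

    def __iter__(self) -> Iterator[PocketTemplate]:
        for templates in self._by_protein.values():
            yield from templates


class IndicationMapping:
    """A set of (indication_id, compound_id) associations.

    Duplicate pairs are rejected; per-indication drug order follows input order.
    """

    def __init__(self, associations: Iterable[tuple[str, str]]):
        self._drugs: dict[str, list[str]] = {}
        self._pairs: set[tuple[str, str]] = set()
        for ind, drug in associations:
            pair = (ind, drug)
            if pair in self._pairs:
                raise ValueError(f"duplicate association: {pair}")
            self._pairs.add(pair)
            self._drugs.setdefault(ind, []).append(drug)

    @property
    def indication_ids(self) -> list[str]:
        return list(self._drugs)

    @property
    def associations(self) -> set[tuple[str, str]]:
        return set(self._pairs)

    def __len__(self) -> int:
        return len(self._pairs)

    def drugs_for(self, indication_id: str) -> list[str]:
        try:
            return list(self._drugs[indication_id])
        except KeyError:
            raise KeyError(f"unknown indication_id: {indication_id!r}") from None

    def validate_against(self, library: CompoundLibrary) -> None:
        """Every associated compound must resolve in the compound library."""
        missing = sorted({d for _, d in self._pairs if d not in library})
        if missing:
            raise ValueError(f"associated compounds absent from library: {missing}")


# ---------------------------------------------------------------------------
# Readers / writers


def read_compound_table(path: str | Path, n_bits: int = DEFAULT_N_BITS) -> CompoundLibrary:
    """Read a compound TSV (columns compound_id, name, smiles[, fingerprint_hex]).

    Fingerprints are taken from ``fingerprint_hex`` when present, otherwise
    computed from SMILES.  Records whose SMILES fails to parse are kept but
    flagged unusable (no fingerprint) with a logged warning; a duplicate
    compound_id is a hard error naming the offender.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"compound_id", "name"}
    if not required.issubset(df.columns):
        raise ValueError(f"compound table missing columns: {sorted(required - set(df.columns))}")
    records: list[CompoundRecord] = []
    for row in df.itertuples(index=False):
        smiles = getattr(row, "smiles", "") or None
        fp_hex = getattr(row, "fingerprint_hex", "") or None
        fingerprint: Fingerprint | None = None
        if fp_hex:
            fingerprint = Fingerprint.from_hex(fp_hex, n_bits=n_bits)
        elif smiles:
            try:
                fingerprint = compute_fingerprint(smiles, n_bits=n_bits)
            except ValueError:
                logger.warning(
                    "compound %s: unparsable SMILES %r; flagged unusable and "
                    "excluded from scoring",
                    row.compound_id,
                    smiles,
                )
        records.append(
            CompoundRecord(
                compound_id=row.compound_id,
                name=row.name,
                smiles=smiles,
                fingerprint=fingerprint,
            )
        )
    return CompoundLibrary(records)


def write_compound_table(library: CompoundLibrary, path: str | Path) -> None:
    rows = []
    for rec in library:
        rows.append(
            {
                "compound_id": rec.compound_id,
                "name": rec.name,
                "smiles": rec.smiles or "",
                "fingerprint_hex": rec.fingerprint.to_hex() if rec.fingerprint else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_pocket_table(path: str | Path, n_bits: int = DEFAULT_N_BITS) -> PocketLibrary:
    """Read a pocket TSV (protein_id, template_id, ligand_smiles or
    ligand_fingerprint_hex, confidence)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"protein_id", "template_id", "confidence"}
    if not required.issubset(df.columns):
        raise ValueError(f"pocket table missing columns: {sorted(required - set(df.columns))}")
    templates: list[PocketTemplate] = []
    for row in df.itertuples(index=False):
        fp_hex = getattr(row, "ligand_fingerprint_hex", "") or None
        smiles = getattr(row, "ligand_smiles", "") or None
        if fp_hex:
            fp = Fingerprint.from_hex(fp_hex, n_bits=n_bits)
        elif smiles:
            fp = compute_fingerprint(smiles, n_bits=n_bits)
        else:
            raise ValueError(
                f"pocket ({row.protein_id}, {row.template_id}): neither "
                "ligand_smiles nor ligand_fingerprint_hex supplied"
            )
        templates.append(
            PocketTemplate(
                protein_id=row.protein_id,
                template_id=row.template_id,
                ligand_fingerprint=fp,
                confidence=float(row.confidence),
            )
        )
    return PocketLibrary(templates)


def write_pocket_table(pockets: PocketLibrary, path: str | Path) -> None:
    rows = [
        {
            "protein_id": t.protein_id,
            "template_id": t.template_id,
            "ligand_fingerprint_hex": t.ligand_fingerprint.to_hex(),
            "confidence": f"{t.confidence:.6f}",
        }
        for t in pockets
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_indication_table(path: str | Path) -> IndicationMapping:
    """Read an indication TSV (columns indication_id, compound_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"indication_id", "compound_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"indication table missing columns: {sorted(required - set(df.columns))}")
    return IndicationMapping(
        (row.indication_id, row.compound_id) for row in df.itertuples(index=False)
    )


def write_indication_table(mapping: IndicationMapping, path: str | Path) -> None:
    rows = [
        {"indication_id": ind, "compound_id": drug}
        for ind in mapping.indication_ids
        for drug in mapping.drugs_for(ind)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
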