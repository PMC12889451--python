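"""Synthetic study generator with planted indication structure.

Real inputs to this kind of analysis — an approved-drug library, a
proteome-wide pocket library, and a curated drug-indication mapping — are
large and proprietary-ish to assemble, so every pipeline stage is exercised
on generated data whose statistical structure is controlled:

* Compounds carry explicit random fingerprints (decoupling the generator
  from chemistry parsing).  Drugs sharing an indication draw bits from that
  indication's *motif* — a reserved block of fingerprint bits — each bit
  independently with probability ``cluster_strength``.
* A subset of proteins per indication are *signal* proteins whose first
  pocket template contains the indication motif, so drugs of one indication
  score high on the same proteins and end up close in signature space.
  At ``cluster_strength = 0`` indication membership leaves no trace and all
  drugs are statistically exchangeable.
* A gold standard is planted to contain a configurable fraction of the focal
  drug set's true consensus top targets, topped up with decoy proteins.

Default scale (200 compounds x 150 proteins, focal indication of 68 drugs)
keeps the full pipeline fast while leaving room for rank statistics; the
focal size mirrors the drug count recovered for the study's indication of
interest.  All randomness derives from one master seed through named
substreams, and equal seeds produce byte-identical written studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .interaction import InteractionMatrix, build_matrix
from .libraries import (
    CompoundLibrary,
    CompoundRecord,
    Fingerprint,
    IndicationMapping,
    PocketLibrary,
    PocketTemplate,
    write_compound_table,
    write_indication_table,
    write_pocket_table,
)
from .targets import consensus_targets


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic study; defaults define the standard conditions."""

    n_compounds: int = 200
    n_proteins: int = 150
    n_templates_per_protein: int = 2
    n_indications: int = 5
    focal_indication_size: int = 68
    other_indication_size: int = 8
    cluster_strength: float = 0.8
    n_bits: int = 512
    motif_bits: int = 32
    noise_bits: int = 24
    signal_proteins_per_indication: int = 10
    gold_size: int = 40
    gold_overlap_fraction: float = 0.5
    gold_top_window: int = 100
    seed: int = 0

    @property
    def indication_sizes(self) -> list[int]:
        return [self.focal_indication_size] + [self.other_indication_size] * (
            self.n_indications - 1
        )

    def validate(self) -> None:
        if min(
            self.n_compounds,
            self.n_proteins,
            self.n_templates_per_protein,
            self.n_indications,
            self.focal_indication_size,
            self.other_indication_size,
            self.n_bits,
            self.motif_bits,
            self.noise_bits,
        ) < 1:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.cluster_strength <= 1.0:
            raise ValueError("cluster_strength must be in [0, 1]")
        if not 0.0 <= self.gold_overlap_fraction <= 1.0:
            raise ValueError("gold_overlap_fraction must be in [0, 1]")
        if sum(self.indication_sizes) > self.n_compounds:
            raise ValueError(
                f"indication sizes sum to {sum(self.indication_sizes)} "
                f"> n_compounds = {self.n_compounds}"
            )
        if self.n_indications * self.motif_bits + self.noise_bits > self.n_bits:
            raise ValueError("not enough fingerprint bits for motifs plus noise")
        if self.n_indications * self.signal_proteins_per_indication > self.n_proteins:
            raise ValueError("not enough proteins for the requested signal proteins")


@dataclass
class SynthStudy:
    """A generated study: the three input libraries, gold standards, and the
    interaction matrix of its usable compounds."""

    config: SynthConfig
    compounds: CompoundLibrary
    pockets: PocketLibrary
    mapping: IndicationMapping
    gold_standards: dict[str, list[str]]
    matrix: InteractionMatrix
    focal_indication: str


def _substreams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(c) for name, c in zip(names, children)}


def generate_study(config: SynthConfig) -> SynthStudy:
    """Generate a full synthetic study from one master seed."""
    config.validate()
    rngs = _substreams(
        config.seed, ("membership", "fingerprints", "templates", "confidence", "gold")
    )
    width = len(str(max(config.n_compounds, config.n_proteins)))
    compound_ids = [f"C{i + 1:0{width}d}" for i in range(config.n_compounds)]
    protein_ids = [f"P{j + 1:0{width}d}" for j in range(config.n_proteins)]
    indication_ids = [f"IND{j:02d}" for j in range(config.n_indications)]
    focal = indication_ids[0]

    # Motif bit blocks are a fixed partition of the low bit indices; the
    # remaining bits form the background pool for noise.
    motifs = {
        ind: list(range(j * config.motif_bits, (j + 1) * config.motif_bits))
        for j, ind in enumerate(indication_ids)
    }
    background = np.arange(config.n_indications * config.motif_bits, config.n_bits)

    # Disjoint indication membership.
    sizes = config.indication_sizes
    chosen = rngs["membership"].choice(
        config.n_compounds, size=sum(sizes), replace=False
    )
    indication_of: dict[str, str] = {}
    offset = 0
    associations: list[tuple[str, str]] = []
    for ind, size in zip(indication_ids, sizes):
        for idx in sorted(chosen[offset : offset + size].tolist()):
            indication_of[compound_ids[idx]] = ind
            associations.append((ind, compound_ids[idx]))
        offset += size

    # Compound fingerprints: background noise plus (for indication members)
    # motif bits kept independently with probability cluster_strength.
    records = []
    for cid in compound_ids:
        bits = set(
            rngs["fingerprints"].choice(background, size=config.noise_bits, replace=False).tolist()
        )
        ind = indication_of.get(cid)
        if ind is not None:
            keep = rngs["fingerprints"].random(config.motif_bits) < config.cluster_strength
            bits.update(b for b, kept in zip(motifs[ind], keep) if kept)
        records.append(
            CompoundRecord(
                compound_id=cid,
                name=cid,
                fingerprint=Fingerprint(bits=frozenset(bits), n_bits=config.n_bits),
            )
        )
    compounds = CompoundLibrary(records)

    # Proteins: the first signal_proteins_per_indication per indication carry
    # that indication's motif in their first template; everything else is
    # background.
    signal_protein_of: dict[str, str] = {}
    j = 0
    for ind in indication_ids:
        for _ in range(config.signal_proteins_per_indication):
            signal_protein_of[protein_ids[j]] = ind
            j += 1

    templates = []
    for pid in protein_ids:
        for t in range(config.n_templates_per_protein):
            ind = signal_protein_of.get(pid)
            if ind is not None and t == 0:
                extra = rngs["templates"].choice(background, size=8, replace=False)
                bits = frozenset(motifs[ind]) | frozenset(extra.tolist())
                confidence = float(rngs["confidence"].uniform(0.7, 1.0))
            else:
                bits = frozenset(
                    rngs["templates"]
                    .choice(background, size=config.motif_bits, replace=False)
                    .tolist()
                )
                confidence = float(rngs["confidence"].uniform(0.2, 1.0))
            templates.append(
                PocketTemplate(
                    protein_id=pid,
                    template_id=f"T{t + 1}",
                    ligand_fingerprint=Fingerprint(bits=bits, n_bits=config.n_bits),
                    confidence=round(confidence, 6),
                )
            )
    pockets = PocketLibrary(templates)
    mapping = IndicationMapping(associations)
    mapping.validate_against(compounds)

    matrix = build_matrix(compounds, pockets)

    # Gold standard planted against the focal drug set's consensus top targets.
    focal_drugs = mapping.drugs_for(focal)
    ranked = [
        row.protein_id
        for row in consensus_targets(matrix, focal_drugs, n=config.gold_top_window)
    ]
    top_window = ranked[: config.gold_top_window]
    n_in = round(config.gold_overlap_fraction * config.gold_size)
    n_decoys = config.gold_size - n_in
    decoy_pool = [p for p in protein_ids if p not in set(top_window)]
    if n_in > len(top_window) or n_decoys > len(decoy_pool):
        raise ValueError(
            "gold_size infeasible: not enough proteins inside/outside the "
            f"top-{config.gold_top_window} window"
        )
    gold_hits = rngs["gold"].choice(len(top_window), size=n_in, replace=False)
    gold_decoys = rngs["gold"].choice(len(decoy_pool), size=n_decoys, replace=False)
    gold = sorted(
        [top_window[int(i)] for i in gold_hits]
        + [decoy_pool[int(i)] for i in gold_decoys]
    )

    return SynthStudy(
        config=config,
        compounds=compounds,
        pockets=pockets,
        mapping=mapping,
        gold_standards={"planted": gold},
        matrix=matrix,
        focal_indication=focal,
    )


def write_study(study: SynthStudy, outdir: str | Path) -> dict[str, Path]:
    """Write the study's input files (compounds/pockets/indications TSVs and
    one gold-standard text file per set).  Byte-identical for equal seeds."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "compounds": outdir / "compounds.tsv",
        "pockets": outdir / "pockets.tsv",
        "indications": outdir / "indications.tsv",
    }
    write_compound_table(study.compounds, paths["compounds"])
    write_pocket_table(study.pockets, paths["pockets"])
    write_indication_table(study.mapping, paths["indications"])
    for name, proteins in study.gold_standards.items():
        path = outdir / f"gold_{name}.txt"
        path.write_text("".join(f"{p}\n" for p in proteins))
        paths[f"gold_{name}"] = path
    return paths


def make_fixture() -> SynthStudy:
    """A tiny hand-verifiable 8-compound x 6-protein study.

    Fingerprints are 16-bit sets chosen so key cells are hand-computable,
    e.g. compound C1 {2,3,4} against protein P1's template {1,2,3} at
    confidence 0.8 scores 0.8 * (2*2 / (3+3)) = 0.5333.  A few compounds
    carry small real SMILES (methane, ethanol, benzene) for heavy-atom
    filter tests; protein P6 has two templates that tie exactly, exercising
    the template_id tie-break.
    """

    def fp(*bits: int) -> Fingerprint:
        return Fingerprint(bits=frozenset(bits), n_bits=16)

    compounds = CompoundLibrary(
        [
            CompoundRecord("C1", "alpha", smiles="c1ccccc1", fingerprint=fp(2, 3, 4)),
            CompoundRecord("C2", "bravo", fingerprint=fp(1, 2, 3)),
            CompoundRecord("C3", "charlie", fingerprint=fp(2, 3)),
            CompoundRecord("C4", "delta", fingerprint=fp(8, 9, 10)),
            CompoundRecord("C5", "echo", fingerprint=fp(8, 9, 11)),
            CompoundRecord("C6", "foxtrot", fingerprint=fp(12, 13)),
            CompoundRecord("C7", "methane", smiles="C", fingerprint=fp(0)),
            CompoundRecord("C8", "ethanol", smiles="CCO", fingerprint=fp(14, 15)),
        ]
    )
    pockets = PocketLibrary(
        [
            PocketTemplate("P1", "T1", fp(1, 2, 3), 0.8),
            PocketTemplate("P2", "T1", fp(2, 3, 4), 1.0),
            PocketTemplate("P2", "T2", fp(2, 3), 0.9),
            PocketTemplate("P3", "T1", fp(8, 9, 10), 0.9),
            PocketTemplate("P4", "T1", fp(8, 9), 0.7),
            PocketTemplate("P4", "T2", fp(9, 11), 0.7),
            PocketTemplate("P5", "T1", fp(12, 13, 14), 0.6),
            PocketTemplate("P6", "LIGB", fp(0), 0.5),
            PocketTemplate("P6", "LIGA", fp(0), 0.5),
        ]
    )
    mapping = IndicationMapping(
        [
            ("IND_A", "C1"),
            ("IND_A", "C2"),
            ("IND_A", "C3"),
            ("IND_B", "C4"),
            ("IND_B", "C5"),
        ]
    )
    config = SynthConfig(
        n_compounds=8,
        n_proteins=6,
        n_templates_per_protein=2,
        n_indications=2,
        focal_indication_size=3,
        other_indication_size=2,
        n_bits=16,
        motif_bits=2,
        noise_bits=1,
        signal_proteins_per_indication=1,
        gold_size=3,
        seed=0,
    )
    return SynthStudy(
        config=config,
        compounds=compounds,
        pockets=pockets,
        mapping=mapping,
        gold_standards={"fixture": ["P1", "P3", "P5"]},
        matrix=build_matrix(compounds, pockets),
        focal_indication="IND_A",
    )
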