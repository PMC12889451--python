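"""Rank drugs by similarity of their proteome-wide interaction signatures.

Generates a small synthetic study with planted indication clusters, builds
all-against-all cosine-distance rankings, and shows that drugs sharing the
focal indication surface at the top of each other's lists.
"""

from drugsig import SynthConfig, all_rankings, generate_study

study = generate_study(
    SynthConfig(
        n_compounds=60, n_proteins=40, n_indications=3,
        focal_indication_size=10, other_indication_size=5,
        signal_proteins_per_indication=4, gold_size=10, gold_top_window=20,
        seed=7,
    )
)
rankings = all_rankings(study.matrix)

focal_drugs = set(study.mapping.drugs_for(study.focal_indication))
query = sorted(focal_drugs)[0]
print(f"focal indication {study.focal_indication} has {len(focal_drugs)} drugs")
print(f"nearest neighbours of {query} (* = same indication):")
for pos, (cid, dist) in enumerate(rankings[query].entries[:10]):
    mark = " *" if cid in focal_drugs else ""
    print(f"  {pos:2d}  {cid}  distance {dist:.4f}{mark}")
print("Small cosine distances mean similar interaction signatures; starred")
print("entries show the planted cluster being recovered ahead of background drugs.")
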