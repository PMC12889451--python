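"""Consensus drug predictions for an indication, with binomial probabilities.

A candidate's consensus score counts how many of the indication's drugs
include it in the top 10 of their similarity lists; the probability column is
the binomial upper tail of seeing that many appearances under random
rankings.  Also builds the two control drug sets: bottoms of the lists after
a heavy-atom filter, and a seeded random draw from a reference drug's list.
"""

from drugsig import (
    SynthConfig,
    all_rankings,
    bottom_filtered_control,
    consensus_predict,
    generate_study,
    random_control,
)

study = generate_study(SynthConfig(seed=1))
rankings = all_rankings(study.matrix)
assoc = study.mapping.drugs_for(study.focal_indication)

predictions = consensus_predict(rankings, assoc, cutoff=10)
print(f"top consensus predictions for {study.focal_indication} ({len(assoc)} drugs):")
print("rank  drug   consensus  avg_rank  probability")
for p in predictions[:8]:
    print(
        f"{p.drug_rank:4d}  {p.compound_id}  {p.consensus_score:9d}"
        f"  {p.average_rank:8.2f}  {p.probability:.3g}"
    )
print("Low probabilities mean the drug appears in far more top-10 windows")
print("than chance allows; associated drugs recovering each other is expected.")

bottom = bottom_filtered_control(rankings, assoc, study.compounds, window=10)
print(f"\nbottom-filtered control (first 3): {[p.compound_id for p in bottom[:3]]}")

reference = assoc[0]
rand = random_control(rankings[reference], n_drugs=5, seed=7)
print(f"random control drawn from {reference}'s list: {rand}")
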