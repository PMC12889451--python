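"""Score compounds against protein pockets and trace what drives each score.

Uses the built-in hand-sized fixture study: 8 compounds with explicit
fingerprints against 6 proteins, each protein carrying one or two pocket
templates (a known ligand fingerprint plus a binding-site confidence).
"""

from drugsig import dice_similarity, make_fixture, trace_top_ligand

study = make_fixture()
matrix = study.matrix

c1 = study.compounds["C1"].fingerprint
template = study.pockets.templates_for("P1")[0]
print(f"Dice(C1, P1 template ligand)       = {dice_similarity(c1, template.ligand_fingerprint):.4f}")
print(f"pocket confidence                  = {template.confidence}")
print(f"interaction score (conf x Dice)    = {matrix.score('C1', 'P1'):.4f}")

# A compound's matrix row is its proteome-wide interaction signature.
print("\ninteraction signature of C1:")
for pid, s in zip(matrix.protein_ids, matrix.signature("C1")):
    print(f"  {pid}: {s:.4f}")

# Which template ligand is responsible for a given cell, with its components.
trace = trace_top_ligand("C1", "P2", study.compounds, study.pockets)
print(
    f"\ntop ligand for (C1, P2): template {trace.template_id} "
    f"(confidence {trace.confidence}, Dice {trace.dice:.3f}) -> score {trace.score:.3f}"
)
print("The score of every cell is the best confidence-weighted chemical")
print("similarity over that protein's pocket templates, in [0, 1].")
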