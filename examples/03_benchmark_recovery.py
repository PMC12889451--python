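"""Benchmark recovery of known drug-indication associations.

Computes the four leave-one-out metrics (IA, nIA, NDCG, nNDCG) at several
cutoffs on planted-cluster synthetic data and compares them with the two
chance baselines: the analytic hypergeometric control and an empirical
control from row-permuted interaction matrices.
"""

from drugsig import (
    SynthConfig,
    all_rankings,
    generate_study,
    hypergeometric_control,
    random_matrix_control,
    run_benchmark,
)

study = generate_study(SynthConfig(seed=1))
rankings = all_rankings(study.matrix)
cutoffs = [10, 25, 50, 100]

report = run_benchmark(rankings, study.mapping, cutoffs)
hyper = hypergeometric_control(rankings, study.mapping, cutoffs)
random_ctrl = random_matrix_control(
    study.matrix, study.mapping, cutoffs, n_reps=20, seed=5, metrics=("IA",)
)

print(f"{'metric':8s}" + "".join(f"  k={k:<5d}" for k in cutoffs))
for name, by_k in report.averages.items():
    print(f"{name:8s}" + "".join(f"  {by_k[k]:7.3f}" for k in cutoffs))
print("controls (chance level for AIA):")
print("hyper   " + "".join(f"  {hyper['averages']['AIA'][k]:7.3f}" for k in cutoffs))
print("permute " + "".join(f"  {random_ctrl.averages['AIA'][k]:7.3f}" for k in cutoffs))
print()
print("AIA/nAIA are percentages of drugs whose partners (or withheld drugs)")
print("are recovered within the cutoff; NDCG/nNDCG grade how near the top.")
print("Planted clustering drives the observed values far above both controls.")
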