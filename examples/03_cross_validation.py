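"""Five-fold cross-validated evaluation of the full ensemble.

Runs the complete pipeline (filtered networks -> walks -> embeddings ->
per-meta-path XGBoost -> MAX integration) on a small planted synthetic
network, with anchored folds, and prints the six benchmark metrics plus a
shuffled-label null control.
"""

from metapathdr import PipelineConfig, SyntheticConfig, generate_hetnet, run_cv

synth = SyntheticConfig(
    n_drugs=60, n_diseases=35, n_proteins=250, n_functions=100,
    n_positive_pairs=120, seed=3,
)
network, positives = generate_hetnet(synth)

config = PipelineConfig(walks_per_start=50, epochs=10)
result = run_cv(network, positives, config, seed=3)
print("five-fold cross-validation, MAX-integrated ensemble (four meta-paths):")
for key, value in result.mean.to_dict().items():
    if key != "counts":
        print(f"  {key:<10s} {value:.3f}")

single = run_cv(
    network, positives,
    PipelineConfig(metapaths=("Dr-P-Di",), walks_per_start=50, epochs=10),
    seed=3,
)
print(f"  shared-target path alone (Dr-P-Di): AUROC {single.mean.auroc:.3f}")

null = run_cv(network, positives, config, seed=3, shuffle_labels=True)
print(f"  null AUROC {null.mean.auroc:.3f}  (labels shuffled; chance = 0.5)")
print()
print("Recovery is partial at this small scale: the planted mechanisms wire")
print("signal mainly into the shared-target path, and tree classifiers use")
print("only part of what the embeddings encode (see docs/methods.md).  The")
print("shuffled-label control sitting at chance verifies there is no label")
print("leakage anywhere in the protocol.")
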