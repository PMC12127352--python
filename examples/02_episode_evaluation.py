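"""Run the N-way-K-shot evaluation protocol on one feature layer.

Samples 5-way-1-shot episodes (1000 per run, averaged over 5 runs here; the
full protocol uses 20 runs), classifies queries by nearest prototype, and
reports mean accuracy with macro precision/recall/F1.
"""

from fascal import EpisodeSpec, GaussianClassSpec, make_gaussian_classes, run_evaluation

features = make_gaussian_classes(GaussianClassSpec(n_classes=10, seed=0))
spec = EpisodeSpec(n_way=5, k_shot=1, q_per_class=15)

summary = run_evaluation(features, spec, episodes_per_run=1000, runs=5, seed=0)
print(f"5-way-1-shot accuracy: {100 * summary.mean_accuracy:.2f}% "
      f"(std over episodes {100 * summary.std_accuracy:.2f})")
print(f"macro P/R/F1: {100 * summary.macro_precision:.2f} / "
      f"{100 * summary.macro_recall:.2f} / {100 * summary.macro_f1:.2f}")
# Accuracy is the fraction of query images assigned to the right class;
# macro metrics average per-class precision/recall with equal class weight.
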