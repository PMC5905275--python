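"""Which substructure features discriminate sweet from bitter?

Computes per-bit class frequencies of the Morgan fingerprint, the
Bayesian class probability P(class | feature), applies the
active-feature rule, and traces the top sweet-active bits back to the
atom environments that set them.
"""

from tasteforest import (
    FixtureSpec,
    active_features,
    bayes_feature_scores,
    bit_to_substructure,
    fingerprint_matrix,
    generate_labeled_set,
    relative_frequencies,
    top_features,
)

records = generate_labeled_set(FixtureSpec(n_per_class=300, motif_purity=0.9, seed=1))
matrix, _ = fingerprint_matrix(records, "morgan")
labels = [r.label for r in records]

scores = bayes_feature_scores(matrix, labels)
_, class_means = relative_frequencies(matrix, labels)
scores = active_features(scores, class_means)

print(f"average relative frequency: sweet {class_means['sweet']:.4f}, "
      f"bitter {class_means['bitter']:.4f}")
print(f"{'bit':>5} {'f_sweet':>8} {'f_bitter':>9} {'P(sweet|F)':>11}  example environment")
for s in top_features(scores, "sweet", k=10):
    env = ""
    for i, rec in enumerate(records):
        if rec.label == "sweet" and matrix[i, s.bit]:
            env = bit_to_substructure(rec, s.bit, "morgan")[0]["substructure"]
            break
    print(f"{s.bit:>5} {s.freq_sweet:>8.3f} {s.freq_bitter:>9.3f} "
          f"{s.p_sweet_given_f:>11.3f}  {env}")

# A bit is "active" for sweet when its frequency among sweet compounds
# exceeds the sweet average while staying below the bitter average.
# The recovered environments contain the planted sulfonamide motif —
# the analysis finds the class-defining chemistry from bits alone.
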