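"""Grouped permutation feature importance on a planted-signal task.

With ~1000 features, shuffling one column barely moves accuracy, so groups
of features are permuted together and the recorded accuracy decrease is
attributed to every group member; a feature's score is its mean decrease
over the permutations that included it. Here the planted informative
clusters should surface at the top of the ranking, and their anatomical
category counts are tabulated the way a tractography study would report
them.
"""

from scregress import (
    ImportanceConfig,
    SyntheticSpec,
    TrainConfig,
    aggregate_by_category,
    generate_dataset,
    make_split,
    run_permutation_importance,
    top_k,
    train_regressor,
)

spec = SyntheticSpec(n_subjects=1000, n_features=100, n_informative=10,
                     n_measures=1, zero_inflation_rate=0.0, target_ceiling=0.9,
                     seed=3)
tables, scores, truth = generate_dataset(spec)
split = make_split(spec.n_subjects, seed=3)
model = train_regressor(tables[0], scores, split, TrainConfig(seed=3))

cfg = ImportanceConfig(group_size=10, n_permutations=2000,
                       mode="test_permute", seed=3)
result = run_permutation_importance(tables[0], scores, split, cfg, model=model)

top10 = top_k(result, 10)
hits = set(top10) & set(truth.informative_ids)
print(f"baseline test r: {result.baseline_r:.3f}")
print(f"top-10 ranked clusters: {list(top10)}")
print(f"planted informative clusters recovered in top-10: {len(hits)}/10")

counts = aggregate_by_category(top10, tables[0].category_map)
print("anatomical category counts of the top-10 clusters:")
for cat, (n, pct) in counts.items():
    print(f"  {cat:>12}: {n} ({pct:.1f}%)")
print("scores are mean decreases in test Pearson r; a large decrease means "
      "the model relies on that cluster.")
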