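"""Simulate an imbalanced benchmark and build balanced sub-training splits.

Generates a 10:1 negative-to-positive synthetic dataset (scaled down from
the 3700/37,000 benchmark shape), then partitions the negatives into ten
disjoint shards, each paired with the full positive set. Every sub-training
dataset is therefore ~1:1 balanced while all negatives are still used.
"""

from m6aminer.datasets import make_subtraining_splits
from m6aminer.synthetic import GeneratorSpec, generate

ds = generate(GeneratorSpec(n_pos=370, n_neg=3700, effect_size=0.8, seed=0))
print(f"dataset: {ds.positive_count} positives, {ds.negative_count} negatives")

splits = make_subtraining_splits(ds, n_splits=10, seed=0)
for s in splits[:3]:
    print(f"split {s.index}: {len(s.positives)} pos + {len(s.negatives)} neg")
print("...")

shards = [frozenset(w.id for w in s.negatives) for s in splits]
assert len(frozenset.union(*shards)) == ds.negative_count
print("negative shards are disjoint and exhaustive; "
      f"sizes {sorted(len(s) for s in shards)[0]}..{sorted(len(s) for s in shards)[-1]}")
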