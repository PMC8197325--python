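"""Generate a synthetic clinical-style table and partition it 6:2:2.

The generator plants a known ground truth: a handful of informative features
drive the binary label through a logistic model, redundant features echo
them, and the rest is pure noise.  The split sizes follow the floor/remainder
rule, so 2990 rows give exactly 1794/598/598.
"""

from xgbstack import SplitSpec, SyntheticSpec, generate_synthetic, split_dataset

spec = SyntheticSpec(n_samples=2990, seed=0)  # defaults: 8+10+50 = 68 features
ds = generate_synthetic(spec)
train, val, test = split_dataset(ds, SplitSpec(6, 2, 2, seed=42))

roles = list(ds.provenance["roles"].values())
print(f"dataset: {ds.n_samples} samples x {ds.n_features} features, "
      f"positive fraction {ds.y.mean():.3f}")
print(f"feature roles: {roles.count('informative')} informative, "
      f"{roles.count('redundant')} redundant, {roles.count('noise')} noise")
print(f"partition sizes (train/val/test): "
      f"{train.n_samples}/{val.n_samples}/{test.n_samples}")
# The partition sizes realize the 6:2:2 protocol exactly; the positive
# fraction is calibrated to the requested label balance (0.5 by default).
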