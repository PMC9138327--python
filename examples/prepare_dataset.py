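"""Dataset construction: dedup, fingerprint filter, balance, split.

Mirrors a curated binding benchmark build: exact duplicates removed,
drugs that cannot be fingerprinted dropped, negatives subsampled to a
1:1 class ratio, then a stratified 7:1.5:1.5 split whose partitions
share no (drug, protein) pair.
"""

import dtifusion as dt
from dtifusion.synthetic import SyntheticSpec

spec = SyntheticSpec(n_pos=600, n_neg=900, seed=1)  # deliberately unbalanced
records = dt.generate_dataset(spec)
print(f"raw records: {len(records)} ({sum(r.label for r in records)} positive)")

records = dt.deduplicate(records)
print(f"after duplicate removal: {len(records)}")

records, removed = dt.drop_unfingerprintable(records)
print(f"unfingerprintable drugs removed: {removed}")

records = dt.balance(records, seed=1)
print(f"after negative subsampling: {len(records)} (1:1 classes)")

split = dt.stratified_split(records, seed=1)
print(f"train/valid/test: {split.sizes()}  leakage: {dt.audit_leakage(split)}")

half = dt.subsample_training(split, 0.5, seed=1)
print(f"50% training subsample: {len(half.train)} rows "
      f"(validation/test fixed at {len(half.valid)}/{len(half.test)})")
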