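"""Dataset model: ingestion, cleaning, balancing and splitting.

The pipeline mirrors a standard binary-DTI benchmark construction:
exact-duplicate removal, dropping drugs that cannot be fingerprinted,
uniform negative subsampling to a 1:1 class ratio, and a stratified
7:1.5:1.5 train/validation/test split with a leakage audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .encode import FingerprintError, morgan_fingerprint

logger = logging.getLogger(__name__)

DEFAULT_RATIOS = (0.7, 0.15, 0.15)
DEFAULT_SEED = 42


class DataError(ValueError):
    """Malformed input table or invalid pipeline precondition."""


@dataclass(frozen=True)
class DTIRecord:
    """One (drug SMILES, protein sequence, binary label) sample."""

    smiles: str
    sequence: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise DataError(f"label must be 0 or 1, got {self.label!r}")
        if not self.smiles or not self.sequence:
            raise DataError("smiles and sequence must be non-empty")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.smiles, self.sequence)


@dataclass
class SplitDataset:
    """Disjoint train/validation/test partitions of DTI records."""

    train: list[DTIRecord]
    valid: list[DTIRecord]
    test: list[DTIRecord]
    seed: int = DEFAULT_SEED
    ratios: tuple[float, float, float] = DEFAULT_RATIOS

    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.valid), len(self.test))


def load_dti_table(path: str | Path) -> list[DTIRecord]:
    """Read a delimited table with smiles/sequence/label columns.

    The delimiter (tab or comma) and the presence of a header row are
    auto-detected. Rows with a non-binary label raise with their row
    number.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    cols = {c.strip().lower(): c for c in df.columns}
    required = ("smiles", "sequence", "label")
    if not all(r in cols for r in required):
        # headerless file: first row was data — re-read with fixed names
        if len(df.columns) == 3:
            df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                             header=None, names=list(required))
            cols = {r: r for r in required}
        else:
            missing = [r for r in required if r not in cols]
            raise DataError(f"missing column(s) {missing} in {path}")
    smiles_col = df[cols["smiles"]].astype(str).str.strip()
    seq_col = df[cols["sequence"]].astype(str).str.strip()
    label_col = df[cols["label"]].astype(str).str.strip()
    records = []
    for i in range(len(df)):
        raw = label_col.iat[i]
        if raw not in ("0", "1"):
            raise DataError(f"non-binary label {raw!r} at row {i + 1} of {path}")
        records.append(DTIRecord(smiles=smiles_col.iat[i], sequence=seq_col.iat[i], label=int(raw)))
    return records


def save_dti_table(records: Sequence[DTIRecord], path: str | Path) -> None:
    """Write records as a TSV with a smiles/sequence/label header."""
    df = pd.DataFrame(
        {"smiles": [r.smiles for r in records],
         "sequence": [r.sequence for r in records],
         "label": [r.label for r in records]}
    )
    df.to_csv(path, sep="\t", index=False)


def deduplicate(records: Sequence[DTIRecord]) -> list[DTIRecord]:
    """Drop exact (smiles, sequence, label) duplicates, keeping first seen.

    A pair that appears with *both* labels is kept as two distinct
    records — the conflict is logged, not resolved.
    """
    seen: set[tuple[str, str, int]] = set()
    pair_labels: dict[tuple[str, str], set[int]] = {}
    out = []
    for r in records:
        key = (r.smiles, r.sequence, r.label)
        if key in seen:
            continue
        seen.add(key)
        labels = pair_labels.setdefault(r.pair, set())
        labels.add(r.label)
        if len(labels) == 2:
            logger.warning("pair %r appears with both labels; keeping both records", r.pair)
        out.append(r)
    return out


def drop_unfingerprintable(records: Sequence[DTIRecord]) -> tuple[list[DTIRecord], int]:
    """Remove records whose SMILES cannot produce a Morgan fingerprint.

    Returns the surviving records and the number removed.
    """
    ok: dict[str, bool] = {}
    out = []
    removed = 0
    for r in records:
        if r.smiles not in ok:
            try:
                morgan_fingerprint(r.smiles)
                ok[r.smiles] = True
            except FingerprintError:
                ok[r.smiles] = False
        if ok[r.smiles]:
            out.append(r)
        else:
            removed += 1
    if removed:
        logger.info("dropped %d record(s) with unfingerprintable drugs", removed)
    return out, removed


def balance(records: Sequence[DTIRecord], seed: int = DEFAULT_SEED) -> list[DTIRecord]:
    """Subsample negatives (uniformly, without replacement) to a 1:1 ratio.

    All positives are kept; order is positives-then-sampled-negatives in
    original order.
    """
    pos = [r for r in records if r.label == 1]
    neg = [r for r in records if r.label == 0]
    if len(neg) < len(pos):
        raise DataError(f"need at least {len(pos)} negatives, have {len(neg)}")
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(neg), size=len(pos), replace=False)
    keep_set = set(keep.tolist())
    return pos + [r for i, r in enumerate(neg) if i in keep_set]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(
    records: Sequence[DTIRecord],
    ratios: tuple[float, float, float] = DEFAULT_RATIOS,
    seed: int = DEFAULT_SEED,
) -> SplitDataset:
    """Seeded stratified split in the given ratios (default 7:1.5:1.5).

    Within each label class of size n the training part takes
    ``round(r_train * n)``, validation ``floor(r_valid * n)`` and test
    the remainder; with two classes of 6571 this yields partition sizes
    9200/1970/1972. Assignment within a class is a seeded uniform
    shuffle, so the three parts always partition the input.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise DataError(f"ratios must sum to 1, got {ratios}")
    rng = np.random.default_rng(seed)
    parts: tuple[list[DTIRecord], list[DTIRecord], list[DTIRecord]] = ([], [], [])
    for label in (1, 0):
        cls = [r for r in records if r.label == label]
        if not cls:
            raise DataError(f"no records with label {label}; split requires both classes")
        n = len(cls)
        n_train = _round_half_up(ratios[0] * n)
        n_valid = int(np.floor(ratios[1] * n))
        order = rng.permutation(n)
        for j, k in enumerate(order):
            if j < n_train:
                parts[0].append(cls[k])
            elif j < n_train + n_valid:
                parts[1].append(cls[k])
            else:
                parts[2].append(cls[k])
    return SplitDataset(train=parts[0], valid=parts[1], test=parts[2], seed=seed, ratios=ratios)


def subsample_training(
    split: SplitDataset, fraction: float, seed: int = DEFAULT_SEED
) -> SplitDataset:
    """Shrink the training partition to ``fraction`` of its rows.

    Sampling is uniform without replacement, per label class (so a
    balanced training set stays balanced: each class keeps
    ``round(fraction * n_class)`` rows). Validation and test are
    untouched, mimicking a small-data regime with a fixed benchmark.
    """
    if not 0 < fraction <= 1:
        raise DataError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return SplitDataset(list(split.train), list(split.valid), list(split.test),
                            seed=split.seed, ratios=split.ratios)
    rng = np.random.default_rng(seed)
    new_train: list[DTIRecord] = []
    for label in (1, 0):
        cls = [r for r in split.train if r.label == label]
        k = _round_half_up(fraction * len(cls))
        keep = set(rng.choice(len(cls), size=k, replace=False).tolist())
        new_train.extend(r for i, r in enumerate(cls) if i in keep)
    return SplitDataset(new_train, list(split.valid), list(split.test),
                        seed=seed, ratios=split.ratios)


def audit_leakage(split: SplitDataset) -> dict[str, int]:
    """Count (smiles, sequence) pairs shared between any two partitions.

    All three counts are zero for any split produced by
    :func:`stratified_split` (it partitions the records); non-zero
    counts flag evaluation leakage.
    """
    train = {r.pair for r in split.train}
    valid = {r.pair for r in split.valid}
    test = {r.pair for r in split.test}
    report = {
        "train_valid": len(train & valid),
        "train_test": len(train & test),
        "valid_test": len(valid & test),
    }
    for k, v in report.items():
        if v:
            logger.warning("leakage: %d pair(s) shared between %s", v, k.replace("_", " and "))
    return report
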