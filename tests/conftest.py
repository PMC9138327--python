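"""Shared fixtures: small vocabularies, tiny configs, and one expensive
session-scoped end-to-end ablation run reused by the slow tests."""

from __future__ import annotations

import numpy as np
import pytest

import dtifusion as dt
from dtifusion.model import ModelConfig
from dtifusion.synthetic import SyntheticSpec, generate_dataset

LETTERS = tuple("ABCDEFGHIJKLMNOPQRSTUVWXYZ")


@pytest.fixture(scope="session")
def letters_vocab() -> dt.Vocabulary:
    return dt.Vocabulary(tokens=LETTERS, kind="protein-kmer")


@pytest.fixture(scope="session")
def kmer_vocab() -> dt.Vocabulary:
    """Letters plus a few multi-order tokens for greedy-match tests."""
    return dt.Vocabulary(tokens=LETTERS + ("AB", "ABC", "KV", "QQQ"), kind="protein-kmer")


@pytest.fixture(scope="session")
def drug_vocab() -> dt.Vocabulary:
    return dt.build_drug_vocab(["CCO", "c1ccncc1", "CC(=O)O"])


def tiny_model_config(**overrides) -> ModelConfig:
    """A shrunken architecture for fast optimization smoke tests."""
    base = dict(
        protein_length=64, drug_length=48,
        protein_embedding_dim=8, drug_embedding_dim=6,
        n_layers=1, n_heads=2, d_model=8, d_ff=16,
        protein_conv_filters=8, protein_kernel_sizes=(3, 5),
        drug_conv_filters=8, drug_kernel_sizes=(2, 4),
        fingerprint_units=(16,), dense_units=(16,),
        embedding_dropout_rate=0.0, seed=0,
    )
    base.update(overrides)
    return ModelConfig(**base)


@pytest.fixture()
def tiny_config() -> ModelConfig:
    return tiny_model_config()


@pytest.fixture(scope="session")
def tiny_split() -> dt.SplitDataset:
    """A small noiseless synthetic dataset split for training smoke tests."""
    spec = SyntheticSpec(n_proteins=60, n_drugs=80, n_pos=120, n_neg=120,
                         protein_length_range=(30, 55), seed=5)
    records = dt.deduplicate(generate_dataset(spec))
    return dt.stratified_split(records, seed=5)


@pytest.fixture(scope="session")
def default_synthetic_split() -> dt.SplitDataset:
    """The default 2000-pair noiseless benchmark, deduplicated and split."""
    spec = SyntheticSpec(seed=11)
    records = dt.deduplicate(generate_dataset(spec))
    return dt.stratified_split(records, seed=11)


@pytest.fixture(scope="session")
def desk_model_config() -> ModelConfig:
    """Reference architecture at desk-scale input lengths.

    The synthetic proteins are at most 100 residues and the assembled
    SMILES under 50 characters, so m=128 / v=64 lose nothing while the
    architecture itself (4 layers, 5 heads, u=20, j=10) stays at the
    reference values.
    """
    return ModelConfig(protein_length=128, drug_length=64, seed=0)


@pytest.fixture(scope="session")
def ablation_results(default_synthetic_split, desk_model_config):
    """Train all five channel configurations once for the whole session."""
    train_cfg = dt.TrainConfig(epochs=8, patience=3, seed=0)
    return dt.run_ablation(default_synthetic_split, desk_model_config, train_cfg)
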