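"""Turn raw sequences into fixed-length model inputs.

Proteins are segmented against the k-mer vocabulary by greedy
longest-match from left to right (deterministic, O(n), and loss-free:
concatenating the emitted tokens reconstructs the input). Drug SMILES
are tokenized one character at a time. Both id lists are padded with the
reserved id 0 (or truncated, keeping the prefix) to a fixed length.
Each drug additionally gets a radius-2 hashed circular (Morgan/ECFP4)
fingerprint folded to 2048 bits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from .vocab import KIND_DRUG, KIND_PROTEIN, PROTEIN_ALPHABET, Vocabulary

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")  # rdkit parse chatter; failures raise below

DEFAULT_PROTEIN_LENGTH = 800
DEFAULT_DRUG_LENGTH = 100
FINGERPRINT_BITS = 2048
FINGERPRINT_RADIUS = 2

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(
    radius=FINGERPRINT_RADIUS, fpSize=FINGERPRINT_BITS
)


class EncodingError(ValueError):
    """Input cannot be encoded (bad character, empty sequence)."""


class FingerprintError(ValueError):
    """SMILES does not parse to a molecule, so no fingerprint exists."""


@dataclass
class EncodedPair:
    """One model input row: fixed-length id vectors plus fingerprint."""

    protein_ids: np.ndarray  # (m,) int
    drug_ids: np.ndarray  # (v,) int
    fingerprint: np.ndarray  # (2048,) uint8 in {0,1}
    label: int | None = None


def tokenize_protein(sequence: str, vocab: Vocabulary) -> list[int]:
    """Greedy longest-match segmentation into vocabulary token ids.

    At every position the longest vocabulary member matching there is
    emitted; because all 26 single letters are in the vocabulary the
    segmentation always succeeds and is exactly invertible.
    """
    if vocab.kind != KIND_PROTEIN:
        raise EncodingError("tokenize_protein requires a protein vocabulary")
    if not sequence:
        raise EncodingError("sequence must be non-empty")
    max_order = vocab.max_order
    ids: list[int] = []
    i = 0
    n = len(sequence)
    while i < n:
        ch = sequence[i]
        if ch not in PROTEIN_ALPHABET:
            raise EncodingError(
                f"invalid character {ch!r} at position {i}; protein sequences are uppercase A-Z"
            )
        for k in range(min(max_order, n - i), 0, -1):
            tok = sequence[i : i + k]
            idx = vocab.index_of.get(tok)
            if idx is not None:
                ids.append(idx)
                i += k
                break
        else:  # single letters are always present, so this cannot happen
            raise EncodingError(f"no token matches at position {i}")
    return ids


def detokenize_protein(ids: Sequence[int], vocab: Vocabulary) -> str:
    """Inverse of :func:`tokenize_protein`; padding ids (0) are ignored."""
    return "".join(vocab.token_at(i) for i in ids if i != Vocabulary.PAD_INDEX)


def tokenize_smiles(smiles: str, vocab: Vocabulary) -> list[int]:
    """One token id per SMILES character.

    Characters absent from the vocabulary map to the reserved
    unknown-token id (the vocabulary was fitted on another corpus) and
    are logged — a deployed predictor must tolerate unseen symbols.
    """
    if vocab.kind != KIND_DRUG:
        raise EncodingError("tokenize_smiles requires a drug vocabulary")
    if not smiles:
        raise EncodingError("smiles must be non-empty")
    unk = vocab.unknown_index
    ids = []
    for ch in smiles:
        idx = vocab.index_of.get(ch)
        if idx is None:
            logger.warning("character %r not in drug vocabulary; using unknown id %d", ch, unk)
            idx = unk
        ids.append(idx)
    return ids


def pad_or_truncate(ids: Sequence[int], target_length: int) -> np.ndarray:
    """Fix the id list to ``target_length``: keep the prefix or right-pad with 0."""
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    out = np.zeros(target_length, dtype=np.int64)
    n = min(len(ids), target_length)
    out[:n] = np.asarray(ids[:n], dtype=np.int64)
    return out


def morgan_fingerprint(smiles: str) -> np.ndarray:
    """Radius-2 hashed circular fingerprint folded to 2048 bits.

    Deterministic and graph-invariant: any two SMILES of the same
    molecule give identical bit vectors.
    """
    mol = Chem.MolFromSmiles(smiles) if smiles else None
    if mol is None:
        raise FingerprintError(f"SMILES {smiles!r} does not parse to a molecule")
    fp = _MORGAN.GetFingerprint(mol)
    arr = np.zeros(FINGERPRINT_BITS, dtype=np.uint8)
    arr[list(fp.GetOnBits())] = 1
    return arr


def encode_pair(
    smiles: str,
    sequence: str,
    protein_vocab: Vocabulary,
    drug_vocab: Vocabulary,
    protein_length: int = DEFAULT_PROTEIN_LENGTH,
    drug_length: int = DEFAULT_DRUG_LENGTH,
    label: int | None = None,
) -> EncodedPair:
    return EncodedPair(
        protein_ids=pad_or_truncate(tokenize_protein(sequence, protein_vocab), protein_length),
        drug_ids=pad_or_truncate(tokenize_smiles(smiles, drug_vocab), drug_length),
        fingerprint=morgan_fingerprint(smiles),
        label=label,
    )


@dataclass
class EncodedDataset:
    """Column-stacked encoded pairs ready for batched model input."""

    protein_ids: np.ndarray  # (n, m)
    drug_ids: np.ndarray  # (n, v)
    fingerprints: np.ndarray  # (n, 2048)
    labels: np.ndarray | None  # (n,)

    def __len__(self) -> int:
        return self.protein_ids.shape[0]

    def take(self, idx: np.ndarray) -> "EncodedDataset":
        return EncodedDataset(
            self.protein_ids[idx],
            self.drug_ids[idx],
            self.fingerprints[idx],
            None if self.labels is None else self.labels[idx],
        )


def encode_records(
    records,
    protein_vocab: Vocabulary,
    drug_vocab: Vocabulary,
    protein_length: int = DEFAULT_PROTEIN_LENGTH,
    drug_length: int = DEFAULT_DRUG_LENGTH,
) -> EncodedDataset:
    """Encode a list of (smiles, sequence, label) records column-wise.

    Fingerprints for repeated SMILES are computed once and cached.
    """
    n = len(records)
    prot = np.zeros((n, protein_length), dtype=np.int64)
    drug = np.zeros((n, drug_length), dtype=np.int64)
    fps = np.zeros((n, FINGERPRINT_BITS), dtype=np.uint8)
    labels = np.zeros(n, dtype=np.int64)
    fp_cache: dict[str, np.ndarray] = {}
    prot_cache: dict[str, np.ndarray] = {}
    for i, rec in enumerate(records):
        if rec.sequence not in prot_cache:
            prot_cache[rec.sequence] = pad_or_truncate(
                tokenize_protein(rec.sequence, protein_vocab), protein_length
            )
        prot[i] = prot_cache[rec.sequence]
        drug[i] = pad_or_truncate(tokenize_smiles(rec.smiles, drug_vocab), drug_length)
        if rec.smiles not in fp_cache:
            fp_cache[rec.smiles] = morgan_fingerprint(rec.smiles)
        fps[i] = fp_cache[rec.smiles]
        labels[i] = rec.label
    return EncodedDataset(prot, drug, fps, labels)
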