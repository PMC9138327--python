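"""Token vocabularies for protein sequences and drug SMILES.

Two dictionary flavours are built here:

* a *protein* vocabulary of 1- to 3-mers over the uppercase alphabet A-Z.
  All 26 single letters are always included so that any sequence can be
  segmented; 2-mers and 3-mers are admitted only if they are frequent
  enough in a reference corpus (frequency screening), which keeps the
  dictionary small while roughly halving encoded sequence length.
* a *drug* vocabulary of the distinct single characters observed in a
  SMILES corpus. SMILES symbols (ring digits, bond symbols, brackets)
  do not compose the way amino-acid k-mers do, so no multi-character
  tokens are formed.

Token indices start at 1; index 0 is reserved for padding so that an
embedding layer can dedicate a row to "no token".
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

PROTEIN_ALPHABET = tuple("ABCDEFGHIJKLMNOPQRSTUVWXYZ")

KIND_PROTEIN = "protein-kmer"
KIND_DRUG = "drug-char"
_VALID_KINDS = (KIND_PROTEIN, KIND_DRUG)


class VocabularyError(ValueError):
    """Raised when a vocabulary violates its structural invariants."""


@dataclass(frozen=True)
class Vocabulary:
    """An ordered token list with 1-based indices (0 = padding).

    Parameters
    ----------
    tokens:
        Ordered, duplicate-free token strings. Position ``i`` holds the
        token with index ``i + 1``.
    kind:
        ``"protein-kmer"`` or ``"drug-char"``.
    """

    tokens: tuple[str, ...]
    kind: str
    index_of: dict[str, int] = field(init=False, repr=False, compare=False)

    PAD_INDEX = 0

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise VocabularyError(f"unknown vocabulary kind {self.kind!r}")
        seen: dict[str, int] = {}
        for pos, tok in enumerate(self.tokens):
            if not tok:
                raise VocabularyError(f"empty token at position {pos}")
            if tok in seen:
                raise VocabularyError(f"duplicate token {tok!r}")
            seen[tok] = pos + 1
        if self.kind == KIND_PROTEIN:
            for tok in self.tokens:
                if not (1 <= len(tok) <= 3) or not all(c in PROTEIN_ALPHABET for c in tok):
                    raise VocabularyError(
                        f"protein token {tok!r} must be 1-3 uppercase letters A-Z"
                    )
            missing = set(PROTEIN_ALPHABET) - set(self.tokens)
            if missing:
                raise VocabularyError(
                    f"protein vocabulary must contain all 26 letters; missing {sorted(missing)}"
                )
        else:
            for tok in self.tokens:
                if len(tok) != 1:
                    raise VocabularyError(f"drug token {tok!r} must be a single character")
        object.__setattr__(self, "index_of", seen)

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index_of

    def order_of(self, token: str) -> int:
        """Length of ``token`` in characters (its k-mer order)."""
        if token not in self.index_of:
            raise KeyError(token)
        return len(token)

    @property
    def max_order(self) -> int:
        return max(len(t) for t in self.tokens)

    @property
    def unknown_index(self) -> int:
        """Reserved id for characters never seen at fit time (drug only)."""
        if self.kind != KIND_DRUG:
            raise VocabularyError("unknown-token id exists only for drug vocabularies")
        return len(self.tokens) + 1

    @property
    def embedding_rows(self) -> int:
        """Number of embedding-table rows needed (pad + tokens [+ unknown])."""
        extra = 1 if self.kind == KIND_DRUG else 0
        return len(self.tokens) + 1 + extra

    def token_at(self, index: int) -> str:
        if not 1 <= index <= len(self.tokens):
            raise VocabularyError(f"index {index} out of range 1..{len(self.tokens)}")
        return self.tokens[index - 1]

    def order_counts(self) -> dict[int, int]:
        """Number of tokens of each k-mer order, e.g. ``{1: 26, 2: 340, 3: 108}``."""
        counts: dict[int, int] = {}
        for tok in self.tokens:
            counts[len(tok)] = counts.get(len(tok), 0) + 1
        return counts


@dataclass(frozen=True)
class ScreenConfig:
    """How candidate 2/3-mers are admitted into the protein vocabulary.

    ``min_per_sequence_count`` is the occurrence threshold; by default a
    candidate is kept if *any single* corpus sequence contains at least
    that many (overlapping) occurrences. Setting ``corpus_total=True``
    instead sums occurrences over the whole corpus before comparing.
    """

    min_per_sequence_count: int = 7
    count_overlapping: bool = True
    corpus_total: bool = False

    def __post_init__(self) -> None:
        if self.min_per_sequence_count < 1:
            raise ValueError("min_per_sequence_count must be >= 1")


def _validate_protein_sequence(seq: str, where: str) -> None:
    for ch in seq:
        if ch not in PROTEIN_ALPHABET:
            raise VocabularyError(
                f"sequence {where} contains invalid character {ch!r}; only uppercase A-Z allowed"
            )


def enumerate_kmers(alphabet: Iterable[str], max_order: int) -> list[str]:
    """All strings of length 1..max_order over ``alphabet``.

    Ordered by length, then lexicographically; over A-Z with
    ``max_order=3`` this yields 26 + 676 + 17576 = 18728 candidates.
    """
    letters = sorted(set(alphabet))
    if not letters:
        raise ValueError("alphabet must be non-empty")
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    out: list[str] = []
    for order in range(1, max_order + 1):
        out.extend("".join(p) for p in itertools.product(letters, repeat=order))
    return out


def _count_occurrences(seq: str, orders: set[int], overlapping: bool) -> dict[str, int]:
    """Occurrence counts of every k-mer of the given orders in ``seq``."""
    counts: dict[str, int] = {}
    if overlapping:
        for k in orders:
            for i in range(len(seq) - k + 1):
                sub = seq[i : i + k]
                counts[sub] = counts.get(sub, 0) + 1
    else:
        # non-overlapping greedy count per k-mer (str.count semantics)
        seen: set[str] = set()
        for k in orders:
            for i in range(len(seq) - k + 1):
                seen.add(seq[i : i + k])
        for sub in seen:
            counts[sub] = seq.count(sub)
    return counts


def screen_valuable(
    corpus: Sequence[str],
    candidates: Sequence[str],
    cfg: ScreenConfig = ScreenConfig(),
) -> list[str]:
    """Subset of ``candidates`` frequent enough in the corpus.

    A candidate passes when at least one corpus sequence contains
    ``cfg.min_per_sequence_count`` or more occurrences of it (or, with
    ``corpus_total``, when the corpus-wide total reaches the threshold).
    Output preserves candidate order.
    """
    orders = {len(c) for c in candidates}
    best: dict[str, int] = {}
    for i, seq in enumerate(corpus):
        _validate_protein_sequence(seq, where=f"#{i}")
        counts = _count_occurrences(seq, orders, cfg.count_overlapping)
        if cfg.corpus_total:
            for sub, n in counts.items():
                best[sub] = best.get(sub, 0) + n
        else:
            for sub, n in counts.items():
                if n > best.get(sub, 0):
                    best[sub] = n
    thr = cfg.min_per_sequence_count
    return [c for c in candidates if best.get(c, 0) >= thr]


def build_protein_vocab(
    corpus: Sequence[str], cfg: ScreenConfig = ScreenConfig()
) -> Vocabulary:
    """Frequency-screened 1-3-mer protein vocabulary.

    All 26 single letters are included unconditionally (the residual of
    any segmentation must be expressible); 2-mers and 3-mers must pass
    ``screen_valuable``. On a large heterogeneous protein corpus with the
    default threshold of 7 this produces a dictionary of a few hundred
    tokens.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    candidates = enumerate_kmers(PROTEIN_ALPHABET, 3)
    two_three = [c for c in candidates if len(c) >= 2]
    kept = screen_valuable(corpus, two_three, cfg)
    tokens = list(PROTEIN_ALPHABET) + kept
    return Vocabulary(tokens=tuple(tokens), kind=KIND_PROTEIN)


def build_drug_vocab(smiles_corpus: Sequence[str]) -> Vocabulary:
    """Character vocabulary of the distinct symbols in a SMILES corpus.

    Characters are taken verbatim (case-sensitive — aromatic lowercase
    atoms count separately) and sorted by Unicode code point so the
    result is independent of corpus ordering.
    """
    if not smiles_corpus:
        raise ValueError("smiles_corpus must be non-empty")
    chars = sorted({ch for s in smiles_corpus for ch in s})
    if not chars:
        raise ValueError("smiles_corpus contains only empty strings")
    return Vocabulary(tokens=tuple(chars), kind=KIND_DRUG)


def save_vocabulary(vocab: Vocabulary, path: str | Path) -> None:
    """Serialize to JSON ``{"kind": ..., "tokens": [...]}`` (indices implied)."""
    payload = {"kind": vocab.kind, "tokens": list(vocab.tokens)}
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def load_vocabulary(path: str | Path) -> Vocabulary:
    """Load a vocabulary saved by :func:`save_vocabulary`.

    Round-trips exactly, including index assignment. An optional
    ``"indices"`` field, if present, must equal the implied 1..n
    assignment (0 is reserved for padding).
    """
    text = Path(path).read_text()
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise VocabularyError(f"malformed vocabulary file {path} at line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(payload, dict) or "kind" not in payload or "tokens" not in payload:
        raise VocabularyError(f"vocabulary file {path} must contain 'kind' and 'tokens'")
    tokens = payload["tokens"]
    if "indices" in payload:
        expected = list(range(1, len(tokens) + 1))
        if payload["indices"] != expected:
            raise VocabularyError(
                f"vocabulary file {path}: indices must be contiguous 1..{len(tokens)} (0 is reserved for padding)"
            )
    return Vocabulary(tokens=tuple(tokens), kind=payload["kind"])
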