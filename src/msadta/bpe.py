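"""Byte-pair-encoding segmentation of SMILES and protein sequences.

Chemical strings carry multi-character units — two-letter atoms (``Cl``,
``Br``), stereocentres (``[C@@H]``), repeated chains (``CCCC``) — that a
character-level dictionary cannot represent as single symbols.  BPE learns a
*multi-granularity* vocabulary from an unlabelled corpus: starting from single
characters, it repeatedly merges the most frequent adjacent token pair until a
threshold ``T`` of merge operations is reached.  A sequence segmented with the
learned merge table mixes granularities, from lone atoms up to whole
functional groups, and is then mapped to a padded integer vector for the
downstream model.

Unlike NLP applications there is no word structure: each corpus line is one
unbroken token stream, and merges may span any adjacent positions within a
sequence but never across sequences.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

PAD_ID = 0

__all__ = [
    "MergeTable",
    "Vocabulary",
    "EncodedSequence",
    "train_bpe",
    "segment",
    "build_vocabulary",
    "encode",
    "read_corpus",
    "PAD_ID",
]


@dataclass(frozen=True)
class MergeTable:
    """An ordered list of learned merge rules; the trained segmenter.

    Attributes
    ----------
    merges:
        ``(left, right)`` token-string pairs in the order they were learned.
        Replaying them in order on any string is deterministic.
    alphabet:
        Single-character tokens seen during training.
    threshold_T:
        The requested number of merge operations; ``len(merges)`` may be
        smaller when training stopped early.
    """

    merges: tuple[tuple[str, str], ...]
    alphabet: frozenset[str]
    threshold_T: int

    def __post_init__(self) -> None:
        if self.threshold_T < 0:
            raise ValueError("threshold_T must be non-negative")
        if len(self.merges) > self.threshold_T:
            raise ValueError("more merges than threshold_T allows")

    @property
    def merged_tokens(self) -> tuple[str, ...]:
        return tuple(left + right for left, right in self.merges)


@dataclass(frozen=True)
class Vocabulary:
    """Token-string -> positive-integer dictionary with reserved ids.

    Id 0 is the padding symbol and is never assigned to a token; unknown
    tokens at encode time map to ``unk_id`` (largest token id + 1).
    """

    token_to_id: dict[str, int]
    threshold_T: int = 0
    alphabet: frozenset[str] = field(default_factory=frozenset)
    merges: tuple[tuple[str, str], ...] = ()

    @property
    def size(self) -> int:
        return len(self.token_to_id)

    @property
    def pad_id(self) -> int:
        return PAD_ID

    @property
    def unk_id(self) -> int:
        return self.size + 1

    @property
    def n_ids(self) -> int:
        """Total id range (pad + tokens + unk); embedding tables need this."""
        return self.size + 2

    def save(self, path: str | Path) -> None:
        payload = {
            "threshold_T": self.threshold_T,
            "alphabet": sorted(self.alphabet),
            "merges": [list(pair) for pair in self.merges],
            "token_to_id": self.token_to_id,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        payload = json.loads(Path(path).read_text())
        return cls(
            token_to_id=dict(payload["token_to_id"]),
            threshold_T=int(payload["threshold_T"]),
            alphabet=frozenset(payload["alphabet"]),
            merges=tuple((a, b) for a, b in payload["merges"]),
        )

    @classmethod
    def from_json_str(cls, text: str) -> "Vocabulary":
        payload = json.loads(text)
        return cls(
            token_to_id=dict(payload["token_to_id"]),
            threshold_T=int(payload["threshold_T"]),
            alphabet=frozenset(payload["alphabet"]),
            merges=tuple((a, b) for a, b in payload["merges"]),
        )

    def to_json_str(self) -> str:
        return json.dumps(
            {
                "threshold_T": self.threshold_T,
                "alphabet": sorted(self.alphabet),
                "merges": [list(pair) for pair in self.merges],
                "token_to_id": self.token_to_id,
            },
            sort_keys=True,
        )

    @property
    def merge_table(self) -> MergeTable:
        return MergeTable(self.merges, self.alphabet, self.threshold_T)


@dataclass(frozen=True)
class EncodedSequence:
    """Fixed-length, zero-padded integer encoding of one drug or protein."""

    ids: np.ndarray
    true_length: int

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=np.int64)
        object.__setattr__(self, "ids", ids)
        if self.true_length > ids.shape[0]:
            raise ValueError("true_length exceeds padded length")
        if np.any(ids[self.true_length :] != PAD_ID):
            raise ValueError("padding positions must be 0")


def _pair_counts(token_seqs: Iterable[list[str]]) -> Counter:
    counts: Counter = Counter()
    for toks in token_seqs:
        for left, right in zip(toks, toks[1:]):
            counts[(left, right)] += 1
    return counts


def _merge_sequence(toks: list[str], pair: tuple[str, str]) -> list[str]:
    # left-to-right, non-overlapping replacement of the pair
    out: list[str] = []
    i = 0
    n = len(toks)
    merged = pair[0] + pair[1]
    while i < n:
        if i + 1 < n and toks[i] == pair[0] and toks[i + 1] == pair[1]:
            out.append(merged)
            i += 2
        else:
            out.append(toks[i])
            i += 1
    return out


def train_bpe(corpus: Sequence[str], threshold_T: int) -> MergeTable:
    """Learn up to ``threshold_T`` merge rules from a corpus.

    Each iteration counts adjacent token pairs over the whole corpus and
    merges the most frequent one into a new token.  Ties are broken by the
    lexicographically smallest ``(left, right)`` pair so training is
    deterministic.  Training stops early once the best pair occurs fewer
    than twice (merging a frequency-1 pair compresses nothing).

    Parameters
    ----------
    corpus:
        Non-empty sequences; each is one unbroken token stream.
    threshold_T:
        Maximum number of merge operations (and hence of new vocabulary
        entries beyond the character alphabet).
    """
    corpus = [s for s in corpus]
    if len(corpus) == 0:
        raise ValueError("corpus must be non-empty")
    if threshold_T < 0:
        raise ValueError("threshold_T must be non-negative")
    if any(len(s) == 0 for s in corpus):
        raise ValueError("corpus sequences must be non-empty strings")

    alphabet = frozenset(ch for s in corpus for ch in s)
    token_seqs = [list(s) for s in corpus]
    merges: list[tuple[str, str]] = []
    for _ in range(threshold_T):
        counts = _pair_counts(token_seqs)
        if not counts:
            break
        best_count = max(counts.values())
        if best_count < 2:
            break
        best = min(p for p, c in counts.items() if c == best_count)
        merges.append(best)
        token_seqs = [_merge_sequence(t, best) for t in token_seqs]
    return MergeTable(tuple(merges), alphabet, threshold_T)


def segment(sequence: str, merges: MergeTable | Vocabulary) -> list[str]:
    """Split a string into multi-granularity tokens by replaying merges.

    The string is exploded into characters and every learned merge is applied
    greedily, in learned order.  Characters outside the training alphabet
    pass through as single-character tokens, and concatenating the output
    always reproduces the input exactly.
    """
    if len(sequence) == 0:
        raise ValueError("sequence must be non-empty")
    if isinstance(merges, Vocabulary):
        merges = merges.merge_table
    toks = list(sequence)
    for pair in merges.merges:
        if len(toks) < 2:
            break
        toks = _merge_sequence(toks, pair)
    return toks


def build_vocabulary(merges: MergeTable) -> Vocabulary:
    """Assign ids: sorted alphabet first, then merged tokens in merge order.

    Ids start at 1; 0 is reserved for padding.  Vocabulary size is
    ``|alphabet| + len(merges)`` (merged-token strings are unique within one
    training run in practice; a duplicate would keep its first id).
    """
    token_to_id: dict[str, int] = {}
    next_id = 1
    for ch in sorted(merges.alphabet):
        token_to_id[ch] = next_id
        next_id += 1
    for tok in merges.merged_tokens:
        if tok not in token_to_id:
            token_to_id[tok] = next_id
            next_id += 1
    return Vocabulary(
        token_to_id=token_to_id,
        threshold_T=merges.threshold_T,
        alphabet=merges.alphabet,
        merges=merges.merges,
    )


def encode(tokens: Sequence[str], vocab: Vocabulary, l: int) -> EncodedSequence:
    """Map tokens to a fixed-length id vector, truncating or zero-padding.

    The first ``min(len(tokens), l)`` slots hold token ids (unknown tokens
    map to ``vocab.unk_id``); the remainder is 0.  Over-length inputs are
    truncated on the right.
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    ids = np.zeros(l, dtype=np.int64)
    kept = min(len(tokens), l)
    for i in range(kept):
        ids[i] = vocab.token_to_id.get(tokens[i], vocab.unk_id)
    return EncodedSequence(ids=ids, true_length=kept)


def encode_string(sequence: str, vocab: Vocabulary, l: int) -> EncodedSequence:
    """Segment then encode in one step."""
    return encode(segment(sequence, vocab.merge_table), vocab, l)


def read_corpus(path: str | Path, fasta: bool | None = None) -> list[str]:
    """Read a segmentation corpus: plain text (one sequence per line) or FASTA.

    ``fasta=None`` autodetects from a leading ``>`` or a ``.fa``/``.fasta``
    suffix; FASTA headers are ignored.
    """
    path = Path(path)
    text = path.read_text()
    if fasta is None:
        fasta = path.suffix.lower() in {".fa", ".fasta", ".faa"} or text.lstrip().startswith(">")
    if fasta:
        from Bio import SeqIO

        return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    return [line.strip() for line in text.splitlines() if line.strip()]


def iter_token_ids(
    sequences: Iterable[str], vocab: Vocabulary, l: int
) -> Iterator[EncodedSequence]:
    for s in sequences:
        yield encode_string(s, vocab, l)
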