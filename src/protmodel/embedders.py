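"""Lightweight sequence embedders: fixed-length one-hot, MSA-aligned one-hot
with align-to-profile for new sequences, and k-mer counts.

All three are desk-scale, dependency-free featurizers that plug into any
downstream tabular learner. Channel layouts share the fixed canonical
residue ordering; per-column layouts place the gap channel last.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .align import align_to_profile
from .alphabet import AA_INDEX, CANONICAL, GAP, GAP_INDEX, UNKNOWN
from .exceptions import FixedLengthError, SequenceValidationError
from .model_core import (
    ProteinModel,
    RequiresMSAForFitMixin,
    embedding_frame,
)
from .profile import fit_column_profile
from .seqio import ProteinSequence, ProteinSequenceSet, ungap

logger = logging.getLogger("protmodel")

__all__ = [
    "OneHotEmbedding",
    "AlignedOneHotEmbedding",
    "KMerEmbedding",
    "decode_onehot",
    "kmer_columns",
]

N_AA = len(CANONICAL)  # 20


class OneHotEmbedding(ProteinModel):
    """Binary indicators over the 20 canonical residues, fixed length L.

    Embedding dimension is 20·L with channel ``pos{p}_{aa}`` set to 1 when
    position p (1-based) holds residue aa. ``X`` produces an all-zero block
    at its position; for X-free sequences the encoding is exactly invertible
    (see :func:`decode_onehot`). Requires every sequence — at fit and at
    transform — to share one gap-free length.
    """

    category = "embedding"
    _requires_fixed_length = True

    def _fit(self, bundle) -> None:
        seqs = bundle.sequences
        if not seqs.uniform_length:
            raise FixedLengthError(
                "one-hot embedding requires fixed-length sequences; "
                f"got lengths {sorted({len(s) for s in seqs})}"
            )
        if seqs.has_gaps:
            raise SequenceValidationError(
                "one-hot embedding requires gap-free sequences; "
                "use the aligned one-hot embedder for gapped input"
            )
        self.length_ = len(seqs[0])
        self.columns_ = [
            f"pos{p}_{aa}"
            for p in range(1, self.length_ + 1)
            for aa in CANONICAL
        ]

    def _transform(self, seqs: ProteinSequenceSet) -> pd.DataFrame:
        values = np.zeros((len(seqs), N_AA * self.length_))
        for r, seq in enumerate(seqs):
            if len(seq) != self.length_:
                raise FixedLengthError(
                    f"{seq.id}: length {len(seq)} != fitted length {self.length_}"
                )
            if seq.has_gaps:
                raise SequenceValidationError(
                    f"{seq.id}: gapped sequence; use the aligned one-hot embedder"
                )
            for p, ch in enumerate(seq.residues):
                if ch == UNKNOWN:
                    continue  # all-zero block
                values[r, N_AA * p + AA_INDEX[ch]] = 1.0
        return embedding_frame(values, seqs.ids, self.columns_)


def decode_onehot(frame: pd.DataFrame) -> ProteinSequenceSet:
    """Invert :class:`OneHotEmbedding` output; all-zero blocks decode to 'X'."""
    values = frame.to_numpy()
    n, dim = values.shape
    if dim % N_AA:
        raise ValueError(f"dimension {dim} is not a multiple of {N_AA}")
    length = dim // N_AA
    blocks = values.reshape(n, length, N_AA)
    out = []
    for r in range(n):
        chars = []
        for p in range(length):
            block = blocks[r, p]
            chars.append(UNKNOWN if block.sum() == 0 else CANONICAL[int(block.argmax())])
        out.append(ProteinSequence(str(frame.index[r]), "".join(chars)))
    return ProteinSequenceSet(out)


class AlignedOneHotEmbedding(RequiresMSAForFitMixin, ProteinModel):
    """Per-column indicators over an MSA: 20 residues plus a gap channel.

    Fitting stores the alignment width W and a column frequency profile
    (pseudocount ``alpha``); embedding dimension is 21·W. A sequence that is
    already W wide and gapped is encoded directly; anything else is first
    aligned to the profile, so new unaligned homologs can be embedded in
    the training coordinate system.
    """

    category = "embedding"

    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def _fit(self, bundle) -> None:
        self.profile_ = fit_column_profile(bundle.alignment, alpha=self.alpha)
        self.width_ = self.profile_.width
        self.columns_ = [
            f"col{j}_{'gap' if a == GAP_INDEX else CANONICAL[a]}"
            for j in range(1, self.width_ + 1)
            for a in range(N_AA + 1)
        ]

    def _encode_gapped(self, gapped: str, row: np.ndarray) -> None:
        for j, ch in enumerate(gapped):
            if ch == UNKNOWN:
                continue
            idx = GAP_INDEX if ch == GAP else AA_INDEX[ch]
            row[(N_AA + 1) * j + idx] = 1.0

    def _transform(self, seqs: ProteinSequenceSet) -> pd.DataFrame:
        values = np.zeros((len(seqs), (N_AA + 1) * self.width_))
        for r, seq in enumerate(seqs):
            if len(seq) == self.width_ and seq.has_gaps:
                gapped = seq.residues
            else:
                query = ungap(seq)[0] if seq.has_gaps else seq
                gapped = align_to_profile(query, self.profile_).gapped
            self._encode_gapped(gapped, values[r])
        return embedding_frame(values, seqs.ids, self.columns_)


def kmer_columns(k: int) -> list[str]:
    """The 20^k k-mer channel names in lexicographic canonical order."""
    return [
        "kmer_" + "".join(mer)
        for mer in itertools.product(sorted(CANONICAL), repeat=k)
    ]


class KMerEmbedding(ProteinModel):
    """Counts of length-k substrings over the canonical alphabet.

    Columns are the 20^k k-mers in lexicographic order; k is capped at 3
    (8000 dense channels) to stay desk-scale. Windows containing ``X`` are
    skipped. With ``normalize=True`` counts become frequencies over the
    counted windows. Works on variable-length, gap-free sequences; fit
    learns nothing but is still required by the lifecycle contract.
    """

    category = "embedding"

    def __init__(self, k: int = 2, normalize: bool = False):
        self.k = k
        self.normalize = normalize

    def _validate_k(self) -> None:
        if not isinstance(self.k, int) or not (1 <= self.k <= 3):
            raise ValueError(f"k must be an integer in [1, 3], got {self.k!r}")

    def _fit(self, bundle) -> None:
        self._validate_k()
        self.columns_ = kmer_columns(self.k)
        self.column_index_ = {c: i for i, c in enumerate(self.columns_)}

    def _transform(self, seqs: ProteinSequenceSet) -> pd.DataFrame:
        k = self.k
        values = np.zeros((len(seqs), len(self.columns_)))
        for r, seq in enumerate(seqs):
            if seq.has_gaps:
                raise SequenceValidationError(
                    f"{seq.id}: k-mer counting requires gap-free sequences"
                )
            if len(seq) < k:
                logger.warning(
                    "[SHORT_SEQUENCE] %r shorter than k=%d; all-zero row",
                    seq.id,
                    k,
                )
                continue
            counted = 0
            for i in range(len(seq) - k + 1):
                window = seq.residues[i : i + k]
                if UNKNOWN in window:
                    continue
                values[r, self.column_index_["kmer_" + window]] += 1.0
                counted += 1
            if self.normalize and counted:
                values[r] /= counted
        return embedding_frame(values, seqs.ids, self.columns_)
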