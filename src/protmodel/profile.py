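"""Per-column symbol frequency profiles over an MSA (independent-sites model).

A :class:`ColumnProfile` holds, for each alignment column j, a frequency
distribution f_j over the 21-symbol alphabet (20 canonical residues, gap
last). Fitting applies additive (pseudocount) smoothing:

    f_j(a) = (c_j(a) + alpha) / (n_j + 21 * alpha)

where c_j(a) counts symbol a in column j (gap included, 'X' excluded) and
n_j is the family depth minus the 'X' occurrences in that column. The
sequence likelihood under the model is the product of column frequencies —
no insert/delete states, no pair couplings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA_GAP_INDEX, ALPHABET_WITH_GAP, UNKNOWN
from .seqio import AlignedFamily

__all__ = ["ColumnProfile", "fit_column_profile"]

N_SYMBOLS = len(ALPHABET_WITH_GAP)  # 21


@dataclass(frozen=True)
class ColumnProfile:
    """W x 21 column frequency matrix with pseudocount metadata.

    ``frequencies[j, a]`` is f_j(a) with symbol order ``ACDEFGHIKLMNPQRSTVWY-``
    (gap last). Every row sums to 1. ``counts_per_column`` is the effective
    count n_j used at fit time (None for profiles constructed analytically,
    e.g. by the synthetic generator).
    """

    frequencies: np.ndarray
    pseudocount: float = 0.0
    counts_per_column: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        freq = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", freq)
        if freq.ndim != 2 or freq.shape[1] != N_SYMBOLS:
            raise ValueError(
                f"frequencies must be W x {N_SYMBOLS}, got shape {freq.shape}"
            )
        if np.any(freq < 0):
            raise ValueError("negative frequency")
        rows = freq.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-12, rtol=0.0):
            worst = int(np.argmax(np.abs(rows - 1.0)))
            raise ValueError(
                f"column {worst} frequencies sum to {rows[worst]!r}, expected 1"
            )
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    @property
    def width(self) -> int:
        return self.frequencies.shape[0]

    def frequency(self, column: int, symbol: str) -> float:
        """f_j(symbol) for a symbol in the 21-letter alphabet."""
        return float(self.frequencies[column, AA_GAP_INDEX[symbol]])

    def consensus(self) -> str:
        """Most frequent canonical residue per column (gap never emitted;
        canonical-order tie-break)."""
        canon = self.frequencies[:, : N_SYMBOLS - 1]
        idx = np.argmax(canon, axis=1)
        return "".join(ALPHABET_WITH_GAP[i] for i in idx)


def fit_column_profile(family: AlignedFamily, alpha: float = 1.0) -> ColumnProfile:
    """Estimate column frequencies from an alignment with pseudocount ``alpha``.

    'X' symbols contribute to no count and shrink that column's effective
    depth n_j. With ``alpha`` = 0 an all-'X' column is undefined and raises.
    """
    if alpha < 0:
        raise ValueError(f"pseudocount must be >= 0, got {alpha}")
    counts = np.zeros((family.width, N_SYMBOLS), dtype=float)
    n_eff = np.full(family.width, float(family.depth))
    for seq in family:
        for j, ch in enumerate(seq.residues):
            if ch == UNKNOWN:
                n_eff[j] -= 1.0
            else:
                counts[j, AA_GAP_INDEX[ch]] += 1.0
    denom = n_eff + N_SYMBOLS * alpha
    if np.any(denom <= 0):
        bad = int(np.argmin(denom))
        raise ValueError(
            f"column {bad} has no observations and alpha=0; use alpha > 0"
        )
    freq = (counts + alpha) / denom[:, None]
    return ColumnProfile(
        frequencies=freq, pseudocount=alpha, counts_per_column=n_eff
    )
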