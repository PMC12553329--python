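"""Synthetic alignment families and labeled variant sets from known profiles.

Every generator starts from a ground-truth :class:`ColumnProfile`, so the
quantities other modules estimate (column frequencies, variant
log-likelihood deltas) have exact known values — the package is fully
testable, including parameter recovery, without downloading anything.

Columns are drawn independently: per column, canonical residue frequencies
come from a symmetric Dirichlet and a fixed probability mass is reserved
for the gap symbol. A concentration below 1 gives peaked, conserved-looking
columns, which is what makes rank tests on variant scores sharp. What this
emulates — and what it does not (phylogenetic correlation between rows,
pairwise epistasis between columns, indel structure) — is discussed in the
methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import CANONICAL
from .profile import ColumnProfile, N_SYMBOLS
from .seqio import (
    AlignedFamily,
    MutationSpec,
    ProteinSequence,
    ProteinSequenceSet,
)
from .zeroshot import variant_delta_scores

__all__ = [
    "SyntheticFamilySpec",
    "make_profile",
    "sample_family",
    "consensus_wt",
    "labeled_variants",
]

#: documented fixture seed used throughout the test suite
DEFAULT_SEED = 42

_SYMBOLS = np.array(list(CANONICAL + "-"))


@dataclass(frozen=True)
class SyntheticFamilySpec:
    """Ground-truth family parameters.

    width
        number of alignment columns W
    depth
        default number of sequences to sample
    concentration
        symmetric Dirichlet parameter per column; 0.5 yields realistically
        conserved (peaked) columns
    gap_rate
        probability mass assigned to the gap symbol in every column
    seed
        RNG seed; identical seeds give identical profiles and families
    """

    width: int = 30
    depth: int = 200
    concentration: float = 0.5
    gap_rate: float = 0.1
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.width < 1 or self.depth < 1:
            raise ValueError("width and depth must be >= 1")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if not (0 <= self.gap_rate < 1):
            raise ValueError("gap_rate must be in [0, 1)")


def make_profile(spec: SyntheticFamilySpec) -> ColumnProfile:
    """Draw a ground-truth column profile from the spec's Dirichlet prior.

    Canonical frequencies are Dirichlet(concentration) scaled by
    (1 - gap_rate); the gap frequency equals gap_rate in every column.
    """
    rng = np.random.default_rng(spec.seed)
    freq = np.zeros((spec.width, N_SYMBOLS))
    canon = rng.dirichlet(
        np.full(len(CANONICAL), spec.concentration), size=spec.width
    )
    freq[:, : len(CANONICAL)] = canon * (1.0 - spec.gap_rate)
    freq[:, -1] = spec.gap_rate
    freq /= freq.sum(axis=1, keepdims=True)  # remove float residue
    return ColumnProfile(frequencies=freq, pseudocount=0.0)


def sample_family(
    profile: ColumnProfile, n: int, seed: int = DEFAULT_SEED, id_prefix: str = "syn"
) -> AlignedFamily:
    """Sample ``n`` aligned sequences, every column independent."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    W = profile.width
    chars = np.empty((n, W), dtype="U1")
    for j in range(W):
        chars[:, j] = rng.choice(_SYMBOLS, size=n, p=profile.frequencies[j])
    members = ProteinSequenceSet(
        ProteinSequence(f"{id_prefix}{i}", "".join(chars[i])) for i in range(n)
    )
    return AlignedFamily(members=members, width=W)


def consensus_wt(profile: ColumnProfile, id: str = "wt") -> ProteinSequence:
    """Gap-free wild type: the most frequent canonical residue per column."""
    return ProteinSequence(id, profile.consensus())


def labeled_variants(
    profile: ColumnProfile,
    wt: ProteinSequence,
    m: int,
    noise_sd: float = 0.0,
    seed: int = DEFAULT_SEED,
) -> tuple[list[list[MutationSpec]], np.ndarray]:
    """Random single/double substitutions with ground-truth labels.

    Each of the ``m`` variants mutates one or two distinct positions
    (equal odds) of a wild type that spans the profile (length W, identity
    column mapping). The label is the true mutant-minus-wild-type
    log-likelihood under the generating profile plus Gaussian noise of
    standard deviation ``noise_sd``; at ``noise_sd=0`` labels equal the
    scorer's delta scores exactly, by construction.
    """
    if len(wt) != profile.width:
        raise ValueError("wild type length must equal profile width")
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    variants: list[list[MutationSpec]] = []
    aa = list(CANONICAL)
    for _ in range(m):
        k = int(rng.integers(1, 3))  # 1 or 2 sites
        positions = sorted(rng.choice(len(wt), size=k, replace=False) + 1)
        muts = []
        for pos in positions:
            wt_aa = wt.residues[pos - 1]
            choices = [a for a in aa if a != wt_aa]
            mut_aa = choices[int(rng.integers(len(choices)))]
            muts.append(MutationSpec(position=int(pos), wt_aa=wt_aa, mut_aa=mut_aa))
        variants.append(muts)
    mapping = list(range(profile.width))
    scores = variant_delta_scores(profile, wt, variants, mapping=mapping)
    labels = np.array([s.score for s in scores])
    if noise_sd > 0:
        labels = labels + rng.normal(0.0, noise_sd, size=m)
    return variants, labels
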