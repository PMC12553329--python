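"""Dependency-light alignment routines.

Two jobs only, both deterministic:

* :func:`center_star_align` — progressive multiple alignment used when a
  model that needs an MSA receives unaligned sequences ("attempt to align"
  semantics, not a replacement for a real aligner).
* :func:`align_to_profile` — global dynamic programming of a gap-free query
  against a fitted :class:`~protmodel.profile.ColumnProfile`, used by the
  aligned one-hot embedder and for mapping a wild type onto profile columns.

Pairwise scoring for center-star: match +1, mismatch 0, linear gap -1.
Profile match scoring is the log-odds of the column frequency against a
uniform background: ln(f_j(a) + eps) - ln(1/20); deletions (gap emitted in
a column) and insertions (query residue consumed without a column) each pay
a fixed penalty. Ties in every traceback are broken the same way
(match, then deletion/gap-in-second, then insertion) so results are
reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .alphabet import AA_GAP_INDEX, GAP, UNKNOWN
from .profile import ColumnProfile
from .seqio import AlignedFamily, ProteinSequence, ProteinSequenceSet

logger = logging.getLogger("protmodel")

__all__ = [
    "pairwise_align",
    "center_star_align",
    "ProfileAlignment",
    "align_to_profile",
]

MATCH_SCORE = 1.0
MISMATCH_SCORE = 0.0
GAP_SCORE = -1.0

# profile-alignment defaults (documented hyperparameters)
PROFILE_EPS = 1e-9
DELETION_PENALTY = -1.5
INSERTION_PENALTY = -1.5
_UNIFORM_BG = 1.0 / 20.0

_DIAG, _UP, _LEFT = 0, 1, 2


def pairwise_align(a: str, b: str) -> tuple[str, str, float]:
    """Global alignment of two residue strings.

    Returns the two gapped strings and the alignment score. Traceback ties
    prefer match/mismatch, then a gap in the second sequence, then a gap in
    the first, making the result deterministic.
    """
    la, lb = len(a), len(b)
    score = np.zeros((la + 1, lb + 1))
    move = np.zeros((la + 1, lb + 1), dtype=np.int8)
    score[:, 0] = GAP_SCORE * np.arange(la + 1)
    score[0, :] = GAP_SCORE * np.arange(lb + 1)
    move[1:, 0] = _UP
    move[0, 1:] = _LEFT
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            m = MATCH_SCORE if a[i - 1] == b[j - 1] else MISMATCH_SCORE
            diag = score[i - 1, j - 1] + m
            up = score[i - 1, j] + GAP_SCORE  # gap in b (second sequence)
            left = score[i, j - 1] + GAP_SCORE  # gap in a
            best = max(diag, up, left)
            score[i, j] = best
            if diag == best:
                move[i, j] = _DIAG
            elif up == best:
                move[i, j] = _UP
            else:
                move[i, j] = _LEFT
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = la, lb
    while i > 0 or j > 0:
        mv = move[i, j]
        if mv == _DIAG:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif mv == _UP:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score[la, lb])


def _merge_into_master(
    master: str, rows: list[str], c_aln: str, s_aln: str
) -> tuple[str, list[str], str]:
    """Merge a (center, other) pairwise alignment into the growing MSA.

    ``master`` is the center with all gaps accumulated so far; ``rows`` are
    previously merged sequences at master width. Once a gap, always a gap:
    gaps already in the master are never removed, new gaps from ``c_aln``
    are inserted everywhere.
    """
    new_master: list[str] = []
    new_rows: list[list[str]] = [[] for _ in rows]
    new_row: list[str] = []
    i = k = 0
    while i < len(master) or k < len(c_aln):
        mi = master[i] if i < len(master) else None
        ck = c_aln[k] if k < len(c_aln) else None
        if mi is not None and ck is not None and (mi != GAP) == (ck != GAP):
            # same center state on both sides (residue/residue or gap/gap)
            new_master.append(mi)
            for r, row in enumerate(rows):
                new_rows[r].append(row[i])
            new_row.append(s_aln[k])
            i += 1
            k += 1
        elif mi == GAP:
            # master has an insertion the new pair lacks
            new_master.append(GAP)
            for r, row in enumerate(rows):
                new_rows[r].append(row[i])
            new_row.append(GAP)
            i += 1
        else:
            # new pair introduces an insertion: gap everything already merged
            new_master.append(GAP)
            for r in range(len(rows)):
                new_rows[r].append(GAP)
            new_row.append(s_aln[k])
            k += 1
    return (
        "".join(new_master),
        ["".join(r) for r in new_rows],
        "".join(new_row),
    )


def center_star_align(sequences: ProteinSequenceSet) -> AlignedFamily:
    """Center-star progressive multiple alignment.

    The center is the sequence minimizing summed pairwise distance
    (equivalently, maximizing summed pairwise score; lowest index breaks
    ties); every other sequence is pairwise-aligned to it and the pairwise
    alignments are merged under "once a gap, always a gap". Input order is
    preserved in the result.
    """
    n = len(sequences)
    if n < 2:
        raise ValueError("center-star alignment requires at least 2 sequences")
    strings = [s.residues for s in sequences]
    if any(GAP in s for s in strings):
        raise ValueError("center-star input must be gap-free (ungap first)")
    total = np.zeros(n)
    pair_score = {}
    for i in range(n):
        for j in range(i + 1, n):
            _, _, sc = pairwise_align(strings[i], strings[j])
            pair_score[(i, j)] = sc
            total[i] += sc
            total[j] += sc
    center = int(np.argmax(total))  # max summed score == min summed distance

    master = strings[center]
    merged_rows: list[str] = []
    merged_idx: list[int] = []
    for j in range(n):
        if j == center:
            continue
        c_aln, s_aln, _ = pairwise_align(strings[center], strings[j])
        master, merged_rows, new_row = _merge_into_master(
            master, merged_rows, c_aln, s_aln
        )
        merged_rows.append(new_row)
        merged_idx.append(j)

    width = len(master)
    out: list[str | None] = [None] * n
    out[center] = master
    for idx, row in zip(merged_idx, merged_rows):
        out[idx] = row
    members = ProteinSequenceSet(
        seq.with_residues(aligned)
        for seq, aligned in zip(sequences, out)
    )
    return AlignedFamily(members=members, width=width)


@dataclass(frozen=True)
class ProfileAlignment:
    """Result of aligning a query to a profile.

    ``gapped`` always has length W (one character per profile column, gap
    where a deletion was placed). ``query_columns[i]`` is the 0-based column
    holding query residue i, or None when the residue was consumed as an
    insertion. ``score`` is the DP objective of the returned alignment.
    """

    gapped: str
    query_columns: list[int | None]
    score: float


def profile_match_score(profile: ColumnProfile, column: int, aa: str) -> float:
    """Log-odds of residue ``aa`` in ``column`` versus a uniform background.

    'X' scores 0 (neutral): unknown residues neither reward nor penalize a
    column assignment.
    """
    if aa == UNKNOWN:
        return 0.0
    f = profile.frequencies[column, AA_GAP_INDEX[aa]]
    return math.log(f + PROFILE_EPS) - math.log(_UNIFORM_BG)


def align_to_profile(
    seq: ProteinSequence,
    profile: ColumnProfile,
    deletion_penalty: float = DELETION_PENALTY,
    insertion_penalty: float = INSERTION_PENALTY,
) -> ProfileAlignment:
    """Globally align a gap-free query to the profile's W columns.

    Every column is either matched by one query residue or emitted as a
    gap (deletion); query residues not assigned to any column are consumed
    silently as insertions, so the output width is always W. Traceback ties
    prefer match, then deletion, then insertion.
    """
    if seq.has_gaps:
        raise ValueError(f"{seq.id}: align_to_profile requires a gap-free query")
    q = seq.residues
    if not q:
        raise ValueError("empty query")
    L, W = len(q), profile.width
    score = np.empty((L + 1, W + 1))
    move = np.empty((L + 1, W + 1), dtype=np.int8)
    score[0, 0] = 0.0
    for i in range(1, L + 1):
        score[i, 0] = i * insertion_penalty
        move[i, 0] = _UP
    for j in range(1, W + 1):
        score[0, j] = j * deletion_penalty
        move[0, j] = _LEFT
    match = np.empty((L, W))
    for i in range(L):
        for j in range(W):
            match[i, j] = profile_match_score(profile, j, q[i])
    for i in range(1, L + 1):
        for j in range(1, W + 1):
            diag = score[i - 1, j - 1] + match[i - 1, j - 1]
            left = score[i, j - 1] + deletion_penalty  # gap in column j
            up = score[i - 1, j] + insertion_penalty  # skip query residue i
            best = max(diag, left, up)
            score[i, j] = best
            if diag == best:
                move[i, j] = _DIAG
            elif left == best:
                move[i, j] = _LEFT
            else:
                move[i, j] = _UP
    gapped: list[str] = []
    cols: list[int | None] = [None] * L
    i, j = L, W
    while i > 0 or j > 0:
        mv = move[i, j]
        if mv == _DIAG:
            gapped.append(q[i - 1])
            cols[i - 1] = j - 1
            i, j = i - 1, j - 1
        elif mv == _LEFT:
            gapped.append(GAP)
            j -= 1
        else:
            i -= 1
    return ProfileAlignment(
        gapped="".join(reversed(gapped)),
        query_columns=cols,
        score=float(score[L, W]),
    )
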