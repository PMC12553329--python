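"""Protein sequence and alignment data types, FASTA/A2M I/O, mutation notation.

Sequences are validated at construction against the canonical 20-residue
alphabet plus ``X`` (unknown) and ``-`` (gap). Mutation positions are
1-based on the ungapped wild type, the universal deep-mutational-scanning
convention; multi-mutant strings join tokens with ``:`` (``"A2C:G5W"``).
"""

from __future__ import annotations

import io
import logging
import os
import re
from collections.abc import Sequence as _AbcSequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .alphabet import AA_INDEX, CANONICAL, GAP, UNKNOWN, VALID_CHARS
from .exceptions import (
    FastaFormatError,
    MutationParseError,
    SequenceValidationError,
    WildTypeMismatchError,
)

logger = logging.getLogger("protmodel")

__all__ = [
    "ProteinSequence",
    "ProteinSequenceSet",
    "AlignedFamily",
    "MutationSpec",
    "read_fasta",
    "write_fasta",
    "read_mutation_file",
    "parse_mutation_string",
    "apply_mutations",
    "diff_sequences",
    "saturation_mutagenesis",
    "ungap",
]


def _validate_residues(residues: str, where: str = "sequence") -> None:
    if not residues:
        raise SequenceValidationError(f"{where}: empty residue string")
    for offset, ch in enumerate(residues, start=1):
        if ch not in VALID_CHARS:
            raise SequenceValidationError(
                f"{where}: invalid character {ch!r} at position {offset}"
            )


@dataclass(frozen=True)
class ProteinSequence:
    """Identifier plus validated residue string, optionally tied to a structure.

    Parameters
    ----------
    id : str
        Non-empty record identifier.
    residues : str
        Uppercase string over the canonical alphabet plus ``X`` and ``-``.
    structure_ref : str or None
        Optional path/identifier of an associated structure.
    """

    id: str
    residues: str
    structure_ref: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceValidationError("sequence id must be non-empty")
        if self.residues != self.residues.upper():
            raise SequenceValidationError(
                f"{self.id}: residues must be uppercase (normalize on read)"
            )
        _validate_residues(self.residues, where=self.id)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> str:
        return self.residues[i]

    @property
    def has_gaps(self) -> bool:
        return GAP in self.residues

    @property
    def has_unknown(self) -> bool:
        return UNKNOWN in self.residues

    def with_residues(self, residues: str, id: str | None = None) -> "ProteinSequence":
        return ProteinSequence(id or self.id, residues, self.structure_ref)


class ProteinSequenceSet(_AbcSequence):
    """Ordered, deterministic collection of :class:`ProteinSequence`.

    Plays the role the ``X`` array plays in a tabular learning problem:
    models consume one of these and emit one row (or one score) per member,
    in order.
    """

    def __init__(self, sequences: Iterable[ProteinSequence]):
        self._sequences: tuple[ProteinSequence, ...] = tuple(sequences)
        for s in self._sequences:
            if not isinstance(s, ProteinSequence):
                raise TypeError(f"expected ProteinSequence, got {type(s).__name__}")

    def __len__(self) -> int:
        return len(self._sequences)

    def __getitem__(self, i):  # supports slicing
        if isinstance(i, slice):
            return ProteinSequenceSet(self._sequences[i])
        return self._sequences[i]

    def __iter__(self) -> Iterator[ProteinSequence]:
        return iter(self._sequences)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ProteinSequenceSet)
            and self._sequences == other._sequences
        )

    def __repr__(self) -> str:
        return f"ProteinSequenceSet(n={len(self)})"

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self._sequences]

    @property
    def residue_strings(self) -> list[str]:
        return [s.residues for s in self._sequences]

    @property
    def uniform_length(self) -> bool:
        """True iff all members share one length (vacuously true when empty)."""
        lengths = {len(s) for s in self._sequences}
        return len(lengths) <= 1

    @property
    def has_gaps(self) -> bool:
        return any(s.has_gaps for s in self._sequences)

    @classmethod
    def from_strings(
        cls, residues: Iterable[str], ids: Iterable[str] | None = None
    ) -> "ProteinSequenceSet":
        residues = list(residues)
        if ids is None:
            ids = [f"seq{i}" for i in range(len(residues))]
        return cls(ProteinSequence(i, r) for i, r in zip(ids, residues, strict=True))


@dataclass(frozen=True)
class AlignedFamily:
    """A multiple sequence alignment: equal-width gapped sequences.

    ``width`` is the number of alignment columns; every member's residue
    string has exactly that length.
    """

    members: ProteinSequenceSet
    width: int = field(default=0)

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError("AlignedFamily requires at least one member")
        widths = {len(s) for s in self.members}
        if len(widths) != 1:
            raise ValueError(f"members have unequal lengths: {sorted(widths)}")
        actual = widths.pop()
        if self.width == 0:
            object.__setattr__(self, "width", actual)
        elif self.width != actual:
            raise ValueError(f"declared width {self.width} != member length {actual}")

    @property
    def depth(self) -> int:
        return len(self.members)

    def column(self, j: int) -> str:
        """Column ``j`` (0-based) as a string of depth characters."""
        return "".join(s.residues[j] for s in self.members)

    def __iter__(self) -> Iterator[ProteinSequence]:
        return iter(self.members)


_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


@dataclass(frozen=True, order=True)
class MutationSpec:
    """A single substitution: wild-type residue, 1-based position, mutant residue."""

    position: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa not in AA_INDEX:
            raise MutationParseError(f"non-canonical wild-type residue {self.wt_aa!r}")
        if self.mut_aa not in AA_INDEX:
            raise MutationParseError(f"non-canonical mutant residue {self.mut_aa!r}")
        if self.position < 1:
            raise MutationParseError(f"position must be >= 1, got {self.position}")
        if self.wt_aa == self.mut_aa:
            raise MutationParseError(
                f"wild-type and mutant residues identical in {self.wt_aa}{self.position}{self.mut_aa}"
            )

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    @classmethod
    def from_token(cls, token: str) -> "MutationSpec":
        m = _MUTATION_RE.match(token.strip())
        if m is None:
            raise MutationParseError(f"malformed mutation token {token!r}")
        wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
        return cls(position=pos, wt_aa=wt, mut_aa=mut)


def mutation_string(muts: Iterable[MutationSpec]) -> str:
    """Canonical string form of a mutation list; empty list renders as 'WT'."""
    muts = list(muts)
    return ":".join(str(m) for m in muts) if muts else "WT"


def parse_mutation_string(s: str) -> list[MutationSpec]:
    """Parse ``"A2C"`` or ``"A2C:G5W"`` into :class:`MutationSpec` objects.

    Token order is preserved. Raises :class:`MutationParseError` for
    malformed tokens, non-canonical residues, position 0, or wt == mutant.
    """
    if not s or not s.strip():
        raise MutationParseError("empty mutation string")
    return [MutationSpec.from_token(tok) for tok in s.strip().split(":")]


def read_mutation_file(text_or_path: str | os.PathLike) -> list[list[MutationSpec]]:
    """Read a mutation-list file: one mutation string per line, '#' comments.

    A line reading ``WT`` (case-insensitive) denotes the empty mutation
    list (the wild type itself). Returns one mutation list per
    non-comment line, in file order.
    """
    text = _as_text(text_or_path, probe=lambda t: "\n" in t or _looks_like_mutations(t))
    variants: list[list[MutationSpec]] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.upper() == "WT":
            variants.append([])
        else:
            variants.append(parse_mutation_string(line))
    return variants


def _looks_like_mutations(t: str) -> bool:
    return bool(_MUTATION_RE.match(t.strip().split(":")[0]))


def _as_text(text_or_path, probe) -> str:
    if isinstance(text_or_path, os.PathLike):
        return Path(text_or_path).read_text()
    if isinstance(text_or_path, str):
        if probe(text_or_path):
            return text_or_path
        return Path(text_or_path).read_text()
    raise TypeError(f"expected str or path, got {type(text_or_path).__name__}")


def _normalize_residues(raw: str) -> str:
    # A2M tolerance: lowercase -> uppercase, '.' -> '-'
    return raw.upper().replace(".", GAP)


def read_fasta(text_or_path: str | os.PathLike) -> ProteinSequenceSet:
    """Read FASTA/A2M text (or a path to it) into a :class:`ProteinSequenceSet`.

    Records may be line-wrapped; lowercase letters and ``.`` are accepted
    and normalized to uppercase and ``-``. Record order is preserved.
    Duplicate ids are allowed with a logged warning; order disambiguates.

    Raises
    ------
    FastaFormatError
        On empty input or input with no records.
    SequenceValidationError
        Naming the record and offset of the first invalid character.
    """
    text = _as_text(text_or_path, probe=lambda t: t.lstrip().startswith(">"))
    if not text.strip():
        raise FastaFormatError("empty FASTA input")
    try:
        records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    except ValueError as exc:
        raise FastaFormatError(f"not valid FASTA: {exc}") from exc
    if not records:
        raise FastaFormatError("no FASTA records found")
    seqs: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in records:
        rid = rec.id if rec.id else rec.description
        if not rid:
            raise FastaFormatError("record with empty identifier")
        if rid in seen:
            logger.warning("[DUPLICATE_ID] FASTA id %r occurs more than once", rid)
        seen.add(rid)
        residues = _normalize_residues(str(rec.seq))
        _validate_residues(residues, where=f"record {rid!r}")
        seqs.append(ProteinSequence(rid, residues))
    return ProteinSequenceSet(seqs)


def write_fasta(sequences: ProteinSequenceSet, path: str | os.PathLike) -> None:
    """Write sequences as 80-column-wrapped FASTA; round-trips exactly."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    with open(path, "w") as fh:
        writer = FastaWriter(fh, wrap=80)
        writer.write_file(records)


def fasta_text(sequences: ProteinSequenceSet) -> str:
    """FASTA text for a sequence set (80-column wrapped)."""
    buf = io.StringIO()
    FastaWriter(buf, wrap=80).write_file(
        [SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences]
    )
    return buf.getvalue()


def apply_mutations(
    seq: ProteinSequence, muts: Iterable[MutationSpec]
) -> ProteinSequence:
    """Apply substitutions to a copy of ``seq``; the input is unchanged.

    Positions are 1-based on ``seq``. Each mutation's stated wild-type
    residue must match the current residue at that position (mutations in
    one list are independent, not chained). The result id is suffixed
    with the mutation string; the empty list returns an identical copy.

    Raises
    ------
    WildTypeMismatchError
        If a mutation's wt residue disagrees with the sequence.
    IndexError
        If a position falls outside the sequence.
    """
    muts = list(muts)
    if not muts:
        return seq
    residues = list(seq.residues)
    for m in muts:
        if not (1 <= m.position <= len(residues)):
            raise IndexError(
                f"mutation {m} out of range for length-{len(residues)} sequence"
            )
        found = residues[m.position - 1]
        if found != m.wt_aa:
            raise WildTypeMismatchError(
                f"mutation {m}: expected wild-type {m.wt_aa!r} at position "
                f"{m.position}, found {found!r}"
            )
        residues[m.position - 1] = m.mut_aa
    new_id = f"{seq.id}_{mutation_string(muts)}"
    return seq.with_residues("".join(residues), id=new_id)


def ungap(seq: ProteinSequence) -> tuple[ProteinSequence, list[int]]:
    """Remove gap characters; also return 1-based original indices kept.

    Raises :class:`SequenceValidationError` on an all-gap sequence.
    """
    kept = [(i + 1, ch) for i, ch in enumerate(seq.residues) if ch != GAP]
    if not kept:
        raise SequenceValidationError(f"{seq.id}: sequence is all gaps")
    mapping = [i for i, _ in kept]
    residues = "".join(ch for _, ch in kept)
    return seq.with_residues(residues), mapping


def diff_sequences(a: ProteinSequence, b: ProteinSequence) -> list[MutationSpec]:
    """Minimal substitution list turning ``a`` into ``b``, sorted by position.

    Both sequences must be gap-free and of equal length; ragged input
    should be aligned first.
    """
    if a.has_gaps or b.has_gaps:
        raise SequenceValidationError("diff_sequences requires gap-free sequences")
    if len(a) != len(b):
        raise SequenceValidationError(
            f"length mismatch ({len(a)} vs {len(b)}): align the sequences first"
        )
    muts = []
    for i, (x, y) in enumerate(zip(a.residues, b.residues), start=1):
        if x != y:
            muts.append(MutationSpec(position=i, wt_aa=x, mut_aa=y))
    return muts


def saturation_mutagenesis(
    seq: ProteinSequence, positions: Iterable[int] | None = None
) -> ProteinSequenceSet:
    """All single substitutions to the other 19 canonical residues.

    ``positions`` are 1-based; default is every position. Order is
    deterministic: position-major, canonical-alphabet-minor. Variant ids
    encode the mutation string. ``X`` is not a mutable target and the
    wild type must be gap-free.
    """
    if seq.has_gaps:
        raise SequenceValidationError(
            f"{seq.id}: saturation mutagenesis requires a gap-free sequence"
        )
    if positions is None:
        positions = range(1, len(seq) + 1)
    variants: list[ProteinSequence] = []
    for pos in positions:
        if not (1 <= pos <= len(seq)):
            raise IndexError(f"position {pos} out of range for length {len(seq)}")
        wt = seq.residues[pos - 1]
        if wt == UNKNOWN:
            raise SequenceValidationError(
                f"{seq.id}: position {pos} is 'X' (unknown) and cannot be mutated"
            )
        for mut in CANONICAL:
            if mut == wt:
                continue
            variants.append(
                apply_mutations(seq, [MutationSpec(position=pos, wt_aa=wt, mut_aa=mut)])
            )
    return ProteinSequenceSet(variants)
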