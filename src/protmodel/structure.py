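"""Minimal protein structure handling.

Only what capability checking needs: pull a chain's residue sequence out of
a PDB file and verify that a sequence and a structure describe the same
protein. A residue exists iff it has a CA atom; HETATM records are ignored;
coordinates and geometry are out of scope. Author numbering is reported
as-is — this module never renumbers.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

from .exceptions import ChainNotFoundError, StructureParseError
from .seqio import ProteinSequence, ungap

__all__ = ["StructureRecord", "MatchReport", "parse_chain_sequence", "check_sequence_structure_match"]


@dataclass(frozen=True)
class StructureRecord:
    """One chain's residue content: sequence plus author residue numbers."""

    source: str
    chain_id: str
    residue_sequence: ProteinSequence
    residue_numbers: list[int]

    def __post_init__(self) -> None:
        if len(self.residue_sequence) != len(self.residue_numbers):
            raise StructureParseError(
                "residue sequence and residue numbers have different lengths"
            )


@dataclass(frozen=True)
class MatchReport:
    """Outcome of comparing a sequence against a structure chain."""

    exact_match: bool
    mismatch_positions: list[int] = field(default_factory=list)
    length_difference: int = 0


def parse_chain_sequence(
    pdb_text_or_path: str | os.PathLike, chain_id: str
) -> StructureRecord:
    """Extract one chain's residue sequence from PDB text (or a path to it).

    One residue per distinct (residue number, insertion code) that carries a
    CA atom, in file order. Three-letter codes map to one-letter; unknown
    residue names become ``X``. Alternate locations collapse to a single
    residue. Raises :class:`ChainNotFoundError` listing available chains if
    the chain is absent.
    """
    source = "<text>"
    if isinstance(pdb_text_or_path, os.PathLike):
        source = str(pdb_text_or_path)
        text = Path(pdb_text_or_path).read_text()
    elif "\n" not in pdb_text_or_path and Path(pdb_text_or_path).exists():
        source = pdb_text_or_path
        text = Path(pdb_text_or_path).read_text()
    else:
        text = pdb_text_or_path

    if "ATOM" not in text:
        raise StructureParseError("no ATOM records in PDB input")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("s", io.StringIO(text))
    try:
        model = next(structure.get_models())
    except StopIteration:  # pragma: no cover - PDBParser always yields a model
        raise StructureParseError("no models in PDB input")

    available = [c.id for c in model]
    if chain_id not in available:
        raise ChainNotFoundError(chain_id, available)

    letters: list[str] = []
    numbers: list[int] = []
    for residue in model[chain_id]:
        het, resseq, _icode = residue.id
        if het.strip():  # HETATM / water
            continue
        if not residue.has_id("CA"):
            continue
        letters.append(protein_letters_3to1.get(residue.get_resname().upper(), "X"))
        numbers.append(resseq)
    if not letters:
        raise StructureParseError(f"chain {chain_id!r} has no CA-bearing residues")
    return StructureRecord(
        source=source,
        chain_id=chain_id,
        residue_sequence=ProteinSequence(f"{source}:{chain_id}", "".join(letters)),
        residue_numbers=numbers,
    )


def check_sequence_structure_match(
    seq: ProteinSequence, rec: StructureRecord
) -> MatchReport:
    """Compare a (possibly gapped) sequence with a structure chain.

    Never raises: the report encodes failure. ``exact_match`` is true iff
    the ungapped sequence equals the chain's residue sequence.
    Position numbers in the report are 1-based on the ungapped sequence.
    """
    ungapped, _ = ungap(seq)
    struct_res = rec.residue_sequence.residues
    ldiff = len(ungapped) - len(struct_res)
    mismatches = [
        i
        for i, (a, b) in enumerate(
            zip(ungapped.residues, struct_res), start=1
        )
        if a != b
    ]
    exact = ldiff == 0 and not mismatches
    return MatchReport(
        exact_match=exact, mismatch_positions=mismatches, length_difference=ldiff
    )
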