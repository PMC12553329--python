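"""Residue alphabet shared by every channel layout in the package.

The 20 canonical amino acids are kept in a single fixed order; every index
derived anywhere (one-hot channels, profile columns, k-mer lexicographic
order) uses this ordering. The gap symbol is never part of the canonical
set; layouts that include it place it last.
"""

CANONICAL: str = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN: str = "X"
GAP: str = "-"

#: canonical residues followed by the gap symbol (gap always last)
ALPHABET_WITH_GAP: str = CANONICAL + GAP

#: index of each canonical residue in the fixed ordering
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(CANONICAL)}

#: index over the 21-symbol (canonical + gap) layout
AA_GAP_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET_WITH_GAP)}

#: index of the gap channel in 21-symbol layouts
GAP_INDEX: int = len(CANONICAL)

#: every character a validated sequence may contain
VALID_CHARS: frozenset[str] = frozenset(CANONICAL) | {UNKNOWN, GAP}


def is_canonical(ch: str) -> bool:
    return ch in AA_INDEX
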