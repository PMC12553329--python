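"""Exception hierarchy. Every error the package raises derives from ProtModelError."""

from sklearn.exceptions import NotFittedError as _SklearnNotFittedError


class ProtModelError(Exception):
    """Base class for all package errors."""


class SequenceValidationError(ProtModelError, ValueError):
    """A residue string contains characters outside the alphabet."""


class FastaFormatError(ProtModelError, ValueError):
    """Input is not parseable FASTA/A2M."""


class MutationParseError(ProtModelError, ValueError):
    """A mutation string token is malformed or violates invariants."""


class WildTypeMismatchError(ProtModelError, ValueError):
    """A mutation's stated wild-type residue disagrees with the sequence."""


class NotFittedError(ProtModelError, _SklearnNotFittedError):
    """transform/predict called before fit; also a sklearn NotFittedError."""


class CapabilityError(ProtModelError, ValueError):
    """A model's declared input requirement cannot be satisfied by the data."""


class FixedLengthError(CapabilityError):
    """A fixed-length model received ragged sequences."""


class NotInstalledError(ProtModelError, RuntimeError):
    """A registry stub for a heavier dependency tier was instantiated."""


class ScoreError(ProtModelError, ValueError):
    """A likelihood could not be evaluated (e.g. zero frequency at alpha=0)."""


class MappingError(ProtModelError, ValueError):
    """A mutation position maps to no profile column."""


class ContractViolationError(ProtModelError, ValueError):
    """A conditional sequence model returned an invalid distribution."""


class StructureParseError(ProtModelError, ValueError):
    """PDB text could not be interpreted."""


class ChainNotFoundError(StructureParseError):
    """Requested chain absent from the structure."""

    def __init__(self, chain_id: str, available: list[str]):
        self.chain_id = chain_id
        self.available = list(available)
        super().__init__(
            f"chain {chain_id!r} not found; available chains: {sorted(self.available)}"
        )
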