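"""The uniform model lifecycle: init with hyperparameters, fit, transform/
predict, score — plus the capability (mixin) system that lets heterogeneous
models declare what their inputs must look like.

Every model in the package derives from :class:`ProteinModel`, a
scikit-learn ``BaseEstimator``: hyperparameters are constructor arguments
(introspectable via ``get_params``/``set_params``, so ``sklearn.clone`` and
pipelines work unchanged), data arrives only at ``fit`` time, and fitted
state lives in trailing-underscore attributes. Embedders implement
``transform`` and return a finite numeric matrix with named channels;
scorers implement ``predict`` and return one score per sequence.

Capabilities are declared by mixing in the marker classes
(:class:`RequiresMSAForFitMixin`, :class:`RequiresStructureMixin`,
:class:`RequiresWTMixin`); ``fit`` then runs the corresponding ensure_*
remediation, and :func:`check_compatibility` reports unmet requirements
without raising so a user can ask "which models can run on my data?".
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator

from .align import center_star_align
from .exceptions import CapabilityError, NotFittedError
from .seqio import (
    AlignedFamily,
    ProteinSequence,
    ProteinSequenceSet,
    ungap,
)
from .structure import StructureRecord

logger = logging.getLogger("protmodel")

__all__ = [
    "ModelCapabilities",
    "DataBundle",
    "CompatibilityReport",
    "ProteinModel",
    "RequiresMSAForFitMixin",
    "RequiresStructureMixin",
    "RequiresWTMixin",
    "as_bundle",
    "as_sequence_set",
    "ensure_msa_on_fit",
    "ensure_structure",
    "ensure_wt",
    "check_compatibility",
    "embedding_frame",
]


@dataclass(frozen=True)
class ModelCapabilities:
    """Immutable declaration of a model's input requirements and output kind."""

    requires_msa_for_fit: bool = False
    requires_structure: bool = False
    requires_wt: bool = False
    requires_fixed_length: bool = False
    output_kind: str = "per_sequence_vector"  # or "per_sequence_score"


@dataclass(frozen=True)
class DataBundle:
    """Everything a user's dataset may carry, in one immutable object.

    ``sequences`` is always present; alignment, wild type, structures and
    labels are optional and models declare (via capabilities) which of them
    they need. ``labels``, when present, holds one value per sequence.
    """

    sequences: ProteinSequenceSet
    alignment: AlignedFamily | None = None
    wild_type: ProteinSequence | None = None
    structures: dict[str, StructureRecord] | None = None
    wt_structure: StructureRecord | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.sequences, ProteinSequenceSet):
            object.__setattr__(
                self, "sequences", as_sequence_set(self.sequences)
            )
        if self.labels is not None:
            labels = np.asarray(self.labels, dtype=float)
            if labels.shape != (len(self.sequences),):
                raise ValueError(
                    f"labels shape {labels.shape} does not match "
                    f"{len(self.sequences)} sequences"
                )
            object.__setattr__(self, "labels", labels)

    def replace(self, **changes) -> "DataBundle":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class CompatibilityReport:
    """Unmet-requirement list for one (model, data) pair; never raises."""

    unmet: tuple[str, ...] = field(default_factory=tuple)

    @property
    def compatible(self) -> bool:
        return not self.unmet

    def __str__(self) -> str:
        return "compatible" if self.compatible else "unmet: " + ", ".join(self.unmet)


def as_sequence_set(X) -> ProteinSequenceSet:
    """Coerce the accepted input forms to a :class:`ProteinSequenceSet`."""
    if isinstance(X, ProteinSequenceSet):
        return X
    if isinstance(X, DataBundle):
        return X.sequences
    if isinstance(X, AlignedFamily):
        return X.members
    if isinstance(X, ProteinSequence):
        return ProteinSequenceSet([X])
    if isinstance(X, (list, tuple)):
        if all(isinstance(s, ProteinSequence) for s in X):
            return ProteinSequenceSet(X)
        if all(isinstance(s, str) for s in X):
            return ProteinSequenceSet.from_strings(X)
    raise TypeError(f"cannot interpret {type(X).__name__} as protein sequences")


def as_bundle(X, labels=None) -> DataBundle:
    """Coerce sequences / alignments / bundles into a :class:`DataBundle`."""
    if isinstance(X, DataBundle):
        return X if labels is None else X.replace(labels=labels)
    if isinstance(X, AlignedFamily):
        return DataBundle(sequences=X.members, alignment=X, labels=labels)
    return DataBundle(sequences=as_sequence_set(X), labels=labels)


# ---------------------------------------------------------------------------
# capability remediation


def ensure_msa_on_fit(bundle: DataBundle) -> DataBundle:
    """Guarantee the bundle carries an alignment; auto-align if it must.

    Pass-through (same object) when an alignment is already present, so the
    operation is idempotent. Uniform-length sequence sets are wrapped as a
    width-L family directly; ragged sets are ungapped and run through
    center-star alignment with a logged warning that automatic alignment
    occurred.
    """
    if bundle.alignment is not None:
        return bundle
    seqs = bundle.sequences
    if len(seqs) < 2:
        raise CapabilityError(
            "model requires an MSA for fit but got fewer than 2 unaligned sequences"
        )
    if seqs.uniform_length:
        logger.info("[WRAP_ALIGNED] uniform-length sequences wrapped as alignment")
        fam = AlignedFamily(members=seqs)
    else:
        logger.warning(
            "[AUTO_ALIGN] sequences were not aligned; running center-star alignment"
        )
        ungapped = ProteinSequenceSet(ungap(s)[0] for s in seqs)
        fam = center_star_align(ungapped)
    return bundle.replace(alignment=fam)


def ensure_structure(bundle: DataBundle) -> DataBundle:
    """Resolve a structure for every sequence, falling back to the wild-type
    structure (with one logged warning per fallback) when a sequence has
    none of its own."""
    structures = dict(bundle.structures or {})
    missing: list[str] = []
    for seq in bundle.sequences:
        if seq.id in structures:
            continue
        if bundle.wt_structure is not None:
            logger.warning(
                "[WT_STRUCTURE_FALLBACK] sequence %r has no structure; "
                "using wild-type structure",
                seq.id,
            )
            structures[seq.id] = bundle.wt_structure
        else:
            missing.append(seq.id)
    if missing:
        raise CapabilityError(
            f"model requires structures but none resolvable for: {missing}"
        )
    return bundle.replace(structures=structures)


def ensure_wt(bundle: DataBundle) -> DataBundle:
    """Require a gap-free wild-type sequence; pass-through when present."""
    if bundle.wild_type is None:
        raise CapabilityError("model requires a wild-type sequence; none provided")
    if bundle.wild_type.has_gaps:
        raise CapabilityError(
            "wild-type sequence must be gap-free (variants are defined on "
            "wild-type coordinates)"
        )
    return bundle


_REQ_NO_SEQUENCES = "no sequences"
_REQ_MSA = "requires MSA for fit"
_REQ_STRUCTURE = "requires structures (or a wild-type structure)"
_REQ_WT = "requires a wild-type sequence"
_REQ_WT_GAPFREE = "requires a gap-free wild-type sequence"
_REQ_FIXED_LENGTH = "requires fixed-length sequences"


def check_compatibility(model_or_caps, bundle: DataBundle) -> CompatibilityReport:
    """Report every unmet requirement of a model against a bundle.

    Purely observational: neither the model nor the bundle is mutated and
    nothing raises. ``compatible`` is true iff the unmet list is empty.
    The report describes the data as given; some requirements (an MSA for
    uniform-length or alignable sequences) could still be remediated at
    fit time by the ensure_* hooks.
    """
    caps: ModelCapabilities = (
        model_or_caps
        if isinstance(model_or_caps, ModelCapabilities)
        else model_or_caps.capabilities
    )
    unmet: list[str] = []
    if len(bundle.sequences) == 0:
        unmet.append(_REQ_NO_SEQUENCES)
    if caps.requires_msa_for_fit and bundle.alignment is None:
        unmet.append(_REQ_MSA)
    if caps.requires_structure:
        structures = bundle.structures or {}
        covered = all(s.id in structures for s in bundle.sequences)
        if not (covered or bundle.wt_structure is not None):
            unmet.append(_REQ_STRUCTURE)
    if caps.requires_wt:
        if bundle.wild_type is None:
            unmet.append(_REQ_WT)
        elif bundle.wild_type.has_gaps:
            unmet.append(_REQ_WT_GAPFREE)
    if caps.requires_fixed_length and not bundle.sequences.uniform_length:
        unmet.append(_REQ_FIXED_LENGTH)
    return CompatibilityReport(unmet=tuple(unmet))


def embedding_frame(
    values: np.ndarray, ids: list[str], columns: list[str]
) -> pd.DataFrame:
    """Build the post-transform matrix: one row per input sequence (input
    order), named feature channels, no non-finite entries."""
    values = np.asarray(values, dtype=float)
    if values.shape != (len(ids), len(columns)):
        raise ValueError(
            f"embedding shape {values.shape} != ({len(ids)}, {len(columns)})"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("embedding contains non-finite values")
    return pd.DataFrame(values, index=pd.Index(ids, name="id"), columns=columns)


# ---------------------------------------------------------------------------
# base estimator and capability mixins


class RequiresMSAForFitMixin:
    """Model needs its fit data aligned; unaligned input is auto-aligned."""

    _requires_msa_for_fit = True


class RequiresStructureMixin:
    """Model needs a structure per sequence (wild-type structure fallback)."""

    _requires_structure = True


class RequiresWTMixin:
    """Model needs a gap-free wild-type sequence to function."""

    _requires_wt = True


class ProteinModel(BaseEstimator):
    """Base class: hyperparameters at init, data at fit, state in ``*_``.

    Subclasses implement ``_fit(bundle)`` and either ``_transform(seqs)``
    (embedders) or ``_predict(seqs)`` (scorers). Refitting starts from
    scratch; fitting twice on the same data reproduces outputs exactly.
    """

    _requires_msa_for_fit = False
    _requires_structure = False
    _requires_wt = False
    _requires_fixed_length = False
    _output_kind = "per_sequence_vector"
    category = "embedding"

    @property
    def capabilities(self) -> ModelCapabilities:
        return ModelCapabilities(
            requires_msa_for_fit=self._requires_msa_for_fit,
            requires_structure=self._requires_structure,
            requires_wt=self._requires_wt,
            requires_fixed_length=self._requires_fixed_length,
            output_kind=self._output_kind,
        )

    # -- lifecycle ---------------------------------------------------------

    def fit(self, X, y=None) -> "ProteinModel":
        bundle = as_bundle(X, labels=y)
        if len(bundle.sequences) == 0:
            raise CapabilityError("cannot fit on an empty sequence set")
        caps = self.capabilities
        if caps.requires_wt:
            bundle = ensure_wt(bundle)
        if caps.requires_msa_for_fit:
            bundle = ensure_msa_on_fit(bundle)
        if caps.requires_structure:
            bundle = ensure_structure(bundle)
        self._fit(bundle)
        self.is_fitted_ = True
        return self

    def _fit(self, bundle: DataBundle) -> None:  # pragma: no cover - abstract
        raise NotImplementedError

    def _check_fitted(self) -> None:
        if not getattr(self, "is_fitted_", False):
            raise NotFittedError(
                f"{type(self).__name__} is not fitted; call fit() first"
            )

    def transform(self, X) -> pd.DataFrame:
        self._check_fitted()
        return self._transform(as_sequence_set(X))

    def _transform(self, seqs: ProteinSequenceSet) -> pd.DataFrame:
        raise NotImplementedError(f"{type(self).__name__} is not an embedder")

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        return np.asarray(self._predict(as_sequence_set(X)), dtype=float)

    def _predict(self, seqs: ProteinSequenceSet) -> np.ndarray:
        raise NotImplementedError(f"{type(self).__name__} is not a predictor")

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)

    def score(self, X, y=None) -> float:
        """Spearman rank correlation between predictions and labels.

        Zero-shot scores are rank-scale quantities, so rank correlation is
        the framework-wide goodness measure for predictive models.
        """
        bundle = as_bundle(X, labels=y)
        if bundle.labels is None:
            raise ValueError("score requires labels")
        preds = self.predict(bundle.sequences)
        rho = spearmanr(preds, bundle.labels).statistic
        return float(rho)

    def check_compatibility(self, X) -> CompatibilityReport:
        return check_compatibility(self, as_bundle(X))
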