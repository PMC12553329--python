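"""Zero-shot variant-effect scoring.

Two scoring families, both label-free:

* **Site-frequency (independent-sites) likelihood** — a sequence is scored
  against a :class:`~protmodel.profile.ColumnProfile` fitted on related
  sequences: log-likelihood is the sum of per-column log frequencies, and a
  variant's score is the mutant-minus-wild-type difference, which for this
  model reduces to a sum over mutated columns. This deliberately implements
  the independent-column model itself (no insert/delete state machinery);
  wrapping an external profile-HMM engine is out of scope.

* **Marginal scoring protocols** — masked, wild-type and mutant marginals
  turn any conditional residue-probability model (the contract protein
  language models satisfy) into a variant score. The protocols are
  implemented over the abstract :class:`ConditionalSequenceModel`; the
  built-in backend is the context-free :class:`ProfileConditionalModel`,
  under which all three protocols provably coincide.

Scores are natural-log units, higher = more favorable, and the empty
variant scores exactly 0.
"""

from __future__ import annotations

import abc
import logging
import math
from dataclasses import dataclass

import numpy as np

from .alphabet import AA_GAP_INDEX, AA_INDEX, CANONICAL, UNKNOWN
from .align import align_to_profile
from .exceptions import (
    ContractViolationError,
    MappingError,
    ScoreError,
    WildTypeMismatchError,
)
from .model_core import ProteinModel, RequiresMSAForFitMixin, RequiresWTMixin
from .model_core import ModelCapabilities
from .profile import ColumnProfile, fit_column_profile
from .seqio import (
    AlignedFamily,
    MutationSpec,
    ProteinSequence,
    ProteinSequenceSet,
    apply_mutations,
    diff_sequences,
    mutation_string,
    ungap,
)

logger = logging.getLogger("protmodel")

__all__ = [
    "ColumnProfile",
    "fit_column_profile",
    "loglik",
    "wt_column_mapping",
    "VariantScore",
    "variant_delta_scores",
    "ConditionalSequenceModel",
    "ProfileConditionalModel",
    "marginal_score",
    "MARGINAL_MODES",
    "ProfileLikelihoodScorer",
    "MarginalLikelihoodScorer",
]

MARGINAL_MODES = ("masked", "wildtype", "mutant")


def _log_frequency(profile: ColumnProfile, column: int, symbol: str) -> float:
    f = profile.frequencies[column, AA_GAP_INDEX[symbol]]
    if f <= 0.0:
        raise ScoreError(
            f"symbol {symbol!r} has zero frequency in column {column}; "
            "refit the profile with a pseudocount alpha > 0"
        )
    return math.log(f)


def loglik(profile: ColumnProfile, seq: ProteinSequence | str) -> float:
    """Sum of per-column natural-log frequencies of a width-W sequence.

    'X' positions are skipped with a logged warning. A zero frequency
    (possible only at alpha = 0) raises :class:`ScoreError`.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    if len(residues) != profile.width:
        raise ValueError(
            f"sequence length {len(residues)} != profile width {profile.width}"
        )
    total = 0.0
    for j, ch in enumerate(residues):
        if ch == UNKNOWN:
            logger.warning("[UNKNOWN_SKIPPED] 'X' at column %d skipped in loglik", j)
            continue
        total += _log_frequency(profile, j, ch)
    return total


def wt_column_mapping(
    profile: ColumnProfile,
    wt: ProteinSequence,
    family: AlignedFamily | None = None,
) -> list[int | None]:
    """Map each 1-based wild-type position to its profile column (0-based).

    If the wild type is a member of the fitted family, its own gap pattern
    provides the mapping; otherwise the wild type is aligned to the profile
    and residues consumed as insertions map to ``None``.
    """
    if wt.has_gaps:
        raise ValueError("wild type must be gap-free")
    if family is not None:
        if family.width != profile.width:
            raise ValueError("family width does not match profile width")
        for member in family:
            ungapped, positions = ungap(member)
            if ungapped.residues == wt.residues:
                return [p - 1 for p in positions]
        logger.info(
            "[WT_ALIGNED] wild type not a family member; aligning to profile"
        )
    return align_to_profile(wt, profile).query_columns


@dataclass(frozen=True)
class VariantScore:
    """A scored variant: id, mutation list, natural-log score vs wild type."""

    variant_id: str
    mutations: tuple[MutationSpec, ...]
    score: float

    def __post_init__(self) -> None:
        if not self.mutations and self.score != 0.0:
            raise ValueError("the empty variant must score exactly 0")


def _check_mutation_on_wt(wt: ProteinSequence, m: MutationSpec) -> None:
    if not (1 <= m.position <= len(wt)):
        raise IndexError(f"mutation {m} out of range for length-{len(wt)} wild type")
    found = wt.residues[m.position - 1]
    if found != m.wt_aa:
        raise WildTypeMismatchError(
            f"mutation {m}: expected {m.wt_aa!r} at wild-type position "
            f"{m.position}, found {found!r}"
        )


def variant_delta_scores(
    profile: ColumnProfile,
    wt: ProteinSequence,
    variants: list[list[MutationSpec]],
    family: AlignedFamily | None = None,
    mapping: list[int | None] | None = None,
) -> list[VariantScore]:
    """Mutant-minus-wild-type log-likelihood for each mutation list.

    Under the independent-sites model the full-sequence difference
    telescopes to a sum over mutated columns only:
    sum_i [ln f_{j(i)}(mut_i) - ln f_{j(i)}(wt_i)]. A mutation at a
    position that maps to no profile column raises :class:`MappingError`.
    """
    if mapping is None:
        mapping = wt_column_mapping(profile, wt, family=family)
    if len(mapping) != len(wt):
        raise ValueError("mapping length does not match wild-type length")
    out: list[VariantScore] = []
    for muts in variants:
        muts = list(muts)
        if not muts:
            out.append(VariantScore("WT", (), 0.0))
            continue
        total = 0.0
        for m in muts:
            _check_mutation_on_wt(wt, m)
            col = mapping[m.position - 1]
            if col is None:
                raise MappingError(
                    f"mutation {m}: wild-type position {m.position} maps to "
                    "no profile column (aligned as an insertion)"
                )
            total += _log_frequency(profile, col, m.mut_aa)
            total -= _log_frequency(profile, col, m.wt_aa)
        out.append(VariantScore(mutation_string(muts), tuple(muts), total))
    return out


class ConditionalSequenceModel(abc.ABC):
    """Contract for conditional residue-probability backends.

    ``residue_distribution(context, position, masked)`` returns a length-20
    probability vector over the canonical residues (fixed ordering) at a
    1-based position, given a context sequence, optionally with the queried
    position masked. This is the interface protein language models expose;
    any implementation can be plugged into :func:`marginal_score`.
    """

    @abc.abstractmethod
    def residue_distribution(
        self, context: ProteinSequence, position: int, masked: bool
    ) -> np.ndarray:
        """Probability vector over the 20 canonical residues; sums to 1."""


class ProfileConditionalModel(ConditionalSequenceModel):
    """Context-free backend over a column profile.

    The distribution at a position is that column's canonical frequencies
    renormalized over the 20 residues; the context sequence and mask flag
    are ignored entirely. Because of this context independence, the masked,
    wild-type and mutant marginal protocols coincide exactly.
    """

    def __init__(
        self,
        profile: ColumnProfile,
        column_mapping: list[int | None] | None = None,
    ):
        self.profile = profile
        if column_mapping is None:
            column_mapping = list(range(profile.width))
        self.column_mapping = list(column_mapping)

    def residue_distribution(
        self, context: ProteinSequence, position: int, masked: bool
    ) -> np.ndarray:
        if not (1 <= position <= len(self.column_mapping)):
            raise IndexError(f"position {position} outside mapped range")
        col = self.column_mapping[position - 1]
        if col is None:
            raise MappingError(f"position {position} maps to no profile column")
        canon = self.profile.frequencies[col, : len(CANONICAL)].astype(float)
        mass = canon.sum()
        if mass <= 0.0:
            raise ScoreError(
                f"column {col} has zero canonical mass; use alpha > 0"
            )
        return canon / mass


def _validated_distribution(
    model: ConditionalSequenceModel,
    context: ProteinSequence,
    position: int,
    masked: bool,
) -> np.ndarray:
    dist = np.asarray(
        model.residue_distribution(context, position, masked), dtype=float
    )
    if dist.shape != (len(CANONICAL),):
        raise ContractViolationError(
            f"backend returned shape {dist.shape}, expected ({len(CANONICAL)},)"
        )
    if np.any(dist < 0) or abs(float(dist.sum()) - 1.0) > 1e-12:
        raise ContractViolationError(
            "backend distribution is negative or does not sum to 1"
        )
    return dist


def marginal_score(
    model: ConditionalSequenceModel,
    wt: ProteinSequence,
    mutations: list[MutationSpec],
    mode: str = "masked",
) -> float:
    """Variant score from a conditional model under one of three protocols.

    masked
        sum_i [ln p(mut_i | wt masked at i) - ln p(wt_i | wt masked at i)]
    wildtype
        contexts are the unmasked wild type
    mutant
        contexts are the full unmasked mutant sequence

    Natural-log units; the empty mutation list scores 0 in every mode.
    """
    if mode not in MARGINAL_MODES:
        raise ValueError(f"mode must be one of {MARGINAL_MODES}, got {mode!r}")
    mutations = list(mutations)
    if not mutations:
        return 0.0
    for m in mutations:
        _check_mutation_on_wt(wt, m)
    if mode == "mutant":
        context = apply_mutations(wt, mutations)
        masked = False
    else:
        context = wt
        masked = mode == "masked"
    total = 0.0
    for m in mutations:
        dist = _validated_distribution(model, context, m.position, masked)
        p_mut = float(dist[AA_INDEX[m.mut_aa]])
        p_wt = float(dist[AA_INDEX[m.wt_aa]])
        if p_mut <= 0.0 or p_wt <= 0.0:
            raise ScoreError(
                f"zero marginal probability at position {m.position}; "
                "backend must assign positive mass to observed residues"
            )
        total += math.log(p_mut) - math.log(p_wt)
    return total


# ---------------------------------------------------------------------------
# estimator wrappers


class ProfileLikelihoodScorer(RequiresMSAForFitMixin, ProteinModel):
    """Zero-shot scorer: summed log column frequencies of a fitted profile.

    ``predict`` returns the raw log-likelihood of each sequence (width-W
    inputs scored directly, others aligned to the profile first);
    ``score_variants`` returns mutant-minus-wild-type deltas on wild-type
    coordinates. ``alpha`` is the fitting pseudocount (Laplace default,
    guaranteeing finite scores).
    """

    category = "zero_shot"
    _output_kind = "per_sequence_score"

    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def _fit(self, bundle) -> None:
        self.family_ = bundle.alignment
        self.profile_ = fit_column_profile(bundle.alignment, alpha=self.alpha)

    def _predict(self, seqs: ProteinSequenceSet) -> np.ndarray:
        scores = np.empty(len(seqs))
        for i, seq in enumerate(seqs):
            if len(seq) == self.profile_.width:
                scores[i] = loglik(self.profile_, seq)
            else:
                query = ungap(seq)[0] if seq.has_gaps else seq
                gapped = align_to_profile(query, self.profile_).gapped
                scores[i] = loglik(self.profile_, gapped)
        return scores

    def score_variants(
        self, wt: ProteinSequence, variants: list[list[MutationSpec]]
    ) -> list[VariantScore]:
        self._check_fitted()
        return variant_delta_scores(
            self.profile_, wt, variants, family=self.family_
        )


class MarginalLikelihoodScorer(RequiresWTMixin, ProteinModel):
    """Zero-shot scorer running a marginal protocol over a pluggable backend.

    With ``backend=None`` the context-free profile backend is fitted from
    the bundle's alignment (so an MSA is then required); any object
    honoring the :class:`ConditionalSequenceModel` contract may be passed
    instead, in which case no alignment is needed. ``predict`` scores full
    sequences by diffing them against the wild type.
    """

    category = "zero_shot"
    _output_kind = "per_sequence_score"

    def __init__(
        self,
        mode: str = "masked",
        alpha: float = 1.0,
        backend: ConditionalSequenceModel | None = None,
    ):
        self.mode = mode
        self.alpha = alpha
        self.backend = backend

    @property
    def capabilities(self) -> ModelCapabilities:
        return ModelCapabilities(
            requires_msa_for_fit=self.backend is None,
            requires_wt=True,
            output_kind="per_sequence_score",
        )

    def _fit(self, bundle) -> None:
        if self.mode not in MARGINAL_MODES:
            raise ValueError(
                f"mode must be one of {MARGINAL_MODES}, got {self.mode!r}"
            )
        self.wild_type_ = bundle.wild_type
        if self.backend is None:
            profile = fit_column_profile(bundle.alignment, alpha=self.alpha)
            mapping = wt_column_mapping(
                profile, self.wild_type_, family=bundle.alignment
            )
            self.backend_ = ProfileConditionalModel(profile, mapping)
        else:
            self.backend_ = self.backend

    def score_mutations(self, variants: list[list[MutationSpec]]) -> np.ndarray:
        self._check_fitted()
        return np.array(
            [
                marginal_score(self.backend_, self.wild_type_, muts, self.mode)
                for muts in variants
            ]
        )

    def _predict(self, seqs: ProteinSequenceSet) -> np.ndarray:
        variants = [diff_sequences(self.wild_type_, seq) for seq in seqs]
        return self.score_mutations(variants)
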