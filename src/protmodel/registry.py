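"""Model registry: a "virtual toolbox" of embedding and zero-shot methods.

Each descriptor records a model's category, dependency tier and capability
flags. Base-tier models run with this package alone; heavier methods
(protein language models, coupling models, VAE scorers) are represented by
stubs carrying their real capability metadata, so "which models could run
on my data?" is answerable over the whole toolbox without installing any
GPU dependency — instantiating a stub raises a clear not-installed error
naming what would be needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .embedders import AlignedOneHotEmbedding, KMerEmbedding, OneHotEmbedding
from .exceptions import NotInstalledError
from .model_core import (
    CompatibilityReport,
    DataBundle,
    ModelCapabilities,
    check_compatibility,
)
from .seqio import AlignedFamily, ProteinSequenceSet
from .zeroshot import MarginalLikelihoodScorer, ProfileLikelihoodScorer

__all__ = [
    "ModelDescriptor",
    "builtin_registry",
    "get_descriptor",
    "available_models",
    "compatible_models",
    "registry_table",
    "sample_msa",
]

TIERS = ("base", "extra", "external_env")


@dataclass(frozen=True)
class ModelDescriptor:
    """Registry record for one model.

    ``tier`` is the dependency class: *base* (this package only, always
    available), *extra* (additional pip-installable dependencies), or
    *external_env* (a separately built environment driven by subprocess).
    ``requires`` names the missing dependency for non-base tiers.
    """

    name: str
    category: str  # "embedding" | "zero_shot"
    tier: str
    capabilities: ModelCapabilities
    requires: str = ""
    factory: Callable | None = None

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.category not in ("embedding", "zero_shot"):
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def available(self) -> bool:
        return self.tier == "base"

    def instantiate(self, **hyperparameters):
        """Construct the model, or raise for stub tiers."""
        if not self.available or self.factory is None:
            raise NotInstalledError(
                f"model {self.name!r} (tier {self.tier!r}) is not available "
                f"in this installation; requires: {self.requires or self.tier}"
            )
        return self.factory(**hyperparameters)


def _caps(**kw) -> ModelCapabilities:
    return ModelCapabilities(**kw)


def builtin_registry() -> list[ModelDescriptor]:
    """All registered models, implemented and stubbed, in a fixed order."""
    emb, zs = "embedding", "zero_shot"
    score = {"output_kind": "per_sequence_score"}
    return [
        # --- base tier: fully implemented in this package
        ModelDescriptor(
            "onehot", emb, "base",
            _caps(requires_fixed_length=True),
            factory=OneHotEmbedding,
        ),
        ModelDescriptor(
            "onehot_aligned", emb, "base",
            _caps(requires_msa_for_fit=True),
            factory=AlignedOneHotEmbedding,
        ),
        ModelDescriptor(
            "kmer", emb, "base",
            _caps(),
            factory=KMerEmbedding,
        ),
        ModelDescriptor(
            "site_frequency", zs, "base",
            _caps(requires_msa_for_fit=True, **score),
            factory=ProfileLikelihoodScorer,
        ),
        ModelDescriptor(
            "profile_marginal", zs, "base",
            _caps(requires_msa_for_fit=True, requires_wt=True, **score),
            factory=MarginalLikelihoodScorer,
        ),
        # --- extra tier: stubs for pip-installable heavy dependencies
        ModelDescriptor(
            "evmutation", zs, "extra",
            _caps(requires_msa_for_fit=True, requires_wt=True, **score),
            requires="evcouplings",
        ),
        ModelDescriptor(
            "esm2_embedding", emb, "extra",
            _caps(),
            requires="transformers (PyTorch)",
        ),
        ModelDescriptor(
            "esm2_likelihood", zs, "extra",
            _caps(requires_wt=True, **score),
            requires="transformers (PyTorch)",
        ),
        ModelDescriptor(
            "saprot_embedding", emb, "extra",
            _caps(requires_structure=True),
            requires="transformers (PyTorch), foldseek",
        ),
        ModelDescriptor(
            "saprot_likelihood", zs, "extra",
            _caps(requires_structure=True, requires_wt=True, **score),
            requires="transformers (PyTorch), foldseek",
        ),
        ModelDescriptor(
            "msa_transformer_embedding", emb, "extra",
            _caps(requires_msa_for_fit=True),
            requires="transformers, fair-esm",
        ),
        ModelDescriptor(
            "msa_transformer_likelihood", zs, "extra",
            _caps(requires_msa_for_fit=True, requires_wt=True, **score),
            requires="transformers, fair-esm",
        ),
        ModelDescriptor(
            "vespa", zs, "extra",
            _caps(requires_wt=True, **score),
            requires="vespa-effect",
        ),
        # --- external_env tier: separately built environments
        ModelDescriptor(
            "eve_vae", zs, "external_env",
            _caps(requires_msa_for_fit=True, **score),
            requires="a separately built EVE-style environment",
        ),
        ModelDescriptor(
            "ssemb_embedding", emb, "external_env",
            _caps(requires_msa_for_fit=True, requires_structure=True),
            requires="a separately built environment",
        ),
        ModelDescriptor(
            "ssemb_likelihood", zs, "external_env",
            _caps(requires_msa_for_fit=True, requires_structure=True, **score),
            requires="a separately built environment",
        ),
    ]


def get_descriptor(name: str) -> ModelDescriptor:
    for d in builtin_registry():
        if d.name == name:
            return d
    raise KeyError(f"no registered model named {name!r}")


def available_models(
    bundle: DataBundle,
) -> list[tuple[ModelDescriptor, CompatibilityReport]]:
    """Pair every registry entry with its compatibility report for a bundle.

    A pure function of (registry, bundle); the bundle is never mutated.
    Filter with :func:`compatible_models` for the runnable subset.
    """
    return [
        (d, check_compatibility(d.capabilities, bundle))
        for d in builtin_registry()
    ]


def compatible_models(bundle: DataBundle) -> list[ModelDescriptor]:
    """Registry entries that are installed and whose requirements the
    bundle meets."""
    return [
        d
        for d, report in available_models(bundle)
        if d.available and report.compatible
    ]


def registry_table(bundle: DataBundle | None = None) -> str:
    """Human-readable registry dump, optionally scored against a bundle."""
    header = ["name", "category", "tier", "available"]
    if bundle is not None:
        header += ["compatible", "unmet_requirements"]
    rows = [header]
    entries = (
        available_models(bundle)
        if bundle is not None
        else [(d, None) for d in builtin_registry()]
    )
    for d, report in entries:
        row = [d.name, d.category, d.tier, str(d.available).lower()]
        if report is not None:
            row += [
                str(report.compatible).lower(),
                "; ".join(report.unmet) or "-",
            ]
        rows.append(row)
    widths = [max(len(r[c]) for r in rows) for c in range(len(header))]
    return "\n".join(
        "  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
        for row in rows
    )


def sample_msa(family: AlignedFamily, n: int, seed: int) -> AlignedFamily:
    """Uniform sample of ``n`` members without replacement, order preserved.

    No sequence weighting is applied. Identical seeds give identical
    samples; ``n`` must not exceed the family depth.
    """
    if not (1 <= n <= family.depth):
        raise ValueError(f"n must be in [1, {family.depth}], got {n}")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(family.depth, size=n, replace=False))
    members = ProteinSequenceSet(family.members[int(i)] for i in keep)
    return AlignedFamily(members=members, width=family.width)
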