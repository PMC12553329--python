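"""Lifecycle contract, capability remediation and compatibility checking."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.pipeline import Pipeline
from sklearn.decomposition import PCA

from protmodel.embedders import AlignedOneHotEmbedding, KMerEmbedding, OneHotEmbedding
from protmodel.exceptions import CapabilityError, NotFittedError
from protmodel.model_core import (
    DataBundle,
    ModelCapabilities,
    as_bundle,
    check_compatibility,
    ensure_msa_on_fit,
    ensure_structure,
    ensure_wt,
)
from protmodel.seqio import AlignedFamily, ProteinSequence, ProteinSequenceSet
from protmodel.structure import parse_chain_sequence
from protmodel.zeroshot import MarginalLikelihoodScorer, ProfileLikelihoodScorer


class TestLifecycle:
    def test_fit_then_transform_row_count(self):
        model = KMerEmbedding(k=2).fit(["ACDW", "WWA"])
        out = model.transform(["ACDW", "WWA", "AAAA"])
        assert out.shape == (3, 400)

    def test_transform_before_fit_raises(self):
        with pytest.raises(NotFittedError):
            KMerEmbedding().transform(["ACD"])
        with pytest.raises(NotFittedError):
            OneHotEmbedding().transform(["ACD"])

    def test_refit_reproduces_and_refits_from_scratch(self, synth_family):
        model = AlignedOneHotEmbedding(alpha=1.0)
        seqs = synth_family.members[:5]
        a = model.fit(synth_family).transform(seqs)
        b = model.fit(synth_family).transform(seqs)
        assert a.equals(b)
        # refit on different data changes the output dimension
        other = AlignedFamily(
            members=ProteinSequenceSet.from_strings(["ACDW", "AC-W"])
        )
        c = model.fit(other).transform(["ACDW"])
        assert c.shape[1] == 21 * 4

    def test_fit_on_empty_set_rejected(self):
        with pytest.raises(CapabilityError):
            KMerEmbedding().fit([])


class TestParams:
    def test_get_params_reports_hyperparameters(self):
        assert KMerEmbedding(k=3).get_params()["k"] == 3

    def test_set_params_round_trip_and_unknown_rejected(self):
        m = KMerEmbedding(k=2)
        m.set_params(k=3)
        assert m.get_params()["k"] == 3
        with pytest.raises(ValueError):
            m.set_params(order=5)

    @pytest.mark.parametrize(
        "factory",
        [
            lambda: OneHotEmbedding(),
            lambda: KMerEmbedding(k=2),
            lambda: AlignedOneHotEmbedding(alpha=0.5),
            lambda: ProfileLikelihoodScorer(alpha=1.0),
            lambda: MarginalLikelihoodScorer(mode="masked"),
        ],
    )
    def test_clone_via_params_gives_identical_outputs(
        self, factory, synth_family, synth_wt
    ):
        model = factory()
        twin = clone(model)
        if model.capabilities.requires_fixed_length:
            # gap-free, uniform-length data for the fixed-length embedder
            from protmodel.seqio import saturation_mutagenesis

            bundle = DataBundle(sequences=saturation_mutagenesis(synth_wt))
        else:
            bundle = DataBundle(
                sequences=synth_family.members,
                alignment=synth_family,
                wild_type=synth_wt,
            )
        probe = ProteinSequenceSet([synth_wt])
        for m in (model, twin):
            m.fit(bundle)
        if model.category == "embedding":
            assert model.transform(probe).equals(twin.transform(probe))
        else:
            assert np.array_equal(model.predict(probe), twin.predict(probe))

    def test_drop_in_sklearn_pipeline(self, synth_family):
        pipe = Pipeline(
            [("embed", AlignedOneHotEmbedding()), ("pca", PCA(n_components=2))]
        )
        reduced = pipe.fit_transform(synth_family)
        assert reduced.shape == (synth_family.depth, 2)


class TestEnsureMSA:
    def test_already_aligned_passes_through_unchanged(self, toy_msa):
        bundle = as_bundle(toy_msa)
        assert ensure_msa_on_fit(bundle) is bundle

    def test_idempotent(self):
        bundle = as_bundle(ProteinSequenceSet.from_strings(["ACD", "AD"]))
        once = ensure_msa_on_fit(bundle)
        assert ensure_msa_on_fit(once) is once

    def test_ragged_pair_gets_center_star_gap(self, caplog):
        bundle = as_bundle(ProteinSequenceSet.from_strings(["ACD", "AD"]))
        with caplog.at_level("WARNING", logger="protmodel"):
            out = ensure_msa_on_fit(bundle)
        assert out.alignment.width == 3
        assert out.alignment.members.residue_strings == ["ACD", "A-D"]
        assert any("AUTO_ALIGN" in r.message for r in caplog.records)

    def test_uniform_length_wrapped_without_realignment(self):
        bundle = as_bundle(ProteinSequenceSet.from_strings(["ACD", "WYV"]))
        out = ensure_msa_on_fit(bundle)
        assert out.alignment.members.residue_strings == ["ACD", "WYV"]

    def test_single_unaligned_sequence_rejected(self):
        with pytest.raises(CapabilityError):
            ensure_msa_on_fit(as_bundle(ProteinSequenceSet.from_strings(["ACD"])))


class TestEnsureStructure:
    def test_all_own_structures_no_warning(self, pdb_text, caplog):
        rec = parse_chain_sequence(pdb_text, "A")
        bundle = DataBundle(
            sequences=ProteinSequenceSet.from_strings(["ACD"], ids=["s"]),
            structures={"s": rec},
        )
        with caplog.at_level("WARNING", logger="protmodel"):
            out = ensure_structure(bundle)
        assert out.structures["s"] is rec
        assert not caplog.records

    def test_wild_type_fallback_with_warning(self, pdb_text, caplog):
        rec = parse_chain_sequence(pdb_text, "A")
        bundle = DataBundle(
            sequences=ProteinSequenceSet.from_strings(["ACD", "AWD"]),
            wt_structure=rec,
        )
        with caplog.at_level("WARNING", logger="protmodel"):
            out = ensure_structure(bundle)
        assert all(out.structures[i] is rec for i in out.sequences.ids)
        fallbacks = [r for r in caplog.records if "WT_STRUCTURE_FALLBACK" in r.message]
        assert len(fallbacks) == 2  # one warning per fallback

    def test_no_structures_anywhere_names_ids(self):
        bundle = DataBundle(
            sequences=ProteinSequenceSet.from_strings(["ACD"], ids=["orphan"])
        )
        with pytest.raises(CapabilityError, match="orphan"):
            ensure_structure(bundle)


class TestEnsureWT:
    def test_present_passes_through(self):
        bundle = DataBundle(
            sequences=ProteinSequenceSet.from_strings(["ACD"]),
            wild_type=ProteinSequence("wt", "ACD"),
        )
        assert ensure_wt(bundle) is bundle

    def test_absent_rejected(self):
        with pytest.raises(CapabilityError):
            ensure_wt(as_bundle(["ACD"]))

    def test_gapped_wild_type_rejected(self):
        bundle = DataBundle(
            sequences=ProteinSequenceSet.from_strings(["ACD"]),
            wild_type=ProteinSequence("wt", "A-D"),
        )
        with pytest.raises(CapabilityError, match="gap-free"):
            ensure_wt(bundle)


class TestCompatibility:
    def test_structure_requirement_reported(self):
        caps = ModelCapabilities(requires_structure=True)
        report = check_compatibility(caps, as_bundle(["ACD"]))
        assert not report.compatible
        assert any("structure" in u for u in report.unmet)

    def test_kmer_on_bare_sequences_compatible(self):
        report = check_compatibility(KMerEmbedding(), as_bundle(["ACD", "WY"]))
        assert report.compatible

    def test_fixed_length_flagged_on_ragged(self):
        report = check_compatibility(OneHotEmbedding(), as_bundle(["ACD", "WY"]))
        assert any("fixed-length" in u for u in report.unmet)

    def test_check_never_mutates(self, toy_msa):
        bundle = DataBundle(sequences=toy_msa.members, alignment=toy_msa)
        before = (bundle.sequences, bundle.alignment, bundle.wild_type)
        check_compatibility(ModelCapabilities(requires_wt=True), bundle)
        assert (bundle.sequences, bundle.alignment, bundle.wild_type) == before

    def test_labels_validated_per_sequence(self):
        with pytest.raises(ValueError):
            DataBundle(
                sequences=ProteinSequenceSet.from_strings(["ACD", "WYV"]),
                labels=np.array([1.0]),
            )


class TestScore:
    def test_spearman_score_against_labels(self, synth_family, synth_wt):
        model = ProfileLikelihoodScorer(alpha=1.0).fit(synth_family)
        seqs = synth_family.members[:10]
        preds = model.predict(seqs)
        rho = model.score(DataBundle(sequences=seqs, labels=preds))
        assert rho == pytest.approx(1.0)

    def test_score_requires_labels(self, synth_family):
        model = ProfileLikelihoodScorer().fit(synth_family)
        with pytest.raises(ValueError, match="labels"):
            model.score(synth_family.members[:3])
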