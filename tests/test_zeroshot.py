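"""Profile fitting, likelihoods, variant deltas and marginal protocols."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from protmodel.alphabet import CANONICAL
from protmodel.exceptions import (
    ContractViolationError,
    MappingError,
    ScoreError,
    WildTypeMismatchError,
)
from protmodel.profile import ColumnProfile, fit_column_profile
from protmodel.seqio import (
    AlignedFamily,
    MutationSpec,
    ProteinSequence,
    ProteinSequenceSet,
    parse_mutation_string,
)
from protmodel.zeroshot import (
    ConditionalSequenceModel,
    MarginalLikelihoodScorer,
    ProfileConditionalModel,
    ProfileLikelihoodScorer,
    VariantScore,
    loglik,
    marginal_score,
    variant_delta_scores,
    wt_column_mapping,
)


def family(*strings: str) -> AlignedFamily:
    return AlignedFamily(members=ProteinSequenceSet.from_strings(list(strings)))


class TestFitColumnProfile:
    def test_identical_sequences_alpha_zero(self):
        prof = fit_column_profile(family("ACD", "ACD", "ACD", "ACD"), alpha=0.0)
        assert prof.frequency(0, "A") == 1.0
        assert prof.frequency(1, "C") == 1.0
        assert prof.frequency(0, "C") == 0.0

    def test_half_half_column(self):
        prof = fit_column_profile(family("A", "C"), alpha=0.0)
        assert prof.frequency(0, "A") == 0.5
        assert prof.frequency(0, "C") == 0.5

    def test_laplace_single_observation(self):
        # one sequence, alpha=1: f(A) = (1+1)/(1+21) = 2/22, others 1/22
        prof = fit_column_profile(family("A"), alpha=1.0)
        assert prof.frequency(0, "A") == pytest.approx(2 / 22)
        assert prof.frequency(0, "W") == pytest.approx(1 / 22)
        assert prof.frequency(0, "-") == pytest.approx(1 / 22)

    def test_gap_counted_as_symbol(self):
        prof = fit_column_profile(family("A", "-"), alpha=0.0)
        assert prof.frequency(0, "-") == 0.5

    def test_unknown_excluded_from_counts(self):
        prof = fit_column_profile(family("A", "X"), alpha=0.0)
        assert prof.frequency(0, "A") == 1.0  # n_j shrinks to 1

    def test_rows_always_sum_to_one(self, synth_family):
        for alpha in (0.0, 0.3, 1.0, 5.0):
            prof = fit_column_profile(synth_family, alpha=alpha)
            assert np.allclose(prof.frequencies.sum(axis=1), 1.0, atol=1e-12)

    def test_large_alpha_approaches_uniform(self, synth_family):
        prof = fit_column_profile(synth_family, alpha=1e6)
        assert np.max(np.abs(prof.frequencies - 1 / 21)) < 1e-3

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            fit_column_profile(family("A"), alpha=-1.0)

    def test_profile_invariants_enforced(self):
        with pytest.raises(ValueError):
            ColumnProfile(frequencies=np.full((2, 21), 0.5))


class TestLoglik:
    def test_training_sequence_alpha_zero_scores_zero(self):
        prof = fit_column_profile(family("ACD"), alpha=0.0)
        assert loglik(prof, "ACD") == 0.0

    def test_single_half_frequency_column(self):
        prof = fit_column_profile(family("ACD", "AWD"), alpha=0.0)
        assert loglik(prof, "ACD") == pytest.approx(math.log(0.5))

    def test_zero_frequency_advises_pseudocount(self):
        prof = fit_column_profile(family("ACD"), alpha=0.0)
        with pytest.raises(ScoreError, match="alpha > 0"):
            loglik(prof, "WCD")

    def test_unknown_positions_skipped(self, caplog):
        prof = fit_column_profile(family("ACD"), alpha=0.0)
        with caplog.at_level("WARNING", logger="protmodel"):
            assert loglik(prof, "XCD") == 0.0
        assert any("UNKNOWN_SKIPPED" in r.message for r in caplog.records)

    def test_width_mismatch_rejected(self):
        prof = fit_column_profile(family("ACD"), alpha=0.0)
        with pytest.raises(ValueError):
            loglik(prof, "AC")

    def test_equals_brute_force_log_product(self, synth_family, rng):
        """Summed log frequencies equal the logged product of per-column
        frequencies computed directly from the matrix."""
        prof = fit_column_profile(synth_family, alpha=1.0)
        for seq in synth_family.members[:5]:
            direct = math.log(
                np.prod([prof.frequency(j, ch) for j, ch in enumerate(seq.residues)])
            )
            assert loglik(prof, seq) == pytest.approx(direct, rel=1e-9)


class TestVariantDeltaScores:
    def test_empty_variant_scores_exactly_zero(self, synth_profile, synth_wt):
        scores = variant_delta_scores(synth_profile, synth_wt, [[]])
        assert scores[0].score == 0.0
        assert scores[0].variant_id == "WT"

    def test_reduced_formula_equals_full_loglik_difference(self):
        prof = fit_column_profile(
            family("ACDW", "ACDW", "AWDW", "GCDW"), alpha=1.0
        )
        wt = ProteinSequence("wt", "ACDW")
        muts = parse_mutation_string("A1G:C2W")
        [delta] = variant_delta_scores(prof, wt, [muts], mapping=[0, 1, 2, 3])
        full = loglik(prof, "GWDW") - loglik(prof, "ACDW")
        assert delta.score == pytest.approx(full, abs=1e-9)

    def test_mutation_to_more_frequent_symbol_is_positive(self):
        prof = fit_column_profile(family("W", "W", "W", "A"), alpha=0.0)
        wt = ProteinSequence("wt", "A")
        [delta] = variant_delta_scores(prof, wt, [[MutationSpec(1, "A", "W")]],
                                       mapping=[0])
        assert delta.score > 0

    def test_wild_type_mapping_from_family_membership(self):
        fam = family("A-CD", "AWCD")
        prof = fit_column_profile(fam, alpha=1.0)
        wt = ProteinSequence("wt", "ACD")  # ungapped first member
        mapping = wt_column_mapping(prof, wt, family=fam)
        assert mapping == [0, 2, 3]

    def test_insertion_position_raises_mapping_error(self, synth_profile):
        # wild type longer than the profile: some residue is an insertion
        wt = ProteinSequence("wt", synth_profile.consensus() + "W")
        mapping = wt_column_mapping(synth_profile, wt)
        ins = mapping.index(None) + 1
        wt_aa = wt.residues[ins - 1]
        mut_aa = "A" if wt_aa != "A" else "C"
        with pytest.raises(MappingError):
            variant_delta_scores(
                synth_profile, wt, [[MutationSpec(ins, wt_aa, mut_aa)]],
                mapping=mapping,
            )

    def test_mismatching_wt_residue_rejected(self, synth_profile, synth_wt):
        pos = 1
        wrong = "A" if synth_wt.residues[0] != "A" else "C"
        other = "W" if wrong != "W" else "Y"
        with pytest.raises(WildTypeMismatchError):
            variant_delta_scores(
                synth_profile, synth_wt,
                [[MutationSpec(pos, wrong, other)]],
            )

    def test_nonzero_score_for_empty_variant_rejected(self):
        with pytest.raises(ValueError):
            VariantScore("WT", (), 1.0)


class _UniformBackend(ConditionalSequenceModel):
    def residue_distribution(self, context, position, masked):
        return np.full(20, 1 / 20)


class _BrokenBackend(ConditionalSequenceModel):
    def residue_distribution(self, context, position, masked):
        return np.full(20, 1 / 19)  # does not sum to 1


class TestMarginalScore:
    @pytest.mark.parametrize("mode", ["masked", "wildtype", "mutant"])
    def test_empty_mutation_list_is_zero(self, mode, synth_wt):
        assert marginal_score(_UniformBackend(), synth_wt, [], mode) == 0.0

    def test_modes_collapse_for_context_free_backend(
        self, synth_profile, synth_wt, synth_variants
    ):
        backend = ProfileConditionalModel(synth_profile)
        variants, _ = synth_variants
        for muts in variants[:15]:
            scores = {
                mode: marginal_score(backend, synth_wt, muts, mode)
                for mode in ("masked", "wildtype", "mutant")
            }
            vals = list(scores.values())
            assert max(vals) - min(vals) < 1e-9

    def test_collapsed_modes_equal_delta_loglik(
        self, synth_profile, synth_wt, synth_variants
    ):
        backend = ProfileConditionalModel(synth_profile)
        variants, _ = synth_variants
        deltas = variant_delta_scores(
            synth_profile, synth_wt, variants, mapping=list(range(synth_profile.width))
        )
        for muts, delta in zip(variants, deltas):
            got = marginal_score(backend, synth_wt, muts, "masked")
            assert got == pytest.approx(delta.score, abs=1e-9)

    def test_disjoint_double_is_sum_of_singles(self, synth_profile, synth_wt):
        backend = ProfileConditionalModel(synth_profile)
        wt = synth_wt
        m1 = MutationSpec(1, wt.residues[0], "W" if wt.residues[0] != "W" else "Y")
        m2 = MutationSpec(5, wt.residues[4], "W" if wt.residues[4] != "W" else "Y")
        double = marginal_score(backend, wt, [m1, m2], "masked")
        singles = marginal_score(backend, wt, [m1], "masked") + marginal_score(
            backend, wt, [m2], "masked"
        )
        assert double == pytest.approx(singles, abs=1e-12)

    def test_invalid_mode_rejected(self, synth_wt):
        with pytest.raises(ValueError, match="mode"):
            marginal_score(_UniformBackend(), synth_wt, [], "argmax")

    def test_broken_backend_contract_violation(self, synth_wt):
        muts = [MutationSpec(1, synth_wt.residues[0],
                             "W" if synth_wt.residues[0] != "W" else "Y")]
        with pytest.raises(ContractViolationError):
            marginal_score(_BrokenBackend(), synth_wt, muts, "masked")


class TestScorerEstimators:
    def test_profile_scorer_rank_consistency(
        self, synth_profile, synth_wt, synth_variants
    ):
        variants, labels = synth_variants
        scores = variant_delta_scores(
            synth_profile, synth_wt, variants,
            mapping=list(range(synth_profile.width)),
        )
        rho = spearmanr([s.score for s in scores], labels).statistic
        assert rho == 1.0

    def test_predict_aligns_off_width_sequences(self, synth_family):
        model = ProfileLikelihoodScorer(alpha=1.0).fit(synth_family)
        wt_like, _ = __import__("protmodel").ungap(synth_family.members[0])
        out = model.predict(ProteinSequenceSet([wt_like]))
        assert np.isfinite(out).all()

    def test_marginal_scorer_predict_matches_score_mutations(
        self, synth_family, synth_wt
    ):
        from protmodel.model_core import DataBundle
        from protmodel.seqio import apply_mutations

        model = MarginalLikelihoodScorer(mode="wildtype")
        model.fit(
            DataBundle(
                sequences=synth_family.members,
                alignment=synth_family,
                wild_type=synth_wt,
            )
        )
        muts = [MutationSpec(2, synth_wt.residues[1],
                             "W" if synth_wt.residues[1] != "W" else "Y")]
        via_seq = model.predict(ProteinSequenceSet([apply_mutations(synth_wt, muts)]))
        via_muts = model.score_mutations([muts])
        assert via_seq[0] == pytest.approx(via_muts[0], abs=1e-12)
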