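"""Permutation importance and fusion-layer heatmaps."""

import numpy as np
import pytest

from capsmhc.interpret import (
    capture_heatmap,
    importance_profile,
    permutation_importance,
    routing_state_of,
    top_positions,
)
from capsmhc.model import CapsNetMHC
from capsmhc.network import ConfigurationError, squash
from capsmhc.records import BindingRecord


def _stratum(records, k):
    return [r for r in records if len(r.peptide) == k]


@pytest.fixture(scope="module")
def stratum9(small_labelled):
    binary, _, _, _ = small_labelled
    recs = _stratum(binary, 9)
    assert len({int(r.value) for r in recs}) == 2
    return recs


class TestPermutationImportance:
    def test_position_out_of_range(self, trained_small_model, stratum9):
        with pytest.raises(ValueError):
            permutation_importance(trained_small_model, stratum9, position=10)

    def test_mixed_lengths_rejected(self, trained_small_model, small_labelled):
        binary, _, _, _ = small_labelled
        with pytest.raises(ValueError):
            permutation_importance(trained_small_model, binary, position=1)

    def test_single_class_stratum_is_nan(self, trained_small_model, stratum9):
        positives = [r for r in stratum9 if r.value == 1]
        sc = permutation_importance(trained_small_model, positives, position=2)
        assert np.isnan(sc.score)

    def test_deterministic_under_seed(self, trained_small_model, stratum9):
        a = permutation_importance(trained_small_model, stratum9, 2, n_repeats=3, seed=5)
        b = permutation_importance(trained_small_model, stratum9, 2, n_repeats=3, seed=5)
        assert a == b

    def test_constant_column_scores_exactly_zero(self, trained_small_model, stratum9):
        # force a constant residue at position 5: the permutation is an identity
        recs = [
            BindingRecord(r.peptide[:4] + "G" + r.peptide[5:], r.allele, "binary", r.value)
            for r in stratum9
        ]
        sc = permutation_importance(trained_small_model, recs, position=5, n_repeats=3)
        assert sc.score == 0.0 and sc.dispersion == 0.0

    def test_peptide_insensitive_model_scores_near_zero(self, allele_table, stratum9):
        # an untrained zero-weight model scores every record 0.5: shuffling
        # peptide residues cannot move the (tie-corrected) AUC at all
        est = CapsNetMHC(allele_table=allele_table, epochs=0, random_state=0)
        pairs = [(r.peptide, r.allele) for r in stratum9]
        est.fit(pairs, np.array([float(r.value) for r in stratum9]))
        est.core_.set_all_weights(0.0)
        sc = permutation_importance(est, stratum9, position=2, n_repeats=3)
        assert sc.score == pytest.approx(0.0, abs=1e-12)

    def test_dispersion_shrinks_with_more_repeats(self, trained_small_model, stratum9):
        few = [
            permutation_importance(
                trained_small_model, stratum9, 3, n_repeats=5, seed=s
            ).score
            for s in range(6)
        ]
        many = [
            permutation_importance(
                trained_small_model, stratum9, 3, n_repeats=50, seed=s
            ).score
            for s in range(6)
        ]
        assert np.std(many) < np.std(few)


class TestImportanceProfile:
    def test_single_length_table_has_k_rows(self, trained_small_model, stratum9):
        prof = importance_profile(trained_small_model, stratum9, n_repeats=2)
        assert len(prof) == 9
        assert list(prof["position"]) == list(range(1, 10))

    def test_profile_deterministic(self, trained_small_model, stratum9):
        a = importance_profile(trained_small_model, stratum9, n_repeats=2, seed=3)
        b = importance_profile(trained_small_model, stratum9, n_repeats=2, seed=3)
        assert a.equals(b)

    def test_covers_all_available_lengths(self, trained_small_model, small_labelled):
        binary, _, _, _ = small_labelled
        some = [r for r in binary if len(r.peptide) in (8, 9)]
        prof = importance_profile(trained_small_model, some, n_repeats=1)
        assert set(prof["length"]) == {8, 9}


class TestHeatmaps:
    def test_capsule_heatmap_shape_and_squash_consistency(
        self, trained_small_model, stratum9
    ):
        rec = stratum9[0]
        hm = capture_heatmap(trained_small_model, rec.peptide, rec.allele, "capsule")
        assert hm.values.shape == (16, 16)
        state = routing_state_of(trained_small_model, rec.peptide, rec.allele)
        assert np.allclose(squash(state.s, axis=-1)[None], state.v[None], atol=1e-6)
        assert np.allclose(hm.values, state.v)
        assert np.all(np.linalg.norm(state.v, axis=-1) < 1.0)

    def test_zero_weight_model_gives_zero_heatmap(self, allele_table, stratum9):
        est = CapsNetMHC(allele_table=allele_table, epochs=0, random_state=0)
        rec = stratum9[0]
        est.fit([(rec.peptide, rec.allele)], np.array([1.0]))
        est.core_.set_all_weights(0.0)
        hm = capture_heatmap(est, rec.peptide, rec.allele, "capsule")
        assert np.allclose(hm.values, 0.0)

    def test_mode_model_mismatch_rejected(self, trained_small_model, stratum9):
        rec = stratum9[0]
        with pytest.raises(ConfigurationError):
            capture_heatmap(trained_small_model, rec.peptide, rec.allele, "concat")
        with pytest.raises(ConfigurationError):
            capture_heatmap(trained_small_model, rec.peptide, rec.allele, "saliency")

    def test_concat_heatmap_reshapes_the_440_latent(self, allele_table, stratum9):
        est = CapsNetMHC(allele_table=allele_table, fusion="concat", epochs=1, random_state=0)
        pairs = [(r.peptide, r.allele) for r in stratum9[:20]]
        est.fit(pairs, np.array([float(r.value) for r in stratum9[:20]]))
        hm = capture_heatmap(est, *pairs[0], "concat")
        assert hm.values.shape == (40, 11) and hm.values.size == 440

    def test_conv_heatmap_is_final_feature_map(self, allele_table, stratum9):
        est = CapsNetMHC(allele_table=allele_table, fusion="conv", epochs=1, random_state=0)
        pairs = [(r.peptide, r.allele) for r in stratum9[:20]]
        est.fit(pairs, np.array([float(r.value) for r in stratum9[:20]]))
        hm = capture_heatmap(est, *pairs[0], "conv")
        assert hm.values.shape == (20, 20)

    def test_same_allele_heatmaps_more_alike_than_across_alleles(
        self, trained_small_model, small_labelled
    ):
        """The overall capsule pattern is dominated by the HLA allele:
        averaged over peptide pairs, heatmaps correlate more within an
        allele than across alleles."""
        import itertools

        binary, _, _, _ = small_labelled
        alleles = sorted({r.allele for r in binary})
        peps = {a: [r.peptide for r in binary if r.allele == a][:5] for a in alleles}
        h = {
            (a, p): capture_heatmap(trained_small_model, p, a, "capsule").values.ravel()
            for a in alleles
            for p in peps[a]
        }
        within = [
            np.corrcoef(h[(a, p1)], h[(a, p2)])[0, 1]
            for a in alleles
            for p1, p2 in itertools.combinations(peps[a], 2)
        ]
        across = [
            np.corrcoef(h[(alleles[0], p1)], h[(alleles[1], p2)])[0, 1]
            for p1 in peps[alleles[0]]
            for p2 in peps[alleles[1]]
        ]
        assert np.mean(within) > np.mean(across)
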