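import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sibpen import (
    AscertainmentModel,
    Dataset,
    Sibship,
    TraitModel,
    TwoLocusModel,
    combined_penetrance,
    normalizing_constant,
)


class TestTraitModel:
    def test_beta_independent_causes(self):
        # exact: 0.5 + 0.5 - 0.25
        assert TraitModel(f=0.5, gamma=0.5).beta == pytest.approx(0.75, abs=0)

    def test_beta_no_phenocopies(self):
        assert TraitModel(f=0.3).beta == pytest.approx(0.3, abs=0)

    def test_combined_penetrance_matches_property(self):
        trait = TraitModel(f=0.2, gamma=0.05)
        assert combined_penetrance(trait) == trait.beta

    @pytest.mark.parametrize("bad", [{"f": -0.1}, {"f": 1.5}, {"f": 0.5, "gamma": 1.0}])
    def test_invalid_probabilities_rejected(self, bad):
        with pytest.raises(ValueError):
            TraitModel(**bad)

    @given(f=st.floats(0, 1), gamma=st.floats(0, 0.999))
    def test_beta_bounds(self, f, gamma):
        beta = TraitModel(f=f, gamma=gamma).beta
        assert max(f, gamma) - 1e-12 <= beta <= 1.0 + 1e-12


class TestNormalizingConstant:
    # oracle: independent direct enumeration over the (r, t) triangle
    @staticmethod
    def _oracle(k, s):
        best = 0.0
        for t in range(1, s + 1):
            for r in range(1, t + 1):
                best = max(best, r**k + t)
        return 1.0 / best

    @pytest.mark.parametrize("k", [-2.0, -1.0, 0.0, 0.5, 1.0, 2.0, 3.0])
    @pytest.mark.parametrize("s", [1, 2, 3, 5, 8])
    def test_matches_oracle(self, k, s):
        assert normalizing_constant(k, s) == pytest.approx(self._oracle(k, s), rel=1e-12)

    def test_known_values_s2(self):
        # max weight cells for s=2: k=1 -> (2,2): 4; k=0 -> (1,2): 3;
        # k=2 -> (2,2): 6; k=-1 -> (1,2): 1 + 2 = 3 (not (2,2): 2.5)
        assert normalizing_constant(1.0, 2) == pytest.approx(0.25)
        assert normalizing_constant(0.0, 2) == pytest.approx(1 / 3)
        assert normalizing_constant(2.0, 2) == pytest.approx(1 / 6)
        assert normalizing_constant(-1.0, 2) == pytest.approx(1 / 3)

    def test_invalid_s(self):
        with pytest.raises(ValueError):
            normalizing_constant(1.0, 0)

    @given(k=st.floats(-3, 3), s=st.integers(1, 10))
    @settings(max_examples=60)
    def test_all_weights_are_probabilities(self, k, s):
        c = normalizing_constant(k, s)
        asc = AscertainmentModel(k=k, c=c)
        for t in range(1, s + 1):
            for r in range(1, t + 1):
                prob = asc.acceptance_probability(r, t, s)
                assert 0.0 <= prob <= 1.0 + 1e-12


class TestAscertainmentModel:
    def test_r_zero_never_ascertained(self):
        asc = AscertainmentModel(k=1.0)
        assert asc.acceptance_probability(0, 2, 2) == 0.0

    def test_single_ascertainment_weight(self):
        asc = AscertainmentModel(k=1.0)
        # c = 1/4 for s=2; weight for (r=1, t=1) is (1 + 1)/4
        assert asc.acceptance_probability(1, 1, 2) == pytest.approx(0.5)
        assert asc.acceptance_probability(2, 2, 2) == pytest.approx(1.0)

    def test_explicit_c_too_large_rejected(self):
        asc = AscertainmentModel(k=1.0, c=0.5)
        with pytest.raises(ValueError):
            asc.constant_for(2)

    def test_invalid_r_t(self):
        with pytest.raises(ValueError):
            AscertainmentModel(k=1.0).acceptance_probability(2, 1, 2)


class TestSibship:
    def test_counts(self):
        sib = Sibship(np.array([1, 1, 0], bool), np.array([1, 0, 1], bool), proband_index=0)
        assert (sib.s, sib.r, sib.t) == (3, 1, 2)

    def test_proband_must_be_qi(self):
        with pytest.raises(ValueError):
            Sibship(np.array([1, 0], bool), np.array([0, 1], bool), proband_index=0)

    def test_sib_states_sorted(self):
        sib = Sibship(np.array([1, 0], bool), np.array([1, 0], bool))
        assert sib.sib_states() == (0, 3)


class TestDataset:
    def test_config_counts(self):
        sibs = [
            Sibship(np.array([1, 0], bool), np.array([1, 0], bool), 0),
            Sibship(np.array([0, 1], bool), np.array([0, 1], bool), 1),
            Sibship(np.array([1, 1], bool), np.array([1, 1], bool), 0),
        ]
        counts = Dataset.from_sibships(sibs).config_counts()
        assert counts == {(0, 3): 2, (3, 3): 1}

    def test_mixed_sizes_rejected(self):
        sibs = [
            Sibship(np.array([1], bool), np.array([1], bool), 0),
            Sibship(np.array([1, 0], bool), np.array([1, 0], bool), 0),
        ]
        with pytest.raises(ValueError):
            Dataset.from_sibships(sibs)

    def test_bad_proband_rejected(self):
        with pytest.raises(ValueError):
            Dataset(
                np.array([[True, False]]),
                np.array([[False, True]]),
                np.array([0]),
            )


class TestTwoLocusModel:
    def test_haplotype_frequencies_sum_to_one(self):
        model = TwoLocusModel(p=0.01, q=0.02, dprime=0.7)
        freqs = model.haplotype_frequencies()
        assert freqs.sum() == pytest.approx(1.0, rel=1e-12)
        assert np.all(freqs >= 0)

    def test_complete_ld_rare_alleles(self):
        # p = q, D' = 1 puts all V haplotypes on D: hVd = 0
        freqs = TwoLocusModel(p=0.001, q=0.001, dprime=1.0).haplotype_frequencies()
        assert freqs[1] == pytest.approx(0.0, abs=1e-15)
        assert freqs[0] == pytest.approx(0.001, rel=1e-9)

    def test_no_ld_factorizes(self):
        p, q = 0.01, 0.03
        freqs = TwoLocusModel(p=p, q=q, dprime=0.0).haplotype_frequencies()
        assert freqs[0] == pytest.approx(p * q, rel=1e-12)

    def test_replace(self):
        model = TwoLocusModel()
        assert model.replace(dprime=0.0).dprime == 0.0
        assert model.dprime == 1.0

    @pytest.mark.parametrize(
        "kwargs", [{"theta": 0.6}, {"dprime": 1.2}, {"penetrances": (0.5, 0.5)}, {"alpha": -0.1}]
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            TwoLocusModel(**kwargs)
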