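import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sibpen import (
    AscertainmentModel,
    Sibship,
    TraitModel,
    TwoLocusModel,
    dataset_log_likelihood,
    family_likelihood,
    ld_lod,
    le_lod,
    maximize_ld_lod,
    simulate_dataset,
)
from sibpen.models import Dataset
from tests.conftest import make_dataset


def oracle_family_likelihood(carrier, affected, model, theta=None):
    """Independent brute-force two-locus family likelihood.

    Enumerates the disease alleles on the four parental haplotypes (the Vv
    parent's V- and v-haplotypes, the vv parent's two haplotypes) with
    probabilities conditional on their marker alleles, then for each sib sums
    over parental gametes with recombination. Written without any shared code
    with the production implementation.
    """
    p, q = model.p, model.q
    theta = model.theta if theta is None else theta
    hVD, hVd, hvD, hvd = np.clip(model.haplotype_frequencies(), 0.0, None)
    pD_given_V = hVD / (hVD + hVd)
    pD_given_v = hvD / (hvD + hvd)
    f_DD, f_Dd, f_dd = model.penetrances
    pen = {2: f_DD, 1: f_Dd, 0: f_dd}

    total = 0.0
    # a, b: D-allele indicator on the Vv parent's V / v haplotype
    # e, g: D-allele indicators on the vv parent's haplotypes
    for a, b, e, g in product((0, 1), repeat=4):
        w = (
            (pD_given_V if a else 1 - pD_given_V)
            * (pD_given_v if b else 1 - pD_given_v)
            * (pD_given_v if e else 1 - pD_given_v)
            * (pD_given_v if g else 1 - pD_given_v)
        )
        fam = 1.0
        for c, aff in zip(carrier, affected):
            sib = 0.0
            # gametes from the Vv parent: (marker is V, disease allele, prob)
            for mk, dis, pg in (
                (1, a, (1 - theta) / 2),
                (0, b, (1 - theta) / 2),
                (1, b, theta / 2),
                (0, a, theta / 2),
            ):
                if mk != int(c):
                    continue
                for dis2 in (e, g):
                    geno = dis + dis2
                    prob_aff = pen[geno]
                    sib += pg * 0.5 * (prob_aff if aff else 1 - prob_aff)
            fam *= sib
        total += w * fam
    return total


def random_model(rng):
    return TwoLocusModel(
        p=float(rng.uniform(0.0005, 0.2)),
        q=float(rng.uniform(0.0005, 0.2)),
        dprime=float(rng.uniform(0, 1)),
        theta=float(rng.uniform(0, 0.5)),
        penetrances=tuple(rng.uniform(0, 1, 3)),
        alpha=1.0,
    )


class TestFamilyLikelihoodOracle:
    @given(seed=st.integers(0, 10_000), s=st.integers(1, 3))
    @settings(max_examples=60, deadline=None)
    def test_equals_bruteforce(self, seed, s):
        rng = np.random.default_rng(seed)
        model = random_model(rng)
        carrier = rng.random(s) < 0.5
        affected = rng.random(s) < 0.5
        got = family_likelihood(Sibship(carrier, affected), model)
        want = oracle_family_likelihood(carrier, affected, model)
        assert got == pytest.approx(want, rel=1e-12, abs=1e-300)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_normalizes_over_all_configurations(self, seed):
        rng = np.random.default_rng(seed)
        model = random_model(rng)
        s = 2
        total = 0.0
        for states in product((0, 1), repeat=2 * s):
            carrier = np.array(states[:s], bool)
            affected = np.array(states[s:], bool)
            total += family_likelihood(Sibship(carrier, affected), model)
        assert total == pytest.approx(1.0, rel=1e-10)

    def test_unlinked_evaluation(self):
        model = TwoLocusModel(penetrances=(0.7, 0.7, 0.1))
        sib = Sibship(np.array([True, False]), np.array([True, True]))
        got = family_likelihood(sib, model, linked=False)
        want = oracle_family_likelihood(
            [True, False], [True, True], model.replace(dprime=0.0), theta=0.5
        )
        assert got == pytest.approx(want, rel=1e-12)


class TestHandDerivedValues:
    """Closed-form checks at p = q -> 0, D' = 1, theta = 0."""

    def qiqi(self):
        return make_dataset([((1, 1), (1, 1))])

    def test_linked_qi_qi(self):
        # carrier sibs are Dd with certainty; P = (f/2)^2 per sib pair
        model = TwoLocusModel(penetrances=(0.5, 0.5, 0.0))
        sib = Sibship(np.array([True, True]), np.array([True, True]))
        assert family_likelihood(sib, model) == pytest.approx(0.0625, rel=1e-6)

    def test_ld_lod_full_penetrance(self):
        # ld_lod for one (QI, QI) family at f = 1, alpha = 1: log10(4)
        model = TwoLocusModel(penetrances=(1.0, 1.0, 0.0), alpha=1.0)
        assert ld_lod(self.qiqi(), model) == pytest.approx(math.log10(4), abs=1e-3)

    def test_le_lod_qi_qi(self):
        # LE-LOD for one (QI, QI) family at f=1: log10(1.5) as q -> 0
        model = TwoLocusModel(penetrances=(1.0, 1.0, 0.0), alpha=1.0)
        assert le_lod(self.qiqi(), model) == pytest.approx(math.log10(1.5), abs=1e-3)

    def test_lod_zero_when_alpha_zero(self):
        model = TwoLocusModel(penetrances=(0.9, 0.8, 0.1), alpha=0.0)
        assert ld_lod(self.qiqi(), model) == pytest.approx(0.0, abs=1e-12)

    def test_lod_zero_at_null_model(self):
        model = TwoLocusModel(theta=0.5, penetrances=(0.9, 0.8, 0.1), alpha=1.0)
        assert ld_lod(self.qiqi(), model) == pytest.approx(0.0, abs=1e-12)


class TestLodProperties:
    def test_additivity_across_families(self, rng, single_ascertainment):
        trait = TraitModel(f=0.5, gamma=0.1)
        d = simulate_dataset(trait, single_ascertainment, 2, 40, rng)
        model = TwoLocusModel(penetrances=(0.6, 0.6, 0.1), alpha=0.9)
        first = Dataset(d.carrier[:25], d.affected[:25], d.proband_index[:25])
        second = Dataset(d.carrier[25:], d.affected[25:], d.proband_index[25:])
        assert ld_lod(d, model) == pytest.approx(
            ld_lod(first, model) + ld_lod(second, model), rel=1e-10
        )

    def test_log_likelihood_matches_manual_sum(self, rng, single_ascertainment):
        d = simulate_dataset(TraitModel(f=0.5), single_ascertainment, 2, 10, rng)
        model = TwoLocusModel(penetrances=(0.5, 0.5, 0.05), alpha=1.0)
        manual = sum(math.log10(family_likelihood(sib, model)) for sib in d.sibships())
        assert dataset_log_likelihood(d, model) == pytest.approx(manual, rel=1e-10)


class TestMaximizeLdLod:
    def test_mod_at_least_lod_at_generating_model(self, rng, single_ascertainment):
        trait = TraitModel(f=0.5, gamma=0.1)
        d = simulate_dataset(trait, single_ascertainment, 2, 100, rng)
        gen_model = TwoLocusModel(
            penetrances=(trait.beta, trait.beta, trait.gamma), alpha=1.0
        )
        fit = maximize_ld_lod(d)
        assert fit.ld_mod >= ld_lod(d, gen_model) - 1e-9
        assert 0.0 <= fit.f_hat <= 1.0
        assert fit.argmax.penetrances[1] == fit.f_hat

    def test_bias_shrinks_with_sample_size(self, single_ascertainment):
        """f_hat consistency: mean bias at N=400 well below the N=20 bias."""
        trait = TraitModel(f=0.05, gamma=0.0)
        rng = np.random.default_rng(77)
        small = [
            maximize_ld_lod(simulate_dataset(trait, single_ascertainment, 2, 20, rng)).f_hat
            for _ in range(60)
        ]
        large = [
            maximize_ld_lod(simulate_dataset(trait, single_ascertainment, 2, 400, rng)).f_hat
            for _ in range(30)
        ]
        bias_small = abs(np.mean(small) - trait.f)
        bias_large = abs(np.mean(large) - trait.f)
        assert bias_large < 0.5 * bias_small

    def test_le_lod_max_matches_le_lod_at_argmax(self, rng, single_ascertainment):
        d = simulate_dataset(TraitModel(f=0.5), single_ascertainment, 2, 50, rng)
        fit = maximize_ld_lod(d)
        assert fit.le_lod_max == pytest.approx(le_lod(d, fit.argmax), rel=1e-9)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            maximize_ld_lod(
                Dataset(np.empty((0, 2), bool), np.empty((0, 2), bool), np.empty(0, np.int64))
            )
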