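import numpy as np
import pytest

from sibpen import AscertainmentModel, Dataset, Sibship, TraitModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_ascertainment():
    return AscertainmentModel(k=1.0)


@pytest.fixture
def trait_half():
    return TraitModel(f=0.5, gamma=0.0)


def make_dataset(rows, probands=None):
    """Build a Dataset from per-family (carrier, affected) sib-tuples.

    ``rows`` is a list of (carrier_tuple, affected_tuple); ``probands`` a list
    of per-family proband indices (default: first QI in each family).
    """
    sibships = []
    for i, (carrier, affected) in enumerate(rows):
        if probands is None:
            qi = [j for j, (c, a) in enumerate(zip(carrier, affected)) if c and a]
            proband = qi[0] if qi else None
        else:
            proband = probands[i]
        sibships.append(Sibship(np.array(carrier, bool), np.array(affected, bool), proband))
    return Dataset.from_sibships(sibships)
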