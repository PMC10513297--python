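"""Counting estimators of attributable penetrance and their exact expectations.

Two moment-style estimators are computed from carrier/affection status alone
(parents are treated as phenotypically and genotypically unknown here):

* ``f_tilde`` -- the classical single-ascertainment correction: drop the
  designated proband from each family, then take the proportion affected
  among the remaining carrier sibs. Families with no remaining carrier do
  not contribute, effectively shrinking the sample.
* ``f_tilde_star`` -- the naive estimate with no ascertainment correction:
  the proportion affected among all carrier sibs, proband included.

Per-family proportions are averaged across families (each family weighted
equally); a pooled variant that aggregates counts across the whole dataset
before dividing is available via ``pooled=True`` for comparison.

``expected_estimates_exact`` is the brute-force oracle: it enumerates all
``4**s`` per-sib configurations, weights each by its population probability
times the ascertainment weight, and returns the exact expectations of both
estimators under the generating model.
"""

from __future__ import annotations

from itertools import product
from math import prod
from typing import NamedTuple

import numpy as np

from .models import AscertainmentModel, Dataset, TraitModel

__all__ = ["EstimateResult", "f_tilde", "f_tilde_star", "expected_estimates_exact"]

_MAX_ENUMERABLE_S = 12


class EstimateResult(NamedTuple):
    """A point estimate plus the number of families that could not be scored."""

    estimate: float
    n_noncontributing: int


def f_tilde(dataset: Dataset, pooled: bool = False) -> EstimateResult:
    """Single-ascertainment-corrected penetrance estimate.

    Drops the designated proband (one QI per family) and scores the
    proportion affected among remaining carrier sibs. Returns NaN (with the
    exclusion count) when no family contributes.
    """
    if np.any(dataset.proband_index < 0):
        raise ValueError("f_tilde requires a designated proband in every family")
    n_carrier = dataset.carrier.sum(axis=1)
    n_qi = (dataset.carrier & dataset.affected).sum(axis=1)
    # the proband is always a QI, so after the drop the family holds
    # n_carrier - 1 carriers of whom n_qi - 1 are affected
    contributes = n_carrier >= 2
    n_excluded = int((~contributes).sum())
    if not np.any(contributes):
        return EstimateResult(float("nan"), n_excluded)
    num = (n_qi[contributes] - 1).astype(float)
    den = (n_carrier[contributes] - 1).astype(float)
    if pooled:
        return EstimateResult(float(num.sum() / den.sum()), n_excluded)
    return EstimateResult(float(np.mean(num / den)), n_excluded)


def f_tilde_star(dataset: Dataset, pooled: bool = False) -> EstimateResult:
    """Naive penetrance estimate: proportion affected among all carrier sibs.

    Every ascertained family has at least one carrier (its QI), so in
    ascertained data all families contribute and the estimate is bounded
    below by 1/s.
    """
    n_carrier = dataset.carrier.sum(axis=1)
    n_qi = (dataset.carrier & dataset.affected).sum(axis=1)
    contributes = n_carrier >= 1
    n_excluded = int((~contributes).sum())
    if not np.any(contributes):
        return EstimateResult(float("nan"), n_excluded)
    num = n_qi[contributes].astype(float)
    den = n_carrier[contributes].astype(float)
    if pooled:
        return EstimateResult(float(num.sum() / den.sum()), n_excluded)
    return EstimateResult(float(np.mean(num / den)), n_excluded)


def expected_estimates_exact(
    trait: TraitModel, asc: AscertainmentModel, s: int, pooled: bool = False
) -> tuple[float, float]:
    """Exact ascertainment-weighted expectations of f_tilde and f_tilde_star.

    Enumerates all ``4**s`` joint (carrier, affected) sib configurations,
    weights each by its generating probability times ``(r**k + t)`` for
    ``r >= 1``, renormalizes, and averages the per-family proportions over
    contributing configurations. Because the post-drop proportion
    ``(r-1)/(carriers-1)`` is the same whichever QI is designated proband,
    averaging over the uniformly random proband choice is implicit. With
    ``pooled=True`` the large-N limit of the pooled (count-aggregating)
    variant is returned instead.
    """
    s = int(s)
    if s < 1:
        raise ValueError(f"s must be >= 1, got {s}")
    if s > _MAX_ENUMERABLE_S:
        raise ValueError(f"enumeration is guarded at s <= {_MAX_ENUMERABLE_S}, got {s}")
    beta, gamma = trait.beta, trait.gamma
    # per-sib states (carrier, affected) with population probabilities
    state_prob = {
        (True, True): 0.5 * beta,
        (True, False): 0.5 * (1.0 - beta),
        (False, True): 0.5 * gamma,
        (False, False): 0.5 * (1.0 - gamma),
    }
    num_t = den_t = 0.0  # f_tilde, over configs with >= 2 carriers
    num_s = den_s = 0.0  # f_tilde_star, over configs with >= 1 carrier
    any_ascertainable = False
    for config in product(state_prob, repeat=s):
        p_config = prod(state_prob[st] for st in config)
        if p_config == 0.0:
            continue
        n_carrier = sum(c for c, _ in config)
        r = sum(1 for c, a in config if c and a)
        t = sum(1 for _, a in config if a)
        if r < 1:
            continue
        any_ascertainable = True
        w = p_config * (float(r) ** asc.k + t)
        if pooled:
            num_s += w * r
            den_s += w * n_carrier
        else:
            num_s += w * (r / n_carrier)
            den_s += w
        if n_carrier >= 2:
            if pooled:
                num_t += w * (r - 1)
                den_t += w * (n_carrier - 1)
            else:
                num_t += w * ((r - 1) / (n_carrier - 1))
                den_t += w
    if not any_ascertainable:
        raise ValueError("no configuration is ascertainable under this model")
    e_tilde = num_t / den_t if den_t > 0 else float("nan")
    e_star = num_s / den_s if den_s > 0 else float("nan")
    return e_tilde, e_star
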