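"""Sibship simulation under the generalized k-model of ascertainment.

Datasets are produced by rejection sampling: sibships are drawn from the
population model and accepted with probability ``c * (r**k + t)`` (zero when
``r = 0``), which realizes the ascertainment distribution exactly for any
``k`` without algebra. Each accepted family gets a proband drawn uniformly
at random among its qualifying individuals.

Two generators are provided: the co-segregation generator, in which the
marker carrier parent also carries the causal allele (complete coupling),
and a null generator, in which phenotypes are driven by a causal locus
unlinked to the marker, so within-family marker-phenotype association is
purely ascertainment-induced.
"""

from __future__ import annotations

import numpy as np

from .models import AscertainmentModel, Dataset, Sibship, TraitModel

__all__ = [
    "simulate_sibship",
    "ascertain",
    "simulate_dataset",
    "simulate_null_dataset",
]


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def simulate_sibship(
    trait: TraitModel, s: int, rng: np.random.Generator | int | None = None
) -> Sibship:
    """Draw one (unascertained) sibship from the population model.

    Each sib independently inherits the variant from the single heterozygous
    carrier parent with probability 1/2; carriers are affected with
    probability ``beta = gamma + f - gamma*f`` and non-carriers with
    probability ``gamma``.
    """
    rng = _as_rng(rng)
    s = int(s)
    if s < 1:
        raise ValueError(f"sibship size s must be >= 1, got {s}")
    carrier = rng.random(s) < 0.5
    p_aff = np.where(carrier, trait.beta, trait.gamma)
    affected = rng.random(s) < p_aff
    return Sibship(carrier, affected)


def ascertain(
    sibship: Sibship,
    asc: AscertainmentModel,
    rng: np.random.Generator | int | None = None,
) -> bool:
    """Bernoulli ascertainment with probability ``c * (r**k + t)`` for r >= 1."""
    rng = _as_rng(rng)
    prob = asc.acceptance_probability(sibship.r, sibship.t, sibship.s)
    return bool(rng.random() < prob)


def _draw_accepted(
    trait: TraitModel,
    asc: AscertainmentModel,
    s: int,
    N: int,
    rng: np.random.Generator,
    *,
    null: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized rejection sampling; returns (carrier, affected) of N accepted families."""
    c = asc.constant_for(s)
    beta, gamma = trait.beta, trait.gamma
    if beta == 0.0:
        raise ValueError(
            "no sibship can ever be ascertained: with f=0 and gamma=0 no "
            "carrier is ever affected, so r >= 1 is unattainable"
        )
    # rough acceptance rate to size the first batch; refined adaptively
    p_qi = 0.5 * beta
    rate_guess = max(c * (1.0 - (1.0 - p_qi) ** s), 1e-6)
    carriers, affecteds = [], []
    have = 0
    while have < N:
        need = N - have
        batch = int(min(max(2048, need / rate_guess * 1.5), 4_000_000))
        carrier = rng.random((batch, s)) < 0.5
        if null:
            causal = rng.random((batch, s)) < 0.5
            affected = rng.random((batch, s)) < np.where(causal, beta, gamma)
        else:
            affected = rng.random((batch, s)) < np.where(carrier, beta, gamma)
        r = (carrier & affected).sum(axis=1)
        t = affected.sum(axis=1)
        # r = 0 families are never ascertained; keep r**k off them (k may be < 0)
        weight = np.zeros(batch)
        asc_ok = r >= 1
        weight[asc_ok] = c * (r[asc_ok].astype(float) ** asc.k + t[asc_ok])
        keep = rng.random(batch) < weight
        n_kept = int(keep.sum())
        if n_kept:
            carriers.append(carrier[keep])
            affecteds.append(affected[keep])
            have += n_kept
        rate_guess = max(0.5 * rate_guess, min(1.0, (n_kept + 1) / batch))
    carrier = np.concatenate(carriers)[:N]
    affected = np.concatenate(affecteds)[:N]
    return carrier, affected


def _draw_probands(
    carrier: np.ndarray, affected: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Uniformly random QI per family (every family is guaranteed r >= 1)."""
    qi = carrier & affected
    r = qi.sum(axis=1)
    pick = (rng.random(qi.shape[0]) * r).astype(np.int64)
    # stable argsort puts QI column indices (ascending) in the first r slots
    order = np.argsort(~qi, axis=1, kind="stable")
    return order[np.arange(qi.shape[0]), pick]


def _simulate(
    trait: TraitModel,
    asc: AscertainmentModel,
    s: int,
    N: int,
    rng: np.random.Generator | int | None,
    *,
    null: bool,
) -> Dataset:
    if int(N) < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    seed = rng if not isinstance(rng, np.random.Generator) else None
    rng = _as_rng(rng)
    carrier, affected = _draw_accepted(trait, asc, int(s), int(N), rng, null=null)
    proband = _draw_probands(carrier, affected, rng)
    provenance = {
        "f": trait.f,
        "gamma": trait.gamma,
        "k": asc.k,
        "c": asc.constant_for(int(s)),
        "s": int(s),
        "N": int(N),
        "null": bool(null),
        "seed": seed,
    }
    return Dataset(carrier, affected, proband, provenance)


def simulate_dataset(
    trait: TraitModel,
    asc: AscertainmentModel,
    s: int,
    N: int,
    rng: np.random.Generator | int | None = None,
) -> Dataset:
    """N ascertained sibships with the variant in complete coupling with disease."""
    return _simulate(trait, asc, s, N, rng, null=False)


def simulate_null_dataset(
    trait: TraitModel,
    asc: AscertainmentModel,
    s: int,
    N: int,
    rng: np.random.Generator | int | None = None,
) -> Dataset:
    """N ascertained sibships generated under no linkage and no disequilibrium.

    Phenotypes are driven by a causal locus unlinked to the marker: the
    marker-carrier parent is heterozygous at that locus and sibs inherit it
    with probability 1/2 independently of the marker. Trait parameters (f,
    gamma) and the QI-based ascertainment rule are unchanged, so the marker
    is phenotypically neutral but families still enter through a
    marker-carrying affected sib.
    """
    return _simulate(trait, asc, s, N, rng, null=True)
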