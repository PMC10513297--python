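"""Core domain types for penetrance estimation in ascertained sibships.

The scientific setting: a very rare variant of interest (VOI) acting as an
autosomal dominant risk allele. Families are nuclear sibships recruited
*because* they contain at least one qualifying individual (QI) -- a sib who
is both a VOI heterozygote and affected -- with recruitment probability
depending on the number of QIs (``r``) and the number of affected sibs
(``t``) through a generalized k-model weight ``c * (r**k + t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "TraitModel",
    "AscertainmentModel",
    "Sibship",
    "Dataset",
    "TwoLocusModel",
    "ReplicateSummary",
    "combined_penetrance",
    "normalizing_constant",
]


def _check_probability(name: str, value: float, *, closed_top: bool = True) -> float:
    value = float(value)
    hi_ok = value <= 1.0 if closed_top else value < 1.0
    if not (0.0 <= value and hi_ok):
        top = "1" if closed_top else "1)"
        raise ValueError(f"{name} must be a probability in [0, {top}], got {value!r}")
    return value


@dataclass(frozen=True)
class TraitModel:
    """Generating trait model for a rare dominant variant.

    Parameters
    ----------
    f : float
        Attributable penetrance: probability that a heterozygous carrier is
        affected *due to the variant itself*.
    gamma : float
        Combined penetrance of all causes other than the variant. Because the
        variant is assumed very rare, ``gamma`` is effectively the population
        prevalence of the disease.

    The two causes act independently, so the total carrier penetrance is
    ``beta = gamma + f - gamma * f`` while non-carriers are affected with
    probability ``gamma``.
    """

    f: float
    gamma: float = 0.0

    def __post_init__(self) -> None:
        _check_probability("f", self.f)
        _check_probability("gamma", self.gamma, closed_top=False)

    @property
    def beta(self) -> float:
        """Total probability that a carrier is affected (any cause)."""
        return combined_penetrance(self)


def combined_penetrance(trait: TraitModel) -> float:
    """Carrier penetrance under independent causes: ``gamma + f - gamma*f``."""
    return trait.gamma + trait.f - trait.gamma * trait.f


def normalizing_constant(k: float, s: int) -> float:
    """Largest ``c`` making ``c*(r**k + t)`` a probability for all attainable (r, t).

    Attainable cells satisfy ``1 <= r <= t <= s``; they are enumerated by brute
    force because for negative ``k`` the maximizing cell need not be (s, s).
    """
    s = int(s)
    if s < 1:
        raise ValueError(f"sibship size s must be >= 1, got {s}")
    max_weight = max(
        float(r) ** k + t for t in range(1, s + 1) for r in range(1, t + 1)
    )
    return 1.0 / max_weight


@dataclass(frozen=True)
class AscertainmentModel:
    """Generalized k-model of family ascertainment.

    A sibship with ``r`` qualifying individuals and ``t`` affected sibs is
    recruited with probability ``c * (r**k + t)`` when ``r >= 1`` and never
    otherwise. ``k = 1`` is classical single ascertainment, ``k = 0``
    complete/truncate ascertainment.

    ``c`` may be left unset, in which case the tightest valid constant for a
    given sibship size is used (see :func:`normalizing_constant`).
    """

    k: float
    c: float | None = None

    def __post_init__(self) -> None:
        if self.c is not None:
            c = float(self.c)
            if not (0.0 < c <= 1.0):
                raise ValueError(f"c must be in (0, 1], got {c!r}")

    def constant_for(self, s: int) -> float:
        """The normalizing constant in force for ``s``-sized sibships."""
        if self.c is not None:
            c = float(self.c)
            if c > normalizing_constant(self.k, s):
                raise ValueError(
                    f"c={c} makes c*(r**k + t) exceed 1 for some (r, t) with s={s}"
                )
            return c
        return normalizing_constant(self.k, s)

    def acceptance_probability(self, r: int, t: int, s: int) -> float:
        """P[sibship is ascertained | r, t] for an ``s``-sized sibship."""
        if not (0 <= r <= t <= s):
            raise ValueError(f"require 0 <= r <= t <= s, got r={r}, t={t}, s={s}")
        if r == 0:
            return 0.0
        return self.constant_for(s) * (float(r) ** self.k + t)


@dataclass(frozen=True)
class Sibship:
    """One nuclear family: a carrier x non-carrier mating and its sibs.

    Parental marker genotypes are fixed by construction: one parent is a VOI
    heterozygote (alleles Vv) and the other a non-carrier (vv). Parental
    phenotypes are always unknown.
    """

    carrier: np.ndarray
    affected: np.ndarray
    proband_index: int | None = None

    def __post_init__(self) -> None:
        carrier = np.asarray(self.carrier, dtype=bool)
        affected = np.asarray(self.affected, dtype=bool)
        if carrier.ndim != 1 or carrier.shape != affected.shape:
            raise ValueError("carrier and affected must be 1-D arrays of equal length")
        if carrier.size < 1:
            raise ValueError("a sibship needs at least one sib")
        object.__setattr__(self, "carrier", carrier)
        object.__setattr__(self, "affected", affected)
        if self.proband_index is not None:
            i = int(self.proband_index)
            if not (0 <= i < carrier.size):
                raise ValueError(f"proband_index {i} out of range for s={carrier.size}")
            if not (carrier[i] and affected[i]):
                raise ValueError("the proband must be a QI (carrier and affected)")
            object.__setattr__(self, "proband_index", i)

    @property
    def s(self) -> int:
        return int(self.carrier.size)

    @property
    def r(self) -> int:
        """Number of qualifying individuals (carrier and affected)."""
        return int(np.count_nonzero(self.carrier & self.affected))

    @property
    def t(self) -> int:
        """Number of affected sibs regardless of carrier status."""
        return int(np.count_nonzero(self.affected))

    def sib_states(self) -> tuple[int, ...]:
        """Per-sib state codes ``2*carrier + affected``, sorted.

        Sib order carries no information in any of the statistics, so the
        sorted tuple identifies the family configuration.
        """
        codes = 2 * self.carrier.astype(int) + self.affected.astype(int)
        return tuple(sorted(codes.tolist()))


@dataclass
class Dataset:
    """A collection of equally sized sibships plus generating provenance.

    Stored column-wise as boolean matrices of shape ``(N, s)`` for speed;
    ``proband_index`` holds -1 for sibships without a designated proband.
    """

    carrier: np.ndarray
    affected: np.ndarray
    proband_index: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.carrier = np.asarray(self.carrier, dtype=bool)
        self.affected = np.asarray(self.affected, dtype=bool)
        self.proband_index = np.asarray(self.proband_index, dtype=np.int64)
        if self.carrier.ndim != 2 or self.carrier.shape != self.affected.shape:
            raise ValueError("carrier and affected must be (N, s) arrays of equal shape")
        if self.proband_index.shape != (self.carrier.shape[0],):
            raise ValueError("proband_index must have one entry per sibship")
        has = self.proband_index >= 0
        if np.any(self.proband_index >= self.carrier.shape[1]):
            raise ValueError("proband_index out of range")
        rows = np.nonzero(has)[0]
        cols = self.proband_index[has]
        if not np.all(self.carrier[rows, cols] & self.affected[rows, cols]):
            raise ValueError("every designated proband must be a QI")

    @classmethod
    def from_sibships(cls, sibships: Sequence[Sibship], provenance: dict | None = None) -> "Dataset":
        if len(sibships) == 0:
            raise ValueError("a Dataset needs at least one sibship")
        sizes = {sib.s for sib in sibships}
        if len(sizes) != 1:
            raise ValueError(f"all sibships must share one size s, got sizes {sorted(sizes)}")
        carrier = np.stack([sib.carrier for sib in sibships])
        affected = np.stack([sib.affected for sib in sibships])
        proband = np.array(
            [-1 if sib.proband_index is None else sib.proband_index for sib in sibships],
            dtype=np.int64,
        )
        return cls(carrier, affected, proband, provenance or {})

    @property
    def N(self) -> int:
        return int(self.carrier.shape[0])

    @property
    def s(self) -> int:
        return int(self.carrier.shape[1])

    @property
    def r(self) -> np.ndarray:
        return (self.carrier & self.affected).sum(axis=1)

    @property
    def t(self) -> np.ndarray:
        return self.affected.sum(axis=1)

    def sibships(self) -> Iterator[Sibship]:
        for i in range(self.N):
            p = int(self.proband_index[i])
            yield Sibship(self.carrier[i], self.affected[i], None if p < 0 else p)

    def __len__(self) -> int:
        return self.N

    def config_counts(self) -> dict[tuple[int, ...], int]:
        """Multiplicity of each distinct family configuration.

        Configurations are order-free tuples of per-sib state codes
        ``2*carrier + affected``. Likelihood work is done once per distinct
        configuration and weighted by these counts.
        """
        codes = np.sort(2 * self.carrier.astype(np.int8) + self.affected.astype(np.int8), axis=1)
        uniq, counts = np.unique(codes, axis=0, return_counts=True)
        return {tuple(int(v) for v in row): int(n) for row, n in zip(uniq, counts)}


def _haplotype_frequencies(p: float, q: float, dprime: float) -> np.ndarray:
    """Frequencies of haplotypes (VD, Vd, vD, vd) implied by (p, q, D')."""
    d_max = min(p * (1.0 - q), (1.0 - p) * q)
    d = dprime * d_max
    freqs = np.array(
        [
            p * q + d,
            p * (1.0 - q) - d,
            (1.0 - p) * q - d,
            (1.0 - p) * (1.0 - q) + d,
        ]
    )
    return freqs


@dataclass(frozen=True)
class TwoLocusModel:
    """Marker-disease analysis model for nuclear-family likelihoods.

    The marker is the variant of interest (allele V at frequency ``p``); the
    disease locus has allele D at frequency ``q``. ``dprime`` is the
    standardized disequilibrium coefficient between V and D, ``theta`` the
    recombination fraction, ``penetrances`` the vector
    (f_DD, f_Dd, f_dd), and ``alpha`` Smith's admixture parameter (the
    probability that a family is of the linked type).
    """

    p: float = 0.001
    q: float = 0.001
    dprime: float = 1.0
    theta: float = 0.0
    penetrances: tuple[float, float, float] = (1.0, 1.0, 0.0)
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"p must be in (0, 1), got {self.p!r}")
        if not (0.0 < self.q < 1.0):
            raise ValueError(f"q must be in (0, 1), got {self.q!r}")
        if not (0.0 <= self.dprime <= 1.0):
            raise ValueError(f"dprime must be in [0, 1], got {self.dprime!r}")
        if not (0.0 <= self.theta <= 0.5):
            raise ValueError(f"theta must be in [0, 0.5], got {self.theta!r}")
        pen = tuple(float(v) for v in self.penetrances)
        if len(pen) != 3:
            raise ValueError("penetrances must be (f_DD, f_Dd, f_dd)")
        for name, v in zip(("f_DD", "f_Dd", "f_dd"), pen):
            _check_probability(name, v)
        object.__setattr__(self, "penetrances", pen)
        _check_probability("alpha", self.alpha)
        freqs = _haplotype_frequencies(self.p, self.q, self.dprime)
        if np.any(freqs < -1e-12):
            raise ValueError("implied haplotype frequencies are negative")

    def haplotype_frequencies(self) -> np.ndarray:
        """Frequencies of (VD, Vd, vD, vd); nonnegative and summing to 1."""
        return np.clip(_haplotype_frequencies(self.p, self.q, self.dprime), 0.0, None)

    def replace(self, **kwargs) -> "TwoLocusModel":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


@dataclass
class ReplicateSummary:
    """Cross-replicate summary of one estimate or statistic.

    ``values`` holds only contributing replicates (NaNs removed);
    ``n_noncontributing`` counts replicates (or, context depending, families)
    that could not be scored, e.g. no remaining carrier after dropping the
    proband.
    """

    estimate_name: str
    values: np.ndarray
    n_noncontributing: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        self.values = values[~np.isnan(values)]

    @property
    def n_replicates(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.values.size else float("nan")

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.values.size > 1 else float("nan")
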