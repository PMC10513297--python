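# Methods

This note defines the generating model, the estimators and statistics, and
the numerical conventions used by `sibpen`. Everything stated here is
computed by the package; tolerances and replicate counts for the headline
numbers live in `tests/test_acceptance.py` and `scripts/acceptance.py`.

## Generating model

**Trait.** A rare variant of interest (VOI) acts as an autosomal dominant
risk allele. A carrier is affected with probability

```
beta = gamma + f - gamma * f
```

where `f` is the *attributable* penetrance (probability of affection due to
the variant itself) and `gamma` the combined penetrance of all other causes,
acting independently. Non-carriers are affected with probability `gamma`.
Because the VOI is very rare, `gamma` doubles as the population prevalence.

**Families.** Each family is a sibship of fixed size `s` from a mating of
one VOI heterozygote (Vv) by one non-carrier (vv); each sib inherits the
variant independently with probability 1/2. Parents are always phenotypically
unknown. For the counting estimators the parents are treated as entirely
unobserved; the likelihood statistics use the parental marker genotypes,
which are fixed by construction.

**Ascertainment (k-model).** A sibship with `r` qualifying individuals
(QIs: carrier *and* affected) and `t` affected sibs is recruited with
probability

```
P[ascertained | r, t] = c * (r^k + t)   for r >= 1,   0 otherwise.
```

`k = 1` is classical single ascertainment and `k = 0` complete/truncate
ascertainment. The normalizing constant `c` is the largest value keeping
every attainable weight a probability; it is found by brute force over the
triangle `1 <= r <= t <= s` because for negative `k` the maximizing cell
need not be `(s, s)`. `c` cancels from every expectation computed here, so
its exact value only affects simulation efficiency.

Datasets are drawn by vectorized rejection sampling: population sibships are
generated in batches and accepted with probability `c (r^k + t)`, which
realizes the ascertained distribution exactly for any `k` without algebra.
Each accepted family receives a designated proband drawn uniformly among its
QIs.

**Null generator.** For specificity studies, phenotypes can instead be driven
by a causal locus unlinked to the marker: the marker-carrier parent is also
heterozygous at an unlinked causal locus, each sib inherits that allele with
probability 1/2 independently of the marker, and affection follows
`beta`/`gamma` by causal-allele status. The same QI-based ascertainment rule
is applied, so within-family marker–phenotype association in the retained
data is purely ascertainment-induced. (Which parent carries the unlinked
causal allele is immaterial, since its transmissions are independent of the
marker's.)

## Counting estimators

- `f_tilde` (single-ascertainment correction): drop the designated proband,
  take the affected proportion among the remaining carrier sibs, and average
  these per-family proportions across families. Families with no remaining
  carrier do not contribute (their count is reported).
- `f_tilde_star` (no correction): affected proportion among all carrier
  sibs, proband included, averaged per family. In ascertained data every
  family contributes and the per-family proportion is bounded below by
  `1/s`.

Both average *per-family proportions* (each family weighted equally); a
pooled variant that aggregates counts before dividing is available via
`pooled=True`.

**Exact expectations.** `expected_estimates_exact` enumerates all `4^s`
joint (carrier, affected) sib configurations, weights each by its generating
probability times `(r^k + t)` for `r >= 1`, and renormalizes. The post-drop
proportion `(r-1)/(n_carriers-1)` does not depend on which QI is the
proband, so the random proband choice is averaged implicitly. Enumeration is
guarded at `s <= 12`.

## Two-locus family likelihood

The analysis model places the marker (the VOI, allele V at frequency `p`)
and a disease locus (allele D at frequency `q`) at recombination fraction
`theta` with standardized disequilibrium `D'`, giving haplotype frequencies

```
h_VD = pq + D,  h_Vd = p(1-q) - D,  h_vD = (1-p)q - D,  h_vd = (1-p)(1-q) + D,
D = D' * min(p(1-q), (1-p)q).
```

A family's likelihood is `P(sib marker genotypes, sib phenotypes | parental
marker genotypes Vv x vv)`: a sum over the 2^4 assignments of disease
alleles to the four parental haplotypes (weighted by the conditional allele
frequencies given each haplotype's marker allele), Mendelian transmission
with recombination in the Vv parent (recombination in the marker-homozygous
parent is invisible), and penetrance factors `(f_DD, f_Dd, f_dd)` applied to
sibs only — parents contribute no phenotype factor. Both parents may carry D,
which matters for correct null behavior when `gamma = 0`.

The default analysis model fixes `p = q = 0.001`, `D' = 1`, `theta = 0`;
only the penetrances and Smith's admixture proportion `alpha` (probability
that a family is of the linked type) are free.

### LD-LOD and LD-MOD

The LD-LOD is the log10 ratio of the admixed model
`alpha * L(theta, D') + (1 - alpha) * L(theta = 0.5)` to the no-linkage
hypothesis at the same penetrances. The null keeps the haplotype model and
differs only by `theta = 0.5`. At `theta = 0.5` a family likelihood
factorizes into a marker term times a phenotype term, and the phenotype term
is shared with the numerator's unlinked component, so per family the LOD
reduces to `log10(alpha * L_linked / L_unlinked + 1 - alpha)`: all
trait-only factors cancel, and the statistic equals the likelihood ratio of
the marker data *given* all phenotypes. That conditioning is what makes the
maximized statistic free of ascertainment assumptions — any recruitment
acting through phenotypes divides out. (A null with `D' = 0` is available
via `null_dprime=0.0`.)

The LD-MOD maximizes the LD-LOD over `(f_DD, f_Dd, f_dd, alpha)` in the unit
box; `f_hat` is the maximizing `f_Dd`.

### LE-LOD and LE-LOD(max)

The ordinary linkage-equilibrium LOD sets `D' = 0` in the numerator (keeping
`theta`) against the `theta = 0.5` null, so only within-family
co-segregation contributes. `LE-LOD(max)` evaluates it at the LD-MOD's
maximizing model; it is the co-segregation evidence statistic whose
exceedance counts over replicates quantify power and specificity.

### TBF

The proband-conditioned Bayes factor divides each family's likelihood, under
both hypotheses, by the likelihood of its proband's own marker genotype and
phenotype (the proband is a QI by construction, so the correction is one
shared term per family):

```
TBF = sum over families of
      log10[ L_alt(family) / L_alt(proband) ]
    - log10[ L_null(family) / L_null(proband) ]
```

with the same `theta = 0.5` null convention as the LD-LOD, and the proband
likelihood computed as a 1-sib family of the same mating. For 1-sib families
the statistic is identically zero, as is the statistic at `alpha = 0`.

`maximize_tbf` maximizes over *ordered* trait models
(`f_DD >= f_Dd >= f_dd`) times `alpha`. The ordering restriction defines the
admissible trait-model space; without it the objective is dominated by
inverted-penetrance models (`f_dd` near 1) with no genetic interpretation.
The maximizing `f_Dd` is reported as `f_TBF`. The purpose of this maximizer
is diagnostic: the proband correction pays back exactly one QI's worth of
linkage evidence per family regardless of how the trait model fits the
*other* sibs, so with phenocopies present the maximizing penetrance is
driven far above the generating value even at very large N — proband
conditioning and MOD-style maximization do not mix.

## Numerical choices

- **Multilinearity + configuration caching.** For a fixed `(p, q, D',
  theta)` the family likelihood is multilinear in the augmented penetrance
  vector `(f_DD, f_Dd, f_dd, 1)`, so per-configuration coefficient tables
  are built once and evaluated over whole parameter grids with `einsum`. A
  family's likelihood depends only on the multiset of per-sib states
  (`2*carrier + affected`), and 2-sib datasets have at most 10 distinct
  configurations, so per-configuration LOD surfaces are cached and shared
  across replicates.
- **Maximization.** A coarse grid (0.05 steps over three penetrances and
  `alpha`, argmax ties broken toward the smaller `f_Dd`) seeds a bounded
  Nelder-Mead refinement for the LD-MOD. The TBF maximizer reports the grid
  optimum over the ordered trait-model space by default (`refine=True`
  enables the same polishing, constrained to ordered models).
- **Reproducibility.** Replicate seeds derive from
  `numpy.random.SeedSequence(entropy=master_seed, spawn_key=(cell,
  replicate))`, so any cell or single replicate can be regenerated
  independently of execution order.
- **Zero-probability handling.** Log-ratios at impossible models evaluate to
  `-inf` and are excluded from argmaxes; a model making both hypotheses
  impossible for some family is treated as `-inf`, not `0/0`.

## Pedigree I/O

Datasets round-trip through LINKAGE pre-makeped files (one row per
individual: famID, indID, fatherID, motherID, sex, affection 2/1/0, two
marker allele columns; allele 1 = VOI). Proband designations and generating
provenance live in a YAML sidecar (`<file>.meta.yaml`) so the pedigree file
itself remains consumable by classical linkage software. Files with
unexpected mating types are read with a warning; variable sibship sizes
within one dataset are rejected.

## Limitations

- Nuclear sibships only: no general pedigree peeling, no loops, no
  multipoint analysis, no marker maps.
- One fixed sibship size per dataset; the k-model is the only recruitment
  mechanism implemented.
- The analysis model fixes `p`, `q`, `D'`, `theta`; they are not estimated.
- The TBF maximizer's grid resolution (0.05) bounds the granularity of
  `f_TBF` unless refinement is enabled.
- Exact enumeration of estimator expectations is exponential in `s` and
  guarded at `s <= 12`.
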