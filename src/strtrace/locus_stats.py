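"""Per-locus diversity statistics and Hardy-Weinberg exact testing.

Heterozygosity uses Nei's unbiased estimator (the small-sample correction
2n/(2n-1) applied by the standard pedigree software); the Hardy-Weinberg
test is the Guo-Thompson Markov-chain Monte Carlo approximation to the
multi-allele exact test, batched so a Monte-Carlo standard error accompanies
the p-value.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "HweResult",
    "observed_heterozygosity",
    "expected_heterozygosity_unbiased",
    "pic",
    "hwe_exact_test",
    "bonferroni",
]

LOG2 = math.log(2.0)


@dataclass(frozen=True)
class HweResult:
    """Monte-Carlo exact-test result: p-value, its standard error, chain length."""

    p_value: float
    se: float
    n_steps: int


def observed_heterozygosity(matrix: GenotypeMatrix, locus: str) -> float:
    """Fraction of non-missing individuals carrying two distinct alleles."""
    j = matrix.locus_index(locus)
    calls = matrix.alleles[:, j, :]
    ok = calls[:, 0] != MISSING
    if not ok.any():
        raise ValueError(f"locus {locus} has no non-missing calls")
    return float((calls[ok, 0] != calls[ok, 1]).mean())


def expected_heterozygosity_unbiased(
    freqs: dict[int, float], n: int, unbiased: bool = True
) -> float:
    """Expected heterozygosity He = 1 - sum p_i^2, with Nei's 2n/(2n-1) correction.

    ``n`` is the diploid sample size behind the frequencies.  Set
    ``unbiased=False`` for the plain gene-diversity estimate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    gd = 1.0 - sum(p * p for p in freqs.values())
    if not unbiased:
        return gd
    return (2 * n) / (2 * n - 1) * gd


def pic(freqs: dict[int, float]) -> float:
    """Polymorphic information content of a locus.

    PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2: the probability that a
    parent is informative for linkage, i.e. heterozygous with an offspring
    whose genotype resolves which allele was transmitted.
    """
    p = np.asarray(list(freqs.values()))
    s2 = float(np.sum(p * p))
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    cross = s2 * s2 - float(np.sum(p**4))
    return 1.0 - s2 - cross


def _table_logprob(cells: Counter, n_het: int) -> float:
    """Log conditional probability of a genotype-count table, up to the
    constant that depends only on allele counts and n."""
    return n_het * LOG2 - sum(math.lgamma(c + 1) for c in cells.values())


def hwe_exact_test(
    matrix: GenotypeMatrix,
    locus: str,
    dememorization: int = 5000,
    batches: int = 100,
    iters_per_batch: int = 1000,
    seed: int | None = None,
) -> HweResult:
    """Guo-Thompson Markov-chain exact test for Hardy-Weinberg proportions.

    Runs a Metropolis chain over genotype tables with the observed allele
    counts, using allele-swap proposals between random individuals.  The
    p-value is the stationary fraction of tables whose conditional
    probability does not exceed the observed table's (ties included);
    batching gives the Monte-Carlo standard error.  Defaults match common
    software practice (dememorization 5000, 100 batches of 1000).

    A monomorphic locus returns p = 1 by convention.
    """
    j = matrix.locus_index(locus)
    calls = matrix.alleles[:, j, :]
    ok = calls[:, 0] != MISSING
    geno = calls[ok].astype(np.int64).copy()
    if geno.shape[0] == 0:
        raise ValueError(f"locus {locus} has no non-missing calls")
    if np.unique(geno).size < 2:
        return HweResult(1.0, 0.0, 0)

    rng = np.random.default_rng(seed)
    n = geno.shape[0]
    cells: Counter = Counter()
    for a, b in geno:
        cells[(min(a, b), max(a, b))] += 1
    n_het = int((geno[:, 0] != geno[:, 1]).sum())
    logp = _table_logprob(cells, n_het)
    logp_obs = logp
    tol = 1e-9

    # The chain state keeps each individual's two allele copies in ordered
    # slots.  The uniform distribution over slot-states has table marginal
    # proportional to 2^h * n! / prod(n_ij!) -- exactly the conditional
    # distribution of genotype tables given allele counts -- so uniformly
    # chosen slot swaps need no acceptance step.
    total = dememorization + batches * iters_per_batch
    picks = rng.integers(0, n, size=(total, 2))
    sides = rng.integers(0, 2, size=(total, 2))

    batch_hits = np.zeros(batches)
    step = 0
    for phase, n_iter in ((None, dememorization), *((b, iters_per_batch) for b in range(batches))):
        hits = 0
        for _ in range(n_iter):
            u, v = picks[step]
            r, s = sides[step]
            step += 1
            if u != v:
                gu = (min(geno[u, 0], geno[u, 1]), max(geno[u, 0], geno[u, 1]))
                gv = (min(geno[v, 0], geno[v, 1]), max(geno[v, 0], geno[v, 1]))
                au, av = geno[u, r], geno[v, s]
                geno[u, r] = av
                geno[v, s] = au
                nu = (min(geno[u, 0], geno[u, 1]), max(geno[u, 0], geno[u, 1]))
                nv = (min(geno[v, 0], geno[v, 1]), max(geno[v, 0], geno[v, 1]))
                if (nu, nv) != (gu, gv) and (nu, nv) != (gv, gu):
                    d_logp = LOG2 * (
                        int(nu[0] != nu[1]) + int(nv[0] != nv[1])
                        - int(gu[0] != gu[1]) - int(gv[0] != gv[1])
                    )
                    for cell, delta in ((gu, -1), (gv, -1), (nu, +1), (nv, +1)):
                        c = cells[cell]
                        d_logp += math.lgamma(c + 1) - math.lgamma(c + 1 + delta)
                        cells[cell] = c + delta
                        if cells[cell] == 0:
                            del cells[cell]
                    logp += d_logp
            if phase is not None and logp <= logp_obs + tol:
                hits += 1
        if phase is not None:
            batch_hits[phase] = hits / n_iter

    p = float(batch_hits.mean())
    se = float(batch_hits.std(ddof=1) / math.sqrt(batches)) if batches > 1 else 0.0
    return HweResult(p, se, total)


def bonferroni(p_values: list[float], alpha: float = 0.05) -> list[bool]:
    """Bonferroni significance flags: p_i <= alpha / m over m tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    m = len(p_values)
    if m == 0:
        return []
    cut = alpha / m
    return [p <= cut for p in p_values]
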