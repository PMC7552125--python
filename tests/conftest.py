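import numpy as np
import pytest

import strtrace as st


@pytest.fixture(scope="session")
def table1():
    return st.load_pirenaica_table1()


@pytest.fixture(scope="session")
def ilst005_freqs():
    """Biallelic frequencies recovered by inverting the published unbiased
    He = 0.372 at n = 114 diploid individuals."""
    n = 114
    two_pq = 0.372 * (2 * n - 1) / (2 * n)
    disc = (1.0 - 2.0 * two_pq) ** 0.5
    p = (1.0 + disc) / 2.0
    return {178: p, 182: 1.0 - p}


@pytest.fixture
def tiny_matrix():
    """Two populations, two loci, one missing call."""
    alleles = np.array(
        [
            [[100, 102], [131, 131]],
            [[100, 100], [131, 135]],
            [[102, 102], [-1, -1]],
            [[104, 102], [135, 135]],
        ],
        dtype=np.int32,
    )
    return st.GenotypeMatrix(
        ["a1", "a2", "b1", "b2"], ["A", "A", "B", "B"], ["BM1824", "BM2113"], alleles
    )


def enumerate_genotypes(freqs):
    """HWE genotype distribution of a locus: {(a<=b): prob}."""
    alleles = sorted(freqs)
    out = {}
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            out[(a, b)] = freqs[a] ** 2 if a == b else 2 * freqs[a] * freqs[b]
    return out


def pe1p_enumeration(freqs):
    """Brute-force PE-1P: P(random candidate shares no allele with a random
    offspring), summing over all offspring x candidate genotype pairs."""
    gp = enumerate_genotypes(freqs)
    total = 0.0
    for off, p_off in gp.items():
        for cand, p_cand in gp.items():
            if not set(off) & set(cand):
                total += p_off * p_cand
    return total


def pe2p_enumeration(freqs):
    """Brute-force PE-2P: P(random ordered couple cannot produce a random
    offspring), by full enumeration of couple x offspring genotypes."""
    gp = enumerate_genotypes(freqs)
    total = 0.0
    for sire, ps in gp.items():
        for dam, pd_ in gp.items():
            off_possible = {tuple(sorted((a, b))) for a in sire for b in dam}
            for off, po in gp.items():
                if off not in off_possible:
                    total += ps * pd_ * po
    return total


def pesi_enumeration(freqs):
    """Brute-force PE-SI: P(two full sibs differ), enumerating parent pairs
    and the Mendelian transmission distribution."""
    gp = enumerate_genotypes(freqs)
    identical = 0.0
    for g1, p1 in gp.items():
        for g2, p2 in gp.items():
            off = {}
            for a in g1:
                for b in g2:
                    key = tuple(sorted((a, b)))
                    off[key] = off.get(key, 0.0) + 0.25
            identical += p1 * p2 * sum(v * v for v in off.values())
    return 1.0 - identical


def random_spectrum(rng, k_max=12):
    k = int(rng.integers(2, k_max + 1))
    p = rng.dirichlet(np.ones(k) * rng.uniform(0.3, 3.0))
    p = np.maximum(p, 1e-6)
    p = p / p.sum()
    return {int(100 + 2 * i): float(x) for i, x in enumerate(p)}
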