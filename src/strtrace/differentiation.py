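"""Population differentiation: Weir-Cockerham theta, allele-size R_ST and
Reynolds drift distance.

The F_ST estimator is the Weir & Cockerham (1984) variance-component theta:
per allele and locus, components a (among populations), b (among individuals
within populations) and c (within individuals) are estimated from sample
sizes, allele frequencies and heterozygote frequencies; the global estimate
is the ratio of summed components across loci and alleles (ratio of sums,
never a mean of ratios), so low-information loci cannot dominate.  Estimates
can be slightly negative in undifferentiated data.

R_ST replaces allele identity with allele size (bp): it contrasts the
within-population allele-size variance with the total, which makes it the
natural statistic under stepwise mutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "wc_fst",
    "pairwise_fst",
    "slatkin_rst",
    "reynolds_distance",
]


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance (or differentiation) matrix."""

    labels: list[str]
    values: np.ndarray
    name: str = "distance"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        with np.errstate(invalid="ignore"):  # inf distances: inf - inf -> nan
            if np.nanmax(np.abs(v - v.T), initial=0.0) > 1e-12:
                raise ValueError("matrix is not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 0:
            raise ValueError("diagonal must be zero")
        self.values = v

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_phylip(self) -> str:
        lines = [f"{len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            lines.append(lab + "  " + "  ".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_phylip(cls, text: str, name: str = "distance") -> "DistanceMatrix":
        lines = [l for l in text.splitlines() if l.strip()]
        n = int(lines[0].split()[0])
        labels, rows = [], []
        for line in lines[1 : n + 1]:
            parts = line.split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        return cls(labels, np.asarray(rows), name)


def _wc_components(matrix: GenotypeMatrix, pops: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus summed (a, a+b+c) Weir-Cockerham components."""
    r = len(pops)
    pop_rows = [matrix.pop_indices(p) for p in pops]
    a_sum = np.zeros(matrix.n_loci)
    abc_sum = np.zeros(matrix.n_loci)
    for j in range(matrix.n_loci):
        ns, freqs, hets, alleles = [], [], [], set()
        for rows in pop_rows:
            calls = matrix.alleles[rows, j, :]
            ok = calls[:, 0] != MISSING
            calls = calls[ok]
            if calls.shape[0] == 0:
                ns.append(0)
                freqs.append({})
                hets.append({})
                continue
            ns.append(calls.shape[0])
            vals, cnt = np.unique(calls.ravel(), return_counts=True)
            f = {int(v): c / (2 * calls.shape[0]) for v, c in zip(vals, cnt)}
            freqs.append(f)
            alleles.update(f)
            het_mask = calls[:, 0] != calls[:, 1]
            h = {}
            for v in vals:
                carries = (calls == v).any(axis=1)
                h[int(v)] = float((carries & het_mask).mean())
            hets.append(h)
        live = [i for i, n in enumerate(ns) if n > 0]
        if len(live) < 2:
            continue  # locus uninformative for this comparison
        n_i = np.asarray([ns[i] for i in live], dtype=float)
        r_eff = len(live)
        nbar = n_i.mean()
        if nbar <= 1:
            continue
        nc = (r_eff * nbar - (n_i**2).sum() / (r_eff * nbar)) / (r_eff - 1)
        if nc <= 0:
            continue
        for al in sorted(alleles):
            p_i = np.asarray([freqs[i].get(al, 0.0) for i in live])
            h_i = np.asarray([hets[i].get(al, 0.0) for i in live])
            pbar = (n_i * p_i).sum() / (r_eff * nbar)
            s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r_eff - 1) * nbar)
            hbar = (n_i * h_i).sum() / (r_eff * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r_eff - 1) / r_eff * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - (r_eff - 1) / r_eff * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            a_sum[j] += a
            abc_sum[j] += a + b + c
    return a_sum, abc_sum


def wc_fst(
    matrix: GenotypeMatrix,
    loci: list[str] | None = None,
    populations: list[str] | None = None,
) -> tuple[dict[str, float], float]:
    """Weir-Cockerham theta per locus and globally.

    Returns ``(per_locus, global_theta)``; the global value is the ratio of
    component sums across loci.  Requires at least two populations; loci
    with no informative pair of populations get NaN per-locus estimates and
    do not contribute to the global ratio.
    """
    pops = populations if populations is not None else matrix.populations()
    if len(pops) < 2:
        raise ValueError("F_ST needs at least two populations")
    sub = matrix if loci is None else matrix.subset(loci=loci)
    a, abc = _wc_components(sub, pops)
    with np.errstate(divide="ignore", invalid="ignore"):
        per = np.where(abc != 0, a / abc, np.nan)
    per_locus = {name: float(per[j]) for j, name in enumerate(sub.loci)}
    denom = abc.sum()
    if denom == 0:
        raise ValueError("no informative loci for F_ST")
    return per_locus, float(a.sum() / denom)


def pairwise_fst(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise Weir-Cockerham theta between all population pairs.

    Negative pair estimates are clamped to zero in the distance output
    (the raw estimator can dip below zero when differentiation is absent).
    """
    pops = matrix.populations()
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    out = np.zeros((len(pops), len(pops)))
    for i, j in combinations(range(len(pops)), 2):
        _, theta = wc_fst(matrix, populations=[pops[i], pops[j]])
        out[i, j] = out[j, i] = max(theta, 0.0)
    return DistanceMatrix(pops, out, "wc_fst")


def _rst_components(matrix: GenotypeMatrix, pops: list[str]) -> tuple[float, float]:
    """Summed (S_total - S_within, S_total) allele-size variance components."""
    num = 0.0
    den = 0.0
    pop_rows = [matrix.pop_indices(p) for p in pops]
    for j in range(matrix.n_loci):
        sizes_by_pop = []
        for rows in pop_rows:
            calls = matrix.alleles[rows, j, :]
            s = calls[calls != MISSING].astype(float)
            if s.size >= 2:
                sizes_by_pop.append(s)
        if len(sizes_by_pop) < 2:
            continue
        pooled = np.concatenate(sizes_by_pop)
        s_total = float(pooled.var(ddof=1))
        if s_total == 0:
            continue
        w = np.asarray([s.size for s in sizes_by_pop], dtype=float)
        s_within = float(np.sum(w * [s.var(ddof=1) for s in sizes_by_pop]) / w.sum())
        num += s_total - s_within
        den += s_total
    return num, den


def slatkin_rst(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise R_ST from allele-size variances.

    R_ST = (S_total - S_within) / S_total per pair, where S_within is the
    copy-weighted mean within-population allele-size variance and S_total
    the pooled variance; loci are combined as a ratio of summed components.
    Allele labels must be sizes in bp (integers), so the statistic is
    meaningful under stepwise mutation.
    """
    pops = matrix.populations()
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    out = np.zeros((len(pops), len(pops)))
    for i, j in combinations(range(len(pops)), 2):
        num, den = _rst_components(matrix, [pops[i], pops[j]])
        if den == 0:
            raise ValueError(f"no allele-size variance between {pops[i]} and {pops[j]}")
        out[i, j] = out[j, i] = max(num / den, 0.0)
    return DistanceMatrix(pops, out, "rst")


def reynolds_distance(matrix: GenotypeMatrix, variant: str = "log") -> DistanceMatrix:
    """Reynolds drift distance from pairwise theta.

    ``log`` variant: D = -ln(1 - theta), linear in divergence time under
    pure drift; ``linearized`` variant: D = theta / (1 - theta).  Negative
    theta is clamped to zero first, so D = 0 iff theta <= 0; theta = 1
    yields an infinite distance.
    """
    fst = pairwise_fst(matrix)
    theta = np.clip(fst.values, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        if variant == "log":
            d = -np.log(1.0 - theta)
        elif variant == "linearized":
            d = np.where(theta < 1.0, theta / (1.0 - theta), np.inf)
        else:
            raise ValueError(f"unknown variant {variant!r}")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(fst.labels, d, f"reynolds_{variant}")
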