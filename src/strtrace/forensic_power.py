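"""Match and parentage-exclusion probabilities, panel combination and
minimal-panel search for STR marker panels.

Single-locus quantities
-----------------------
MP     probability two random individuals share a genotype at the locus.
PE-1P  probability the locus excludes a random non-parent when the second
       parent is untyped: the candidate carries neither offspring allele.
PE-2P  probability the locus excludes a random candidate *couple* given only
       the offspring genotype.
PE-SI  probability two full siblings differ in genotype at the locus.

All expected-mode quantities assume Hardy-Weinberg genotype proportions in
the reference population.  Panels combine multiplicatively:

    CMP = prod_l MP_l          CPE = 1 - prod_l (1 - PE_l)

so every added locus tightens both the match and the exclusion bound; the
minimal-panel search exploits this monotonicity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, LocusForensicSummary

__all__ = [
    "PanelCurve",
    "PanelDesign",
    "NAMED_PANELS",
    "matching_probability",
    "pe_one_parent",
    "pe_two_parents",
    "pe_sibling",
    "combine_panel",
    "minimal_panel_size",
]

#: Marker lists of the commercial panels the reference study compares.
#: ``bovine22_studied`` is the subset of the Bovine Genotype 2.2 add-on panel
#: covered by the 30-marker ISAG-FAO set (MGTG4B, RM67 and SPS113 are not).
NAMED_PANELS: dict[str, list[str]] = {
    "stockmarks11": [
        "BM1824", "BM2113", "ETH03", "ETH010", "ETH225", "INRA023",
        "SPS115", "TGLA53", "TGLA122", "TGLA126", "TGLA227",
    ],
    "isag12": [
        "BM1824", "BM2113", "ETH03", "ETH010", "ETH225", "INRA023",
        "SPS115", "TGLA53", "TGLA122", "TGLA126", "TGLA227", "BM1818",
    ],
    "bovine22_studied": ["CSRM60", "CSSM66", "ETH185"],
}


@dataclass
class PanelCurve:
    """Cumulative match/exclusion trajectories over an ordered marker panel."""

    loci: list[str]
    cmp: np.ndarray
    cpe1: np.ndarray
    cpe2: np.ndarray
    cpesi: np.ndarray

    def cmp_scientific(self, prefix: int | None = None) -> str:
        v = self.cmp[(prefix or len(self.loci)) - 1]
        return f"{v:.3e}"


@dataclass
class PanelDesign:
    """Result of a minimal-panel search for one metric and threshold."""

    metric: str
    threshold: float
    minimal_size: int | None
    selected_loci: list[str]
    achieved: float | None


def _hwe_genotype_probs(freqs: dict[int, float]) -> dict[tuple[int, int], float]:
    alleles = sorted(freqs)
    out = {}
    for a, b in combinations_with_replacement(alleles, 2):
        out[(a, b)] = freqs[a] ** 2 if a == b else 2 * freqs[a] * freqs[b]
    return out


def matching_probability(
    source: GenotypeMatrix | dict[int, float],
    mode: str = "observed",
    locus: str | None = None,
) -> float:
    """Probability that two random individuals share a single-locus genotype.

    ``observed`` mode sums squared relative frequencies of the genotypes
    actually seen in a :class:`GenotypeMatrix` (the convention of the
    forensic software the reference study used); ``expected`` mode sums
    squared Hardy-Weinberg genotype probabilities from an allele-frequency
    map and is the only mode computable from a spectrum alone.
    """
    if mode == "observed":
        if not isinstance(source, GenotypeMatrix):
            raise TypeError("observed mode requires a GenotypeMatrix")
        if locus is None:
            raise ValueError("observed mode requires a locus name")
        j = source.locus_index(locus)
        calls = np.sort(source.alleles[:, j, :], axis=1)
        calls = calls[calls[:, 0] != MISSING]
        if calls.shape[0] == 0:
            raise ValueError(f"locus {locus} has no non-missing calls")
        _, counts = np.unique(calls, axis=0, return_counts=True)
        rel = counts / counts.sum()
        return float(np.sum(rel * rel))
    if mode == "expected":
        if isinstance(source, GenotypeMatrix):
            raise TypeError("expected mode takes an allele-frequency map")
        return float(sum(p * p for p in _hwe_genotype_probs(source).values()))
    raise ValueError(f"unknown mode {mode!r}")


def pe_one_parent(freqs: dict[int, float]) -> float:
    """One-parent exclusion power.

    Probability that a random Hardy-Weinberg individual shares no allele
    with a random Hardy-Weinberg offspring (second parent untyped):

        PE1P = sum_a p_a^2 (1-p_a)^2 + sum_{a<b} 2 p_a p_b (1 - p_a - p_b)^2
    """
    p = np.asarray(sorted(freqs.values()))
    hom = float(np.sum(p**2 * (1 - p) ** 2))
    het = 0.0
    vals = list(freqs.values())
    for i in range(len(vals)):
        for j in range(i + 1, len(vals)):
            pa, pb = vals[i], vals[j]
            het += 2 * pa * pb * (1 - pa - pb) ** 2
    return hom + het


def pe_two_parents(freqs: dict[int, float]) -> float:
    """Couple exclusion power, offspring genotype only.

    Probability a random ordered pair of Hardy-Weinberg genotypes is
    Mendelian-incompatible with a random Hardy-Weinberg offspring.  A pair
    is compatible when one member can contribute each offspring allele:
    for offspring aa that is [1-(1-p_a)^2]^2; for offspring ab it is
    2[1-(1-p_a)^2][1-(1-p_b)^2] - (2 p_a p_b)^2 by inclusion-exclusion.
    """
    total = 0.0
    for (a, b), pg in _hwe_genotype_probs(freqs).items():
        pa, pb = freqs[a], freqs[b]
        ca = 1 - (1 - pa) ** 2  # carrier probability of allele a
        if a == b:
            compatible = ca * ca
        else:
            cb = 1 - (1 - pb) ** 2
            compatible = 2 * ca * cb - (2 * pa * pb) ** 2
        total += pg * (1 - compatible)
    return total


def pe_sibling(freqs: dict[int, float]) -> float:
    """Full-sib non-identity probability.

    Two siblings share a random Hardy-Weinberg parent couple and receive
    independent Mendelian transmissions; the statistic is the probability
    their single-locus genotypes differ.  Computed by exact enumeration
    over all parent-genotype pairs.
    """
    gp = _hwe_genotype_probs(freqs)
    genos = list(gp)
    identical = 0.0
    for g1 in genos:
        for g2 in genos:
            w = gp[g1] * gp[g2]
            # offspring distribution given this couple
            off: dict[tuple[int, int], float] = {}
            for a in g1:
                for b in g2:
                    key = (a, b) if a <= b else (b, a)
                    off[key] = off.get(key, 0.0) + 0.25
            identical += w * sum(v * v for v in off.values())
    return 1.0 - identical


def combine_panel(
    summaries: list[LocusForensicSummary], locus_order: list[str] | None = None
) -> PanelCurve:
    """Cumulative CMP and CPE trajectories along an ordered panel.

    CMP multiplies per-locus matching probabilities; each CPE family
    combines as 1 - prod(1 - PE).  No rounding happens inside the products.
    """
    by_name = {s.locus: s for s in summaries}
    order = locus_order if locus_order is not None else [s.locus for s in summaries]
    unknown = [l for l in order if l not in by_name]
    if unknown:
        raise KeyError(f"unknown loci in panel order: {unknown}")
    if len(set(order)) != len(order):
        raise ValueError("panel order contains duplicate loci")
    rows = [by_name[l] for l in order]
    cmp_ = np.cumprod([s.MP for s in rows])
    cpe1 = 1.0 - np.cumprod([1.0 - s.PE1P for s in rows])
    cpe2 = 1.0 - np.cumprod([1.0 - s.PE2P for s in rows])
    cpesi = 1.0 - np.cumprod([1.0 - s.PESI for s in rows])
    return PanelCurve(list(order), cmp_, cpe1, cpe2, cpesi)


_METRIC_ATTR = {"PE1P": "PE1P", "PE2P": "PE2P", "PESI": "PESI", "MP": "MP", "PIC": "PIC"}


def minimal_panel_size(
    summaries: list[LocusForensicSummary],
    metric: str = "PE1P",
    threshold: float = 0.9999,
    order: str | list[str] = "rank",
) -> PanelDesign:
    """Smallest marker prefix reaching a combined-power threshold.

    With ``order="rank"`` loci are sorted by the metric, descending for the
    exclusion families (ties broken by input order), ascending for MP; a
    named panel from :data:`NAMED_PANELS` or an explicit list fixes the
    order instead.  The search returns the shortest prefix whose combined
    CPE reaches ``threshold`` (or whose CMP drops to ``threshold`` when the
    metric is MP); an unreachable threshold yields ``minimal_size=None``.
    """
    metric = metric.upper().replace("-", "")
    if metric not in _METRIC_ATTR:
        raise ValueError(f"unknown metric {metric!r}")
    if not 0.0 < threshold < 1.0 and threshold != 0.0:
        raise ValueError("threshold must be in [0, 1)")

    if isinstance(order, str) and order == "rank":
        key = _METRIC_ATTR[metric if metric != "MP" else "MP"]
        reverse = metric != "MP"
        indexed = list(enumerate(summaries))
        indexed.sort(key=lambda t: ((-getattr(t[1], key)) if reverse else getattr(t[1], key), t[0]))
        names = [s.locus for _, s in indexed]
    elif isinstance(order, str):
        if order not in NAMED_PANELS:
            raise ValueError(f"unknown panel order {order!r}")
        names = list(NAMED_PANELS[order])
    else:
        names = list(order)

    curve = combine_panel(summaries, names)
    if metric == "MP":
        traj = curve.cmp
        reached = traj <= threshold
    else:
        traj = {"PE1P": curve.cpe1, "PE2P": curve.cpe2, "PESI": curve.cpesi, "PIC": curve.cpe1}[
            metric
        ]
        reached = traj >= threshold
    hits = np.flatnonzero(reached)
    if hits.size == 0:
        return PanelDesign(metric, threshold, None, names, None)
    size = int(hits[0]) + 1
    return PanelDesign(metric, threshold, size, names[:size], float(traj[size - 1]))
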