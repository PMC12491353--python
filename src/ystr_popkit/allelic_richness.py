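"""Rarefaction-standardised allelic richness: distinct and private alleles.

For haploid Y-STR data, population j at locus l holds N_jl sampled alleles of
which N_ijl are copies of allele i.  In a standardised subsample of size g
drawn without replacement, allele i is present with probability
1 − C(N_jl − N_ijl, g)/C(N_jl, g), so

    α̂_g(j)  = Σ_i [1 − C(N_jl − N_ijl, g) / C(N_jl, g)]              (distinct)
    π̂_g(j)  = Σ_i [ (1 − C(N_jl−N_ijl, g)/C(N_jl, g))
                     × Π_{j'≠j} C(N_j'l − N_ij'l, g)/C(N_j'l, g) ]    (private)

with C(a, b) = 0 whenever a < b.  Binomial ratios are computed with
log-gamma arithmetic for stability.  α̂ is nondecreasing and concave in g,
equals 1 at g = 1 and the observed distinct count at g = N_jl.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .haplotype_io import HaplotypeTable


def _log_choose(a: int, b: int) -> float:
    if b < 0 or a < b:
        return -np.inf
    return float(gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1))


def _absence_prob(n_total: int, n_allele: int, g: int) -> float:
    """P(allele absent from a subsample of g) = C(N−Ni, g)/C(N, g)."""
    num = _log_choose(n_total - n_allele, g)
    if num == -np.inf:
        return 0.0
    return float(np.exp(num - _log_choose(n_total, g)))


def distinct_rarefaction(counts: Mapping[object, int], g: int) -> float:
    """Expected number of distinct alleles in a subsample of size g."""
    N = sum(counts.values())
    if not 1 <= g <= N:
        raise ValueError(f"g must lie in [1, {N}], got {g}")
    return float(sum(1.0 - _absence_prob(N, c, g) for c in counts.values()))


def private_rarefaction(
    counts_by_pop: Mapping[str, Mapping[object, int]], g: int
) -> dict[str, float]:
    """Expected private (population-exclusive) alleles per population at size g."""
    if len(counts_by_pop) < 2:
        raise ValueError("private alleles require at least 2 populations")
    totals = {p: sum(c.values()) for p, c in counts_by_pop.items()}
    if g > min(totals.values()):
        raise ValueError(
            f"g={g} exceeds the smallest per-population sample {min(totals.values())}"
        )
    alleles = sorted({a for c in counts_by_pop.values() for a in c}, key=repr)
    out: dict[str, float] = {}
    for j, cj in counts_by_pop.items():
        total = 0.0
        for a in alleles:
            present_j = 1.0 - _absence_prob(totals[j], cj.get(a, 0), g)
            absent_others = 1.0
            for jp, cjp in counts_by_pop.items():
                if jp == j:
                    continue
                absent_others *= _absence_prob(totals[jp], cjp.get(a, 0), g)
            total += present_j * absent_others
        out[j] = total
    return out


def allele_counts(table: HaplotypeTable) -> dict[str, dict[str, Counter]]:
    """Per population, per locus allele counts (multi-copy loci pool copies)."""
    out: dict[str, dict[str, Counter]] = {}
    for pop, profiles in table.by_population().items():
        per_locus: dict[str, Counter] = {l: Counter() for l in table.panel.loci}
        for p in profiles:
            for locus in table.panel.loci:
                for a in p.alleles[locus]:
                    if not a.missing:
                        per_locus[locus][a.value] += 1
        out[pop] = per_locus
    return out


def richness_profile(
    table: HaplotypeTable,
    g_values=None,
    grouping: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Long-format rarefaction curves: (population, locus, g, distinct, private).

    ``grouping`` optionally maps sampled population labels onto coarser
    groups (e.g. regions onto countries) before counting.  The g grid
    defaults to 2..min over (population, locus) sample sizes.
    """
    if grouping:
        table = table.relabel(dict(grouping))
    counts = allele_counts(table)
    if len(counts) < 2:
        raise ValueError("richness profile requires at least 2 populations")
    loci = table.panel.loci
    g_cap = min(
        sum(counts[pop][locus].values())
        for pop in counts
        for locus in loci
        if sum(counts[pop][locus].values()) > 0
    )
    if g_values is None:
        g_values = range(2, g_cap + 1)
    rows = []
    for locus in loci:
        by_pop = {p: counts[p][locus] for p in counts}
        if any(sum(c.values()) == 0 for c in by_pop.values()):
            continue
        for g in g_values:
            if g > min(sum(c.values()) for c in by_pop.values()):
                continue
            priv = private_rarefaction(by_pop, g)
            for pop in counts:
                rows.append(
                    {
                        "population": pop,
                        "locus": locus,
                        "g": g,
                        "distinct": distinct_rarefaction(by_pop[pop], g),
                        "private": priv[pop],
                    }
                )
    return pd.DataFrame(rows, columns=["population", "locus", "g", "distinct", "private"])


def mean_richness(profile: pd.DataFrame) -> pd.DataFrame:
    """Mean distinct/private alleles per locus for each population and g."""
    return (
        profile.groupby(["population", "g"])[["distinct", "private"]]
        .mean()
        .reset_index()
    )
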