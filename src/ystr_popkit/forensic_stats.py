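"""Forensic and diversity parameters of a Y-STR haplotype table.

Implements the standard forensic summary for haplotype data: Nei's haplotype
diversity HD = n(1 − Σp²)/(n − 1), haplotype match probability HMP = 1 − HD,
discrimination capacity DC = h/n, fraction of unique haplotypes
FUH = 100 × singletons/h, per-locus gene diversity / match probability /
power of discrimination, and microvariant prevalence.

Haplotype frequencies are reported under two conventions: count/n (the
counting method) and count/h (frequency among distinct haplotypes); forensic
reports in the literature use both, so the summary labels each explicitly.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .haplotype_io import AlleleFrequencyTable, HaplotypeTable, allele_frequencies

HaplotypeKey = tuple


@dataclass(frozen=True)
class HaplotypeSpectrum:
    """Multiplicity spectrum of canonical haplotypes."""

    counts: Mapping[HaplotypeKey, int]
    n: int
    h: int
    singletons: int

    @classmethod
    def from_counts(cls, counts: Mapping[HaplotypeKey, int]) -> "HaplotypeSpectrum":
        n = sum(counts.values())
        return cls(
            counts=dict(counts),
            n=n,
            h=len(counts),
            singletons=sum(1 for c in counts.values() if c == 1),
        )


def _haplotype_key(profile, panel) -> HaplotypeKey:
    """Canonical key: allele values along panel positions; missing -> None.

    Missing is encoded as None (not NaN) so that equal keys compare equal and
    missing is distinct from every real allele.
    """
    key = []
    for locus in panel.loci:
        for a in profile.alleles[locus]:
            key.append(None if a.missing else a.value)
    return tuple(key)


def spectrum(table: HaplotypeTable, strict: bool = False) -> HaplotypeSpectrum:
    """Collapse a table into its haplotype multiplicity spectrum.

    With ``strict=True`` profiles with any missing allele are dropped;
    otherwise missing marks the key as distinct from every complete one.
    """
    if table.n == 0:
        raise ValueError("empty table")
    counts: Counter = Counter()
    for p in table.profiles:
        if strict and not p.is_complete():
            continue
        counts[_haplotype_key(p, table.panel)] += 1
    if not counts:
        raise ValueError("no profiles left after strict filtering")
    return HaplotypeSpectrum.from_counts(counts)


def haplotype_diversity(s: HaplotypeSpectrum) -> float:
    """Nei's HD = n(1 − Σ p_i²)/(n − 1) over haplotype frequencies."""
    if s.n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    sum_p2 = sum((c / s.n) ** 2 for c in s.counts.values())
    return s.n * (1.0 - sum_p2) / (s.n - 1)


def match_probability(s: HaplotypeSpectrum) -> float:
    """Σ p_i² over haplotype frequencies (random match probability)."""
    return sum((c / s.n) ** 2 for c in s.counts.values())


def discrimination_capacity(s: HaplotypeSpectrum) -> float:
    """DC = h/n: distinct haplotypes over sample size."""
    return s.h / s.n


def fraction_unique(s: HaplotypeSpectrum) -> float:
    """FUH (%) = 100 × singleton haplotypes / distinct haplotypes."""
    return 100.0 * s.singletons / s.h


def hmp(hd: float) -> float:
    """Haplotype match probability = 1 − HD."""
    if not 0.0 <= hd <= 1.0:
        raise ValueError(f"HD must lie in [0, 1], got {hd}")
    return 1.0 - hd


def locus_stats(freqs: AlleleFrequencyTable) -> pd.DataFrame:
    """Per-locus gene diversity, match probability and power of discrimination.

    MP = Σ p_i²; PD = 1 − MP; GD_biased = 1 − Σ p_i²;
    GD_unbiased = n/(n−1) × GD_biased (the STRAF convention).
    """
    rows = []
    for locus, spec in freqs.counts.items():
        n = freqs.n[locus]
        mp = sum((c / n) ** 2 for c in spec.values())
        gd = 1.0 - mp
        rows.append(
            {
                "locus": locus,
                "n": n,
                "n_alleles": len(spec),
                "MP": mp,
                "PD": 1.0 - mp,
                "GD_biased": gd,
                "GD_unbiased": n / (n - 1) * gd if n > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("locus")


def microvariant_scan(table: HaplotypeTable) -> pd.DataFrame:
    """Per locus: number and % of profiles carrying any non-integer allele.

    A profile counts once per locus if any copy there has a nonzero
    fractional part (so a DYS385 pair (13.2, 17) counts as a carrier).
    """
    rows = []
    for locus in table.panel.loci:
        carriers = sum(
            1
            for p in table.profiles
            if any(a.is_microvariant for a in p.alleles[locus])
        )
        rows.append(
            {
                "locus": locus,
                "carriers": carriers,
                "percent": 100.0 * carriers / table.n if table.n else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("locus")


@dataclass(frozen=True)
class ForensicSummary:
    """Aggregated haplotype-level and per-locus forensic parameters."""

    n: int
    h: int
    singletons: int
    HD: float
    HMP: float
    MP_hap: float
    DC: float
    FUH: float
    most_common_count: int
    most_common_freq_by_n: float
    most_common_freq_by_h: float
    mean_GD: float
    sd_GD: float
    n_loci_5plus_alleles: int
    per_locus: pd.DataFrame
    microvariants: pd.DataFrame

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n", "h", "singletons", "HD", "HMP", "MP_hap", "DC", "FUH",
                "most_common_count", "most_common_freq_by_n",
                "most_common_freq_by_h", "mean_GD", "sd_GD",
                "n_loci_5plus_alleles",
            )
        }
        return d


def summarize(table: HaplotypeTable, gd_convention: str = "unbiased") -> ForensicSummary:
    """Full forensic summary of a haplotype table.

    ``gd_convention`` picks which per-locus gene diversity ("unbiased" or
    "biased") feeds the mean/SD over loci; the SD uses the sample (n−1)
    denominator.
    """
    s = spectrum(table)
    freqs = allele_frequencies(table)
    per_locus = locus_stats(freqs)
    micro = microvariant_scan(table)
    hd = haplotype_diversity(s) if s.n >= 2 else 0.0
    gd_col = {"unbiased": "GD_unbiased", "biased": "GD_biased"}[gd_convention]
    gd = per_locus[gd_col].to_numpy()
    mc = max(s.counts.values())
    return ForensicSummary(
        n=s.n,
        h=s.h,
        singletons=s.singletons,
        HD=hd,
        HMP=hmp(hd),
        MP_hap=match_probability(s),
        DC=discrimination_capacity(s),
        FUH=fraction_unique(s),
        most_common_count=mc,
        most_common_freq_by_n=mc / s.n,
        most_common_freq_by_h=mc / s.h,
        mean_GD=float(np.mean(gd)),
        sd_GD=float(np.std(gd, ddof=1)) if len(gd) > 1 else 0.0,
        n_loci_5plus_alleles=int((per_locus["n_alleles"] >= 5).sum()),
        per_locus=per_locus,
        microvariants=micro,
    )
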