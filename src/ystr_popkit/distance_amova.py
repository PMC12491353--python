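"""Squared repeat-count distances, average pairwise differences, and R_ST.

The microsatellite distance between two haplotypes is the sum over loci of
the squared repeat-count difference (DYS385 contributes both positions after
ascending sort of each pair).  Pairwise-difference summaries and a two-level
AMOVA on these distances yield the R_ST analogue of F_ST:

    SSD_total  = (1/N) Σ_{i<j} d_ij          over all N individuals
    SSD_within = Σ_p (1/n_p) Σ_{i<j in p} d_ij
    SSD_among  = SSD_total − SSD_within
    MS_among   = SSD_among/(P−1);  MS_within = SSD_within/(N−P)
    n_c        = (N − Σ n_p²/N)/(P−1)
    σ²_w = MS_within;  σ²_a = (MS_among − MS_within)/n_c
    R_ST = σ²_a/(σ²_a + σ²_w)

Negative R_ST values are reported as computed, never clamped.

Locus-handling switches (`DistanceOptions`) cover the conventions an
Arlequin-style analysis may or may not have used: DYS385 in or out, raw vs
difference-encoded DYS389II, face-value vs rounded microvariants.  Loci
missing in either member of a pair contribute 0 to that pair's distance
(pairwise deletion); strict mode drops incomplete profiles up front.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .haplotype_io import (
    HaplotypeTable,
    LocusPanel,
    STRProfile,
    encode_dys389ii,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceOptions:
    include_dys385: bool = True
    use_encoded_dys389ii: bool = False
    round_microvariants: bool = False
    strict: bool = False  # drop profiles with any missing allele


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-9):
            raise ValueError("diagonal must be zero")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", v)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_phylip(self) -> str:
        lines = [f"{len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            lines.append(
                f"{lab[:10]:<12}" + " ".join(f"{x:.6f}" for x in row)
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))


def _distance_positions(panel: LocusPanel, options: DistanceOptions,
                        locus_subset=None) -> list[tuple[str, int]]:
    loci = list(locus_subset) if locus_subset is not None else list(panel.loci)
    if not loci:
        raise ValueError("empty locus subset")
    positions = []
    for locus, c in panel.positions:
        if locus not in loci:
            continue
        if not options.include_dys385 and locus in panel.multi_copy:
            continue
        positions.append((locus, c))
    if not positions:
        raise ValueError("no positions left after applying options")
    return positions


def _prepared_table(table: HaplotypeTable, options: DistanceOptions) -> HaplotypeTable:
    if options.use_encoded_dys389ii:
        table = encode_dys389ii(table)
    if options.strict:
        profs = tuple(p for p in table.profiles if p.is_complete())
        table = HaplotypeTable(table.panel, profs, table.dys389ii_encoded)
    return table


def _position_matrix(table: HaplotypeTable, options: DistanceOptions) -> np.ndarray:
    table = _prepared_table(table, options)
    X, positions = table.position_matrix()
    keep = [
        j
        for j, (locus, _) in enumerate(positions)
        if options.include_dys385 or locus not in table.panel.multi_copy
    ]
    X = X[:, keep]
    if options.round_microvariants:
        X = np.floor(X + 0.5)  # half away from zero (alleles are positive)
    return X


def haplotype_distance(
    a: STRProfile,
    b: STRProfile,
    panel: LocusPanel,
    locus_subset=None,
    options: DistanceOptions = DistanceOptions(),
) -> float:
    """Σ over included loci of (allele_a − allele_b)²; missing contributes 0."""
    positions = _distance_positions(panel, options, locus_subset)
    total = 0.0
    for locus, c in positions:
        va = a.alleles[locus][c]
        vb = b.alleles[locus][c]
        if va.missing or vb.missing:
            logger.debug("pair (%s,%s): %s copy %d missing; contributes 0",
                         a.sample_id, b.sample_id, locus, c)
            continue
        xa, xb = va.value, vb.value
        if options.round_microvariants:
            xa, xb = np.floor(xa + 0.5), np.floor(xb + 0.5)
        total += (xa - xb) ** 2
    return float(total)


def squared_distance_matrix(
    table: HaplotypeTable, options: DistanceOptions = DistanceOptions()
) -> DistanceMatrix:
    """Individual-level matrix of summed squared repeat differences."""
    prepared = _prepared_table(table, options)
    X = _position_matrix(table, options)
    n = X.shape[0]
    D = np.zeros((n, n))
    for j in range(X.shape[1]):
        col = X[:, j]
        finite = np.isfinite(col)
        diff = np.subtract.outer(col, col) ** 2
        mask = np.outer(finite, finite)
        D += np.where(mask, np.nan_to_num(diff), 0.0)
    labels = tuple(p.sample_id for p in prepared.profiles)
    return DistanceMatrix(labels, D)


@dataclass(frozen=True)
class PairwiseDiffResult:
    """Within (PiX), between (PiXY) and corrected average pairwise differences."""

    pix: pd.Series
    pixy: pd.DataFrame
    corrected: pd.DataFrame


def pairwise_differences(
    table: HaplotypeTable, options: DistanceOptions = DistanceOptions()
) -> PairwiseDiffResult:
    """Average pairwise distances within/between populations.

    PiX uses all n(n−1)/2 unordered within pairs; PiXY all nA×nB cross pairs;
    corrected = PiXY − (PiX + PiY)/2.  Populations of size 1 get PiX = NaN and
    NaN corrected entries.
    """
    prepared = _prepared_table(table, options)
    D = squared_distance_matrix(table, options).values
    pops = prepared.populations
    idx = {pop: [i for i, p in enumerate(prepared.profiles) if p.population == pop]
           for pop in pops}
    pix = {}
    for pop in pops:
        ii = idx[pop]
        if len(ii) < 2:
            pix[pop] = np.nan
            continue
        sub = D[np.ix_(ii, ii)]
        pix[pop] = sub[np.triu_indices(len(ii), k=1)].mean()
    pixy = pd.DataFrame(np.nan, index=pops, columns=pops)
    for a, b in itertools.combinations(pops, 2):
        m = D[np.ix_(idx[a], idx[b])].mean()
        pixy.loc[a, b] = pixy.loc[b, a] = m
    for pop in pops:
        pixy.loc[pop, pop] = pix[pop]
    corrected = pd.DataFrame(0.0, index=pops, columns=pops)
    for a, b in itertools.combinations(pops, 2):
        corrected.loc[a, b] = corrected.loc[b, a] = (
            pixy.loc[a, b] - (pix[a] + pix[b]) / 2.0
        )
    return PairwiseDiffResult(
        pix=pd.Series(pix, name="PiX"), pixy=pixy, corrected=corrected
    )


@dataclass(frozen=True)
class AmovaResult:
    ssd_total: float
    ssd_within: float
    ssd_among: float
    df_among: int
    df_within: int
    sigma2_among: float
    sigma2_within: float
    n_c: float
    rst: float
    degenerate: bool = False


def amova_pair(
    table: HaplotypeTable,
    pop_a: str,
    pop_b: str,
    options: DistanceOptions = DistanceOptions(),
) -> AmovaResult:
    """Two-level AMOVA between two populations on squared repeat distances."""
    sub = table.subset([pop_a, pop_b])
    prepared = _prepared_table(sub, options)
    sizes = {pop: sum(1 for p in prepared.profiles if p.population == pop)
             for pop in (pop_a, pop_b)}
    if min(sizes.values()) < 2:
        raise ValueError("each population needs at least 2 members for AMOVA")
    D = squared_distance_matrix(sub, options).values
    groups = [p.population for p in prepared.profiles]
    N = len(groups)
    P = 2
    iu = np.triu_indices(N, k=1)
    ssd_total = D[iu].sum() / N
    ssd_within = 0.0
    for pop, npop in sizes.items():
        ii = [i for i, g in enumerate(groups) if g == pop]
        sub_d = D[np.ix_(ii, ii)]
        ssd_within += sub_d[np.triu_indices(npop, k=1)].sum() / npop
    ssd_among = ssd_total - ssd_within
    ms_among = ssd_among / (P - 1)
    ms_within = ssd_within / (N - P)
    n_c = (N - sum(s**2 for s in sizes.values()) / N) / (P - 1)
    sigma2_w = ms_within
    sigma2_a = (ms_among - ms_within) / n_c
    denom = sigma2_a + sigma2_w
    if abs(denom) < 1e-12:
        return AmovaResult(ssd_total, ssd_within, ssd_among, P - 1, N - P,
                           sigma2_a, sigma2_w, n_c, rst=0.0, degenerate=True)
    return AmovaResult(ssd_total, ssd_within, ssd_among, P - 1, N - P,
                       sigma2_a, sigma2_w, n_c, rst=sigma2_a / denom)


def rst_matrix(
    table: HaplotypeTable, options: DistanceOptions = DistanceOptions()
) -> DistanceMatrix:
    """Pairwise R_ST over all populations (diagonal 0; negatives kept)."""
    pops = table.populations
    if len(pops) < 2:
        raise ValueError("R_ST matrix requires at least 2 populations")
    M = np.zeros((len(pops), len(pops)))
    for (i, a), (j, b) in itertools.combinations(enumerate(pops), 2):
        M[i, j] = M[j, i] = amova_pair(table, a, b, options).rst
    return DistanceMatrix(tuple(pops), M)
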