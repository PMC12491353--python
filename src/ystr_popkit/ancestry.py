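"""Ancestry-variability statistics on Q matrices and haplogroup prediction.

The variability of admixture membership vectors within a population is
summarised by an F_ST-style statistic on the rows of a Q matrix (individuals
× K clusters, rows on the simplex).  With column means p̄_k,

    F_ST = ( mean_i Σ_k q_ik² − Σ_k p̄_k² ) / ( 1 − Σ_k p̄_k² ),

normalised by F_ST^max, the maximum over all row-stochastic matrices with the
same column means.  The maximiser concentrates rows at simplex vertices:
⌊I·p̄_k⌋ rows go wholly to cluster k, and the remaining fractional column
masses (each < 1, hence at most K−1 mixed rows) are packed by a sequential
fill, taking the best packing over orderings of the residual columns.  Low
F_ST/F_ST^max indicates homogeneous (non-admixed-looking) membership.

Haplogroup assignment is a configurable naive-Bayes classifier over per-locus
allele frequencies with additive pseudocount smoothing, in the spirit of the
public Y-STR haplogroup predictors.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .haplotype_io import HaplotypeTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Q matrices


@dataclass(frozen=True)
class QMatrix:
    """Individuals × K membership coefficients with population labels."""

    values: np.ndarray
    individuals: tuple[str, ...]
    populations: tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("Q must be 2-D")
        if (v < -1e-9).any() or (v > 1 + 1e-9).any():
            raise ValueError("Q entries must lie in [0, 1]")
        if not np.allclose(v.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("Q rows must sum to 1")
        if len(self.individuals) != v.shape[0] or len(self.populations) != v.shape[0]:
            raise ValueError("label lengths must match rows")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "individuals", tuple(self.individuals))
        object.__setattr__(self, "populations", tuple(self.populations))

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def rows_for(self, population: str) -> np.ndarray:
        mask = [p == population for p in self.populations]
        return self.values[np.asarray(mask)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[f"Q{i+1}" for i in range(self.k)]
        )
        df.insert(0, "individual", self.individuals)
        df.insert(1, "population", self.populations)
        return df


def read_qmatrix(path, fmt: str = "csv") -> QMatrix:
    """Read a Q matrix from plain CSV (individual, population, Q1..QK) or a
    STRUCTURE-style q file ("idx label miss pop : q1 ... qK")."""
    if fmt == "csv":
        df = pd.read_csv(path)
        qcols = [c for c in df.columns if str(c).upper().startswith("Q")]
        return QMatrix(
            df[qcols].to_numpy(float),
            tuple(df.iloc[:, 0].astype(str)),
            tuple(df["population"].astype(str))
            if "population" in df.columns
            else tuple("pop1" for _ in range(len(df))),
        )
    if fmt == "structure":
        inds, pops, rows = [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or ":" not in line:
                    continue
                meta, qpart = line.split(":", 1)
                fields = meta.split()
                inds.append(fields[1] if len(fields) > 1 else fields[0])
                pops.append(fields[-1])
                rows.append([float(x) for x in qpart.split()])
        return QMatrix(np.array(rows), tuple(inds), tuple(pops))
    raise ValueError(f"unknown Q-matrix format {fmt!r}")


# ---------------------------------------------------------------------------
# F_ST / F_ST^max


def _fst_from_rows(q: np.ndarray) -> tuple[float, bool]:
    pbar = q.mean(axis=0)
    denom = 1.0 - (pbar**2).sum()
    if denom < 1e-12:
        return 0.0, True
    num = (q**2).sum(axis=1).mean() - (pbar**2).sum()
    return float(num / denom), False


def fst_of_q(q: np.ndarray) -> float:
    """Variance-style F_ST of membership rows (0 = identical rows).

    A degenerate population (all mass on a single vertex, denominator 0) is
    reported as 0.
    """
    q = np.asarray(q, dtype=float)
    if q.shape[0] < 2:
        raise ValueError("F_ST of a Q block requires at least 2 rows")
    fst, degenerate = _fst_from_rows(q)
    if degenerate:
        logger.info("degenerate Q block (single-vertex mean); F_ST set to 0")
    return fst


def _sequential_fill(residual: np.ndarray, order: Sequence[int], n_rows: int) -> np.ndarray:
    """Pack residual column masses into n_rows rows of capacity 1, in order."""
    K = residual.size
    rows = np.zeros((n_rows, K))
    r = 0
    cap = 1.0
    for k in order:
        m = residual[k]
        while m > 1e-12:
            if r >= n_rows:  # numerical crumbs
                rows[-1, k] += m
                break
            take = min(m, cap)
            rows[r, k] += take
            m -= take
            cap -= take
            if cap <= 1e-12:
                r += 1
                cap = 1.0
    return rows


def qmax_matrix(pbar: np.ndarray, I: int) -> np.ndarray:
    """A row-stochastic I×K matrix with column means p̄ maximising Σ q²."""
    pbar = np.asarray(pbar, dtype=float)
    if abs(pbar.sum() - 1.0) > 1e-6 or (pbar < -1e-12).any():
        raise ValueError("p̄ must lie on the simplex")
    K = pbar.size
    col_mass = I * pbar
    pure = np.floor(col_mass + 1e-9).astype(int)
    residual = col_mass - pure
    residual[residual < 1e-9] = 0.0
    n_res = I - int(pure.sum())
    rows = [np.eye(K)[k] for k in range(K) for _ in range(pure[k])]
    if n_res > 0:
        active = [k for k in range(K) if residual[k] > 0]
        best = None
        best_val = -np.inf
        orders = (
            itertools.permutations(active)
            if len(active) <= 7
            else [tuple(sorted(active, key=lambda k: -residual[k]))]
        )
        for order in orders:
            cand = _sequential_fill(residual, order, n_res)
            val = (cand**2).sum()
            if val > best_val + 1e-12:
                best_val, best = val, cand
        rows.extend(best)
    Q = np.array(rows) if rows else np.zeros((0, K))
    return Q


def fst_max_of_q(pbar: np.ndarray, I: int) -> float:
    """Maximum F_ST over conforming Q matrices (vertex-concentration bound).

    Degenerate p̄ (all mass on one cluster) yields 0 by convention.
    """
    pbar = np.asarray(pbar, dtype=float)
    if I < 2:
        raise ValueError("I must be >= 2")
    if 1.0 - (pbar**2).sum() < 1e-12:
        return 0.0
    fst, _ = _fst_from_rows(qmax_matrix(pbar, I))
    return fst


@dataclass(frozen=True)
class FstructResult:
    population: str
    fst: float
    fst_max: float
    ratio: float
    replicates: np.ndarray  # bootstrap sample of ratios (possibly empty)


def _ratio(q: np.ndarray) -> tuple[float, float, float]:
    fst, degenerate = _fst_from_rows(q)
    if degenerate:
        return 0.0, 0.0, 0.0
    fmax = fst_max_of_q(q.mean(axis=0), q.shape[0])
    if fmax <= 0:
        return fst, fmax, 0.0
    return fst, fmax, fst / fmax


def fst_ratio_bootstrap(
    qmat: QMatrix, B: int = 100, seed: int | None = None
) -> list[FstructResult]:
    """Point estimate and within-population bootstrap of F_ST/F_ST^max.

    Rows are resampled with replacement within each population; B = 0 returns
    the point estimates only.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    results = []
    for pop in dict.fromkeys(qmat.populations):
        q = qmat.rows_for(pop)
        if q.shape[0] < 2:
            logger.warning("population %s has a single row; skipped", pop)
            continue
        fst, fmax, ratio = _ratio(q)
        reps = np.empty(B)
        for b in range(B):
            idx = rng.integers(0, q.shape[0], size=q.shape[0])
            reps[b] = _ratio(q[idx])[2]
        results.append(FstructResult(pop, fst, fmax, ratio, reps))
    return results


def kruskal_wallis(groups: Mapping[str, Sequence[float]]):
    """Kruskal–Wallis rank test across groups: (H, df, p).

    All-identical values yield H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        return 0.0, len(groups) - 1, 1.0
    H, p = stats.kruskal(*arrays)
    return float(H), len(groups) - 1, float(p)


def haplogroup_composition(
    counts: Mapping[str, int], total: int | None = None, decimals: int = 2
) -> pd.DataFrame:
    """Haplogroup counts with percentages truncated to ``decimals`` places.

    Percentages are floored (not rounded) at the requested precision, the
    convention of the forensic reports this mirrors (76/128 → 59.37%).
    """
    total = total if total is not None else sum(counts.values())
    scale = 10**decimals
    rows = [
        {
            "haplogroup": hg,
            "count": c,
            "percent": math.floor(100.0 * c / total * scale) / scale,
        }
        for hg, c in counts.items()
    ]
    return pd.DataFrame(rows, columns=["haplogroup", "count", "percent"])


# ---------------------------------------------------------------------------
# naive-Bayes haplogroup predictor


@dataclass(frozen=True)
class HaplogroupModel:
    """Per-haplogroup, per-locus allele probabilities (pseudocount-smoothed)."""

    haplogroups: tuple[str, ...]
    priors: Mapping[str, float]
    tables: Mapping[str, Mapping[str, Mapping[float, float]]]  # hg -> locus -> allele -> P
    unseen: Mapping[str, Mapping[str, float]]  # hg -> locus -> P(unseen allele)
    alpha: float
    loci: tuple[str, ...]


def fit_haplogroup_model(
    reference: HaplotypeTable,
    labels: Mapping[str, str] | None = None,
    alpha: float = 0.5,
    uniform_priors: bool = False,
) -> HaplogroupModel:
    """Fit allele-frequency tables per haplogroup with additive smoothing.

    ``labels`` maps sample ids to haplogroup labels; by default the table's
    population field is taken as the haplogroup.  Each locus uses a support
    of the alleles observed across all references plus one unseen bucket, so
    P(a | hg) = (count + α) / (N + α·(V + 1)).
    """
    get_label = (lambda p: labels[p.sample_id]) if labels else (lambda p: p.population)
    hgs = sorted({get_label(p) for p in reference.profiles})
    counts: dict[str, dict[str, dict[float, int]]] = {
        hg: {l: {} for l in reference.panel.loci} for hg in hgs
    }
    n_obs: dict[str, dict[str, int]] = {hg: {l: 0 for l in reference.panel.loci} for hg in hgs}
    for p in reference.profiles:
        hg = get_label(p)
        for locus in reference.panel.loci:
            for a in p.alleles[locus]:
                if a.missing:
                    continue
                counts[hg][locus][a.value] = counts[hg][locus].get(a.value, 0) + 1
                n_obs[hg][locus] += 1
    loci = tuple(
        l
        for l in reference.panel.loci
        if any(n_obs[hg][l] > 0 for hg in hgs)
        or logger.warning("locus %s absent from references; dropped", l)
    )
    support = {
        l: sorted({a for hg in hgs for a in counts[hg][l]}) for l in loci
    }
    tables: dict[str, dict[str, dict[float, float]]] = {}
    unseen: dict[str, dict[str, float]] = {}
    for hg in hgs:
        tables[hg] = {}
        unseen[hg] = {}
        for l in loci:
            V = len(support[l]) + 1  # +1 unseen bucket
            denom = n_obs[hg][l] + alpha * V
            tables[hg][l] = {
                a: (counts[hg][l].get(a, 0) + alpha) / denom for a in support[l]
            }
            unseen[hg][l] = alpha / denom
    if uniform_priors:
        priors = {hg: 1.0 / len(hgs) for hg in hgs}
    else:
        label_counts = {hg: 0 for hg in hgs}
        for p in reference.profiles:
            label_counts[get_label(p)] += 1
        total = sum(label_counts.values())
        priors = {hg: c / total for hg, c in label_counts.items()}
    return HaplogroupModel(tuple(hgs), priors, tables, unseen, alpha, loci)


def predict_from_values(
    values: Mapping[str, object], model: HaplogroupModel
) -> list[tuple[str, float]]:
    """Rank haplogroups by naive-Bayes posterior for plain locus → value(s).

    Values may be scalars or tuples (multi-copy loci contribute each copy).
    Loci missing from ``values`` or from the model are skipped; if no locus
    is usable the posterior falls back to the priors.
    """
    logpost = {}
    any_locus = False
    for hg in model.haplogroups:
        lp = math.log(model.priors[hg]) if model.priors[hg] > 0 else -math.inf
        for locus, raw in values.items():
            if locus not in model.tables[hg]:
                continue
            vals = raw if isinstance(raw, (tuple, list)) else (raw,)
            for v in vals:
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    continue
                p = model.tables[hg][locus].get(float(v), model.unseen[hg][locus])
                lp += math.log(p)
                any_locus = True
        logpost[hg] = lp
    if not any_locus:
        logger.warning("no usable loci; returning prior as posterior")
        logpost = {hg: math.log(max(model.priors[hg], 1e-300)) for hg in model.haplogroups}
    m = max(logpost.values())
    post = {hg: math.exp(lp - m) for hg, lp in logpost.items()}
    z = sum(post.values())
    ranked = sorted(
        ((hg, p / z) for hg, p in post.items()), key=lambda t: (-t[1], t[0])
    )
    return ranked


def predict_haplogroup(profile, model: HaplogroupModel) -> list[tuple[str, float]]:
    """Ranked (haplogroup, posterior) for an STR profile; ties alphabetical."""
    values = {
        locus: tuple(a.as_float() for a in copies)
        for locus, copies in profile.alleles.items()
    }
    return predict_from_values(values, model)
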