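"""Stepwise-mutation-model simulator for Y-STR tables and Dirichlet Q matrices.

The generator emulates the statistical shape of a small Arabian-peninsula
Y-STR sample: ~128 males typed at the 17 Yfiler positions, a few founder
lineages with strongly skewed proportions (a dominant ~59% lineage and a
~21% secondary lineage), star-like haplotype clusters produced by shallow
geometric genealogical depths, and a partial-repeat (".2") microvariant at
DYS458 concentrated in the dominant lineage.

Each individual draws a lineage by proportion, copies that lineage's founder
haplotype, and accumulates symmetric single-step mutations: at every locus,
each of ``depth`` generations mutates the repeat count by ±1 with
probability μ (the stepwise mutation model under which squared-difference
R_ST is the natural estimator).  Per-population divergence is modelled by
letting each population's founder copies drift independently for
``divergence_depth`` generations before individuals are drawn.  Everything
is deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ancestry import QMatrix
from .haplotype_io import (
    Allele,
    HaplotypeTable,
    LocusPanel,
    STRProfile,
    YFILER_PANEL,
)

#: Founder haplotypes: plausible modal Yfiler values for the three lineages.
#: These are configuration constants, not biology claims.
DEFAULT_FOUNDERS: dict[str, dict[str, object]] = {
    "J1a": {
        "DYS19": 14, "DYS389I": 13, "DYS389II": 30, "DYS390": 23, "DYS391": 11,
        "DYS392": 11, "DYS393": 12, "DYS385": (13, 17), "DYS438": 10,
        "DYS439": 11, "DYS437": 14, "DYS448": 20, "DYS456": 15, "DYS458": 18,
        "DYS635": 21, "YGATAH4": 11,
    },
    "E1b1b": {
        "DYS19": 13, "DYS389I": 13, "DYS389II": 30, "DYS390": 24, "DYS391": 10,
        "DYS392": 11, "DYS393": 13, "DYS385": (16, 18), "DYS438": 10,
        "DYS439": 12, "DYS437": 14, "DYS448": 20, "DYS456": 15, "DYS458": 16,
        "DYS635": 22, "YGATAH4": 11,
    },
    "Other": {
        "DYS19": 15, "DYS389I": 12, "DYS389II": 28, "DYS390": 22, "DYS391": 10,
        "DYS392": 13, "DYS393": 14, "DYS385": (11, 14), "DYS438": 9,
        "DYS439": 10, "DYS437": 15, "DYS448": 19, "DYS456": 16, "DYS458": 15,
        "DYS635": 23, "YGATAH4": 12,
    },
}


@dataclass(frozen=True)
class LineageSpec:
    name: str
    proportion: float
    founder: Mapping[str, object]


@dataclass(frozen=True)
class MicrovariantRule:
    """Inject a partial-repeat offset at a locus for one lineage's carriers."""

    locus: str = "DYS458"
    lineage: str = "J1a"
    probability: float = 1.0
    offset: float = 0.2


def default_lineages() -> tuple[LineageSpec, ...]:
    return (
        LineageSpec("J1a", 0.59, DEFAULT_FOUNDERS["J1a"]),
        LineageSpec("E1b1b", 0.21, DEFAULT_FOUNDERS["E1b1b"]),
        LineageSpec("Other", 0.20, DEFAULT_FOUNDERS["Other"]),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped defaults: one population of 128 males, three lineages,
    μ = 0.002/locus/generation, mean genealogical depth 50 (geometric)."""

    populations: tuple[tuple[str, int], ...] = (("Yemen", 128),)
    lineages: tuple[LineageSpec, ...] = field(default_factory=default_lineages)
    mu: float = 0.002
    depth: int = 50
    depth_distribution: str = "geometric"  # or "fixed"
    microvariant_rules: tuple[MicrovariantRule, ...] = (
        MicrovariantRule("DYS458", "J1a", 1.0),
        MicrovariantRule("DYS458", "Other", 0.15),
    )
    divergence_depth: int = 0
    seed: int | None = None
    panel: LocusPanel = YFILER_PANEL

    def __post_init__(self):
        props = [l.proportion for l in self.lineages]
        if abs(sum(props) - 1.0) > 1e-9 or any(p < 0 for p in props):
            raise ValueError("lineage proportions must be non-negative and sum to 1")
        if not 0 < self.mu <= 0.1:
            raise ValueError("mu must lie in (0, 0.1]")
        if any(n < 1 for _, n in self.populations):
            raise ValueError("population sizes must be >= 1")


def _mutate(value: int, generations: int, mu: float, rng: np.random.Generator) -> int:
    """Net displacement after `generations` chances of a ±1 step with prob μ."""
    k = rng.binomial(generations, mu)
    if k == 0:
        return value
    steps = rng.integers(0, 2, size=k) * 2 - 1
    return int(value + steps.sum())


def _founder_vectors(config: SimulationConfig):
    """Per-lineage founder values as {locus: tuple of ints}."""
    out = {}
    for lin in config.lineages:
        vals = {}
        for locus in config.panel.loci:
            raw = lin.founder[locus]
            vals[locus] = tuple(raw) if isinstance(raw, (tuple, list)) else (raw,)
        out[lin.name] = vals
    return out


def simulate_table(
    config: SimulationConfig = SimulationConfig(), seed: int | None = None
) -> tuple[HaplotypeTable, pd.Series]:
    """Simulate a haplotype table; returns (table, true lineage per sample)."""
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    founders = _founder_vectors(config)
    props = np.array([l.proportion for l in config.lineages])
    names = [l.name for l in config.lineages]
    profiles = []
    truth: dict[str, str] = {}
    for pop, n in config.populations:
        # population-specific founder drift
        pop_founders = {}
        for lin in names:
            pop_founders[lin] = {
                locus: tuple(
                    _mutate(v, config.divergence_depth, config.mu, rng)
                    for v in copies
                )
                for locus, copies in founders[lin].items()
            }
        for i in range(n):
            lin = names[rng.choice(len(names), p=props)]
            if config.depth_distribution == "geometric":
                depth = int(rng.geometric(1.0 / max(config.depth, 1)))
            else:
                depth = config.depth
            values: dict[str, object] = {}
            for locus in config.panel.loci:
                copies = tuple(
                    _mutate(v, depth, config.mu, rng)
                    for v in pop_founders[lin][locus]
                )
                values[locus] = copies if len(copies) > 1 else copies[0]
            for rule in config.microvariant_rules:
                if rule.lineage == lin and rng.random() < rule.probability:
                    v = values[rule.locus]
                    if isinstance(v, tuple):
                        values[rule.locus] = (v[0] + rule.offset,) + v[1:]
                    else:
                        values[rule.locus] = v + rule.offset
            sid = f"{pop}_{i+1:03d}"
            profiles.append(STRProfile.build(sid, pop, values, config.panel))
            truth[sid] = lin
    table = HaplotypeTable(panel=config.panel, profiles=tuple(profiles))
    return table, pd.Series(truth, name="lineage")


def simulate_q(
    sizes: Mapping[str, int],
    K: int,
    alpha: Mapping[str, float | Sequence[float]],
    seed: int | None = None,
) -> QMatrix:
    """Dirichlet membership model: rows i.i.d. Dirichlet(alpha_pop)."""
    rng = np.random.default_rng(seed)
    rows, inds, pops = [], [], []
    for pop, n in sizes.items():
        a = alpha[pop]
        avec = np.full(K, float(a)) if np.isscalar(a) else np.asarray(a, float)
        if (avec <= 0).any():
            raise ValueError("alpha must be > 0")
        for i in range(n):
            rows.append(rng.dirichlet(avec))
            inds.append(f"{pop}_{i+1:03d}")
            pops.append(pop)
    return QMatrix(np.array(rows), tuple(inds), tuple(pops))


def study_config(seed: int | None = None) -> SimulationConfig:
    """The study-shaped default configuration (n=128, 59/21/20 lineages)."""
    return replace(SimulationConfig(), seed=seed)


def divergence_config(
    divergence_depth: int,
    n_per_pop: int = 50,
    mu: float = 0.01,
    depth: int = 10,
    seed: int | None = None,
) -> SimulationConfig:
    """Two populations split from one founder set; an experiment config for
    checking that R_ST grows with divergence depth."""
    return SimulationConfig(
        populations=(("popA", n_per_pop), ("popB", n_per_pop)),
        lineages=(LineageSpec("J1a", 1.0, DEFAULT_FOUNDERS["J1a"]),),
        mu=mu,
        depth=depth,
        depth_distribution="fixed",
        microvariant_rules=(),
        divergence_depth=divergence_depth,
        seed=seed,
    )
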