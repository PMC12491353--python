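"""Reading, validation and canonical representation of Y-STR haplotype tables.

The central objects are :class:`LocusPanel` (which loci exist and how they are
reported), :class:`STRProfile` (one male's alleles) and :class:`HaplotypeTable`
(a labelled collection of profiles).  The default panel is the 17-marker Yfiler
set: 16 locus labels, of which DYS385 is a constitutively duplicated locus
reported as an unordered pair, so a complete haplotype carries 17 allele
values.

Conventions
-----------
* Alleles are decimal repeat counts (``14``, ``17.2``).  Microvariants keep
  their fractional part; the only legal fractional parts are .1/.2/.3.
* Missing data: the sentinel input code ``99`` and blank cells both map to a
  single missing state (:attr:`Allele.missing`).
* DYS385 pairs are always stored sorted ascending (the assay cannot phase the
  two copies).
* DYS389II is stored RAW.  The difference encoding (DYS389II − DYS389I) used
  for allele-frequency display is a view applied by
  :func:`encode_dys389ii` / :func:`decode_dys389ii`, guarded by a state flag
  on the table, and is never used in distance computations by default.
"""

from __future__ import annotations

import logging
import math
import os
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical Yfiler locus labels (DYS385 contributes two allele values).
YFILER_LOCI: tuple[str, ...] = (
    "DYS19", "DYS389I", "DYS389II", "DYS390", "DYS391", "DYS392", "DYS393",
    "DYS385", "DYS438", "DYS439", "DYS437", "DYS448", "DYS456", "DYS458",
    "DYS635", "YGATAH4",
)

MISSING_CODE = 99.0
_VALID_FRACTIONS = (0.0, 0.1, 0.2, 0.3)

# alias -> canonical locus name (matching is done on upper-cased, separator-
# stripped column names, so "Y-GATA-H4", "YGATA H4" etc. all resolve)
_LOCUS_ALIASES = {
    "YGATAH4": "YGATAH4",
    "GATAH4": "YGATAH4",
    "H4": "YGATAH4",
    "DYS385AB": "DYS385",
}

_SAMPLE_COLUMN_NAMES = {"SAMPLEID", "SAMPLE", "ID", "SAMPLENAME", "INDIVIDUAL"}
_POPULATION_COLUMN_NAMES = {"POPULATION", "POP", "GROUP", "REGION"}


def _normalize_colname(name: str) -> str:
    return "".join(ch for ch in str(name).upper() if ch.isalnum())


class HaplotypeIOError(ValueError):
    """Hard error while reading or validating a haplotype table."""


@dataclass(frozen=True, order=True)
class Allele:
    """A decimal repeat count, or a flagged missing call.

    Missing alleles sort after every real allele, so sorted DYS385 pairs are
    deterministic even with partial data.
    """

    missing: bool
    value: float

    def __init__(self, value: float | None = None, missing: bool = False):
        if value is None:
            missing = True
        if not missing:
            value = float(value)
            if value == MISSING_CODE:
                missing, value = True, math.inf
            else:
                if value <= 0:
                    raise HaplotypeIOError(f"allele value must be > 0, got {value}")
                value = round(value, 1)
                frac = round(value - math.floor(value), 1)
                if frac not in _VALID_FRACTIONS:
                    raise HaplotypeIOError(
                        f"allele {value} has fractional part {frac}; "
                        "legal microvariant parts are .1, .2, .3"
                    )
        else:
            value = math.inf
        object.__setattr__(self, "missing", bool(missing))
        object.__setattr__(self, "value", value)

    @classmethod
    def parse(cls, text: object) -> "Allele":
        """Parse an allele from a text cell.

        Accepts "." and "," decimal separators; empty cells, "NA" and the
        code 99 all map to missing.
        """
        if text is None or (isinstance(text, float) and math.isnan(text)):
            return cls(missing=True)
        s = str(text).strip()
        if s == "" or s.upper() in {"NA", "NAN", "NONE", "-"}:
            return cls(missing=True)
        s = s.replace(",", ".")
        try:
            v = float(s)
        except ValueError as exc:
            raise HaplotypeIOError(f"unparsable allele {text!r}") from exc
        return cls(v)

    @property
    def is_microvariant(self) -> bool:
        if self.missing:
            return False
        return round(self.value - math.floor(self.value), 1) != 0.0

    def as_float(self) -> float:
        """Numeric view; missing becomes NaN."""
        return math.nan if self.missing else self.value

    def __repr__(self) -> str:  # compact; shows 14 not 14.0
        if self.missing:
            return "Allele(missing)"
        v = self.value
        return f"Allele({int(v)})" if v == int(v) else f"Allele({v})"


MISSING_ALLELE = Allele(missing=True)


@dataclass(frozen=True)
class LocusPanel:
    """Which loci exist, which are multi-copy, and derived encodings.

    ``derived_encoding`` maps a locus whose conventional reported value is a
    difference of two raw values to the locus subtracted from it (default:
    DYS389II − DYS389I, the Yfiler display convention).
    """

    loci: tuple[str, ...] = YFILER_LOCI
    multi_copy: frozenset[str] = frozenset({"DYS385"})
    derived_encoding: Mapping[str, str] = field(
        default_factory=lambda: {"DYS389II": "DYS389I"}
    )

    def __post_init__(self):
        object.__setattr__(self, "loci", tuple(self.loci))
        object.__setattr__(self, "multi_copy", frozenset(self.multi_copy))
        if len(set(self.loci)) != len(self.loci):
            raise HaplotypeIOError("locus names must be unique")
        if not self.multi_copy <= set(self.loci):
            raise HaplotypeIOError("multi_copy loci must be a subset of loci")
        for derived, base in self.derived_encoding.items():
            if derived not in self.loci or base not in self.loci:
                raise HaplotypeIOError("derived_encoding refers to unknown loci")

    def n_copies(self, locus: str) -> int:
        return 2 if locus in self.multi_copy else 1

    @property
    def positions(self) -> tuple[tuple[str, int], ...]:
        """Flat (locus, copy index) positions; the default panel has 17."""
        out: list[tuple[str, int]] = []
        for locus in self.loci:
            for c in range(self.n_copies(locus)):
                out.append((locus, c))
        return tuple(out)

    @property
    def n_positions(self) -> int:
        return len(self.positions)


YFILER_PANEL = LocusPanel()


@dataclass(frozen=True)
class STRProfile:
    """One male's alleles across the panel.

    ``alleles`` maps every panel locus to a tuple of :class:`Allele`
    (length 1, or 2 sorted ascending for multi-copy loci).
    """

    sample_id: str
    population: str
    alleles: Mapping[str, tuple[Allele, ...]]

    @classmethod
    def build(
        cls,
        sample_id: str,
        population: str,
        values: Mapping[str, object],
        panel: LocusPanel = YFILER_PANEL,
    ) -> "STRProfile":
        """Construct from plain values (floats, pairs, None for missing)."""
        alleles: dict[str, tuple[Allele, ...]] = {}
        for locus in panel.loci:
            raw = values.get(locus)
            ncop = panel.n_copies(locus)
            if raw is None:
                copies = tuple(MISSING_ALLELE for _ in range(ncop))
            elif isinstance(raw, (tuple, list)):
                if len(raw) != ncop:
                    raise HaplotypeIOError(
                        f"{locus} expects {ncop} value(s), got {len(raw)}"
                    )
                copies = tuple(
                    v if isinstance(v, Allele) else Allele.parse(v) for v in raw
                )
            else:
                if ncop != 1:
                    raise HaplotypeIOError(f"{locus} expects {ncop} values")
                copies = (raw if isinstance(raw, Allele) else Allele.parse(raw),)
            alleles[locus] = tuple(sorted(copies)) if ncop > 1 else copies
        return cls(str(sample_id), str(population), alleles)

    def values_at(self, locus: str) -> tuple[float, ...]:
        return tuple(a.as_float() for a in self.alleles[locus])

    def is_complete(self) -> bool:
        return not any(a.missing for copies in self.alleles.values() for a in copies)


@dataclass(frozen=True)
class ReadReport:
    """Rows rejected during :func:`read_table`, with reasons."""

    n_read: int
    rejected: tuple[tuple[int, str, str], ...] = ()  # (row index, sample id, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


@dataclass(frozen=True)
class HaplotypeTable:
    """Validated collection of profiles sharing a :class:`LocusPanel`."""

    panel: LocusPanel
    profiles: tuple[STRProfile, ...]
    dys389ii_encoded: bool = False
    read_report: ReadReport | None = None

    def __post_init__(self):
        object.__setattr__(self, "profiles", tuple(self.profiles))
        ids = [p.sample_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            dup = [s for s, c in Counter(ids).items() if c > 1]
            raise HaplotypeIOError(f"duplicate sample_id(s): {dup}")
        for p in self.profiles:
            if set(p.alleles) != set(self.panel.loci):
                raise HaplotypeIOError(
                    f"profile {p.sample_id} does not cover the panel loci"
                )

    @property
    def n(self) -> int:
        return len(self.profiles)

    @property
    def populations(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p in self.profiles:
            seen.setdefault(p.population, None)
        return tuple(seen)

    def by_population(self) -> dict[str, tuple[STRProfile, ...]]:
        out: dict[str, list[STRProfile]] = {}
        for p in self.profiles:
            out.setdefault(p.population, []).append(p)
        return {k: tuple(v) for k, v in out.items()}

    def subset(self, populations: Iterable[str]) -> "HaplotypeTable":
        keep = set(populations)
        return replace(
            self,
            profiles=tuple(p for p in self.profiles if p.population in keep),
            read_report=None,
        )

    def relabel(self, mapping: Mapping[str, str]) -> "HaplotypeTable":
        """Group populations (e.g. region -> country) via a label mapping."""
        profs = tuple(
            replace(p, population=mapping.get(p.population, p.population))
            for p in self.profiles
        )
        return replace(self, profiles=profs, read_report=None)

    def position_matrix(self) -> tuple[np.ndarray, tuple[tuple[str, int], ...]]:
        """n × P float matrix over panel positions (NaN = missing)."""
        positions = self.panel.positions
        X = np.full((self.n, len(positions)), np.nan)
        for i, prof in enumerate(self.profiles):
            for j, (locus, c) in enumerate(positions):
                X[i, j] = prof.alleles[locus][c].as_float()
        return X, positions

    def to_dataframe(self, dys385_style: str = "split") -> pd.DataFrame:
        rows = []
        for p in self.profiles:
            row: dict[str, object] = {"SampleID": p.sample_id, "Population": p.population}
            for locus in self.panel.loci:
                copies = p.alleles[locus]
                if self.panel.n_copies(locus) == 2:
                    if dys385_style == "joined":
                        row[locus] = "-".join(_format_allele(a) for a in copies)
                    else:
                        row[f"{locus}a"], row[f"{locus}b"] = (
                            _format_allele(copies[0]),
                            _format_allele(copies[1]),
                        )
                else:
                    row[locus] = _format_allele(copies[0])
            rows.append(row)
        cols = ["SampleID", "Population"]
        for locus in self.panel.loci:
            if self.panel.n_copies(locus) == 2 and dys385_style != "joined":
                cols += [f"{locus}a", f"{locus}b"]
            else:
                cols.append(locus)
        return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)


def _format_allele(a: Allele) -> str:
    if a.missing:
        return str(int(MISSING_CODE))
    return str(int(a.value)) if a.value == int(a.value) else f"{a.value:.1f}"


# ---------------------------------------------------------------------------
# reading / writing


def _resolve_columns(columns: Sequence[str], panel: LocusPanel):
    """Map raw header names onto (sample, population, locus-copy) roles."""
    sample_col = pop_col = None
    locus_cols: dict[str, dict[int, str]] = {}
    unknown: list[str] = []
    for col in columns:
        norm = _normalize_colname(col)
        canon = _LOCUS_ALIASES.get(norm, norm)
        matched = False
        for locus in panel.loci:
            lnorm = _normalize_colname(locus)
            if canon == lnorm:
                locus_cols.setdefault(locus, {})[-1] = col  # combined / single
                matched = True
            elif panel.n_copies(locus) == 2 and canon in (lnorm + "A", lnorm + "B"):
                locus_cols.setdefault(locus, {})[0 if canon.endswith("A") else 1] = col
                matched = True
            if matched:
                break
        if matched:
            continue
        if sample_col is None and norm in _SAMPLE_COLUMN_NAMES:
            sample_col = col
        elif pop_col is None and norm in _POPULATION_COLUMN_NAMES:
            pop_col = col
        elif norm.startswith(("DYS", "YGATA", "GATA", "Y")):
            unknown.append(col)
        # other metadata columns are silently ignored
    if unknown:
        raise HaplotypeIOError(f"unknown locus column(s): {unknown}")
    missing = [l for l in panel.loci if l not in locus_cols]
    if missing:
        raise HaplotypeIOError(f"panel loci absent from header: {missing}")
    return sample_col, pop_col, locus_cols


def _parse_pair_cell(cell: object) -> tuple[Allele, Allele]:
    s = str(cell).strip()
    for sep in ("-", "/", "|"):
        if sep in s:
            a, b = s.split(sep, 1)
            return Allele.parse(a), Allele.parse(b)
    raise HaplotypeIOError(f"cannot split multi-copy cell {cell!r} into two alleles")


def read_table(
    path,
    panel: LocusPanel = YFILER_PANEL,
    *,
    delimiter: str | None = None,
    default_population: str = "default",
) -> HaplotypeTable:
    """Read a delimited haplotype table (TSV default, CSV autodetected).

    Accepts YHRD-style column naming: DYS385 as "DYS385a"/"DYS385b" or a
    combined "DYS385" column holding "13-17".  Rows with unparsable alleles
    are rejected (logged and listed in ``table.read_report``); unknown locus
    columns and duplicate sample ids are hard errors.
    """
    df = pd.read_csv(path, sep=delimiter, engine="python", dtype=str)
    sample_col, pop_col, locus_cols = _resolve_columns(df.columns, panel)
    if sample_col is None:
        sample_col = df.columns[0]
        if sample_col in {c for copies in locus_cols.values() for c in copies.values()}:
            raise HaplotypeIOError("no sample id column found")
    profiles: list[STRProfile] = []
    rejected: list[tuple[int, str, str]] = []
    for idx, row in df.iterrows():
        sid = str(row[sample_col]).strip()
        popn = str(row[pop_col]).strip() if pop_col is not None else default_population
        try:
            values: dict[str, object] = {}
            for locus, colmap in locus_cols.items():
                if -1 in colmap and panel.n_copies(locus) == 2:
                    values[locus] = _parse_pair_cell(row[colmap[-1]])
                elif -1 in colmap:
                    values[locus] = Allele.parse(row[colmap[-1]])
                else:
                    values[locus] = tuple(
                        Allele.parse(row[colmap[c]]) for c in sorted(colmap)
                    )
            profiles.append(STRProfile.build(sid, popn, values, panel))
        except HaplotypeIOError as exc:
            logger.warning("rejecting row %s (%s): %s", idx, sid, exc)
            rejected.append((int(idx), sid, str(exc)))
    report = ReadReport(n_read=len(df), rejected=tuple(rejected))
    return HaplotypeTable(panel=panel, profiles=tuple(profiles), read_report=report)


def write_table(
    table: HaplotypeTable,
    path,
    *,
    delimiter: str = "\t",
    dys385_style: str = "split",
) -> None:
    """Write a table; round-trips through :func:`read_table` field-for-field."""
    df = table.to_dataframe(dys385_style=dys385_style)
    df.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# DYS389II encoding


def encode_dys389ii_profile(profile: STRProfile, direction: str = "encode",
                            panel: LocusPanel = YFILER_PANEL) -> STRProfile:
    """Apply (or invert) the DYS389II difference encoding on one profile.

    encoded DYS389II = raw DYS389II − DYS389I; if either locus is missing the
    profile is returned unchanged with a warning.
    """
    for derived, base in panel.derived_encoding.items():
        a389ii = profile.alleles[derived][0]
        a389i = profile.alleles[base][0]
        if a389ii.missing or a389i.missing:
            logger.warning(
                "profile %s: %s or %s missing; encoding unchanged",
                profile.sample_id, derived, base,
            )
            return profile
        if direction == "encode":
            new = a389ii.value - a389i.value
        elif direction == "decode":
            new = a389ii.value + a389i.value
        else:
            raise ValueError("direction must be 'encode' or 'decode'")
        alleles = dict(profile.alleles)
        alleles[derived] = (Allele(new),)
        profile = replace(profile, alleles=alleles)
    return profile


def encode_dys389ii(table: HaplotypeTable) -> HaplotypeTable:
    """Difference-encode DYS389II table-wide (idempotent via the state flag)."""
    if table.dys389ii_encoded:
        return table
    profs = tuple(encode_dys389ii_profile(p, "encode", table.panel) for p in table.profiles)
    return replace(table, profiles=profs, dys389ii_encoded=True, read_report=None)


def decode_dys389ii(table: HaplotypeTable) -> HaplotypeTable:
    if not table.dys389ii_encoded:
        return table
    profs = tuple(encode_dys389ii_profile(p, "decode", table.panel) for p in table.profiles)
    return replace(table, profiles=profs, dys389ii_encoded=False, read_report=None)


# ---------------------------------------------------------------------------
# allele frequencies


@dataclass(frozen=True)
class AlleleFrequencyTable:
    """Per-locus allele spectra: counts, frequencies and haploid sample sizes.

    Multi-copy loci pool both copies into one spectrum, so their n is
    2 × the number of complete calls.
    """

    counts: Mapping[str, Mapping[float, int]]
    n: Mapping[str, int]

    @property
    def frequencies(self) -> dict[str, dict[float, float]]:
        return {
            locus: {a: c / self.n[locus] for a, c in spec.items()}
            for locus, spec in self.counts.items()
        }

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"locus": locus, "allele": a, "count": c, "frequency": c / self.n[locus]}
            for locus, spec in self.counts.items()
            for a, c in sorted(spec.items())
        ]
        return pd.DataFrame(rows, columns=["locus", "allele", "count", "frequency"])


def allele_frequencies(table: HaplotypeTable) -> AlleleFrequencyTable:
    """Count alleles per locus over non-missing calls and normalise.

    Loci with zero non-missing calls are excluded with a warning.
    """
    if table.n == 0:
        raise HaplotypeIOError("cannot compute allele frequencies of an empty table")
    counts: dict[str, dict[float, int]] = {}
    n: dict[str, int] = {}
    for locus in table.panel.loci:
        spec: Counter = Counter()
        for prof in table.profiles:
            for a in prof.alleles[locus]:
                if not a.missing:
                    spec[a.value] += 1
        if not spec:
            logger.warning("locus %s has zero non-missing calls; excluded", locus)
            continue
        counts[locus] = dict(spec)
        n[locus] = sum(spec.values())
    return AlleleFrequencyTable(counts=counts, n=n)
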