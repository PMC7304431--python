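"""Codominant genotype tables with per-individual metadata.

The central container is :class:`GenotypeTable`: an ordered set of
individuals, an ordered set of microsatellite loci, and for each
(individual, locus) an unordered pair of allele labels or a wholly
missing call.  Individuals carry the metadata the downstream fitness
models need: sex, calendar year of capture, age, and litter size
(0-4 pouch young for a female Tasmanian devil; ``None`` when unknown).

On disk the table is a GenAlEx-style CSV: metadata columns first
(``id, sex, year, age, litter_size``), then two columns per locus.
Allele labels are opaque strings and survive a write/read round trip
byte-identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Cell values normalised to "missing" on read, by default.
DEFAULT_MISSING_CODES = frozenset({"", "0", "NA", "na"})

METADATA_COLUMNS = ["id", "sex", "year", "age", "litter_size"]


class GenotypeError(ValueError):
    """Malformed genotype input (half-calls, duplicate ids, bad layout)."""


@dataclass(frozen=True)
class IndividualRecord:
    """Metadata for one sampled individual.

    ``litter_size`` is the count of offspring (0-4) for females with
    reproductive data, ``None`` when unknown (including all males).
    """

    id: str
    sex: str | None = None
    year: int | None = None
    age: float | None = None
    litter_size: int | None = None

    def __post_init__(self) -> None:
        if self.litter_size is not None and self.litter_size not in (0, 1, 2, 3, 4):
            raise ValueError(
                f"individual {self.id!r}: litter_size must be in 0..4, "
                f"got {self.litter_size!r}"
            )

    @property
    def bred(self) -> bool | None:
        """Whether the individual produced at least one offspring."""
        if self.litter_size is None:
            return None
        return self.litter_size >= 1


@dataclass
class GenotypeTable:
    """Individuals x loci codominant genotype calls plus metadata.

    ``calls`` is an object array of shape ``(n_individuals, n_loci, 2)``
    holding allele labels as strings, with ``None`` in both slots for a
    missing call.  Half-calls (one allele present) are rejected at
    construction time.
    """

    individuals: list[IndividualRecord]
    loci: list[str]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=object)
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)"
            )
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != n:
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise GenotypeError(f"duplicate individual ids: {dupes}")
        if len(set(self.loci)) != L:
            raise GenotypeError("duplicate locus names")
        for k in range(n):
            for j in range(L):
                a, b = self.calls[k, j]
                if (a is None) != (b is None):
                    raise GenotypeError(
                        f"half-call at individual {ids[k]!r}, locus "
                        f"{self.loci[j]!r}: ({a!r}, {b!r})"
                    )

    # -- basic views ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L) array, True where the call is missing."""
        return np.array(
            [[self.calls[k, j, 0] is None for j in range(self.n_loci)]
             for k in range(self.n_individuals)]
        )

    def locus_index(self, locus: str) -> int:
        return self.loci.index(locus)

    def monomorphic_loci(self) -> list[str]:
        """Loci with at most one distinct observed allele."""
        out = []
        for j, locus in enumerate(self.loci):
            alleles = {a for k in range(self.n_individuals)
                       for a in self.calls[k, j] if a is not None}
            if len(alleles) <= 1:
                out.append(locus)
        return out

    def subset(self, indices: Sequence[int]) -> "GenotypeTable":
        """New table with the individuals at ``indices`` (in order)."""
        return GenotypeTable(
            individuals=[self.individuals[i] for i in indices],
            loci=list(self.loci),
            calls=self.calls[list(indices)].copy(),
        )

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [i.id for i in self.individuals],
                "sex": [i.sex for i in self.individuals],
                "year": [i.year for i in self.individuals],
                "age": [i.age for i in self.individuals],
                "litter_size": [i.litter_size for i in self.individuals],
            }
        )


# ---------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------

def _parse_meta(row: pd.Series) -> IndividualRecord:
    def _opt(v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            return None
        return v

    year = _opt(row.get("year"))
    age = _opt(row.get("age"))
    litter = _opt(row.get("litter_size"))
    return IndividualRecord(
        id=str(row["id"]),
        sex=_opt(row.get("sex")),
        year=int(year) if year is not None else None,
        age=float(age) if age is not None else None,
        litter_size=int(litter) if litter is not None else None,
    )


def load_genotype_table(
    path,
    missing_codes: Iterable[str] = DEFAULT_MISSING_CODES,
    layout: str = "paired",
) -> GenotypeTable:
    """Read a two-column-per-locus CSV into a :class:`GenotypeTable`.

    Parameters
    ----------
    path
        CSV file with header ``id,sex,year,age,litter_size`` followed by
        locus columns.
    missing_codes
        Cell values (after stripping) treated as missing.  A call is
        missing only if *both* of its columns are missing; one missing
        allele of a pair is a hard error naming individual and locus.
    layout
        ``"paired"``: the two columns of each locus are adjacent
        (``L1, L1.1, L2, L2.1, ...``).  ``"blocked"``: all first alleles
        come first, then all second alleles in the same locus order.
    """
    missing = {str(c) for c in missing_codes}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    meta_cols = [c for c in METADATA_COLUMNS if c in df.columns]
    if "id" not in meta_cols:
        raise GenotypeError("CSV must contain an 'id' column")
    geno_cols = [c for c in df.columns if c not in meta_cols]
    if len(geno_cols) % 2:
        raise GenotypeError(
            f"odd number of genotype columns ({len(geno_cols)}); "
            "each locus needs two"
        )
    n_loci = len(geno_cols) // 2

    def _canon(name: str) -> str:
        # pandas mangles duplicate headers to "L.1"; also accept _a/_b
        for suf in (".1", "_b", "_a"):
            if name.endswith(suf):
                return name[: -len(suf)]
        return name

    if layout == "paired":
        pairs = [(geno_cols[2 * j], geno_cols[2 * j + 1]) for j in range(n_loci)]
    elif layout == "blocked":
        pairs = [(geno_cols[j], geno_cols[j + n_loci]) for j in range(n_loci)]
    else:
        raise ValueError(f"unknown layout {layout!r}")
    loci = [_canon(a) for a, _ in pairs]

    individuals = [_parse_meta(row) for _, row in df[meta_cols].iterrows()]
    calls = np.empty((len(df), n_loci, 2), dtype=object)
    for j, (ca, cb) in enumerate(pairs):
        for k in range(len(df)):
            a = df[ca].iloc[k].strip()
            b = df[cb].iloc[k].strip()
            a_missing, b_missing = a in missing, b in missing
            if a_missing != b_missing:
                raise GenotypeError(
                    f"half-call at individual {individuals[k].id!r}, "
                    f"locus {loci[j]!r}"
                )
            calls[k, j, 0] = None if a_missing else a
            calls[k, j, 1] = None if b_missing else b
    return GenotypeTable(individuals=individuals, loci=loci, calls=calls)


def write_genotype_table(table: GenotypeTable, path, missing_code: str = "") -> None:
    """Write the CSV dialect :func:`load_genotype_table` reads."""
    data: dict[str, list] = {
        "id": [], "sex": [], "year": [], "age": [], "litter_size": []
    }
    for ind in table.individuals:
        data["id"].append(ind.id)
        data["sex"].append("" if ind.sex is None else ind.sex)
        data["year"].append("" if ind.year is None else ind.year)
        data["age"].append("" if ind.age is None else ind.age)
        data["litter_size"].append(
            "" if ind.litter_size is None else ind.litter_size
        )
    df = pd.DataFrame(data)
    for j, locus in enumerate(table.loci):
        col_a = [missing_code if table.calls[k, j, 0] is None
                 else table.calls[k, j, 0] for k in range(table.n_individuals)]
        col_b = [missing_code if table.calls[k, j, 1] is None
                 else table.calls[k, j, 1] for k in range(table.n_individuals)]
        df[locus] = col_a
        df[f"{locus}.1"] = col_b
    # pandas would re-mangle "Locus.1" headers on write; emit manually
    header = list(df.columns)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(header) + "\n")
        for _, row in df.iterrows():
            fh.write(",".join(str(v) for v in row.tolist()) + "\n")


# ---------------------------------------------------------------------
# filtering and allele frequencies
# ---------------------------------------------------------------------

def complete_case_filter(
    table: GenotypeTable,
    require_sex: str | None = None,
    require_traits: bool = False,
) -> GenotypeTable:
    """Retain individuals with zero missing calls (and optional filters).

    ``require_sex`` keeps only individuals of that sex; ``require_traits``
    additionally requires a known litter size.  Idempotent.  An empty
    result is a warning, not an error.
    """
    miss = table.missing_mask()
    keep = []
    for k, ind in enumerate(table.individuals):
        if require_sex is not None and ind.sex != require_sex:
            continue
        if require_traits and ind.litter_size is None:
            continue
        if miss[k].any():
            continue
        keep.append(k)
    if not keep:
        warnings.warn("complete_case_filter retained zero individuals")
    return table.subset(keep)


def allele_frequencies(
    table: GenotypeTable,
    grouping: Mapping[str, object] | None = None,
) -> dict:
    """Gene-counting allele frequencies per locus.

    With ``grouping`` (individual id -> cohort label) returns
    ``{cohort: {locus: {allele: freq}}}``; otherwise frequencies pooled
    over all individuals, ``{locus: {allele: freq}}``.  Frequencies at a
    locus sum to 1 over observed alleles; a locus (or locus-cohort) with
    no non-missing call maps to an empty dict.
    """
    if grouping is not None:
        cohorts: dict[object, list[int]] = {}
        for k, ind in enumerate(table.individuals):
            cohorts.setdefault(grouping[ind.id], []).append(k)
        return {
            g: allele_frequencies(table.subset(idx))
            for g, idx in sorted(cohorts.items(), key=lambda kv: str(kv[0]))
        }

    out: dict[str, dict[str, float]] = {}
    for j, locus in enumerate(table.loci):
        counts: dict[str, int] = {}
        for k in range(table.n_individuals):
            for a in table.calls[k, j]:
                if a is not None:
                    counts[a] = counts.get(a, 0) + 1
        total = sum(counts.values())
        out[locus] = (
            {a: c / total for a, c in sorted(counts.items())} if total else {}
        )
    return out


def year_grouping(table: GenotypeTable) -> dict[str, int]:
    """Convenience grouping: individual id -> calendar year of capture."""
    return {ind.id: ind.year for ind in table.individuals}
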