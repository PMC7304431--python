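"""Per-individual multilocus heterozygosity indices and temporal trends.

Three indices are computed, all standard in the heterozygosity-fitness
literature:

* **Internal relatedness (IR)** — allele-frequency-weighted homozygosity,
  ``IR = (2H - sum f) / (2N - sum f)`` over the individual's typed
  polymorphic loci (N loci, H homozygous, ``sum f`` the population
  frequencies of the 2N allele copies carried).  Homozygosity for rare
  alleles pushes IR higher than homozygosity for common ones, because it
  is more likely to reflect inbred mating.  IR = 1 for a fully
  homozygous genotype and is negative for heterozygote-rich genotypes.
* **sMLH** — standardized multilocus heterozygosity: the individual's
  summed 0/1 heterozygosity divided by the summed sample-mean observed
  heterozygosity of the same loci (population mean 1 on complete data).
* **HL** — heterozygosity-by-loci: expected-heterozygosity-weighted
  homozygosity, ``HL = sum(E_hom) / (sum(E_hom) + sum(E_het))`` in [0, 1].

Monomorphic loci carry no information about inbreeding and are excluded
from IR (they would otherwise drag every individual toward apparent
homozygosity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genotype_io import GenotypeTable, allele_frequencies

__all__ = [
    "MLHRecord",
    "TrendFit",
    "internal_relatedness",
    "smlh",
    "hl",
    "compute_mlh",
    "mlh_correlations",
    "index_year_trend",
]


@dataclass
class MLHRecord:
    id: str
    ir: float
    smlh: float
    hl: float
    prop_typed: float


def internal_relatedness(
    calls: Sequence, freqs: Mapping[str, Mapping[str, float]],
    loci: Sequence[str],
) -> float:
    """IR for one individual's calls (``calls[j]`` is an allele pair).

    Loci that are monomorphic in ``freqs`` or untyped are skipped.
    Returns NaN when the denominator is zero (no usable loci).
    """
    n = h = 0
    sum_f = 0.0
    for j, locus in enumerate(loci):
        a, b = calls[j]
        if a is None:
            continue
        f = freqs[locus]
        if len(f) < 2:
            continue
        n += 1
        if a == b:
            h += 1
        sum_f += f[a] + f[b]
    denom = 2 * n - sum_f
    if n == 0 or denom == 0:
        return float("nan")
    return (2 * h - sum_f) / denom


def smlh(
    calls: Sequence, locus_mean_het: Mapping[str, float],
    loci: Sequence[str],
) -> float:
    num = den = 0.0
    for j, locus in enumerate(loci):
        a, b = calls[j]
        if a is None:
            continue
        num += float(a != b)
        den += locus_mean_het[locus]
    return num / den if den > 0 else float("nan")


def hl(
    calls: Sequence, locus_uhe: Mapping[str, float],
    loci: Sequence[str],
) -> float:
    e_hom = e_het = 0.0
    for j, locus in enumerate(loci):
        a, b = calls[j]
        if a is None or locus_uhe[locus] <= 0:
            continue
        if a == b:
            e_hom += locus_uhe[locus]
        else:
            e_het += locus_uhe[locus]
    tot = e_hom + e_het
    return e_hom / tot if tot > 0 else float("nan")


def compute_mlh(
    table: GenotypeTable,
    include_focal: bool = True,
) -> pd.DataFrame:
    """All three indices for every individual.

    Allele frequencies are pooled over the full table (all sexes and
    years).  With ``include_focal=False`` each individual's IR uses
    frequencies computed with that individual left out.

    Returns a DataFrame indexed by individual id with columns
    ``ir, smlh, hl, prop_typed`` plus ``sex, year, age, litter_size``.
    """
    from .locus_stats import per_locus_summary, unbiased_he

    freqs = allele_frequencies(table)
    L = table.n_loci
    # per-locus sample mean observed het and unbiased expected het
    mean_het: dict[str, float] = {}
    locus_uhe: dict[str, float] = {}
    for j, locus in enumerate(table.loci):
        hets = n = 0
        for k in range(table.n_individuals):
            a, b = table.calls[k, j]
            if a is None:
                continue
            n += 1
            hets += int(a != b)
        mean_het[locus] = hets / n if n else 0.0
        locus_uhe[locus] = unbiased_he(freqs[locus], n) if n else 0.0

    rows = []
    for k, ind in enumerate(table.individuals):
        calls = [tuple(table.calls[k, j]) for j in range(L)]
        if include_focal:
            f_use = freqs
        else:
            others = [i for i in range(table.n_individuals) if i != k]
            f_use = allele_frequencies(table.subset(others))
        rows.append(
            {
                "id": ind.id,
                "sex": ind.sex,
                "year": ind.year,
                "age": ind.age,
                "litter_size": ind.litter_size,
                "prop_typed": np.mean([c[0] is not None for c in calls]),
                "ir": internal_relatedness(calls, f_use, table.loci),
                "smlh": smlh(calls, mean_het, table.loci),
                "hl": hl(calls, locus_uhe, table.loci),
            }
        )
    return pd.DataFrame(rows).set_index("id")


def mlh_correlations(mlh_df: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations among IR, sMLH and HL."""
    cols = ["ir", "smlh", "hl"]
    return mlh_df[cols].corr(method="pearson")


@dataclass
class TrendFit:
    """OLS fit of an index on calendar year, with t-based inference."""

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    slope_p: float
    intercept_p: float
    n: int


def index_year_trend(values: Sequence[float], years: Sequence[float]) -> TrendFit:
    """Ordinary least squares of an index on raw calendar year."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(years, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(x))
    y, x = y[ok], x[ok]
    if len(np.unique(x)) < 2:
        raise ValueError("need at least two distinct years for a trend")
    if np.ptp(y) == 0:
        # constant response: slope exactly 0, no evidence of trend
        return TrendFit(0.0, 0.0, float(y[0]), 0.0, 1.0, 0.0, len(y))
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return TrendFit(
        slope=float(res.params[1]),
        slope_se=float(res.bse[1]),
        intercept=float(res.params[0]),
        intercept_se=float(res.bse[0]),
        slope_p=float(res.pvalues[1]),
        intercept_p=float(res.pvalues[0]),
        n=int(res.nobs),
    )
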