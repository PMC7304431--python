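"""Per-locus diversity, Hardy-Weinberg exact tests, F_IS, null alleles.

Implements the standard microsatellite summary panel: number of alleles
(Na), observed heterozygosity (H_O), unbiased expected heterozygosity
(H_E, the small-sample-corrected gene diversity), an exact test of
Hardy-Weinberg proportions conditional on allele counts, Nei's
within-cohort inbreeding coefficient F_IS, and the Brookfield
heterozygote-deficit estimator of null-allele frequency.

The Hardy-Weinberg test is the conditional exact test: the p-value is
the total conditional probability (given the allele counts) of genotype
configurations no more probable than the observed one.  For loci with
up to three alleles the genotype configurations are enumerated
completely; beyond that the null is sampled by Monte-Carlo shuffling of
the allele vector, with the add-one p-value correction.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .genotype_io import GenotypeTable, allele_frequencies

__all__ = [
    "LocusSummary",
    "FisSeries",
    "per_locus_summary",
    "hwe_exact_test",
    "nei_fis",
    "brookfield_null",
    "null_allele_table",
    "locus_summary_frame",
]


@dataclass
class LocusSummary:
    """One diversity-table row for a locus."""

    locus: str
    n_typed: int
    na: int
    ho: float
    uhe: float
    hwe_p: float  # NaN for monomorphic / untestable loci
    null_by_group: dict = field(default_factory=dict)


def _genotype_counts(table: GenotypeTable, j: int) -> dict[tuple[str, str], int]:
    counts: dict[tuple[str, str], int] = {}
    for k in range(table.n_individuals):
        a, b = table.calls[k, j]
        if a is None:
            continue
        key = tuple(sorted((a, b)))
        counts[key] = counts.get(key, 0) + 1
    return counts


def unbiased_he(freqs: Mapping[str, float], n_typed: int) -> float:
    """Nei's unbiased gene diversity, (2n/(2n-1)) * (1 - sum p^2)."""
    if n_typed < 1:
        return float("nan")
    s = 1.0 - sum(p * p for p in freqs.values())
    if n_typed == 0 or 2 * n_typed - 1 == 0:
        return float("nan")
    return (2 * n_typed) / (2 * n_typed - 1) * s


def per_locus_summary(
    table: GenotypeTable,
    hwe_n_mc: int = 10_000,
    seed: int = 0,
) -> list[LocusSummary]:
    """Diversity summary for every locus (pooled over all individuals)."""
    freqs = allele_frequencies(table)
    rng = np.random.default_rng(seed)
    out = []
    for j, locus in enumerate(table.loci):
        g = _genotype_counts(table, j)
        n = sum(g.values())
        f = freqs[locus]
        na = len(f)
        if n == 0:
            out.append(LocusSummary(locus, 0, 0, float("nan"),
                                    float("nan"), float("nan")))
            continue
        het = sum(c for (a, b), c in g.items() if a != b)
        ho = het / n
        uhe = unbiased_he(f, n)
        if na >= 2:
            p = hwe_exact_test(
                g, n_mc=hwe_n_mc, seed=int(rng.integers(0, 2**31 - 1))
            )
        else:
            p = float("nan")
        out.append(LocusSummary(locus, n, na, ho, uhe, p))
    return out


# ---------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------

def _log_config_prob(counts: Mapping[tuple[str, str], int],
                     allele_counts: Mapping[str, int]) -> float:
    """log P(genotype configuration | allele counts) under HWE.

    P = N! * prod_a(n_a!) * 2^H / ( (2N)! / ... ) -- the classical
    conditional distribution: N! / prod(n_ij!) * 2^H * prod(n_a!) / (2N)!.
    """
    n = sum(counts.values())
    het = sum(c for (a, b), c in counts.items() if a != b)
    lp = math.lgamma(n + 1) + het * math.log(2.0)
    for c in counts.values():
        lp -= math.lgamma(c + 1)
    for na in allele_counts.values():
        lp += math.lgamma(na + 1)
    lp -= math.lgamma(2 * n + 1)
    return lp


def _allele_counts(counts: Mapping[tuple[str, str], int]) -> dict[str, int]:
    ac: dict[str, int] = {}
    for (a, b), c in counts.items():
        ac[a] = ac.get(a, 0) + c
        ac[b] = ac.get(b, 0) + c
    return ac


def _enumerate_configs(allele_counts: dict[str, int]):
    """Yield all genotype-count configurations with the given allele counts.

    Feasible only for few alleles; used for <= 3 alleles.  Enumerates the
    heterozygote counts; homozygote counts follow by subtraction.
    """
    alleles = sorted(allele_counts)
    het_pairs = list(itertools.combinations(alleles, 2))

    def rec(i: int, remaining: dict[str, int], current: dict):
        if i == len(het_pairs):
            config = dict(current)
            ok = True
            for a in alleles:
                r = remaining[a]
                if r < 0 or r % 2:
                    ok = False
                    break
                if r:
                    config[(a, a)] = r // 2
            if ok:
                yield config
            return
        a, b = het_pairs[i]
        m = min(remaining[a], remaining[b])
        for h in range(m + 1):
            remaining[a] -= h
            remaining[b] -= h
            if h:
                current[(a, b)] = h
            yield from rec(i + 1, remaining, current)
            if h:
                del current[(a, b)]
            remaining[a] += h
            remaining[b] += h

    yield from rec(0, dict(allele_counts), {})


def hwe_exact_test(
    genotype_counts: Mapping[tuple[str, str], int],
    n_mc: int = 10_000,
    seed: int = 0,
    max_enum_alleles: int = 3,
) -> float:
    """Exact test of Hardy-Weinberg proportions at one locus.

    ``genotype_counts`` maps unordered allele pairs to counts.  Returns
    the conditional exact p-value (complete enumeration for up to
    ``max_enum_alleles`` alleles) or a Monte-Carlo estimate with the
    add-one correction otherwise.  Monomorphic input returns NaN.
    """
    counts = {tuple(sorted(k)): v for k, v in genotype_counts.items() if v > 0}
    ac = _allele_counts(counts)
    if len(ac) < 2:
        return float("nan")
    lp_obs = _log_config_prob(counts, ac)
    tol = 1e-9  # configs equal to observed up to float noise count as <=

    if len(ac) <= max_enum_alleles:
        p = 0.0
        for config in _enumerate_configs(ac):
            lp = _log_config_prob(config, ac)
            if lp <= lp_obs + tol:
                p += math.exp(lp)
        return min(p, 1.0)

    rng = np.random.default_rng(seed)
    pool = np.array(
        [a for a, c in sorted(ac.items()) for _ in range(c)], dtype=object
    )
    n_extreme = 0
    for _ in range(n_mc):
        rng.shuffle(pool)
        sim: dict[tuple[str, str], int] = {}
        for i in range(0, len(pool), 2):
            key = tuple(sorted((pool[i], pool[i + 1])))
            sim[key] = sim.get(key, 0) + 1
        if _log_config_prob(sim, ac) <= lp_obs + tol:
            n_extreme += 1
    return (1 + n_extreme) / (n_mc + 1)


# ---------------------------------------------------------------------
# F_IS
# ---------------------------------------------------------------------

@dataclass
class FisSeries:
    """Per (locus, cohort) F_IS values and unweighted cohort means."""

    per_locus: pd.DataFrame  # index loci, columns cohorts, NaN undefined
    cohort_mean: pd.Series


def nei_fis(table: GenotypeTable, grouping: Mapping[str, object]) -> FisSeries:
    """Nei's F_IS = 1 - Ho/Hs per locus and cohort.

    Hs is the small-sample-corrected within-cohort gene diversity
    ``(n/(n-1)) * (1 - sum p^2 - Ho/(2n))``.  Monomorphic locus-cohorts
    are NaN and excluded from the cohort mean.
    """
    cohorts: dict[object, list[int]] = {}
    for k, ind in enumerate(table.individuals):
        cohorts.setdefault(grouping[ind.id], []).append(k)
    cohort_labels = sorted(cohorts, key=str)
    mat = pd.DataFrame(
        np.nan, index=list(table.loci), columns=cohort_labels, dtype=float
    )
    for g in cohort_labels:
        sub = table.subset(cohorts[g])
        freqs = allele_frequencies(sub)
        for j, locus in enumerate(sub.loci):
            gc = _genotype_counts(sub, j)
            n = sum(gc.values())
            f = freqs[locus]
            if n < 2 or len(f) < 2:
                continue
            ho = sum(c for (a, b), c in gc.items() if a != b) / n
            hs = (n / (n - 1)) * (1.0 - sum(p * p for p in f.values())
                                  - ho / (2 * n))
            if hs <= 0:
                continue
            mat.loc[locus, g] = 1.0 - ho / hs
    return FisSeries(per_locus=mat, cohort_mean=mat.mean(axis=0, skipna=True))


# ---------------------------------------------------------------------
# null alleles
# ---------------------------------------------------------------------

def brookfield_null(ho: float, uhe: float) -> float:
    """Brookfield's null-allele frequency estimate r = (He-Ho)/(1+He).

    Clamped to 0 when the heterozygote deficit is negative.
    """
    r = (uhe - ho) / (1.0 + uhe)
    return max(r, 0.0)


def null_allele_table(
    table: GenotypeTable, grouping: Mapping[str, object]
) -> pd.DataFrame:
    """Per-locus, per-cohort null-allele frequency estimates.

    Each cell uses that cohort's own allele frequencies and Ho/He.
    Monomorphic locus-cohorts are NaN (no heterozygote deficit is
    definable without variation).
    """
    cohorts: dict[object, list[int]] = {}
    for k, ind in enumerate(table.individuals):
        cohorts.setdefault(grouping[ind.id], []).append(k)
    cohort_labels = sorted(cohorts, key=str)
    out = pd.DataFrame(
        np.nan, index=list(table.loci), columns=cohort_labels, dtype=float
    )
    for g in cohort_labels:
        sub = table.subset(cohorts[g])
        freqs = allele_frequencies(sub)
        for j, locus in enumerate(sub.loci):
            gc = _genotype_counts(sub, j)
            n = sum(gc.values())
            f = freqs[locus]
            if n == 0 or len(f) < 2:
                continue
            ho = sum(c for (a, b), c in gc.items() if a != b) / n
            out.loc[locus, g] = brookfield_null(ho, unbiased_he(f, n))
    return out


def locus_summary_frame(
    summaries: list[LocusSummary],
    null_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the diversity table (one row per locus) as a DataFrame.

    Column order: Locus, N, Na, H_O, H_E, p-value, then one null-allele
    frequency column per cohort when ``null_table`` is given.
    """
    df = pd.DataFrame(
        {
            "Locus": [s.locus for s in summaries],
            "N": [s.n_typed for s in summaries],
            "Na": [s.na for s in summaries],
            "H_O": [s.ho for s in summaries],
            "H_E": [s.uhe for s in summaries],
            "p-value": [s.hwe_p for s in summaries],
        }
    )
    if null_table is not None:
        for col in null_table.columns:
            df[str(col)] = null_table[col].reindex(df["Locus"]).to_numpy()
    return df
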