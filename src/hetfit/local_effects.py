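"""Locus-by-locus test of local vs general heterozygosity effects.

Under inbreeding, multilocus heterozygosity predicts fitness through
genome-wide identity by descent ("general effects").  The alternative
("local effects") is that one or a few loci, in linkage with genes
under selection, carry the signal on their own.  With far fewer
complete cases than loci, a simultaneous multiple regression is not
fittable, so each locus is given its own model and the set is compared
by AIC:

* a **base** model: litter size (events out of 4 trials) on year alone;
* one **single-locus** model per polymorphic locus, adding that locus's
  0/1 heterozygosity to the base model;
* an **HO** model adding each female's mean observed heterozygosity
  across loci (the multilocus measure, on the same scale as the
  single-locus 0/1 predictors).

The analysis subset is females with known litter size and no missing
genotypes.  Predictors are left unstandardized and plain AIC is used
throughout; year is coded 0 at the first study year.  A local effect is
indicated only when some single-locus model both beats the multilocus
model decisively (its AIC lower by more than 4) and shows a
heterozygosity slope of larger magnitude than the multilocus slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeTable, complete_case_filter
from .hfc_models import fit_binomial_glm
from .identity_disequilibrium import het_matrix

__all__ = [
    "LocalEffectsRow",
    "EffectsSummary",
    "run_local_effects",
    "classify_effects",
    "local_effects_frame",
]


@dataclass
class LocalEffectsRow:
    model: str            # locus name, "HO", or "base"
    aic: float
    delta_aic_base: float
    delta_aic_ho: float
    b0: float
    se_b0: float
    b_year: float
    se_year: float
    b_het: float | None
    se_het: float | None
    het_rate: float | None   # heterozygote frequency in the subset


def run_local_effects(
    table: GenotypeTable,
    year_zero: int = 2006,
    criterion: str = "aic",
) -> list[LocalEffectsRow]:
    """Fit the base / single-locus / multilocus-HO model family.

    Loci monomorphic within the analysis subset are excluded (their
    model would duplicate the base model).  Rows are sorted by AIC
    ascending, ties broken alphabetically by model id.
    """
    sub = complete_case_filter(table, require_sex="female", require_traits=True)
    n = sub.n_individuals
    if n == 0:
        raise ValueError("no complete-case females with litter data")
    n_params_max = 4
    if n < 10 * n_params_max:
        warnings.warn(
            f"analysis subset has {n} cases for up to {n_params_max} "
            "parameters; estimates may be unstable"
        )
    h = het_matrix(sub)     # complete cases: no NaN
    df = pd.DataFrame({
        "litter_size": [i.litter_size for i in sub.individuals],
        "year": [float(i.year) - year_zero for i in sub.individuals],
    })
    df["mean_ho"] = h.mean(axis=1)

    def _crit(fit):
        return fit.criterion(criterion)

    base_fit = fit_binomial_glm(df, "litter_size", ("year",), trials=4)
    ho_fit_df = df.assign(het=df["mean_ho"])
    ho_fit = fit_binomial_glm(ho_fit_df, "litter_size", ("year", "het"),
                              trials=4)
    aic_base, aic_ho = _crit(base_fit), _crit(ho_fit)

    rows = [
        LocalEffectsRow(
            model="base", aic=aic_base, delta_aic_base=0.0,
            delta_aic_ho=aic_base - aic_ho,
            b0=float(base_fit.params["const"]),
            se_b0=float(base_fit.bse["const"]),
            b_year=float(base_fit.params["year"]),
            se_year=float(base_fit.bse["year"]),
            b_het=None, se_het=None, het_rate=None,
        ),
        LocalEffectsRow(
            model="HO", aic=aic_ho, delta_aic_base=aic_ho - aic_base,
            delta_aic_ho=0.0,
            b0=float(ho_fit.params["const"]),
            se_b0=float(ho_fit.bse["const"]),
            b_year=float(ho_fit.params["year"]),
            se_year=float(ho_fit.bse["year"]),
            b_het=float(ho_fit.params["het"]),
            se_het=float(ho_fit.bse["het"]),
            het_rate=float(df["mean_ho"].mean()),
        ),
    ]

    excluded = []
    for j, locus in enumerate(sub.loci):
        col = h[:, j]
        if np.all(col == col[0]):
            excluded.append(locus)
            continue
        fit = fit_binomial_glm(df.assign(het=col), "litter_size",
                               ("year", "het"), trials=4)
        aic = _crit(fit)
        rows.append(LocalEffectsRow(
            model=locus, aic=aic,
            delta_aic_base=aic - aic_base, delta_aic_ho=aic - aic_ho,
            b0=float(fit.params["const"]), se_b0=float(fit.bse["const"]),
            b_year=float(fit.params["year"]),
            se_year=float(fit.bse["year"]),
            b_het=float(fit.params["het"]), se_het=float(fit.bse["het"]),
            het_rate=float(col.mean()),
        ))
    if excluded:
        warnings.warn(
            "loci monomorphic in the analysis subset were excluded "
            f"(model identical to base): {excluded}"
        )
    rows.sort(key=lambda r: (r.aic, r.model))
    return rows


@dataclass
class EffectsSummary:
    """Structured verdict from the locus-by-locus AIC comparison."""

    verdict: str    # "local-effects-indicated" | "consistent-with-general-effects"
    better_than_ho: list[str] = field(default_factory=list)   # dAIC_HO < -4
    similar_to_ho: list[str] = field(default_factory=list)    # |dAIC_HO| < 2
    stronger_than_ho: list[str] = field(default_factory=list)  # |b| > |b_HO|
    negative_slope_loci: list[str] = field(default_factory=list)
    ho_slope: float | None = None


def classify_effects(rows: list[LocalEffectsRow]) -> EffectsSummary:
    """Apply the support/effect-size interpretation rules.

    "local-effects-indicated" requires at least one locus whose model is
    substantially better supported than the multilocus model (AIC lower
    by more than 4) *and* whose heterozygosity slope exceeds the
    multilocus slope in magnitude; otherwise the pattern is read as
    genome-wide inbreeding depression.  Loci with negative slopes
    (heterozygotes less fit) are flagged: that direction is opposite to
    the inbreeding-depression prediction.
    """
    ho_rows = [r for r in rows if r.model == "HO"]
    ho_slope = ho_rows[0].b_het if ho_rows else None
    loci = [r for r in rows if r.model not in ("base", "HO")]

    better = [r.model for r in loci if r.delta_aic_ho < -4]
    similar = [r.model for r in loci if abs(r.delta_aic_ho) < 2]
    stronger = (
        [r.model for r in loci
         if r.b_het is not None and abs(r.b_het) > abs(ho_slope)]
        if ho_slope is not None else []
    )
    negative = [r.model for r in loci if r.b_het is not None and r.b_het < 0]

    local = bool(set(better) & set(stronger))
    return EffectsSummary(
        verdict="local-effects-indicated" if local
        else "consistent-with-general-effects",
        better_than_ho=better,
        similar_to_ho=similar,
        stronger_than_ho=stronger,
        negative_slope_loci=negative,
        ho_slope=ho_slope,
    )


def local_effects_frame(rows: list[LocalEffectsRow]) -> pd.DataFrame:
    """Report table: one row per model, AIC-sorted."""
    return pd.DataFrame(
        {
            "Locus": [r.model for r in rows],
            "AIC": [r.aic for r in rows],
            "dAIC_base": [r.delta_aic_base for r in rows],
            "dAIC_HO": [r.delta_aic_ho for r in rows],
            "b0": [r.b0 for r in rows],
            "SE_b0": [r.se_b0 for r in rows],
            "b_year": [r.b_year for r in rows],
            "SE_year": [r.se_year for r in rows],
            "b_HO": [r.b_het for r in rows],
            "SE_HO": [r.se_het for r in rows],
            "H_O": [r.het_rate for r in rows],
        }
    )
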