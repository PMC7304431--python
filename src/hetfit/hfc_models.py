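"""Heterozygosity-fitness GLMs with information-theoretic model averaging.

Reproductive success of females is modelled with logit-link binomial
GLMs on candidate predictors {age, IR, year}:

* litter size as events/trials with 4 trials (maximum litter),
  over all females;
* a Bernoulli model for whether a female bred at all;
* litter size over breeders only (litter >= 1).

Predictors are standardized to mean 0, SD 0.5 (centre, divide by two
sample standard deviations) so binary and continuous coefficients are
on comparable scales; year is coded 0 at the first study year before
standardization.  All 2^3 predictor subsets are fitted, ranked by an
information criterion (AICc by default), and coefficients reported as
conditional (natural) model averages: each term averaged over the
models that contain it with renormalized Akaike weights, with the
variance-inflated "adjusted" standard error

    SE_adj = sum_m w_m * sqrt(var_m + (beta_m - beta_bar)^2),

95% CIs as estimate +/- 1.96 * SE_adj, relative importance (RI) as the
sum of full-set Akaike weights of models containing the term, and the
R^2 of the global (all-predictor) model.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelFit",
    "AveragedModel",
    "gelman_standardize",
    "fit_binomial_glm",
    "all_subsets_average",
    "glm_r2",
    "run_reproductive_models",
]


def gelman_standardize(x) -> np.ndarray:
    """Centre and divide by two sample standard deviations.

    The result has mean 0 and SD 0.5, putting continuous predictors on
    the scale of a centred binary predictor.  Errors on zero variance.
    """
    x = np.asarray(x, dtype=float)
    sd = np.std(x, ddof=1)
    if sd == 0 or np.isnan(sd):
        raise ValueError("cannot standardize a zero-variance vector")
    return (x - np.mean(x)) / (2.0 * sd)


@dataclass
class ModelFit:
    """A fitted binomial GLM plus its information-criterion bookkeeping."""

    predictors: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    llf: float          # includes the binomial combinatorial constant
    k: int
    n: int
    aic: float
    aicc: float
    deviance: float
    null_deviance: float
    converged: bool
    result: object = field(repr=False, default=None)

    def criterion(self, which: str) -> float:
        return self.aic if which == "aic" else self.aicc


def fit_binomial_glm(
    data: pd.DataFrame,
    response: str,
    predictors: tuple[str, ...] | list[str],
    trials: int | str | None = None,
) -> ModelFit:
    """Maximum-likelihood logit-link binomial GLM.

    ``trials=None`` fits a Bernoulli model on a 0/1 response;
    an integer fits events/trials (e.g. litter size out of 4).  The
    log-likelihood includes the log C(trials, y) constant so AIC is
    comparable with mainstream GLM output.
    """
    X = sm.add_constant(
        data[list(predictors)].astype(float), has_constant="add"
    )
    y = data[response].astype(float).to_numpy()
    if trials is None:
        endog = y
    else:
        ntr = (data[trials].astype(float).to_numpy()
               if isinstance(trials, str)
               else np.full(len(y), float(trials)))
        endog = np.column_stack([y, ntr - y])
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit()
    k = len(res.params)
    n = len(y)
    aic = -2.0 * res.llf + 2 * k
    aicc = aic + (2.0 * k * (k + 1)) / (n - k - 1) if n - k - 1 > 0 else np.inf
    return ModelFit(
        predictors=tuple(predictors),
        params=pd.Series(res.params, index=X.columns),
        bse=pd.Series(res.bse, index=X.columns),
        llf=float(res.llf),
        k=k,
        n=n,
        aic=float(aic),
        aicc=float(aicc),
        deviance=float(res.deviance),
        null_deviance=float(res.null_deviance),
        converged=bool(res.converged),
        result=res,
    )


def glm_r2(fit: ModelFit, data: pd.DataFrame, response: str,
           trials: int | str | None = None,
           method: str = "variance") -> float:
    """R^2 for a binomial GLM.

    ``method="variance"``: variance-function-based R^2,
    1 - sum((y-mu)^2/V(mu)) / sum((y-mu0)^2/V(mu0)) on the proportion
    scale.  ``method="kl"``: deviance (Kullback-Leibler) based,
    1 - D / D_null.
    """
    if method == "kl":
        return 1.0 - fit.deviance / fit.null_deviance
    if method != "variance":
        raise ValueError(f"unknown R^2 method {method!r}")
    y = data[response].astype(float).to_numpy()
    if trials is None:
        ntr = np.ones_like(y)
    elif isinstance(trials, str):
        ntr = data[trials].astype(float).to_numpy()
    else:
        ntr = np.full(len(y), float(trials))
    prop = y / ntr
    mu = np.asarray(fit.result.mu)      # fitted success probability
    mu0 = np.sum(y) / np.sum(ntr)

    def _ss(p_hat):
        v = p_hat * (1 - p_hat) / ntr
        return np.sum((prop - p_hat) ** 2 / v)

    return float(1.0 - _ss(mu) / _ss(np.full(len(y), mu0)))


@dataclass
class AveragedModel:
    """Conditional model-averaged coefficient table over all subsets."""

    response: str
    n: int
    coef: pd.DataFrame          # index: term; estimate, adj_se, ci_lo, ci_hi, ri
    r2_global: float
    candidates: pd.DataFrame    # model, k, loglik, criterion, delta, weight
    criterion: str
    fits: dict = field(repr=False, default_factory=dict)


def all_subsets_average(
    data: pd.DataFrame,
    response: str,
    predictors: tuple[str, ...] = ("age", "ir", "year"),
    trials: int | str | None = None,
    criterion: str = "aicc",
    subset_delta: float | None = None,
    r2_method: str = "variance",
) -> AveragedModel:
    """Fit all predictor subsets and conditionally average coefficients.

    ``subset_delta`` restricts averaging (and RI) to models within that
    criterion distance of the best; by default the full candidate set is
    used.  Non-convergent member models are dropped with a warning.
    """
    fits: dict[tuple[str, ...], ModelFit] = {}
    for r in range(len(predictors) + 1):
        for subset in itertools.combinations(predictors, r):
            fit = fit_binomial_glm(data, response, subset, trials=trials)
            if not fit.converged:
                warnings.warn(f"model {subset} did not converge; excluded")
                continue
            fits[subset] = fit

    crit = {s: f.criterion(criterion) for s, f in fits.items()}
    best = min(crit.values())
    if subset_delta is not None:
        fits = {s: f for s, f in fits.items()
                if crit[s] - best <= subset_delta}
        crit = {s: crit[s] for s in fits}
    delta = {s: c - best for s, c in crit.items()}
    raw_w = {s: np.exp(-d / 2.0) for s, d in delta.items()}
    tot = sum(raw_w.values())
    weight = {s: w / tot for s, w in raw_w.items()}

    terms = ["const", *predictors]
    rows = []
    for term in terms:
        members = [s for s in fits
                   if term == "const" or term in s]
        if not members:
            rows.append({"term": term, "estimate": np.nan, "adj_se": np.nan,
                         "ci_lo": np.nan, "ci_hi": np.nan, "ri": 0.0})
            continue
        w = np.array([weight[s] for s in members])
        w = w / w.sum()                      # renormalized: conditional average
        b = np.array([fits[s].params[term] for s in members])
        v = np.array([fits[s].bse[term] ** 2 for s in members])
        b_bar = float(np.sum(w * b))
        adj_se = float(np.sum(w * np.sqrt(v + (b - b_bar) ** 2)))
        ri = float(sum(weight[s] for s in members)) if term != "const" else np.nan
        rows.append({
            "term": term, "estimate": b_bar, "adj_se": adj_se,
            "ci_lo": b_bar - 1.96 * adj_se, "ci_hi": b_bar + 1.96 * adj_se,
            "ri": ri,
        })
    coef = pd.DataFrame(rows).set_index("term")

    global_fit = fits.get(tuple(predictors))
    r2 = (glm_r2(global_fit, data, response, trials=trials, method=r2_method)
          if global_fit is not None else np.nan)

    cand = pd.DataFrame(
        {
            "model": ["+".join(s) if s else "(intercept)" for s in fits],
            "k": [fits[s].k for s in fits],
            "loglik": [fits[s].llf for s in fits],
            criterion: [crit[s] for s in fits],
            "delta": [delta[s] for s in fits],
            "weight": [weight[s] for s in fits],
        }
    ).sort_values("delta").reset_index(drop=True)

    return AveragedModel(
        response=response,
        n=len(data),
        coef=coef,
        r2_global=float(r2),
        candidates=cand,
        criterion=criterion,
        fits=fits,
    )


def run_reproductive_models(
    mlh_df: pd.DataFrame,
    year_zero: int = 2006,
    criterion: str = "aicc",
    subset_delta: float | None = None,
    r2_method: str = "variance",
) -> dict[str, AveragedModel]:
    """The three female reproductive-success model sets.

    ``mlh_df`` is the per-individual frame from
    :func:`hetfit.mlh.compute_mlh` (columns ``sex, year, age,
    litter_size, ir``).  Rows are restricted to females with known
    litter size; rows missing any predictor are dropped from all
    candidate models of a response so criteria are comparable.

    Returns ``{"litter_all": ..., "breeding": ..., "litter_breeders": ...}``.
    """
    df = mlh_df.copy()
    df = df[(df["sex"] == "female") & df["litter_size"].notna()]
    df = df.dropna(subset=["ir", "age", "year"])
    if df.empty:
        raise ValueError("no female records with litter size and predictors")
    df["year0"] = df["year"].astype(float) - year_zero
    std = df.assign(
        age=gelman_standardize(df["age"]),
        ir=gelman_standardize(df["ir"]),
        year=gelman_standardize(df["year0"]),
        bred=(df["litter_size"] >= 1).astype(float),
    )
    kwargs = dict(criterion=criterion, subset_delta=subset_delta,
                  r2_method=r2_method)
    out = {
        "litter_all": all_subsets_average(
            std, "litter_size", trials=4, **kwargs),
        "breeding": all_subsets_average(std, "bred", trials=None, **kwargs),
    }
    breeders = df[df["litter_size"] >= 1]
    if breeders.empty:
        raise ValueError("no breeding females (litter >= 1)")
    std_b = breeders.assign(
        age=gelman_standardize(breeders["age"]),
        ir=gelman_standardize(breeders["ir"]),
        year=gelman_standardize(breeders["year0"]),
    )
    out["litter_breeders"] = all_subsets_average(
        std_b, "litter_size", trials=4, **kwargs)
    return out


def averaged_model_frame(models: dict[str, AveragedModel]) -> pd.DataFrame:
    """Flatten model-averaged results to a report table."""
    label = {"const": "Intercept", "age": "Age", "ir": "IR", "year": "Year"}
    rows = []
    for name, m in models.items():
        for term, r in m.coef.iterrows():
            rows.append({
                "Model": name,
                "N": m.n,
                "Predictor": label.get(term, term),
                "Estimate": r["estimate"],
                "SE": r["adj_se"],
                "RI": r["ri"],
                "R2": m.r2_global if term == "const" else np.nan,
            })
    return pd.DataFrame(rows)
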