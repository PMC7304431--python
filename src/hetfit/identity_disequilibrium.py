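"""Identity disequilibrium: the g2 statistic with bootstrap and permutation.

g2 measures the excess covariance in heterozygosity across loci within
individuals.  Under variance in inbreeding, an individual homozygous at
one locus is more likely homozygous at others; g2 > 0 quantifies that
association and is the precondition for reading heterozygosity-fitness
correlations as inbreeding depression.  Under the multiplicative model
(heterozygosity probability scaled by 1 - f per locus) the population
value is Var(f) / (1 - E[f])^2.

The estimator works on the 0/1 heterozygosity matrix.  For each ordered
locus pair (i, j), restricted to the N_ij individuals typed at both:

    num_ij = mean_k h_ki h_kj
    den_ij = sum_{k != l} h_ki h_lj / (N_ij (N_ij - 1))
    g2     = sum(num) / sum(den) - 1

Missing data are handled pairwise-complete: each locus pair uses its own
N_ij.  Precision comes from bootstrapping individuals; the p-value from
permuting every locus column independently, which destroys between-locus
association while preserving each column's heterozygosity rate and
missingness pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genotype_io import GenotypeTable

__all__ = ["G2Result", "het_matrix", "g2_point", "g2_inference"]


@dataclass
class G2Result:
    g2: float
    se: float
    p: float
    n_iter: int
    seed: int
    n_individuals: int
    n_loci: int


def het_matrix(table: GenotypeTable) -> np.ndarray:
    """(n, L) float matrix: 1 heterozygous, 0 homozygous, NaN missing."""
    n, L = table.n_individuals, table.n_loci
    h = np.full((n, L), np.nan)
    for k in range(n):
        for j in range(L):
            a, b = table.calls[k, j]
            if a is not None:
                h[k, j] = float(a != b)
    return h


def g2_point(h: np.ndarray, warn: bool = True) -> float:
    """Point estimate of g2 from a 0/1/NaN heterozygosity matrix.

    Locus pairs observed in fewer than two individuals are dropped (with
    a warning); if every pair is dropped, or the denominator sum is zero,
    returns NaN.
    """
    h = np.asarray(h, dtype=float)
    if h.ndim != 2 or h.shape[1] < 2 or h.shape[0] < 3:
        raise ValueError("need at least 3 individuals and 2 loci")
    M = (~np.isnan(h)).astype(float)
    H = np.where(np.isnan(h), 0.0, h)
    S1 = H.T @ H          # sum_k h_ki h_kj over k typed at both
    N = M.T @ M           # N_ij
    A = H.T @ M           # sum over k in K_ij of h_ki
    # B = sum over l in K_ij of h_lj  ==  A transposed
    L = h.shape[1]
    off = ~np.eye(L, dtype=bool)
    valid = off & (N >= 2)
    if warn and (off & ~valid).any():
        warnings.warn(
            f"{int((off & ~valid).sum())} locus pair(s) typed in <2 "
            "individuals were dropped from g2"
        )
    if not valid.any():
        return float("nan")
    num = np.where(valid, S1 / np.where(N > 0, N, 1), 0.0)
    den = np.where(
        valid,
        (A * A.T - S1) / np.where(N >= 2, N * (N - 1), 1),
        0.0,
    )
    den_sum = den[valid].sum()
    if den_sum == 0:
        return float("nan")
    return float(num[valid].sum() / den_sum - 1.0)


def g2_inference(
    h: np.ndarray, n_iter: int = 1000, seed: int = 0
) -> G2Result:
    """g2 with bootstrap SE and a column-permutation p-value.

    SE is the standard deviation of g2 over ``n_iter`` resamples of
    individuals with replacement (resamples on which g2 is undefined are
    skipped).  p = (1 + #{g2_perm >= g2_obs}) / (n_iter + 1), each
    permutation shuffling every locus column independently across
    individuals.  Fully deterministic given ``seed``.
    """
    if n_iter < 100:
        warnings.warn("n_iter < 100: bootstrap/permutation tails unstable")
    h = np.asarray(h, dtype=float)
    n = h.shape[0]
    g2_obs = g2_point(h)
    rng = np.random.default_rng(seed)

    boot = np.empty(n_iter)
    for b in range(n_iter):
        idx = rng.integers(0, n, n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            boot[b] = g2_point(h[idx], warn=False)
    se = float(np.nanstd(boot, ddof=1))

    n_ge = 0
    hp = np.empty_like(h)
    for _ in range(n_iter):
        for j in range(h.shape[1]):
            hp[:, j] = h[rng.permutation(n), j]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g2p = g2_point(hp, warn=False)
        if not np.isnan(g2p) and g2p >= g2_obs:
            n_ge += 1
    p = (1 + n_ge) / (n_iter + 1)
    return G2Result(
        g2=g2_obs, se=se, p=p, n_iter=n_iter, seed=seed,
        n_individuals=n, n_loci=h.shape[1],
    )
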