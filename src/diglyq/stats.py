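"""Differential regulation statistics.

Two routes, matching common proteomics practice:

* an S0-modified Welch statistic with permutation-based FDR control
  (the volcano-plot route), and
* a moderated t-statistic with empirical-Bayes variance shrinkage and
  Benjamini-Hochberg adjustment (the database route).

The S0 "fudge factor" follows the significance-analysis convention: a
constant added to the per-feature standard error, damping the significance
of features whose fold change is small even when their variance is tiny.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests


@dataclass
class PermutationConfig:
    s0: float = 2.0
    fdr_level: float = 0.01
    n_permutations: int = 250
    seed: int = 0

    def validate(self) -> None:
        if self.s0 < 0:
            raise ValueError(f"s0 must be >= 0, got {self.s0}")
        if not 0 < self.fdr_level < 1:
            raise ValueError(f"fdr_level must be in (0,1), got {self.fdr_level}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def welch_statistic(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float, float]:
    """Welch's two-sample t: ``(t, df, two-sided p)``.

    ``t = (mean(x) - mean(y)) / sqrt(s1^2/n1 + s2^2/n2)`` with the
    Welch-Satterthwaite degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    n1, n2 = len(x), len(y)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        return 0.0, float(n1 + n2 - 2), 1.0
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def s0_statistic(x: Sequence[float], y: Sequence[float], s0: float) -> float:
    """S0-modified Welch statistic ``d = (mean(x)-mean(y)) / (se + s0)``."""
    if s0 < 0:
        raise ValueError(f"s0 must be >= 0, got {s0}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    se = math.sqrt(x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y))
    denom = se + s0
    if denom == 0:
        return 0.0
    return float((x.mean() - y.mean()) / denom)


def _d_matrix(values: np.ndarray, g1: np.ndarray, g2: np.ndarray, s0: float) -> np.ndarray:
    """Vectorized S0 statistic for all rows of a features x samples matrix."""
    a, b = values[:, g1], values[:, g2]
    n1, n2 = a.shape[1], b.shape[1]
    se = np.sqrt(a.var(axis=1, ddof=1) / n1 + b.var(axis=1, ddof=1) / n2)
    diff = a.mean(axis=1) - b.mean(axis=1)
    denom = se + s0
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0, diff / denom, 0.0)
    return d


def _permutations(labels: np.ndarray, n_max: int, rng: np.random.Generator) -> List[np.ndarray]:
    """Two-group label assignments for the null, as group-1 index arrays.

    All distinct assignments are enumerated when their count is at most
    ``n_max``; otherwise ``n_max`` are sampled with the supplied generator.
    The observed assignment (and, for equal group sizes, its mirror image)
    is excluded: it is not a permutation of the labels, and counting it
    would let every feature's own statistic inflate its null.
    """
    idx = np.arange(labels.size)
    g1_size = int((labels == labels[0]).sum())
    observed = frozenset(range(g1_size))
    mirror = (
        frozenset(range(g1_size, labels.size))
        if labels.size == 2 * g1_size
        else None
    )

    def is_observed(combo: frozenset) -> bool:
        return combo == observed or combo == mirror

    total = math.comb(labels.size, g1_size)
    if total <= n_max:
        combos = [
            np.array(c)
            for c in itertools.combinations(idx, g1_size)
            if not is_observed(frozenset(c))
        ]
    else:
        combos = []
        while len(combos) < n_max:
            cand = np.sort(rng.permutation(idx)[:g1_size])
            if not is_observed(frozenset(cand.tolist())):
                combos.append(cand)
    return combos


def permutation_fdr(
    matrix: pd.DataFrame,
    labels: Sequence[str],
    config: PermutationConfig,
    group_pair: Tuple[str, str] | None = None,
) -> pd.DataFrame:
    """S0-modified Welch statistics with permutation-based FDR control.

    The observed statistic ``d`` is computed per feature; a null
    distribution is built by permuting the column group labels globally
    (the same permutation for all features, preserving feature
    correlation).  For a threshold tau,

    ``FDR(tau) = mean_perm #{|d_null| >= tau} / max(1, #{|d_obs| >= tau})``

    and the significant set is the largest set with estimated FDR at or
    below ``config.fdr_level``.  Each feature's q is the minimum FDR
    estimate over thresholds at or below its ``|d|``.

    Parameters
    ----------
    matrix:
        log-scale values, features x samples.
    labels:
        per-column group labels; ``group_pair`` selects the two groups to
        contrast (default: the two distinct labels present, first-seen
        order: group1 - group2).
    """
    config.validate()
    labels = np.asarray(labels)
    if labels.size != matrix.shape[1]:
        raise ValueError("labels length must match the number of columns")
    if group_pair is None:
        seen = list(dict.fromkeys(labels))
        if len(seen) != 2:
            raise ValueError("need exactly two groups or an explicit group_pair")
        group_pair = (seen[0], seen[1])
    mask = np.isin(labels, group_pair)
    sub = matrix.loc[:, mask]
    sublabels = labels[mask]
    g1 = np.nonzero(sublabels == group_pair[0])[0]
    g2 = np.nonzero(sublabels == group_pair[1])[0]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples")
    n = len(g1) + len(g2)
    if math.comb(n, len(g1)) < 2:
        raise ValueError("fewer than 2 distinct label permutations")

    values = sub.to_numpy(dtype=float)
    d_obs = _d_matrix(values, g1, g2, config.s0)

    rng = np.random.default_rng(config.seed)
    order = np.concatenate([g1, g2])
    perm_labels = sublabels[order]
    perm_values = values[:, order]
    combos = _permutations(perm_labels, config.n_permutations, rng)
    all_idx = np.arange(n)
    abs_null_sorted_all = []
    for combo in combos:
        pg1 = np.asarray(combo)
        pg2 = np.setdiff1d(all_idx, pg1)
        d_null = _d_matrix(perm_values, pg1, pg2, config.s0)
        abs_null_sorted_all.append(np.sort(np.abs(d_null)))
    null_sorted = np.sort(np.concatenate(abs_null_sorted_all))
    n_perm = len(combos)

    abs_obs = np.abs(d_obs)
    obs_sorted = np.sort(abs_obs)
    # FDR estimate at every candidate threshold tau = each observed |d|
    taus = obs_sorted
    n_null_ge = null_sorted.size - np.searchsorted(null_sorted, taus, side="left")
    n_obs_ge = abs_obs.size - np.searchsorted(obs_sorted, taus, side="left")
    fdr_at_tau = (n_null_ge / n_perm) / np.maximum(1, n_obs_ge)
    fdr_at_tau = np.minimum(fdr_at_tau, 1.0)
    # q for feature i: min FDR over thresholds tau <= |d_i|
    # running minimum of fdr_at_tau from the smallest tau upward
    running_min = np.minimum.accumulate(fdr_at_tau)
    pos = np.searchsorted(taus, abs_obs, side="right") - 1
    q = np.where(pos >= 0, running_min[np.maximum(pos, 0)], 1.0)

    mean1 = values[:, g1].mean(axis=1)
    mean2 = values[:, g2].mean(axis=1)
    log2fc = mean1 - mean2
    welch = np.empty(len(values))
    pvals = np.empty(len(values))
    for i in range(len(values)):
        welch[i], _, pvals[i] = welch_statistic(values[i, g1], values[i, g2])

    out = pd.DataFrame(
        {
            "id": matrix.index,
            "log2fc": log2fc,
            "t_welch": welch,
            "d": d_obs,
            "p": pvals,
            "q": q,
            "significant": q <= config.fdr_level,
            "direction": np.where(log2fc >= 0, "up", "down"),
        }
    ).set_index("id")
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iterations)."""
    if x <= 0:
        return math.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: float) -> Tuple[float, float]:
    """Empirical-Bayes prior ``(d0, s0^2)`` for per-feature variances.

    Method of moments on log sample variances: if ``s2_g ~ s0^2 *
    F(df, d0)`` then ``var(log s2_g) = trigamma(df/2) + trigamma(d0/2)``
    and the mean identity fixes ``log s0^2``.  ``d0`` may be infinite when
    the observed spread of log-variances is no larger than expected from
    sampling alone (complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise ValueError("need at least 2 positive variances")
    z = np.log(s2)
    e = z.mean() - special.digamma(df / 2) + math.log(df / 2)
    v = z.var(ddof=1) - special.polygamma(1, df / 2)
    if v <= 0:
        # no excess spread over pure sampling noise: complete shrinkage to
        # the geometric-mean variance (no chi-square bias correction, which
        # presumes a spread that is absent)
        return math.inf, float(math.exp(z.mean()))
    d0 = 2 * _trigamma_inverse(v)
    s0sq = math.exp(e + special.digamma(d0 / 2) - math.log(d0 / 2))
    return float(d0), float(s0sq)


def moderated_t(
    matrix: pd.DataFrame,
    labels: Sequence[str],
    group_pair: Tuple[str, str] | None = None,
    prior: Tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Two-group moderated t with empirical-Bayes variance shrinkage.

    Per feature, the pooled variance ``s_g^2`` (``d_g = n1+n2-2`` df) is
    shrunk toward the prior:  ``s~^2 = (d0 s0^2 + d_g s_g^2)/(d0 + d_g)``;
    the moderated t is ``effect / (u s~)`` with ``u = sqrt(1/n1 + 1/n2)``
    and ``d0 + d_g`` degrees of freedom, two-sided p.

    ``prior`` overrides the estimated ``(d0, s0^2)`` (useful for checking
    the closed-form update directly); ``d0 = 0`` collapses to the ordinary
    equal-variance t.
    """
    labels = np.asarray(labels)
    if group_pair is None:
        seen = list(dict.fromkeys(labels))
        if len(seen) != 2:
            raise ValueError("need exactly two groups or an explicit group_pair")
        group_pair = (seen[0], seen[1])
    g1 = np.nonzero(labels == group_pair[0])[0]
    g2 = np.nonzero(labels == group_pair[1])[0]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    n1, n2 = len(g1), len(g2)
    dg = n1 + n2 - 2
    a, b = values[:, g1], values[:, g2]
    effect = a.mean(axis=1) - b.mean(axis=1)
    s2 = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / dg
    if not np.isfinite(s2).any() or (s2 <= 0).all():
        raise ValueError("all features have zero residual variance")
    if prior is None:
        d0, s0sq = estimate_variance_prior(s2, dg)
    else:
        d0, s0sq = prior
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_post = math.inf
    else:
        s2_post = (d0 * s0sq + dg * s2) / (d0 + dg)
        df_post = d0 + dg
    u = math.sqrt(1 / n1 + 1 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tmod = effect / (u * np.sqrt(s2_post))
    if math.isinf(df_post):
        p = 2 * stats.norm.sf(np.abs(tmod))
    else:
        p = 2 * stats.t.sf(np.abs(tmod), df_post)
    return pd.DataFrame(
        {
            "id": matrix.index,
            "log2fc": effect,
            "t_moderated": tmod,
            "df": df_post,
            "p": p,
            "d0": d0,
            "s0_squared": s0sq,
        }
    ).set_index("id")


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
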