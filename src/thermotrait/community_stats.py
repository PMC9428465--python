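"""Inferential statistics for thermal-gradient community experiments.

Four families of analysis:

* a sequential likelihood-ratio model ladder choosing among null / linear /
  quadratic polynomial regressions (used for richness, evenness and
  ecosystem function against temperature, and function against evenness);
* ANCOVA of taxon relative abundance on a continuous thermal trait (T_opt,
  or the growth rate at the assay temperature) with assay temperature as a
  categorical factor, fitted with a separate intercept and trait slope per
  level, plus Holm-adjusted pairwise slope contrasts;
* PCA of the (replicate x taxon) relative-abundance matrix;
* PERMANOVA on Bray-Curtis dissimilarities with seeded label permutations,
  optional exhaustive enumeration on small designs, a continuous-predictor
  mode, and Bonferroni-corrected pairwise comparisons.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ALPHA = 0.05


# ---------------------------------------------------------------------------
# Polynomial model ladder
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ModelChoice:
    """Outcome of the quadratic -> linear -> null sequential model ladder."""

    chosen: str                      # "null" | "linear" | "quadratic"
    coefficients: dict               # of the chosen model (raw polynomial terms)
    lrt_stats: tuple                 # ((comparison, statistic, df, p), ...)
    r2: float                        # of the chosen model
    f_stat: tuple | None             # (F, df1, df2, p) vs intercept-only; None for null
    n: int = 0


def _ols_rss(y, x_cols):
    x = sm.add_constant(np.column_stack(x_cols)) if x_cols else np.ones((len(y), 1))
    fit = sm.OLS(y, x).fit()
    return fit, float(fit.ssr)


def polynomial_lrt(x, y, alpha: float = ALPHA) -> ModelChoice:
    """Choose among y ~ 1, y ~ x and y ~ x + x^2 by sequential nested tests.

    Starting from the quadratic model, each step drops the highest-order
    term and tests the drop; the first significant drop (p < ``alpha``)
    stops the descent and the more complex model is retained.  Each nested
    comparison uses the partial F statistic
    ``(RSS_reduced - RSS_full) / (RSS_full / df_resid)`` on (1, df_resid)
    degrees of freedom — the finite-sample-exact form of the Gaussian
    likelihood-ratio comparison (the asymptotic chi-square form is
    anticonservative at these sample sizes, which degrades null-model
    selection).  Raw (non-orthogonal) polynomial terms are used, so the
    reported coefficients are directly interpretable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 4:
        raise ValueError(f"need >= 4 complete observations, have {n}")
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct x values for the quadratic ladder")

    fit0, rss0 = _ols_rss(y, [])
    fit1, rss1 = _ols_rss(y, [x])
    fit2, rss2 = _ols_rss(y, [x, x ** 2])

    # floor RSS at the numerical-noise scale of an exact fit, so perfect
    # models do not produce spurious test signal from rounding error
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    floor = max(1e-300, 1e-24 * max(ss_tot, float(np.mean(y ** 2))))

    def nested_f(rss_red, rss_full, df_resid):
        num = max(rss_red - rss_full, 0.0)
        if rss_full <= floor:
            f = 0.0 if num <= floor else math.inf
        else:
            f = num / (rss_full / df_resid)
        return f, float(stats.f.sf(f, 1, df_resid))

    stat_q, p_q = nested_f(rss1, rss2, n - 3)   # quadratic term
    stat_l, p_l = nested_f(rss0, rss1, n - 2)   # linear term
    lrt_stats = (("quadratic_vs_linear", stat_q, 1, p_q),
                 ("linear_vs_null", stat_l, 1, p_l))

    if p_q < alpha:
        chosen, fit = "quadratic", fit2
        coef = {"intercept": fit2.params[0], "x": fit2.params[1],
                "x2": fit2.params[2]}
        f_stat = (float(fit2.fvalue), 2, n - 3, float(fit2.f_pvalue))
        r2 = float(fit2.rsquared)
    elif p_l < alpha:
        chosen, fit = "linear", fit1
        coef = {"intercept": fit1.params[0], "x": fit1.params[1]}
        f_stat = (float(fit1.fvalue), 1, n - 2, float(fit1.f_pvalue))
        r2 = float(fit1.rsquared)
    else:
        chosen = "null"
        coef = {"intercept": float(np.mean(y))}
        f_stat = None
        r2 = 0.0
    coef = {k: float(v) for k, v in coef.items()}
    return ModelChoice(chosen=chosen, coefficients=coef, lrt_stats=lrt_stats,
                       r2=r2, f_stat=f_stat, n=n)


def function_regressions(temp, evenness, biomass, alpha: float = ALPHA) -> dict:
    """The three paired model-ladder regressions of the function analysis.

    Returns ``{"biomass_vs_temp", "evenness_vs_temp", "biomass_vs_evenness"}``
    mapped to :class:`ModelChoice`.  Records with undefined evenness
    (monoculture replicates) are excluded from the evenness models, with the
    exclusion count logged.
    """
    temp = np.asarray(temp, dtype=float)
    evenness = np.asarray(evenness, dtype=float)
    biomass = np.asarray(biomass, dtype=float)
    if not (temp.size == evenness.size == biomass.size):
        raise ValueError("temp, evenness and biomass must be aligned")
    n_undefined = int(np.sum(~np.isfinite(evenness)))
    if n_undefined:
        logger.info("function_regressions: excluding %d records with "
                    "undefined evenness", n_undefined)
    return {
        "biomass_vs_temp": polynomial_lrt(temp, biomass, alpha),
        "evenness_vs_temp": polynomial_lrt(temp, evenness, alpha),
        "biomass_vs_evenness": polynomial_lrt(evenness, biomass, alpha),
    }


# ---------------------------------------------------------------------------
# ANCOVA: relative abundance ~ thermal trait x temperature factor
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class AncovaResult:
    """Full-interaction ANCOVA of abundance on a trait across factor levels."""

    overall_f: tuple                 # (F, df1, df2, p) vs intercept-only
    r2: float
    per_level_slopes: dict           # level -> (slope, se) or None if inestimable
    pairwise_contrasts: dict         # (level_a, level_b) -> Holm-adjusted p
    n: int


def ancova_trait_abundance(rel_abund, trait, temp_level) -> AncovaResult:
    """Regress relative abundance on a taxon trait, by temperature level.

    The design has one intercept and one trait slope per temperature level
    (cell-means coding of the full interaction model).  Levels whose
    observations carry fewer than two distinct trait values cannot support a
    slope; they keep their intercept and are flagged inestimable (``None``).
    The overall F compares the full model with the intercept-only null.
    Pairwise slope differences between estimable levels are tested with
    Wald z-tests and Holm-adjusted.
    """
    y = np.asarray(rel_abund, dtype=float)
    tr = np.asarray(trait, dtype=float)
    lev = np.asarray(temp_level)
    if not (y.size == tr.size == lev.size):
        raise ValueError("inputs must be aligned")
    mask = np.isfinite(y) & np.isfinite(tr)
    y, tr, lev = y[mask], tr[mask], lev[mask]
    levels = sorted(pd.unique(lev).tolist())
    n = y.size

    estimable = [lv for lv in levels
                 if np.unique(tr[lev == lv]).size >= 2]
    inestimable = [lv for lv in levels if lv not in estimable]
    if inestimable:
        logger.info("ancova: slope inestimable at level(s) %s", inestimable)

    cols, names = [], []
    for lv in levels:
        cols.append((lev == lv).astype(float))
        names.append(f"mu[{lv}]")
    for lv in estimable:
        cols.append(np.where(lev == lv, tr, 0.0))
        names.append(f"slope[{lv}]")
    x = np.column_stack(cols)
    fit = sm.OLS(y, x).fit()
    p_full = x.shape[1]
    rss_full = float(fit.ssr)
    rss_null = float(np.sum((y - y.mean()) ** 2))
    df1 = p_full - 1
    df2 = n - p_full
    if df2 <= 0:
        raise ValueError("not enough observations for the interaction model")
    f_val = ((rss_null - rss_full) / df1) / (rss_full / df2)
    overall = (float(f_val), df1, df2, float(stats.f.sf(f_val, df1, df2)))
    r2 = 1.0 - rss_full / rss_null if rss_null > 0 else np.nan

    slopes: dict = {}
    for lv in levels:
        if lv in estimable:
            j = names.index(f"slope[{lv}]")
            slopes[lv] = (float(fit.params[j]), float(fit.bse[j]))
        else:
            slopes[lv] = None

    pairs = list(itertools.combinations(estimable, 2))
    raw_p = []
    for a, b in pairs:
        ja, jb = names.index(f"slope[{a}]"), names.index(f"slope[{b}]")
        contrast = np.zeros(p_full)
        contrast[ja], contrast[jb] = 1.0, -1.0
        test = fit.t_test(contrast)
        raw_p.append(float(test.pvalue))
    if pairs:
        adjusted = multipletests(raw_p, method="holm")[1]
        pairwise = {pair: float(p) for pair, p in zip(pairs, adjusted)}
    else:
        pairwise = {}
    return AncovaResult(overall_f=overall, r2=float(r2),
                        per_level_slopes=slopes, pairwise_contrasts=pairwise,
                        n=n)


# ---------------------------------------------------------------------------
# PCA of composition
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class PcaResult:
    """Principal components of a column-centred relative-abundance matrix."""

    scores: np.ndarray       # replicate x component
    loadings: np.ndarray     # taxon x component (orthonormal columns)
    var_explained: np.ndarray  # fraction per component, non-increasing


def pca_composition(matrix) -> PcaResult:
    """PCA by SVD of the column-centred matrix, unscaled.

    Proportions share a common scale, so columns are centred but not
    standardised.  The sign of each component is fixed by making its
    largest-magnitude loading positive.  A zero-variance matrix yields zero
    scores and zero variance explained rather than an error.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows and >= 2 columns")
    centered = x - x.mean(axis=0, keepdims=True)
    total_var = float(np.sum(centered ** 2))
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    n_comp = min(x.shape[0] - 1, x.shape[1])
    u, s, vt = u[:, :n_comp], s[:n_comp], vt[:n_comp]
    loadings = vt.T
    scores = u * s
    for j in range(n_comp):
        i_star = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_star, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    # degeneracy threshold relative to the input scale: exact cancellation in
    # the centring leaves residuals of order eps * |x|
    if total_var <= (1e-12) ** 2 * max(1.0, float(np.sum(x ** 2))):
        var_explained = np.zeros(n_comp)
        scores = np.zeros_like(scores)
    else:
        var_explained = s ** 2 / total_var
    return PcaResult(scores=scores, loadings=loadings,
                     var_explained=var_explained)


# ---------------------------------------------------------------------------
# Bray-Curtis + PERMANOVA
# ---------------------------------------------------------------------------

def bray_curtis(matrix) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity between non-negative rows.

    ``d(u, v) = 1 - 2 sum_i min(u_i, v_i) / sum_i (u_i + v_i)``.  Symmetric
    with a zero diagonal.  A pair of all-zero rows has an undefined distance
    (0/0); it is returned as NaN with a warning.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if np.any(x < 0):
        raise ValueError("Bray-Curtis requires non-negative entries")
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        mins = np.minimum(x[i], x[i + 1:]).sum(axis=1)
        sums = x[i].sum() + x[i + 1:].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dij = 1.0 - 2.0 * mins / sums
        d[i, i + 1:] = dij
        d[i + 1:, i] = dij
    if np.isnan(d).any():
        logger.warning("Bray-Curtis undefined for %d all-zero row pair(s)",
                       int(np.isnan(d).sum() // 2))
    return d


@dataclasses.dataclass(frozen=True)
class PermanovaResult:
    """Pseudo-F partition of a distance matrix with a permutation p-value."""

    pseudo_f: float
    df: tuple                # (between, within)
    p_perm: float
    n_perm: int
    pairwise: dict | None = None


def _gower_center(dist: np.ndarray) -> np.ndarray:
    a = -0.5 * dist ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _hat_matrix(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q @ q.T


def _pseudo_f(gower: np.ndarray, hat: np.ndarray, df1: int, df2: int) -> float:
    ss_total = float(np.trace(gower))
    ss_model = float(np.sum(hat * gower))  # trace(H G) for symmetric H, G
    ss_resid = ss_total - ss_model
    return (ss_model / df1) / (ss_resid / df2)


def permanova(
    dist,
    groups,
    n_perm: int = 999,
    seed=None,
    continuous: bool = False,
    exact: bool = False,
) -> PermanovaResult:
    """PERMANOVA: permutation test of a pseudo-F on a distance matrix.

    The distance matrix is Gower-centred and partitioned against the design
    (a one-way factor by default, or an intercept-plus-slope design when
    ``continuous=True``, matching temperature-as-continuous analyses).  The
    p-value uses the add-one estimator
    ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)`` over seeded whole-row label
    permutations.  With ``exact=True`` all distinct label arrangements are
    enumerated instead (small designs only) and
    ``p = #{F >= F_obs} / N_arrangements`` with the identity included.

    Raises ``ValueError`` for singleton groups or fewer than two groups in
    factor mode.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains undefined entries")
    g = np.asarray(groups)
    if g.size != n:
        raise ValueError("groups must align with the distance matrix")

    if continuous:
        z = g.astype(float)
        if np.unique(z).size < 2:
            raise ValueError("continuous predictor is constant")
        x = np.column_stack([np.ones(n), z - z.mean()])
        df1, df2 = 1, n - 2
    else:
        labels, inverse = np.unique(g, return_inverse=True)
        a = labels.size
        if a < 2:
            raise ValueError("need >= 2 groups")
        sizes = np.bincount(inverse)
        if np.any(sizes < 2):
            small = labels[sizes < 2].tolist()
            raise ValueError(f"singleton group(s): {small}")
        x = np.column_stack([np.ones(n)] +
                            [(inverse == j).astype(float) for j in range(a - 1)])
        df1, df2 = a - 1, n - a

    gower = _gower_center(d)
    hat = _hat_matrix(x)
    f_obs = _pseudo_f(gower, hat, df1, df2)

    tol = 1e-12 * max(1.0, abs(f_obs))
    if exact:
        seen = set()
        count_ge = 0
        for perm in itertools.permutations(range(n)):
            key = tuple(g[list(perm)])
            if key in seen:
                continue
            seen.add(key)
            # the design for label pattern g[perm] has hat H[perm][:, perm]
            idx = np.asarray(perm)
            f_p = _pseudo_f(gower, hat[np.ix_(idx, idx)], df1, df2)
            if f_p >= f_obs - tol:
                count_ge += 1
        n_arr = len(seen)
        return PermanovaResult(pseudo_f=float(f_obs), df=(df1, df2),
                               p_perm=count_ge / n_arr, n_perm=n_arr - 1)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        f_p = _pseudo_f(gower[np.ix_(idx, idx)], hat, df1, df2)
        if f_p >= f_obs - tol:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_perm)
    return PermanovaResult(pseudo_f=float(f_obs), df=(df1, df2),
                           p_perm=p, n_perm=n_perm)


def pairwise_permanova(dist, groups, n_perm: int = 999, seed=None) -> pd.DataFrame:
    """PERMANOVA on every group pair with Bonferroni-adjusted p-values.

    Each pair's raw permutation p is multiplied by the number of pairs and
    capped at 1.  Returns a DataFrame ``group_a, group_b, pseudo_f, p_raw,
    p_adjusted``.
    """
    d = np.asarray(dist, dtype=float)
    g = np.asarray(groups)
    labels = np.unique(g)
    pairs = list(itertools.combinations(labels.tolist(), 2))
    n_pairs = len(pairs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for a, b in pairs:
        mask = np.isin(g, [a, b])
        idx = np.where(mask)[0]
        sub = d[np.ix_(idx, idx)]
        res = permanova(sub, g[idx], n_perm=n_perm, seed=rng)
        rows.append({"group_a": a, "group_b": b, "pseudo_f": res.pseudo_f,
                     "p_raw": res.p_perm,
                     "p_adjusted": min(1.0, res.p_perm * n_pairs)})
    return pd.DataFrame(rows)
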