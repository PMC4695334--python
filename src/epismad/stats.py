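"""Shared statistical primitives.

Establishment choices: Benjamini–Hochberg via statsmodels, the chi-square
test via scipy's contingency machinery (no continuity correction — the
variant used for the bound-fraction and binding-mode enrichments),
hypergeometric over-representation and the exact binomial two-library test
via scipy.  The moderated-variance two-sample t (empirical-Bayes shrinkage
of per-gene variances toward a common prior, Smyth-style) is implemented
here because no installed Python package provides it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

MIN_EXPECTED_CELL = 5.0


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    pvalue: float
    low_expected: bool  # any expected cell < 5 — result flagged, not rejected


def chi2_2x2(table) -> Chi2Result:
    """Pearson chi-square on a 2x2 table, df=1, two-sided, no Yates correction.

    A warning flag is set when any expected cell is below 5; the statistic is
    still returned (callers may switch to Fisher's exact test).
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if np.any(obs < 0):
        raise ValueError("cell counts must be non-negative")
    if obs.sum() == 0 or np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        # degenerate margin: no information
        return Chi2Result(0.0, 1.0, True)
    chi2, p, _, expected = stats.chi2_contingency(obs, correction=False)
    return Chi2Result(float(chi2), float(p), bool(np.any(expected < MIN_EXPECTED_CELL)))


def fisher_2x2(table) -> Chi2Result:
    """Fisher's exact test, two-sided; alternative for small expected cells."""
    obs = np.asarray(table, dtype=int)
    _, p = stats.fisher_exact(obs, alternative="two-sided")
    return Chi2Result(float("nan"), float(p), False)


def hypergeom_over(universe: int, set_size: int, draw_size: int, overlap: int) -> float:
    """One-sided over-representation p-value, P(X >= overlap).

    X ~ Hypergeometric(universe, set_size, draw_size): the overlap obtained
    when ``draw_size`` genes are drawn without replacement from a universe
    containing ``set_size`` marked genes.
    """
    if not (0 <= set_size <= universe and 0 <= draw_size <= universe):
        raise ValueError("set sizes must lie within the universe")
    if universe == 0:
        raise ValueError("empty universe")
    if overlap < 0:
        raise ValueError("overlap must be non-negative")
    return float(stats.hypergeom.sf(overlap - 1, universe, set_size, draw_size))


def binomial_two_library(count_a: int, count_b: int, lib_a: float, lib_b: float) -> float:
    """Exact binomial test for one window across two libraries without replicates.

    Conditional on the window total n = count_a + count_b, count_a is
    Binomial(n, lib_a / (lib_a + lib_b)) under the null of equal normalized
    signal; two-sided p by the minimum-likelihood method.
    """
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be positive")
    n = count_a + count_b
    if n == 0:
        return 1.0
    return float(stats.binomtest(count_a, n, lib_a / (lib_a + lib_b), alternative="two-sided").pvalue)


def log2_ratio(count_a: float, count_b: float, lib_a: float, lib_b: float, pseudocount: float = 0.5) -> float:
    """Library-size-normalized log2 fold change with a pseudocount for zeros."""
    return float(np.log2(((count_a + pseudocount) / lib_a) / ((count_b + pseudocount) / lib_b)))


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (x > 0)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = special.polygamma(1, y)
        step = tri * (tri - x) / special.polygamma(2, y)
        y = y - step  # polygamma(2) < 0, so this moves toward the root
        if abs(step) < 1e-10 * y:
            break
    return float(y)


def fit_fdist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to observed per-gene variances.

    Models s2 ~ s0^2 * F(df, d0) and estimates (d0, s0^2) from the first two
    moments of log s2 (Smyth 2004).  Returns d0 = inf when the observed
    spread of log s2 is no larger than expected from chi-square sampling
    alone (i.e. the variances look common).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    half_d0 = _trigamma_inverse(evar)
    s02 = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    return 2.0 * half_d0, s02


def moderated_ttest(group1: np.ndarray, group2: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise two-sample t with empirical-Bayes variance shrinkage.

    ``group1`` and ``group2`` are (genes x replicates) arrays on a log2
    scale.  Per-gene pooled variances are shrunk toward a common prior
    fitted across genes; the t statistic gains the prior degrees of freedom.
    Returns (difference of means: group1 - group2, t, two-sided p).

    Degenerate inputs: if every per-gene variance is zero (noise-free data)
    p is 0 where the means differ and 1 where they agree.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    n1, n2 = g1.shape[1], g2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 replicates per group")
    diff = g1.mean(axis=1) - g2.mean(axis=1)
    df_res = n1 + n2 - 2
    s2 = ((n1 - 1) * g1.var(axis=1, ddof=1) + (n2 - 1) * g2.var(axis=1, ddof=1)) / df_res
    if np.all(s2 <= 0):
        p = np.where(diff == 0.0, 1.0, 0.0)
        t = np.where(diff == 0.0, 0.0, np.inf * np.sign(diff))
        return diff, t, p
    d0, s02 = fit_fdist(s2, df_res)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df_res * s2) / (d0 + df_res)
        df_total = df_res + d0
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        t = np.where(se == 0, np.where(diff == 0, 0.0, np.inf * np.sign(diff)), t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(p), 1.0, p)
    return diff, t, np.clip(p, 0.0, 1.0)


def welch_ttest(group1: np.ndarray, group2: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch two-sample t; degenerate zero-variance rows get
    p = 1 when the means agree and p = 0 when they differ."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.shape[1] < 2 or g2.shape[1] < 2:
        raise ValueError("need at least 2 replicates per group")
    diff = g1.mean(axis=1) - g2.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(g1, g2, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        with np.errstate(invalid="ignore"):
            p[bad] = np.where(diff[bad] == 0.0, 1.0, 0.0)
            t[bad] = np.where(diff[bad] == 0.0, 0.0, np.inf * np.sign(diff[bad]))
    return diff, t, p
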