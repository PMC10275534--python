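"""Repeated-measures inference for the connectivity comparisons.

Implements the paired-samples t-test and the fully within-subject
3 (method: rest, LPF, FIR) x 2 (connection type: within-, between-network)
ANOVA.  Sphericity is handled with the Greenhouse-Geisser epsilon,
estimated per effect from the covariance of the orthonormalized condition
differences; degrees of freedom are multiplied by epsilon and p-values
come from the F distribution with the fractional corrected df.

Effect sizes are generalized eta-squared (eta_g^2) with the
within-design convention: the denominator is the effect SS plus *all*
error terms including the subject SS, so values are comparable across
designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as spla
from scipy import stats as spstats

__all__ = ["TestResult", "paired_t", "rm_anova_oneway", "rm_anova_3x2", "gg_epsilon"]


@dataclass
class TestResult:
    """One test statistic with (possibly fractional, GG-corrected) df."""

    effect: str
    statistic: float  # t for paired tests, F for ANOVA effects
    df1: float
    df2: float
    p_value: float
    effect_size_ges: float
    correction: str = "none"  # "none" | "greenhouse_geisser"
    epsilon: float = 1.0


def paired_t(x: np.ndarray, y: np.ndarray, effect: str = "paired") -> TestResult:
    """Two-sided paired-samples t-test with generalized eta-squared.

    eta_g^2 comes from the two-condition within-subject SS decomposition
    (effect SS over effect + subject + error SS).
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("paired differences have zero variance; t undefined")
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2 * spstats.t.sf(abs(t), df)

    cells = np.column_stack([x, y])
    gm = cells.mean()
    ss_effect = n * ((cells.mean(axis=0) - gm) ** 2).sum()
    ss_subject = 2 * ((cells.mean(axis=1) - gm) ** 2).sum()
    resid = cells - cells.mean(axis=0) - cells.mean(axis=1, keepdims=True) + gm
    ss_error = (resid**2).sum()
    ges = ss_effect / (ss_effect + ss_subject + ss_error)
    return TestResult(
        effect=effect,
        statistic=float(t),
        df1=1.0,
        df2=float(df),
        p_value=float(p),
        effect_size_ges=float(ges),
    )


def _effect_basis(k: int) -> np.ndarray:
    """k x (k-1) orthonormal basis of the contrast space (orthogonal to 1)."""
    return spla.helmert(k, full=False).T


def gg_epsilon(scores: np.ndarray, contrasts: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon for one within-subject effect.

    ``scores`` is subjects x conditions (the cells relevant to the effect,
    collapsed over other factors); ``contrasts`` an orthonormal basis of
    the effect space.  Epsilon is computed from the covariance of the
    transformed scores and lies in [1/df, 1].
    """
    S = np.cov(scores, rowvar=False)
    M = np.asarray(contrasts, dtype=float)
    E = M.T @ S @ M
    df = E.shape[0]
    tr = np.trace(E)
    denom = df * np.trace(E @ E)
    if denom <= 0:
        return 1.0
    eps = tr**2 / denom
    return float(np.clip(eps, 1.0 / df, 1.0))


def rm_anova_oneway(scores: np.ndarray, effect: str = "condition") -> TestResult:
    """One-way within-subject ANOVA (subjects x conditions) with GG
    correction.  With two conditions, F equals the square of the paired t."""
    Y = np.asarray(scores, dtype=float)
    if Y.ndim != 2:
        raise ValueError("scores must be subjects x conditions")
    n, k = Y.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 conditions")
    gm = Y.mean()
    m_s = Y.mean(axis=1)
    m_c = Y.mean(axis=0)
    ss_subject = k * ((m_s - gm) ** 2).sum()
    ss_effect = n * ((m_c - gm) ** 2).sum()
    resid = Y - m_c[None, :] - m_s[:, None] + gm
    ss_error = (resid**2).sum()
    df1, df2 = k - 1, (k - 1) * (n - 1)
    if ss_error == 0:
        raise ValueError("zero error variance; F undefined")
    F = (ss_effect / df1) / (ss_error / df2)
    eps = gg_epsilon(Y, _effect_basis(k)) if df1 > 1 else 1.0
    cdf1, cdf2 = eps * df1, eps * df2
    return TestResult(
        effect=effect,
        statistic=float(F),
        df1=float(cdf1),
        df2=float(cdf2),
        p_value=float(spstats.f.sf(F, cdf1, cdf2)),
        effect_size_ges=float(ss_effect / (ss_effect + ss_subject + ss_error)),
        correction="greenhouse_geisser" if df1 > 1 else "none",
        epsilon=float(eps),
    )


def rm_anova_3x2(
    cells: np.ndarray,
    factor_a: str = "method",
    factor_b: str = "connection_type",
) -> dict[str, TestResult]:
    """Two-way fully within-subject ANOVA with GG correction.

    ``cells`` has shape (subjects, levels_a, levels_b) — at the default
    use, (n, 3 methods, 2 connection types) of Fisher-z scores; any level
    counts >= 2 are accepted.  Returns a result per effect: the two main
    effects and the interaction.
    """
    Y = np.asarray(cells, dtype=float)
    if Y.ndim != 3:
        raise ValueError("cells must be subjects x levels_a x levels_b")
    if np.isnan(Y).any():
        raise ValueError("design must be complete (no missing cells)")
    n, a, b = Y.shape
    if n < 3 or a < 2 or b < 2:
        raise ValueError("need >= 3 subjects and >= 2 levels per factor")

    gm = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_ab = Y.mean(axis=0)
    m_sa = Y.mean(axis=2)
    m_sb = Y.mean(axis=1)

    ss_subject = a * b * ((m_s - gm) ** 2).sum()
    ss_a = n * b * ((m_a - gm) ** 2).sum()
    ss_b = n * a * ((m_b - gm) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2).sum()
    ss_as = b * ((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2).sum()
    ss_bs = a * ((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2).sum()
    ss_total = ((Y - gm) ** 2).sum()
    ss_abs = ss_total - (
        ss_subject + ss_a + ss_b + ss_ab + ss_as + ss_bs
    )
    ss_abs = max(ss_abs, 0.0)

    all_error = ss_subject + ss_as + ss_bs + ss_abs

    M_a = _effect_basis(a)
    M_b = _effect_basis(b)
    M_ab = np.kron(M_a, M_b)

    specs = [
        (factor_a, ss_a, a - 1, ss_as, (a - 1) * (n - 1), m_sa, M_a),
        (factor_b, ss_b, b - 1, ss_bs, (b - 1) * (n - 1), m_sb, M_b),
        (
            f"{factor_a}:{factor_b}",
            ss_ab,
            (a - 1) * (b - 1),
            ss_abs,
            (a - 1) * (b - 1) * (n - 1),
            Y.reshape(n, a * b),
            M_ab,
        ),
    ]
    results: dict[str, TestResult] = {}
    tol = 1e-12 * max(ss_total, 1.0)
    for name, ss_eff, df1, ss_err, df2, scores, M in specs:
        if ss_err <= tol and ss_eff <= tol:
            # identical conditions within every subject: no effect, no error
            results[name] = TestResult(
                effect=name, statistic=0.0, df1=float(df1), df2=float(df2),
                p_value=1.0, effect_size_ges=0.0,
            )
            continue
        F = (ss_eff / df1) / (ss_err / df2)
        eps = gg_epsilon(scores, M) if df1 > 1 else 1.0
        cdf1, cdf2 = eps * df1, eps * df2
        p = float(spstats.f.sf(F, cdf1, cdf2))
        results[name] = TestResult(
            effect=name,
            statistic=float(F),
            df1=float(cdf1),
            df2=float(cdf2),
            p_value=p,
            effect_size_ges=float(ss_eff / (ss_eff + all_error)),
            correction="greenhouse_geisser" if df1 > 1 else "none",
            epsilon=float(eps),
        )
    return results
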