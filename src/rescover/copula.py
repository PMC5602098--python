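"""Gaussian-copula machinery for the synthetic survey.

The published experiment reports only rank correlations (Spearman's rho)
between the seven cover measurements.  A Gaussian copula is the minimal
joint law consistent with those pairwise rank dependencies: for a
bivariate Gaussian copula with parameter ``rho`` the population Spearman
correlation of the two margins is ``(6/pi) * arcsin(rho / 2)``, so a
target rank correlation ``rho_s`` is hit exactly by the copula parameter
``2 * sin(pi * rho_s / 6)`` — as long as both margins are continuous.

When one margin is discretised (the six-photo visual-aid instruments)
the tie structure shrinks the attainable Spearman correlation, and the
copula parameter must be calibrated upward; :func:`calibrate_discretized_rho`
does this by bisection against a Monte-Carlo evaluation of the
post-discretisation Spearman.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy import stats


def spearman_to_pearson(rho_s: float) -> float:
    """Map a Spearman rank correlation to the Gaussian copula parameter.

    Uses the closed-form bivariate-normal link ``rho = 2 sin(pi rho_s / 6)``,
    exact for continuous margins.
    """
    if not -1.0 <= rho_s <= 1.0:
        raise ValueError(f"rho_s must lie in [-1, 1], got {rho_s}")
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def _gauss_copula_uniforms(rho: float, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal(n)
    return stats.norm.cdf(z1), stats.norm.cdf(z2)


def sample_copula_pair(
    rho_s_target: float,
    marginal_a: Callable[[np.ndarray], np.ndarray],
    marginal_b: Callable[[np.ndarray], np.ndarray],
    n: int,
    seed: int | np.random.Generator = 0,
    discretize_b: Sequence[float] | None = None,
    discretize_values: Sequence[float] | None = None,
    calibrate_tol: float = 0.0025,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` paired samples whose Spearman correlation targets ``rho_s_target``.

    Parameters
    ----------
    marginal_a, marginal_b
        Quantile functions (inverse CDFs) mapping uniforms on (0, 1) to
        the desired margins.  Must be non-degenerate.
    discretize_b
        Optional ascending cut points (on the scale of ``marginal_b``'s
        output) that bin the second margin into ``len(cuts) + 1`` ordered
        categories; the copula parameter is then pre-calibrated with
        :func:`calibrate_discretized_rho` so the *post-discretisation*
        Spearman hits the target.
    discretize_values
        Values reported for each category; defaults to the category
        index ``1..k`` (the Spearman correlation is unaffected, being a
        rank statistic).

    Returns
    -------
    (a, b) : arrays of shape (n,)
    """
    if n < 2:
        raise ValueError("need n >= 2 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if discretize_b is None:
        rho = spearman_to_pearson(rho_s_target)
    else:
        # calibration works on the uniform scale: map cut points through
        # the margin's CDF by inverting the quantile function numerically
        u_cuts = _cuts_to_uniform(marginal_b, discretize_b)
        rho = calibrate_discretized_rho(
            rho_s_target, u_cuts, tol=calibrate_tol,
            rng=np.random.default_rng(rng.integers(2**31)),
        )

    ua, ub = _gauss_copula_uniforms(rho, n, rng)
    a = np.asarray(marginal_a(ua), dtype=float)
    if _is_degenerate(a):
        raise ValueError("marginal_a is degenerate (constant); correlation undefined")
    if discretize_b is None:
        b = np.asarray(marginal_b(ub), dtype=float)
        if _is_degenerate(b):
            raise ValueError("marginal_b is degenerate (constant); correlation undefined")
    else:
        cat = np.searchsorted(np.asarray(u_cuts), ub)
        vals = (np.arange(1, len(u_cuts) + 2, dtype=float)
                if discretize_values is None else np.asarray(discretize_values, float))
        b = vals[cat]
    return a, b


def _is_degenerate(x: np.ndarray) -> bool:
    return bool(np.min(x) == np.max(x))


def _cuts_to_uniform(marginal: Callable[[np.ndarray], np.ndarray],
                     cuts: Sequence[float]) -> np.ndarray:
    """Invert a strictly monotone quantile function at the given cut points."""
    from scipy.optimize import brentq

    u_cuts = []
    for c in cuts:
        f = lambda u: float(marginal(np.array([u]))[0]) - c
        lo, hi = 1e-12, 1.0 - 1e-12
        if f(lo) >= 0:
            u_cuts.append(0.0)
        elif f(hi) <= 0:
            u_cuts.append(1.0)
        else:
            u_cuts.append(brentq(f, lo, hi, xtol=1e-12))
    u = np.asarray(u_cuts, float)
    if np.any(np.diff(u) < 0):
        raise ValueError("cut points must be ascending under the marginal")
    return u


def discretized_spearman(rho: float, u_cuts: np.ndarray, n: int,
                         rng: np.random.Generator) -> float:
    """Monte-Carlo Spearman between a continuous margin and a discretised one.

    Spearman correlation is invariant to strictly monotone margins, so the
    simulation runs directly on copula uniforms; the second coordinate is
    binned at ``u_cuts``.
    """
    ua, ub = _gauss_copula_uniforms(rho, n, rng)
    cat = np.searchsorted(u_cuts, ub)
    return float(stats.spearmanr(ua, cat).statistic)


def calibrate_discretized_rho(
    rho_s_target: float,
    u_cuts_or_scheme: Sequence[float],
    tol: float = 0.0025,
    n_mc: int = 300_000,
    rng: np.random.Generator | int | None = None,
    max_iter: int = 40,
) -> float:
    """Find the copula parameter whose post-discretisation Spearman hits the target.

    The map from copula parameter to post-discretisation Spearman is
    monotone increasing, so simple bisection suffices.  The Monte-Carlo
    evaluation uses a fixed, seeded stream so calibration is repeatable.

    Raises
    ------
    ValueError
        If the target exceeds the maximum Spearman attainable under the
        discretisation (reported in the message).
    """
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(12345 if rng is None else rng)
    u_cuts = np.asarray(u_cuts_or_scheme, dtype=float)
    if u_cuts.ndim != 1 or np.any(np.diff(u_cuts) < 0):
        raise ValueError("u_cuts must be an ascending 1-D sequence")
    if rho_s_target == 0.0:
        return 0.0
    sign = 1.0 if rho_s_target > 0 else -1.0
    target = abs(rho_s_target)

    # attainability check at the near-comonotone end
    rmax = 0.9999
    smax = discretized_spearman(sign * rmax, u_cuts, n_mc, rng) * sign
    if target > smax - tol:
        raise ValueError(
            f"target Spearman {rho_s_target:+.3f} unattainable under this "
            f"discretisation; attainable maximum is about {sign * smax:+.3f}"
        )

    lo, hi = 0.0, rmax
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        s = discretized_spearman(sign * mid, u_cuts, n_mc, rng) * sign
        if abs(s - target) <= tol:
            return sign * mid
        if s < target:
            lo = mid
        else:
            hi = mid
    return sign * 0.5 * (lo + hi)


def nearest_positive_definite(corr: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric correlation matrix to the nearest PSD correlation matrix.

    Alternating projections between the PSD cone (eigenvalue clipping)
    and the unit-diagonal set, in the spirit of Higham's algorithm.  For
    mildly indefinite inputs the pairwise entries move very little.
    """
    a = np.asarray(corr, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("corr must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("corr must be symmetric")
    x = a.copy()
    for _ in range(100):
        w, v = np.linalg.eigh(x)
        if w.min() >= eps:
            break
        w = np.clip(w, eps, None)
        x = (v * w) @ v.T
        d = np.sqrt(np.diag(x))
        x = x / np.outer(d, d)
        np.fill_diagonal(x, 1.0)
    return x
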