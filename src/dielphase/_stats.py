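"""Shared small-sample variance machinery.

RNA-seq designs with two or three replicates leave per-gene variance estimates
with very few degrees of freedom, which gives amplitude and fold-change
z-statistics heavy t-tails. Both the diel amplitude statistic and the
fold-change test therefore squeeze per-gene variances toward a common prior
fitted across genes (empirical Bayes, scaled inverse-chi-square prior), the
same information-sharing idea used by moderated-t and negative-binomial
dispersion-shrinkage methods.
"""
from __future__ import annotations

import numpy as np
from scipy.special import digamma, polygamma


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Monotone decreasing target, so the iteration (on the inverse scale)
    converges from the asymptotic starting point ``0.5 + 1/x``.
    """
    if not np.isfinite(x) or x <= 0:
        raise ValueError("trigamma_inverse requires a positive finite argument")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = polygamma(1, y)
        step = tri * (1.0 - tri / x) / polygamma(2, y)
        y += step
        if abs(step) < 1e-10 * abs(y):
            break
    return float(y)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Moderate per-gene sample variances toward a fitted prior.

    Parameters
    ----------
    s2 : per-gene sample variances, each on ``df`` degrees of freedom.
    df : residual degrees of freedom of each ``s2`` entry.

    Returns
    -------
    (s2_post, d0, s0_2) where ``s2_post = (d0*s0_2 + df*s2) / (d0 + df)``;
    ``d0`` is the prior degrees of freedom (``inf`` when the observed spread of
    log-variances is no wider than pure chi-square noise, in which case every
    posterior variance equals the prior point ``s0_2``).
    """
    s2 = np.asarray(s2, dtype=float)
    valid = np.isfinite(s2) & (s2 > 0)
    if valid.sum() < 2:
        return s2.copy(), 0.0, float("nan")
    z = np.log(s2[valid])
    # e is an unbiased estimator of log(sigma^2) under the chi-square model
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_2 = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        post = (d0 * s0_2 + df * s2) / (d0 + df)
        # genes with s2 == 0 still get the prior contribution
        post = np.where(valid | (s2 == 0), post, s2)
        return post, float(d0), s0_2
    # observed spread narrower than sampling noise: common variance for all
    s0_2 = float(np.exp(e_mean))
    return np.full_like(s2, s0_2), float("inf"), s0_2
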