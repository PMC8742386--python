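"""Statistical primitives: exact binomial upper tail, Z-score, BH correction.

The enrichment test asks whether the observed overlap score k of an n-SNP
input set is surprisingly large under the background per-SNP overlap
probability p, i.e. P(X >= k) for X ~ Binomial(n, p).  The tail is computed by
direct summation of the probability mass function in log space (no normal
approximation), which stays accurate to ~1e-13 relative even deep in the tail
where naive floating-point term products underflow.
"""

from __future__ import annotations

import numpy as np

from .errors import SnpEnrichError


def _log_pmf_table(n: int, p: float) -> np.ndarray:
    """log pmf of Binomial(n, p) at k = 0..n, via cumulative log ratios."""
    if p == 0.0:
        out = np.full(n + 1, -np.inf)
        out[0] = 0.0
        return out
    if p == 1.0:
        out = np.full(n + 1, -np.inf)
        out[n] = 0.0
        return out
    k = np.arange(1, n + 1, dtype=float)
    # log C(n,k) accumulated from log C(n,0) = 0
    log_comb = np.concatenate(([0.0], np.cumsum(np.log((n - k + 1) / k))))
    ks = np.arange(n + 1, dtype=float)
    return log_comb + ks * np.log(p) + (n - ks) * np.log1p(-p)


def binomial_test_upper(k, n: int, p: float):
    """One-sided upper-tail binomial p-value, P(X >= k), X ~ Binomial(n, p).

    Exact tail summation (no normal approximation).  ``k`` may be a scalar or
    an integer array; the full pmf table for (n, p) is built once and the
    upper tail accumulated from the smallest terms, so all values of ``k``
    share one stable computation.
    """
    k_arr = np.atleast_1d(np.asarray(k, dtype=np.int64))
    scalar = np.isscalar(k) or np.ndim(k) == 0
    if n < 0:
        raise SnpEnrichError(f"n must be >= 0, got {n}")
    if not (0.0 <= p <= 1.0):
        raise SnpEnrichError(f"p must be in [0, 1], got {p}")
    if ((k_arr < 0) | (k_arr > n)).any():
        raise SnpEnrichError(f"k must be in [0, {n}]")
    log_pmf = _log_pmf_table(n, p)
    # reverse cumulative logsumexp: log P(X >= k), accumulated tail-first
    rev = np.logaddexp.accumulate(log_pmf[::-1])[::-1]
    sf = np.exp(rev)
    sf = np.minimum(sf, 1.0)
    sf[0] = 1.0  # P(X >= 0) exactly
    out = sf[k_arr]
    return float(out[0]) if scalar else out


def z_score(k_obs: int, bg_scores) -> float:
    """Standard score of the observed overlap against the background scores.

    Uses the sample standard deviation (denominator n-1).  If the background
    is degenerate (sd = 0) the convention is 0.0 when k_obs equals the
    background mean and a signed infinity otherwise; callers flag the
    degenerate case in their output.
    """
    bg = np.asarray(bg_scores, dtype=float)
    if bg.size < 2:
        raise SnpEnrichError("z_score needs at least 2 background scores")
    mean = bg.mean()
    sd = bg.std(ddof=1)
    if sd == 0.0:
        if k_obs == mean:
            return 0.0
        return float(np.inf if k_obs > mean else -np.inf)
    return float((k_obs - mean) / sd)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} (p_(j) * m / j), capped at 1, returned in the input
    order.  Values outside [0, 1] are a hard error.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise SnpEnrichError("bh_adjust expects a non-empty 1-D p-value vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise SnpEnrichError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
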