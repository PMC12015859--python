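"""Inferential toolbox: paired tests, Bayes factors, FDR, within-subject CIs, d'.

Conventions: all p-values are two-sided; Cohen's d for paired designs is the
mean difference divided by the standard deviation of the differences; BF10
quantifies evidence for the alternative over the null under the default JZS
prior (Cauchy with scale r on the standardized effect).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import integrate, stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["StatResult", "paired_t", "bf10_jzs_paired", "running_fdr_ttest",
           "morey_ci", "wilcoxon_signed_rank", "bf10_rank", "dprime"]


@dataclass(frozen=True)
class StatResult:
    """A single comparison: statistic, df, two-sided p, effect size, BF10."""

    statistic: float
    df: float | None                  # None flags an exact / rank test
    p: float
    effect_size: float | None = None
    bf10: float | None = None
    method: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")
        if self.bf10 is not None and self.bf10 <= 0:
            raise ValueError("BF10 must be positive")

    def to_json(self, inputs: np.ndarray | None = None, **params) -> str:
        rec = asdict(self)
        rec["params"] = params
        if inputs is not None:
            rec["inputs_sha256"] = hashlib.sha256(
                np.ascontiguousarray(inputs, dtype=np.float64).tobytes()
            ).hexdigest()
        return json.dumps(rec)


def paired_t(x, y, with_bf: bool = False) -> StatResult:
    """Two-tailed paired-samples t-test with matched-pairs Cohen's d.

    ``t = mean(d) / (sd(d)/sqrt(n))`` and ``d_z = mean(d)/sd(d)`` where d are
    the pairwise differences (sd with n-1 denominator).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 2")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return StatResult(0.0, float(d.size - 1), 1.0, 0.0,
                              bf10=bf10_jzs_paired(0.0, d.size) if with_bf else None,
                              method="paired_t")
        raise ValueError("zero variance of differences")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    bf = bf10_jzs_paired(t, n) if with_bf else None
    return StatResult(float(t), float(n - 1), float(p), float(d.mean() / sd),
                      bf10=bf, method="paired_t")


def bf10_jzs_paired(t: float, n: int, r: float = np.sqrt(2) / 2,
                    rtol: float = 1e-6) -> float:
    """Default-prior (JZS) Bayes factor for a paired/one-sample t statistic.

    The alternative places a Cauchy(0, r) prior on the standardized effect
    delta; the marginal likelihood is the noncentral-t density integrated over
    the prior, computed by adaptive quadrature.  BF10 is monotone increasing
    in |t| for fixed n.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    nu = n - 1
    t2 = float(t) * float(t)

    # Likelihood-ratio form of the JZS integral: the Cauchy prior on delta is
    # an inverse-gamma(1/2, 1/2) mixture over the variance ratio g, so
    # BF10 = int_0^inf  pi(g) k^{-1/2} [(1 + t^2/(k nu)) / (1 + t^2/nu)]
    #        ^{-(nu+1)/2} dg  with k = 1 + n g r^2.
    # Evaluated in log space the ratio stays finite for arbitrarily large |t|.
    def integrand_logg(x: float) -> float:
        g = np.exp(x)
        k = 1.0 + n * g * r * r
        log_ratio = np.log1p(t2 / (k * nu)) - np.log1p(t2 / nu)
        log_f = (-0.5 * np.log(2 * np.pi) - 1.5 * x - 1.0 / (2 * g)
                 - 0.5 * np.log(k) - 0.5 * (nu + 1) * log_ratio)
        return float(np.exp(log_f + x))          # Jacobian dg = g dx

    # integrate over log g; the integrand turns over near g ~ t^2/(n r^2 nu),
    # so that point is pinned as a breakpoint for the quadrature
    turnover = min(60.0, np.log1p(t2 / (n * r * r * nu)) + 1.0)
    lo, hi = -60.0, max(60.0, turnover + 20.0)
    bf, err = integrate.quad(integrand_logg, lo, hi, epsrel=rtol, limit=400,
                             points=[0.0, turnover])
    if not np.isfinite(bf) or bf <= 0:
        raise ArithmeticError(
            f"BF integration failed: t={t}, n={n}, value={bf}, err={err}")
    return float(bf)


def _paired_t_vector(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized paired t over axis 0 (subjects); returns (t, p) per column."""
    d = x - y
    n = d.shape[0]
    sd = d.std(axis=0, ddof=1)
    sd = np.where(sd == 0, np.nan, sd)
    t = d.mean(axis=0) / (sd / np.sqrt(n))
    t = np.where(np.isnan(t), 0.0, t)
    p = 2.0 * sps.t.sf(np.abs(t), n - 1)
    return t, p


def running_fdr_ttest(series_x: np.ndarray, series_y: np.ndarray,
                      q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise paired t-tests with Benjamini-Hochberg correction.

    ``series_x`` and ``series_y`` are subjects x timepoints.  Returns
    ``(mask, p)`` where ``mask`` marks timepoints still significant after the
    step-up correction across all tested timepoints.
    """
    x = np.asarray(series_x, dtype=float)
    y = np.asarray(series_y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need matching subjects x timepoints arrays, >= 2 subjects")
    _, p = _paired_t_vector(x, y)
    mask = multipletests(p, alpha=q, method="fdr_bh")[0]
    mask &= p < 1.0   # a constant-zero difference is never a discovery
    return mask, p


def morey_ci(data: np.ndarray, level: float = 0.95) -> np.ndarray:
    """Within-subject CI half-widths per condition (Cousineau-Morey).

    Each subject's mean is removed (grand mean restored) before computing
    per-condition standard errors, and the half-widths are inflated by
    ``sqrt(C / (C - 1))`` for C conditions.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("need subjects x conditions with n >= 2, C >= 2")
    n, c = y.shape
    norm = y - y.mean(axis=1, keepdims=True) + y.mean()
    se = norm.std(axis=0, ddof=1) / np.sqrt(n)
    t_crit = sps.t.ppf(0.5 + level / 2.0, n - 1)
    return t_crit * se * np.sqrt(c / (c - 1))


def wilcoxon_signed_rank(x, y) -> StatResult:
    """Two-sided Wilcoxon signed-rank test (exact for n <= 25).

    Zero differences are dropped; above n = 25 the normal approximation with
    continuity correction is used.  The effect size is the rank-biserial
    correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    n = d.size
    if n <= 25:
        res = sps.wilcoxon(d, method="exact", alternative="two-sided")
    else:
        res = sps.wilcoxon(d, method="approx", correction=True,
                           alternative="two-sided")
    # scipy returns min(W+, W-); report W+ and use it for the effect size
    ranks = sps.rankdata(np.abs(d))
    wp = ranks[d > 0].sum()
    total = n * (n + 1) / 2.0
    rank_biserial = 2.0 * wp / total - 1.0
    return StatResult(float(wp), None, float(res.pvalue),
                      float(rank_biserial), method="wilcoxon_signed_rank")


def bf10_rank(x, y, r: float = np.sqrt(2) / 2) -> float:
    """Rank-based Bayes factor via normal scores of the differences.

    The signed differences are replaced by van der Waerden normal scores
    (preserving sign and rank only), and the JZS paired Bayes factor is
    applied to those scores — an approximation to latent-normal rank methods.
    Invariant under monotone transforms of the differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    signed_ranks = np.sign(d) * ranks
    # map signed ranks to symmetric normal scores on (-1, 1) quantiles
    scores = sps.norm.ppf(0.5 + signed_ranks / (2.0 * (n + 1)))
    sd = scores.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate scores")
    t = scores.mean() / (sd / np.sqrt(n))
    return bf10_jzs_paired(float(t), n, r=r)


def dprime(hits: int, misses: int, fas: int, crs: int,
           correction: str = "loglinear") -> float:
    """Signal-detection sensitivity with an extreme-rate correction.

    ``loglinear`` adds 0.5 to the hit and false-alarm counts and 1 to the
    totals; ``clip`` replaces rates of 0 or 1 by 1/(2N) and 1 - 1/(2N).  Both
    keep d' finite at perfect performance.
    """
    if min(hits, misses, fas, crs) < 0:
        raise ValueError("counts must be non-negative")
    n_sig = hits + misses
    n_noise = fas + crs
    if n_sig == 0 or n_noise == 0:
        raise ValueError("need at least one signal and one noise trial")
    if correction == "loglinear":
        h = (hits + 0.5) / (n_sig + 1.0)
        f = (fas + 0.5) / (n_noise + 1.0)
    elif correction == "clip":
        h = min(max(hits / n_sig, 1.0 / (2 * n_sig)), 1.0 - 1.0 / (2 * n_sig))
        f = min(max(fas / n_noise, 1.0 / (2 * n_noise)), 1.0 - 1.0 / (2 * n_noise))
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return float(sps.norm.ppf(h) - sps.norm.ppf(f))
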