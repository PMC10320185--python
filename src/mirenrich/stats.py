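"""Statistical kernels: exact urn tests, rank tests, p-value combination.

Every test returns a :class:`TestResult`. One-sided orientation is uniform
across the package: ``alternative="less"`` always means the *first* sample is
stochastically smaller than the second (for urn tests the only one-sided
question asked is over-representation, an upper tail).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

from .errors import DomainError

ALTERNATIVES = ("less", "greater", "two_sided")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    alternative: str
    method: str
    n_x: int
    n_y: int

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise DomainError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class UrnSpec:
    """2×2 urn: N genes, K in the term, n drawn (targeted), k overlap.

    ``odds`` is the Wallenius weight of in-term relative to out-of-term
    genes; odds = 1 recovers the central (Fisher-exact) hypergeometric.
    """

    N: int
    K: int
    n: int
    k: int
    odds: float = 1.0

    def __post_init__(self):
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise DomainError(f"invalid urn margins N={self.N} K={self.K} n={self.n}")
        if not (0 <= self.k <= min(self.K, self.n)):
            raise DomainError(f"overlap k={self.k} outside [0, min(K, n)]")
        if not (self.odds > 0 and math.isfinite(self.odds)):
            raise DomainError(f"odds must be positive and finite, got {self.odds}")


def _check_alternative(alternative: str) -> str:
    if alternative not in ALTERNATIVES:
        raise DomainError(f"alternative must be one of {ALTERNATIVES}")
    return alternative


def hypergeom_upper_tail(urn: UrnSpec) -> TestResult:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), evaluated exactly.

    The tail is accumulated in integer arithmetic (sums of binomial
    coefficients) and converted to float once, so no precision is lost to
    log-gamma approximations — the one-sided Fisher exact test of term
    over-representation.
    """
    if urn.odds != 1.0:
        raise DomainError("hypergeom_upper_tail requires odds = 1")
    N, K, n, k = urn.N, urn.K, urn.n, urn.k
    num = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    den = math.comb(N, n)
    p = float(Fraction(num, den))  # correctly-rounded rational -> float
    return TestResult(float(k), min(p, 1.0), "greater", "hypergeom", n, N - n)


def wallenius_pmf_vector(N: int, K: int, n: int, odds: float) -> np.ndarray:
    """Full Wallenius non-central hypergeometric pmf over k = 0..min(K, n).

    Computed by the exact sequential-draw recursion: balls are drawn one at a
    time with probability proportional to remaining weight (in-term balls
    weighted ``odds``). The recursion is exact up to float rounding, so the
    result matches brute-force enumeration of ordered draws.
    """
    kmax = min(K, n)
    prob = np.zeros(kmax + 1)
    prob[0] = 1.0
    ks = np.arange(kmax + 1, dtype=float)
    for j in range(n):
        rem_in = np.maximum(K - ks, 0.0) * odds
        rem_out = np.maximum((N - K) - (j - ks), 0.0)
        tot = rem_in + rem_out
        with np.errstate(invalid="ignore", divide="ignore"):
            p_in = np.where(tot > 0, rem_in / np.where(tot > 0, tot, 1.0), 0.0)
        nxt = prob * (1.0 - p_in)
        nxt[1:] += prob[:-1] * p_in[:-1]
        prob = nxt
    return prob


def wallenius_upper_tail(urn: UrnSpec) -> TestResult:
    """P(X >= k) under the Wallenius non-central hypergeometric with odds w.

    The biased-urn analogue of the Fisher exact upper tail: in-term genes are
    weighted ``urn.odds`` relative to out-of-term genes, correcting the
    enrichment test for unequal targeting propensity.
    """
    N, K, n, k, w = urn.N, urn.K, urn.n, urn.k, urn.odds
    pmf = wallenius_pmf_vector(N, K, n, w)
    p = float(pmf[k:].sum())
    return TestResult(float(k), min(max(p, 0.0), 1.0), "greater", "wallenius", n, N - n)


def estimate_bias_odds(
    term_genes: Iterable[str],
    target_flags: Mapping[str, int],
    bias: Mapping[str, float],
    universe: Iterable[str],
) -> float:
    """Wallenius odds for one term from a per-gene targeting-bias covariate.

    A monotone probability-weighting function pwf(bias) -> P(targeted) is fit
    by isotonic regression on equal-count bins of the covariate; the returned
    odds is the ratio of mean-pwf odds inside the term to outside it. Genes
    with a higher covariate (e.g. more recorded miRNA interactions) are more
    likely to appear targeted regardless of biology; terms enriched for such
    genes receive odds > 1 and hence a less optimistic p-value.
    """
    uni = sorted(set(universe))
    term = set(term_genes)
    if not term <= set(uni):
        raise DomainError("term_genes must be a subset of universe")
    missing = [g for g in uni if g not in bias]
    if missing:
        raise DomainError(f"bias covariate undefined for {len(missing)} universe genes")
    b = np.array([float(bias[g]) for g in uni])
    if np.any(b < 0):
        raise DomainError("bias covariate must be nonnegative")
    f = np.array([1.0 if target_flags.get(g, 0) else 0.0 for g in uni])

    nbins = min(10, len(uni) // 20)
    if nbins < 1:
        nbins = 1
    order = np.lexsort((np.array(uni), b))  # by bias, ties by gene id
    chunks = np.array_split(order, nbins)
    bx = np.array([b[c].mean() for c in chunks])
    by = np.array([f[c].mean() for c in chunks])
    bw = np.array([len(c) for c in chunks], dtype=float)
    if np.ptp(bx) == 0:
        pwf = np.full(len(uni), float(np.average(by, weights=bw)))
    else:
        iso = IsotonicRegression(
            increasing="auto", out_of_bounds="clip", y_min=0.0, y_max=1.0
        )
        iso.fit(bx, by, sample_weight=bw)
        pwf = iso.predict(b)

    in_term = np.array([g in term for g in uni])
    m_in = float(pwf[in_term].mean())
    m_out = float(pwf[~in_term].mean()) if np.any(~in_term) else m_in
    lo, hi = 1e-6, 1.0 - 1e-6
    if not (lo <= m_in <= hi) or not (lo <= m_out <= hi):
        warnings.warn("degenerate pwf mean clamped to [1e-6, 1-1e-6]", stacklevel=2)
    m_in = min(max(m_in, lo), hi)
    m_out = min(max(m_out, lo), hi)
    return (m_in / (1.0 - m_in)) / (m_out / (1.0 - m_out))


def fisher_combine(pvals: Sequence[float]) -> TestResult:
    """Fisher's method: chi2 = -2 sum ln p_i, df = 2 * len(pvals)."""
    if len(pvals) == 0:
        raise DomainError("fisher_combine requires at least one p-value")
    ps = np.asarray(pvals, dtype=float)
    if np.any(ps < 0) or np.any(ps > 1):
        raise DomainError("p-values must lie in [0, 1]")
    if np.any(ps == 0):
        warnings.warn("p = 0 clamped to smallest positive float", stacklevel=2)
        ps = np.where(ps == 0, np.nextafter(0.0, 1.0), ps)
    # canonical summation order makes the statistic permutation-invariant
    # to the last ulp, not just mathematically
    stat = float(-2.0 * np.sum(np.log(np.sort(ps))))
    p = float(sps.chi2.sf(stat, df=2 * len(ps)))
    return TestResult(stat, min(max(p, 0.0), 1.0), "greater", "fisher_combine", len(ps), 0)


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def mwu_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "two_sided"
) -> TestResult:
    """Mann–Whitney U test of x versus y.

    Exact permutation null when n_x + n_y <= 20 with no ties; otherwise the
    normal approximation with tie-corrected variance and 0.5 continuity
    correction. ``alternative="less"``: x stochastically smaller than y.
    """
    _check_alternative(alternative)
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    nx, ny = len(xa), len(ya)
    if nx < 1 or ny < 1:
        raise DomainError("mwu_test requires non-empty samples")
    pooled = np.concatenate([xa, ya])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; p set to 1", stacklevel=2)
        return TestResult(nx * ny / 2.0, 1.0, alternative, "mwu_exact", nx, ny)
    exact = (nx + ny <= 20) and not _has_ties(pooled)
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(
        xa,
        ya,
        alternative=alternative.replace("two_sided", "two-sided"),
        method=method,
        use_continuity=True,
    )
    tag = "mwu_exact" if exact else "mwu_normal"
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)), alternative, tag, nx, ny)


def ks_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "two_sided"
) -> TestResult:
    """Two-sample Kolmogorov–Smirnov test.

    ``alternative="less"`` (x stochastically smaller) corresponds to the
    alternative F_x > F_y on ECDFs. Exact p when n_x * n_y <= 1e4 and there
    are no ties, asymptotic otherwise.
    """
    _check_alternative(alternative)
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    nx, ny = len(xa), len(ya)
    if nx < 1 or ny < 1:
        raise DomainError("ks_test requires non-empty samples")
    # x stochastically smaller <=> its ECDF lies above: scipy's "greater"
    scipy_alt = {"less": "greater", "greater": "less", "two_sided": "two-sided"}[
        alternative
    ]
    pooled = np.concatenate([xa, ya])
    exact = nx * ny <= 10_000 and not _has_ties(pooled)
    res = sps.ks_2samp(xa, ya, alternative=scipy_alt, method="exact" if exact else "asymp")
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)), alternative, "ks", nx, ny)


def camera_pr(
    stat: Mapping[str, float],
    member: Iterable[str],
    rho: float = 0.01,
    alternative: str = "two_sided",
) -> TestResult:
    """Competitive pre-ranked gene-set test (CAMERA, Wu & Smyth style).

    Genes are ranked by ``stat``; the member set's mean rank is compared to
    the overall mean under sampling-without-replacement, with the variance
    inflated by VIF = 1 + (m - 1) * rho for inter-gene correlation rho.
    ``alternative="less"``: member genes sit at *lower* ranks (smaller stat)
    than expected.
    """
    _check_alternative(alternative)
    if not (0.0 <= rho < 1.0):
        raise DomainError("rho must lie in [0, 1)")
    genes = sorted(stat)
    member = set(member)
    if not member:
        raise DomainError("member set is empty")
    if not member < set(genes):
        raise DomainError("member must be a proper subset of the ranked genes")
    values = np.array([float(stat[g]) for g in genes])
    ranks = sps.rankdata(values)  # average ranks on ties
    G, m = len(genes), len(member)
    in_member = np.array([g in member for g in genes])
    mean_member = float(ranks[in_member].mean())
    mu = float(ranks.mean())  # (G + 1) / 2 when tie-free
    sigma2 = float(np.var(ranks))  # population variance of the rank vector
    vif = 1.0 + (m - 1) * rho
    var_mean = sigma2 / m * (G - m) / (G - 1) * vif
    z = (mean_member - mu) / math.sqrt(var_mean)
    if alternative == "less":
        p = float(sps.norm.cdf(z))
    elif alternative == "greater":
        p = float(sps.norm.sf(z))
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult(z, min(p, 1.0), alternative, "camera_pr", m, G - m)


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    ps = np.asarray(pvals, dtype=float)
    if ps.size == 0:
        return []
    if np.any(ps < 0) or np.any(ps > 1):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(ps, method="fdr_bh")[1].tolist()
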