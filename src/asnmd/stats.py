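"""Proportion tests, overlap enrichment and q-value combination.

The proportion test ("pi-test") is the normal approximation to the
binomial without continuity correction, intended for samples of size
n > 40; one-sided P-values are reported. The two-sample form uses the
unpooled variance estimate by default (``pooled=True`` selects the
classical pooled form). Overlap enrichment between a selected set and a
marked set within a common universe is assessed against the
hypergeometric null (sampling without replacement), with the expected
overlap ``n * K / N`` reported alongside the upper-tail probability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

MIN_PI_TEST_N = 40


@dataclass
class ProportionTestResult:
    z: float
    p: float
    direction: str
    estimate: float
    reference: float


@dataclass
class EnrichmentResult:
    universe: int
    marked: int
    selected: int
    observed: int
    expected: float
    p: float


def _tail_p(z: float, alternative: str) -> tuple[float, str]:
    if alternative == "greater":
        return float(sps.norm.sf(z)), "greater"
    if alternative == "less":
        return float(sps.norm.cdf(z)), "less"
    if alternative == "observed":
        direction = "greater" if z >= 0 else "less"
        return float(sps.norm.sf(abs(z))), direction
    raise ValueError(f"unknown alternative {alternative!r}")


def pi_test_one_sample(
    k: int, n: int, p0: float, alternative: str = "observed"
) -> ProportionTestResult:
    """One-sample proportion z-test of k/n against reference p0.

    Normal approximation without continuity correction; a warning is
    emitted for n <= 40 where the approximation is unreliable.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly inside (0, 1)")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    if n <= MIN_PI_TEST_N:
        warnings.warn(f"pi-test normal approximation unreliable for n = {n} <= 40")
    phat = k / n
    z = (phat - p0) / math.sqrt(p0 * (1 - p0) / n)
    p, direction = _tail_p(z, alternative)
    return ProportionTestResult(z=z, p=p, direction=direction, estimate=phat, reference=p0)


def pi_test_two_sample(
    k1: int,
    n1: int,
    k2: int,
    n2: int,
    alternative: str = "greater",
    pooled: bool = False,
) -> ProportionTestResult:
    """Two-sample proportion z-test (unpooled variance by default).

    ``alternative="greater"`` tests p1 > p2 with the upper normal tail;
    swapping the samples flips the sign of z and maps p to 1 - p.
    """
    for n in (n1, n2):
        if n <= MIN_PI_TEST_N:
            warnings.warn(f"pi-test normal approximation unreliable for n = {n} <= 40")
    p1, p2 = k1 / n1, k2 / n2
    if pooled:
        pc = (k1 + k2) / (n1 + n2)
        var = pc * (1 - pc) * (1 / n1 + 1 / n2)
    else:
        var = p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2
    if var == 0:
        warnings.warn("degenerate proportions; z undefined")
        return ProportionTestResult(
            z=float("nan"), p=float("nan"), direction="undefined", estimate=p1, reference=p2
        )
    z = (p1 - p2) / math.sqrt(var)
    p, direction = _tail_p(z, alternative)
    return ProportionTestResult(z=z, p=p, direction=direction, estimate=p1, reference=p2)


def overlap_enrichment(N: int, K: int, n: int, k: int) -> EnrichmentResult:
    """Enrichment of overlap k between a selected n and a marked K in universe N.

    Expected overlap is n*K/N; the p-value is the hypergeometric upper
    tail P(X >= k).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K, n <= N")
    if not 0 <= k <= min(K, n):
        raise ValueError("impossible overlap k")
    expected = n * K / N if N else float("nan")
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(universe=N, marked=K, selected=n, observed=k,
                            expected=expected, p=p)


def wilcoxon_one_sample(values, alternative: str = "greater") -> float:
    """One-sample Wilcoxon signed-rank test of median zero.

    Normal approximation with continuity correction; one-sided p for the
    stated alternative. Requires >= 5 nonzero values.
    """
    vals = np.asarray(values, dtype=float)
    nonzero = vals[vals != 0]
    if len(nonzero) == 0:
        raise ValueError("all values are zero; test undefined")
    if len(nonzero) < 5:
        warnings.warn("fewer than 5 nonzero values; signed-rank test unreliable")
    res = sps.wilcoxon(nonzero, correction=True, alternative=alternative, method="approx")
    return float(res.pvalue)


def mann_whitney(values_a, values_b, alternative: str = "greater") -> float:
    """Two-sample rank-sum (Mann-Whitney) test, normal approximation with
    continuity correction; one-sided p."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if min(len(a), len(b)) < 5:
        warnings.warn("fewer than 5 values per group; rank-sum test unreliable")
    res = sps.mannwhitneyu(a, b, alternative=alternative, use_continuity=True,
                           method="asymptotic")
    return float(res.pvalue)


def combine_neglog_q(*qvalues: float) -> float:
    """Combine q-values as their product (additive on the -log10 scale)."""
    out = 1.0
    for q in qvalues:
        if not 0 <= q <= 1:
            raise ValueError(f"q-value {q} outside [0, 1]")
        if q == 0:
            warnings.warn("q = 0 clipped to the machine floor")
            q = float(np.finfo(float).tiny)
        out *= q
    return out
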