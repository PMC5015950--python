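"""Shared statistical primitives.

Three small pieces used across the scan and enrichment stages: the
R-style one-sample test of proportions (used for the window SNP-deficit
test), Benjamini-Hochberg step-up FDR adjustment with an explicit
hypothesis-universe size, and a two-sided Fisher's exact test on a 2x2
contingency table with an over/under direction label.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
from scipy import stats as _ss

__all__ = ["prop_test_less", "adjust_pvalues_bh", "fisher_exact_2x2"]


def prop_test_less(x: int, n: int, p0: float) -> float:
    """One-sample test of proportions, one-sided alternative ``p < p0``.

    Mirrors R's ``prop.test(x, n, p = p0, alternative = "less",
    correct = TRUE)``: a chi-square statistic with Yates continuity
    correction, whose signed square root is referred to the standard
    normal lower tail.

    Parameters
    ----------
    x : observed successes (here: SNP positions in a window)
    n : trials (eligible positions)
    p0 : null proportion (genome-wide SNP density), in (0, 1)

    Returns
    -------
    The one-sided p-value in [0, 1].
    """
    if not 0 < p0 < 1:
        raise ValueError(f"p0 must be in (0,1), got {p0}")
    if not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    expected = n * p0
    yates = min(0.5, abs(x - expected))
    chisq = (abs(x - expected) - yates) ** 2 / (n * p0 * (1.0 - p0))
    z = np.sign(x / n - p0) * np.sqrt(chisq)
    return float(_ss.norm.cdf(z))


def adjust_pvalues_bh(pvals: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} ( p_(j) * m / j )`` capped at 1, mapped back to
    the input order.  ``m`` is the size of the hypothesis universe and
    defaults to ``len(pvals)``; it may be larger when only a subset of
    tested hypotheses is supplied (the unsupplied ones are then assumed to
    rank after every supplied one, which is conservative and matches how
    significance tables report only their top rows).
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"universe size m={m} smaller than number of p-values {p.size}")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int
) -> tuple[float, Literal["Over", "Under"]]:
    """Two-sided Fisher's exact test on the table ``[[a, b], [c, d]]``.

    Layout follows enrichment convention: columns are (test set,
    reference set), rows are (annotated, not annotated), i.e. ``a`` =
    annotated genes in the test set, ``b`` = annotated in the reference,
    ``c``/``d`` the unannotated complements.  The two-sided p-value sums
    the point probabilities of all tables with the same margins that are
    no more likely than the observed one (the minimum-likelihood method).

    Returns ``(p, direction)`` where direction is ``"Under"`` when the
    test-set annotation rate ``a/(a+c)`` falls below the reference rate
    ``b/(b+d)``, else ``"Over"``.
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("table entries must be non-negative integers")
    if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
        raise ValueError(f"degenerate margin in table ({a}, {b}, {c}, {d})")
    _, p = _ss.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    direction: Literal["Over", "Under"] = (
        "Under" if a * (b + d) < b * (a + c) else "Over"
    )
    return float(min(p, 1.0)), direction
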