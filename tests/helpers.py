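"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (explicit loops, direct
formulas) and never calls the package code it is used to check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def brute_enrichment_score(
    metric: list[float], hit: list[bool], weight_exponent: float = 1.0
) -> float:
    """Running-sum enrichment score by explicit iteration."""
    n = len(metric)
    n_hit = sum(hit)
    denom = sum(abs(m) ** weight_exponent for m, h in zip(metric, hit) if h)
    running = 0.0
    best = 0.0
    for m, h in zip(metric, hit):
        if h:
            running += ((abs(m) ** weight_exponent) / denom
                        if denom > 0 else 1.0 / n_hit)
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


def exhaustive_null(metric: list[float], set_size: int) -> list[float]:
    """ES of every possible same-size gene set (positional)."""
    n = len(metric)
    scores = []
    for positions in combinations(range(n), set_size):
        hit = [i in positions for i in range(n)]
        scores.append(brute_enrichment_score(metric, hit))
    return scores


def direct_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson correlation from the covariance formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum()
                 / math.sqrt((xc**2).sum() * (yc**2).sum()))


def welch_by_hand(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch t statistic and two-sided p from the direct formulas."""
    from scipy.stats import t as tdist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, 2 * tdist.sf(abs(t), df)


def chain_diffusion_scores(
    n: int, alpha: float, horizon: int
) -> list[float]:
    """Knockout scores for a unit-weight chain T -> a1 -> ... -> a_{n-1}.

    Computed by expanding the matrix powers by hand: after deleting T,
    gene a_k (1-based) loses exactly the single length-k walk from T, of
    weight alpha**k, so its row distance is alpha**k for k <= horizon and
    zero beyond.
    """
    return [alpha**k if k <= horizon else 0.0 for k in range(1, n)]
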