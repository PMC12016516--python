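"""Independent oracles used by the test suite.

These are deliberately naive implementations (exact rational enumeration,
literal step-up arithmetic) kept separate from the package so that the
implementation and its checks never share code.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import accumulate
from math import comb

import numpy as np
from scipy.stats import hypergeom


def hypergeom_tail_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact one-sided Fisher P by exhaustive enumeration of the tail.

    Sums hypergeometric probabilities P(X = x) for every x >= a over the
    full support, in exact rational arithmetic.
    """
    n_pop = a + b + c + d
    successes = a + b
    draws = a + c
    lo = max(0, successes + draws - n_pop)
    hi = min(successes, draws)
    assert lo <= a <= hi
    total = sum(
        Fraction(comb(successes, x) * comb(n_pop - successes, draws - x), comb(n_pop, draws))
        for x in range(a, hi + 1)
    )
    return float(total)


def bh_stepup_oracle(pvalues) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up: p(i)*m/i with a cumulative
    minimum taken from the largest rank downwards, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def sweep_fisher_vs_oracle(max_margin: int, sf_fn) -> float:
    """Max |sf_fn - exact enumeration| over every 2x2 table whose four
    margins are all <= max_margin.

    ``sf_fn(a_array, b_array, total_exp, total_ctrl)`` must return the
    one-sided Fisher P for pooled counts.  Tables are grouped by
    (row-margin K, column-margin n, population N); within a group the
    exact tail probabilities are big-integer suffix sums.
    """
    worst = 0.0
    for successes in range(0, max_margin + 1):          # a + b
        for draws in range(0, max_margin + 1):          # a + c
            lo_n = max(successes, draws, 1)
            hi_n = max_margin + min(successes, draws)
            for n_pop in range(lo_n, hi_n + 1):
                amin = max(0, successes + draws - n_pop)
                amax = min(successes, draws)
                denom = comb(n_pop, draws)
                terms = [
                    comb(successes, x) * comb(n_pop - successes, draws - x)
                    for x in range(amin, amax + 1)
                ]
                tails = list(accumulate(reversed(terms)))[::-1]
                oracle = np.array([t / denom for t in tails], dtype=float)
                a_vals = np.arange(amin, amax + 1)
                b_vals = successes - a_vals
                got = sf_fn(a_vals, b_vals, draws, n_pop - draws)
                err = float(np.abs(got - oracle).max())
                if err > worst:
                    worst = err
    return worst


def translate_dna(seq: str) -> str:
    """Standard-genetic-code translation oracle (via Biopython)."""
    from Bio.Seq import Seq

    return str(Seq(seq).translate())
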