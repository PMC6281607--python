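"""Shared fixtures and independent enumeration oracles.

The oracles recompute the exact tests from their combinatorial definitions
with arbitrary-precision integer arithmetic (``math.comb``), independently
of the scipy-based implementations they check.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pytest

from rvburden.synthetic_cohort import fixture_matrix


# same minimum-likelihood convention as the implementation (relative
# tolerance 1 + 1e-7 on the tie comparison), evaluated in exact integers
_TOL_NUM, _TOL_DEN = 10**7 + 1, 10**7


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full enumeration in exact integers."""
    r1, r2, k = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or k == 0 or b + d == 0:
        return 1.0
    lo, hi = max(0, k - r2), min(r1, k)
    numers = [math.comb(r1, x) * math.comb(r2, k - x) for x in range(lo, hi + 1)]
    obs = numers[a - lo]
    total = math.comb(r1 + r2, k)
    kept = sum(n for n in numers if n * _TOL_DEN <= obs * _TOL_NUM)
    return kept / total


def hwe_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional HWE p by enumeration of heterozygote counts."""
    n = n_AA + n_Aa + n_aa
    n_a = n_Aa + 2 * n_aa
    if n_a == 0 or n_a == 2 * n:
        return 1.0
    weights = {}
    for het in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        hom_a = (n_a - het) // 2
        hom_A = n - het - hom_a
        weights[het] = (
            2**het
            * math.factorial(n)
            // (
                math.factorial(hom_A)
                * math.factorial(het)
                * math.factorial(hom_a)
            )
        )
    obs = weights[n_Aa]
    tol_num, tol_den = 10**12 + 1, 10**12
    kept = sum(w for w in weights.values() if w * tol_den <= obs * tol_num)
    return kept / sum(weights.values())


def apply_edit(window_start: int, window_seq: str, pos: int, ref: str, alt: str) -> str:
    """Apply a variant edit to a reference window (sequence oracle)."""
    off = pos - window_start
    assert window_seq[off : off + len(ref)] == ref
    return window_seq[:off] + alt + window_seq[off + len(ref) :]


@pytest.fixture(scope="session")
def top_hits_matrix():
    """Synthetic cohort reproducing the published top-hit carrier tables."""
    return fixture_matrix()


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*informative sites.*", category=UserWarning
        )
        warnings.filterwarnings(
            "ignore", message=".*no LOF flag.*", category=UserWarning
        )
        yield
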