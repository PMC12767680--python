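"""Independent oracles for the exact co-occurrence statistics.

Deliberately naive implementations: exact rational arithmetic and direct
enumeration / simulation, sharing no code with the package's dynamic
programming or Blaker routines.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np


def hypergeom_pmf_exact(N: int, K: int, n: int) -> list[Fraction]:
    """Exact pmf of the overlap of a fixed K-subset with a random n-subset,
    as Fractions over support 0..min(K, n)."""
    out = []
    for k in range(min(K, n) + 1):
        if k > K or n - k > N - K or n - k < 0:
            out.append(Fraction(0))
        else:
            out.append(Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n)))
    return out


def blaker_p_exact(pmf: list[Fraction], observed: int) -> Fraction:
    """Blaker two-sided p-value in exact rational arithmetic."""
    m = len(pmf)
    cdf = [sum(pmf[: i + 1]) for i in range(m)]
    sf = [sum(pmf[i:]) for i in range(m)]
    gamma = [min(c, s) for c, s in zip(cdf, sf)]
    g_obs = gamma[observed]
    return sum(p for p, g in zip(pmf, gamma) if g <= g_obs)


def intersection_pmf_enumerate(N: int, sizes: tuple[int, ...]) -> np.ndarray:
    """Exact intersection-size pmf by enumerating all subset tuples.

    Only feasible for tiny N; used as a ground-truth check of the chained
    hypergeometric recursion.
    """
    universe = range(N)
    total = 0
    counts = np.zeros(min(sizes) + 1, dtype=object)
    pools = [list(itertools.combinations(universe, s)) for s in sizes]
    for combo in itertools.product(*pools):
        inter = set(combo[0])
        for c in combo[1:]:
            inter &= set(c)
        counts[len(inter)] += 1
        total += 1
    return (counts / total).astype(float)


def intersection_sizes_montecarlo(
    N: int, sizes: tuple[int, ...], draws: int, seed: int, chunk: int = 50_000
) -> np.ndarray:
    """Simulated pmf of |A1 ∩ … ∩ Am| for independent random subsets."""
    rng = np.random.default_rng(seed)
    hist = np.zeros(min(sizes) + 1, dtype=np.int64)
    done = 0
    while done < draws:
        b = min(chunk, draws - done)
        member = np.ones((b, N), dtype=bool)
        for s in sizes:
            keys = rng.random((b, N))
            # the s smallest keys per row form a uniform random s-subset
            thresh = np.partition(keys, s - 1, axis=1)[:, s - 1 : s]
            member &= keys <= thresh
        inter = member.sum(axis=1)
        hist += np.bincount(inter, minlength=len(hist))[: len(hist)]
        done += b
    return hist / draws
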